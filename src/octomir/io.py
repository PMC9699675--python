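"""Readers and writers for the pipeline's on-disk formats.

All tabular writers emit a provenance header (``# octomir ...`` comment lines
with config hash and seed) followed by a plain TSV; readers skip ``#`` lines.
Sequences go through FASTA via Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .seed_targets import MatureMiRNA
from .synthetic import SyntheticConfig


def provenance_header(config_hash: str = "", seed: int | None = None) -> str:
    parts = [f"# octomir v{__version__}"]
    if config_hash:
        parts.append(f"# config_hash: {config_hash}")
    if seed is not None:
        parts.append(f"# seed: {seed}")
    return "\n".join(parts) + "\n"


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Mature miRNA FASTA; T is tolerated and converted to U."""
    out = []
    for name, seq in read_fasta(path).items():
        out.append(MatureMiRNA(name=name, mature_seq=seq.replace("T", "U")))
    return out


def write_tsv(
    path: str | Path,
    frame: pd.DataFrame,
    config_hash: str = "",
    seed: int | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash, seed))
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def load_config(path: str | Path) -> SyntheticConfig:
    """Load a SyntheticConfig from a YAML mapping (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "editing_fraction_range" in raw:
        raw["editing_fraction_range"] = tuple(raw["editing_fraction_range"])
    if "planted_rate_range" in raw:
        raw["planted_rate_range"] = tuple(raw["planted_rate_range"])
    return SyntheticConfig(**raw)
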