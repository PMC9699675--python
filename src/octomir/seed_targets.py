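"""MRE (miRNA response element) derivation, 3'UTR scanning and control 8-mers.

An MRE here is the strongest canonical site class (8mer-A1): the Watson-Crick
match to miRNA seed positions 2-8 written 5'->3' on the mRNA, followed by a
trailing adenosine. The trailing A is a positional feature recognized by the
silencing complex, not a base-pairing one, so it is held fixed when one-off
(editing-convertible) octamers are enumerated.

Control octamers preserve the dinucleotide multiset of the source MRE (an
Euler-path shuffle over the de Bruijn multigraph of dinucleotides) and must
also end in A so that the trailing-adenosine composition bias is matched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequtils import (
    RNA_ALPHABET,
    dinucleotide_counts,
    reverse_complement_rna_to_dna,
    validate_alphabet,
)

logger = logging.getLogger(__name__)

MRE_LENGTH = 8

AGE_CLASSES = (
    "bilaterian",
    "protostome",
    "lophotrochozoan+platytrochozoan",
    "mollusc-lineage",
    "cephalopod",
    "coleoid",
    "octopus",
)


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence with family and phylogenetic age class."""

    name: str
    mature_seq: str  # RNA alphabet
    family: str = ""
    age_class: str = "octopus"

    def __post_init__(self) -> None:
        if len(self.mature_seq) < MRE_LENGTH:
            raise ValueError(
                f"mature sequence of {self.name!r} is shorter than 8 nt "
                f"({len(self.mature_seq)} nt)"
            )
        validate_alphabet(self.mature_seq, RNA_ALPHABET, f"mature sequence of {self.name!r}")


@dataclass(frozen=True)
class Mre:
    """One miRNA's 8-mer response element (DNA, sense strand of the mRNA)."""

    mirna_name: str
    octamer: str

    def __post_init__(self) -> None:
        if len(self.octamer) != MRE_LENGTH:
            raise ValueError(f"octamer must be 8 nt, got {self.octamer!r}")
        if not self.octamer.endswith("A"):
            raise ValueError(f"MRE octamer must end in A, got {self.octamer!r}")


@dataclass(frozen=True)
class ControlOctamer:
    """A dinucleotide-preserving shuffle of an MRE, ending in A."""

    source_mre: Mre
    octamer: str


def derive_mre(mirna: MatureMiRNA) -> Mre:
    """Derive the 8mer-A1 response element of a mature miRNA.

    The site is the DNA reverse complement of miRNA positions 2-8 (1-based)
    followed by a trailing adenosine, read 5'->3' on the target mRNA.
    """
    seed = mirna.mature_seq[1:8]  # positions 2-8, 1-based
    return Mre(mirna_name=mirna.name, octamer=reverse_complement_rna_to_dna(seed) + "A")


def scan_utr(utr_seq: str, mre: Mre | str) -> list[int]:
    """All 0-based start positions of the octamer in a UTR, overlapping included.

    Windows containing N never match (exact string match; octamers are N-free).
    """
    octamer = mre.octamer if isinstance(mre, Mre) else mre
    hits: list[int] = []
    start = utr_seq.find(octamer)
    while start != -1:
        hits.append(start)
        start = utr_seq.find(octamer, start + 1)
    return hits


def _euler_paths(octamer: str) -> set[str]:
    """All strings with the same dinucleotide multiset and the same first letter.

    Dinucleotide-preserving permutations of a string are exactly the Euler paths
    of the de Bruijn multigraph whose edges are the string's dinucleotides,
    starting from the string's first character. k=8 gives at most 7 edges, so
    exhaustive depth-first enumeration is cheap.
    """
    edges: dict[str, list[str]] = {}
    for i in range(len(octamer) - 1):
        edges.setdefault(octamer[i], []).append(octamer[i + 1])
    for v in edges:
        edges[v] = sorted(edges[v])

    results: set[str] = set()
    n_edges = len(octamer) - 1

    def walk(node: str, used: dict[str, list[bool]], path: list[str]) -> None:
        if len(path) == n_edges + 1:
            results.add("".join(path))
            return
        succ = edges.get(node, [])
        seen: set[str] = set()
        for idx, nxt in enumerate(succ):
            if used[node][idx] or nxt in seen:
                continue
            seen.add(nxt)  # identical parallel edges yield identical paths
            used[node][idx] = True
            path.append(nxt)
            walk(nxt, used, path)
            path.pop()
            used[node][idx] = False

    used = {v: [False] * len(e) for v, e in edges.items()}
    walk(octamer[0], used, [octamer[0]])
    return results


def dinucleotide_shuffle(
    mre: Mre,
    n: int,
    annotated_mres: Iterable[str] = (),
    seed: int = 0,
) -> list[ControlOctamer]:
    """Sample up to ``n`` dinucleotide-preserving control octamers.

    Controls preserve the source's dinucleotide multiset, end in A (matching the
    trailing adenosine of real MREs), differ from the source, and avoid every
    annotated MRE. Sampling is without replacement from the full feasible set,
    deterministic for a given seed. An empty feasible set (e.g. a homopolymer)
    yields an explicit empty list with a logged warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    excluded = set(annotated_mres) | {mre.octamer}
    feasible = sorted(
        s for s in _euler_paths(mre.octamer) if s.endswith("A") and s not in excluded
    )
    if not feasible:
        logger.warning(
            "no feasible dinucleotide-preserving control for %s (%s)",
            mre.mirna_name,
            mre.octamer,
        )
        return []
    rng = np.random.default_rng(seed)
    take = min(n, len(feasible))
    chosen = rng.choice(len(feasible), size=take, replace=False)
    return [ControlOctamer(source_mre=mre, octamer=feasible[i]) for i in sorted(chosen)]


def one_off_precursors(mre: Mre | str) -> list[str]:
    """Genomic octamers one A-to-I editing event away from the MRE.

    Editing reads A as G, so the precursor of an MRE with a G at position i is
    the same octamer with that G replaced by A. An MRE with no G has no
    precursor. The trailing A is positional and never participates.
    """
    octamer = mre.octamer if isinstance(mre, Mre) else mre
    out = []
    for i, base in enumerate(octamer[:-1]):
        if base == "G":
            out.append(octamer[:i] + "A" + octamer[i + 1 :])
    return out


def g_to_a_controls(mre: Mre | str) -> list[str]:
    """Control direction: octamers convertible to the MRE by G-to-A substitution.

    These replace one non-terminal A of the MRE with G — a substitution that
    A-to-I editing cannot perform, so their conservation acts as a null for the
    one-off comparison. The trailing A is never substituted.
    """
    octamer = mre.octamer if isinstance(mre, Mre) else mre
    out = []
    for i, base in enumerate(octamer[:-1]):
        if base == "A":
            out.append(octamer[:i] + "G" + octamer[i + 1 :])
    return out
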