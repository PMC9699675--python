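"""Pairwise 3'UTR alignment and positional 8-mer conservation rates.

A k-mer occurrence in a reference UTR counts as conserved when the orthologous
UTR carries exactly the same k-mer at the homologous position, homology being
defined by a global pairwise alignment: the k reference positions must map to
k consecutive gap-free alignment columns whose ortholog characters spell the
identical k-mer. Any gap or mismatch inside the window breaks conservation —
an indel changes the site even when the flanks match.

Every occurrence is evaluated independently (multiple occurrences in the same
gene all count). Octamers seen fewer than ``min_occurrences`` times across the
alignment set are flagged ``excluded`` and should not enter downstream rate
panels. Occurrences whose window would run past the UTR end are excluded from
the occurrence count and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

MIN_OCCURRENCES = 10

# global affine-gap scoring, configurable via align_pair arguments
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5

GAP = -1  # sentinel in column maps


@dataclass
class OrthologUtrAlignment:
    """A gapped pairwise alignment of two orthologous 3'UTRs.

    ``colmap_ref[c]`` / ``colmap_orth[c]`` give the 0-based sequence coordinate
    at alignment column ``c``, or -1 at a gap.
    """

    gene_ref: str
    gene_orth: str
    aligned_ref: str
    aligned_orth: str
    colmap_ref: np.ndarray = field(default=None)  # type: ignore[assignment]
    colmap_orth: np.ndarray = field(default=None)  # type: ignore[assignment]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_orth):
            raise ValueError(
                f"gapped rows differ in length for {self.gene_ref}/{self.gene_orth}"
            )
        if self.colmap_ref is None:
            self.colmap_ref = _column_map(self.aligned_ref)
        if self.colmap_orth is None:
            self.colmap_orth = _column_map(self.aligned_orth)

    @property
    def ref_seq(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def orth_seq(self) -> str:
        return self.aligned_orth.replace("-", "")

    def ref_to_column(self) -> np.ndarray:
        """Array mapping reference coordinate -> alignment column."""
        cols = np.flatnonzero(np.frombuffer(self.aligned_ref.encode(), dtype=np.uint8) != ord("-"))
        return cols


def _column_map(gapped: str) -> np.ndarray:
    arr = np.frombuffer(gapped.encode(), dtype=np.uint8)
    is_res = arr != ord("-")
    out = np.cumsum(is_res) - 1
    out[~is_res] = GAP
    return out.astype(np.int64)


_ALIGNER_CACHE: dict[tuple[float, float, float, float], Align.PairwiseAligner] = {}


def _get_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (match, mismatch, gap_open, gap_extend)
    if key not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        # Biopython's affine model: first gap position costs open+extend
        aligner.open_gap_score = gap_open + gap_extend
        aligner.extend_gap_score = gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def align_pair(
    ref_utr: str,
    orth_utr: str,
    gene_ref: str = "ref",
    gene_orth: str = "orth",
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> OrthologUtrAlignment:
    """Global affine-gap alignment of an orthologous UTR pair.

    Deterministic: the first optimal alignment of the engine is always
    returned. Precomputed alignments (aligned FASTA) may be supplied instead
    through :class:`OrthologUtrAlignment` directly.
    """
    if not ref_utr or not orth_utr:
        raise ValueError("cannot align an empty sequence")
    aligner = _get_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(ref_utr, orth_utr)[0]
    ref_row, orth_row = str(aln[0]), str(aln[1])
    return OrthologUtrAlignment(
        gene_ref=gene_ref,
        gene_orth=gene_orth,
        aligned_ref=ref_row,
        aligned_orth=orth_row,
        score=float(aln.score),
    )


def is_conserved_occurrence(aln: OrthologUtrAlignment, pos_ref: int, octamer: str) -> bool:
    """True iff the k-mer at ``pos_ref`` is matched exactly at the homologous position.

    Requires the k reference positions to occupy k consecutive alignment
    columns, gap-free in both rows, with the ortholog characters spelling the
    same k-mer.
    """
    k = len(octamer)
    ref_len = len(aln.ref_seq)
    if pos_ref < 0 or pos_ref + k > ref_len:
        raise IndexError(f"window [{pos_ref}, {pos_ref + k}) out of range for {ref_len} nt UTR")
    cols = aln.ref_to_column()
    c0, c1 = cols[pos_ref], cols[pos_ref + k - 1]
    if c1 - c0 != k - 1:
        return False  # gap in the reference row inside the window
    window_ref = aln.aligned_ref[c0 : c1 + 1]
    window_orth = aln.aligned_orth[c0 : c1 + 1]
    if "-" in window_orth:
        return False
    return window_ref == octamer and window_orth == octamer


@dataclass
class KmerConservationRecord:
    """Aggregate conservation of one octamer across all reference UTRs."""

    octamer: str
    n_occurrences: int
    n_conserved: int
    n_truncated: int = 0  # windows running past the UTR end, not counted
    min_occurrences: int = MIN_OCCURRENCES

    @property
    def rate(self) -> float:
        if self.n_occurrences == 0:
            return float("nan")
        return self.n_conserved / self.n_occurrences

    @property
    def excluded(self) -> bool:
        return self.n_occurrences < self.min_occurrences


def conservation_rates(
    alignments: Iterable[OrthologUtrAlignment],
    octamer_set: Sequence[str],
    min_occurrences: int = MIN_OCCURRENCES,
) -> list[KmerConservationRecord]:
    """Positional conservation rate of each octamer over a set of UTR alignments."""
    if not octamer_set:
        raise ValueError("octamer_set must be nonempty")
    octamers = list(dict.fromkeys(octamer_set))
    n_occ = {o: 0 for o in octamers}
    n_cons = {o: 0 for o in octamers}
    n_trunc = {o: 0 for o in octamers}
    for aln in alignments:
        ref = aln.ref_seq
        for octamer in octamers:
            k = len(octamer)
            start = ref.find(octamer)
            while start != -1:
                if start + k <= len(ref):
                    n_occ[octamer] += 1
                    if is_conserved_occurrence(aln, start, octamer):
                        n_cons[octamer] += 1
                else:  # pragma: no cover - find never returns truncated hits
                    n_trunc[octamer] += 1
                start = ref.find(octamer, start + 1)
    return [
        KmerConservationRecord(
            octamer=o,
            n_occurrences=n_occ[o],
            n_conserved=n_cons[o],
            n_truncated=n_trunc[o],
            min_occurrences=min_occurrences,
        )
        for o in octamers
    ]
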