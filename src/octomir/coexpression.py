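"""Codetection classification, conservation contingency tables and group statistics.

A miRNA and an mRNA count as codetected (coexpressed) when at least one tissue
expresses both above threshold simultaneously — by default 100 CPM for the
miRNA and 10 CPM for the mRNA, comparisons inclusive. Sites are then split
into a 2x2 table (codetection x exact conservation), from which per-arm
conservation scores are computed. Score panels are standardized to Z scores
and compared with two-sided Mann-Whitney U tests under Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

MIRNA_CPM_THRESHOLD = 100.0
MRNA_CPM_THRESHOLD = 10.0


@dataclass(frozen=True)
class CodetectionRule:
    """Thresholds for calling a miRNA-mRNA pair codetected in at least one tissue."""

    mirna_threshold: float = MIRNA_CPM_THRESHOLD
    mrna_threshold: float = MRNA_CPM_THRESHOLD

    def __post_init__(self) -> None:
        if self.mirna_threshold <= 0 or self.mrna_threshold <= 0:
            raise ValueError("CPM thresholds must be positive")


@dataclass(frozen=True)
class MreSite:
    """One MRE occurrence with its conservation and codetection status."""

    mirna_name: str
    gene: str
    position: int
    conserved: bool
    codetected: bool


@dataclass
class ConservationTable:
    """2x2 codetection-by-conservation site counts with per-cell gene counts."""

    n_nocodetect_mismatch: int = 0
    n_nocodetect_match: int = 0
    n_codetect_mismatch: int = 0
    n_codetect_match: int = 0
    genes_nocodetect_mismatch: int = 0
    genes_nocodetect_match: int = 0
    genes_codetect_mismatch: int = 0
    genes_codetect_match: int = 0

    @property
    def total(self) -> int:
        return (
            self.n_nocodetect_mismatch
            + self.n_nocodetect_match
            + self.n_codetect_mismatch
            + self.n_codetect_match
        )


def cpm(counts: np.ndarray, library_sizes: np.ndarray | None = None) -> np.ndarray:
    """Counts-per-million normalization; library size defaults to column sums."""
    counts = np.asarray(counts, dtype=float)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return counts * 1e6 / np.asarray(library_sizes, dtype=float)


def classify_codetection(
    mirna_cpm_row: Sequence[float],
    mrna_cpm_row: Sequence[float],
    rule: CodetectionRule = CodetectionRule(),
) -> bool:
    """True iff some tissue has miRNA >= mirna_threshold and mRNA >= mrna_threshold."""
    m = np.asarray(mirna_cpm_row, dtype=float)
    g = np.asarray(mrna_cpm_row, dtype=float)
    if m.shape != g.shape:
        raise ValueError(f"tissue sets differ: {m.shape} vs {g.shape}")
    return bool(np.any((m >= rule.mirna_threshold) & (g >= rule.mrna_threshold)))


def build_table(sites: Iterable[MreSite]) -> ConservationTable:
    """Partition sites into the 2x2 codetection-by-conservation table.

    Each site increments exactly one cell; distinct genes per cell are counted
    alongside.
    """
    table = ConservationTable()
    genes: dict[tuple[bool, bool], set[str]] = {
        (False, False): set(),
        (False, True): set(),
        (True, False): set(),
        (True, True): set(),
    }
    for site in sites:
        key = (site.codetected, site.conserved)
        genes[key].add(site.gene)
        if key == (False, False):
            table.n_nocodetect_mismatch += 1
        elif key == (False, True):
            table.n_nocodetect_match += 1
        elif key == (True, False):
            table.n_codetect_mismatch += 1
        else:
            table.n_codetect_match += 1
    table.genes_nocodetect_mismatch = len(genes[(False, False)])
    table.genes_nocodetect_match = len(genes[(False, True)])
    table.genes_codetect_mismatch = len(genes[(True, False)])
    table.genes_codetect_match = len(genes[(True, True)])
    return table


def conservation_scores(table: ConservationTable) -> tuple[float | None, float | None]:
    """Per-arm conservation scores (codetected, non-codetected).

    Each score is exact-matches / all-sites within the arm. An empty arm yields
    ``None`` (undefined), never 0.
    """
    def _score(match: int, mismatch: int) -> float | None:
        denom = match + mismatch
        return match / denom if denom else None

    return (
        _score(table.n_codetect_match, table.n_codetect_mismatch),
        _score(table.n_nocodetect_match, table.n_nocodetect_mismatch),
    )


def zscore_panel(rates: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Standardize a panel of conservation rates to Z scores.

    The mean and (population) standard deviation are taken over every defined
    rate in the panel — MREs and their controls together form one population,
    which centres control bars near zero.
    """
    defined = [(label, r) for label, r in rates if r is not None and not math.isnan(r)]
    if len(defined) < 2:
        raise ValueError("need at least 2 defined rates to standardize")
    values = np.array([r for _, r in defined], dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot standardize a panel with zero variance")
    mean = values.mean()
    return [(label, (r - mean) / sd) for label, r in defined]


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    u_statistic: float
    p_raw: float
    p_bonferroni: float
    label: str


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Two-sided Mann-Whitney U for every group pair, Bonferroni-corrected.

    The correction factor is the number of pairwise comparisons actually
    performed; corrected p-values are capped at 1.
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) == 0:
            raise ValueError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out: list[GroupComparison] = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            # fully tied data carry no rank information
            u_stat, p_raw = len(xa) * len(xb) / 2, 1.0
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            u_stat, p_raw = float(res.statistic), float(res.pvalue)
        p_corr = min(1.0, p_raw * m)
        out.append(
            GroupComparison(
                group_a=a,
                group_b=b,
                u_statistic=u_stat,
                p_raw=p_raw,
                p_bonferroni=p_corr,
                label=significance_label(p_corr),
            )
        )
    return out
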