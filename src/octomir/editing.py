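"""A-to-I editing site calling, editing indices and MRE/editing intersection.

Inosine is read as guanosine by sequencers, so editing appears as A-reference
positions with G-containing reads. A position is called an editing site when
it has strictly more than 10 mapped reads, at least 3 of them G, and is absent
from the DNA-variant exclusion set (RNA-only variants; genomic SNPs are not
editing). The per-feature editing index is the total number of sequenced
guanosines divided by the total number of sequenced adenosines-plus-guanosines
over all reference-A positions — i.e. the coverage-weighted mean per-site G
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import seed_targets

MIN_COVERAGE = 11  # "more than 10 mapping reads", strict
MIN_G = 3


@dataclass(frozen=True)
class EditingPileup:
    """Base counts at one reference position of a feature."""

    feature: str
    position: int  # 0-based
    ref_base: str
    a: int
    c: int
    g: int
    t: int
    in_dna_variants: bool = False

    @property
    def coverage(self) -> int:
        return self.a + self.c + self.g + self.t


@dataclass(frozen=True)
class EditingSite:
    feature: str
    position: int
    g_fraction: float  # G / (A + G)


def call_editing_sites(
    pileups: Iterable[EditingPileup],
    min_coverage: int = MIN_COVERAGE,
    min_g: int = MIN_G,
) -> list[EditingSite]:
    """Call A-to-I editing sites from reference-A pileups.

    A site requires ref A, coverage >= ``min_coverage`` (default 11, the strict
    reading of "more than 10"), G count >= ``min_g``, and no DNA-variant flag.
    """
    sites = []
    for p in pileups:
        if p.ref_base != "A" or p.in_dna_variants:
            continue
        if p.coverage < min_coverage or p.g < min_g:
            continue
        denom = p.a + p.g
        sites.append(EditingSite(p.feature, p.position, p.g / denom if denom else 0.0))
    return sites


def editing_index(pileups: Iterable[EditingPileup]) -> float | None:
    """Editing index of one feature: sum(G) / sum(A + G) over reference-A positions.

    C/T reads at reference-A positions are treated as sequencing error and
    excluded from the denominator. Returns ``None`` when no reference-A
    position is covered.
    """
    total_g = 0
    total_ag = 0
    for p in pileups:
        if p.ref_base != "A":
            continue
        total_g += p.g
        total_ag += p.a + p.g
    if total_ag == 0:
        return None
    return total_g / total_ag


def mirna_seed_editing(
    mirna_pileups: Mapping[str, Sequence[EditingPileup]],
    min_coverage: int = MIN_COVERAGE,
) -> dict[str, float | None]:
    """Maximum seed G proportion per miRNA.

    For each miRNA, over reference-A positions 2-8 (1-based) with coverage
    strictly above 10 reads, report the maximum proportion of G reads
    (G / total reads at the position). ``None`` when no seed A qualifies.
    """
    out: dict[str, float | None] = {}
    for name, pileups in mirna_pileups.items():
        best: float | None = None
        for p in pileups:
            if p.ref_base != "A" or not (1 <= p.position <= 7):  # 0-based 1..7
                continue
            if p.coverage < min_coverage:
                continue
            frac = p.g / p.coverage
            if best is None or frac > best:
                best = frac
        out[name] = best
    return out


@dataclass(frozen=True)
class MreEditingOverlap:
    n_mres_considered: int
    n_mres_edited: int

    @property
    def fraction(self) -> float:
        if self.n_mres_considered == 0:
            return float("nan")
        return self.n_mres_edited / self.n_mres_considered


def mre_editing_overlap(
    conserved_mres: Sequence[tuple[str, int]],
    editing_sites: Iterable[EditingSite],
    coverage: Mapping[str, Sequence[float]],
    min_coverage: int = MIN_COVERAGE,
    mode: str = "mean",
    k: int = seed_targets.MRE_LENGTH,
) -> MreEditingOverlap:
    """Intersect conserved MRE windows with called editing sites.

    ``conserved_mres`` are (feature, 0-based start) windows of length ``k``;
    ``coverage`` maps feature -> per-position read coverage. Windows whose
    mean (or, with ``mode="min"``, minimum) coverage is below ``min_coverage``
    are excluded from the denominator. The result counts windows overlapping
    at least one called editing site.
    """
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    edited_positions: dict[str, set[int]] = {}
    for s in editing_sites:
        edited_positions.setdefault(s.feature, set()).add(s.position)
    considered = 0
    edited = 0
    for feature, start in conserved_mres:
        cov = np.asarray(coverage[feature], dtype=float)[start : start + k]
        stat = cov.mean() if mode == "mean" else cov.min()
        if stat < min_coverage:
            continue
        considered += 1
        window = range(start, start + k)
        if any(pos in edited_positions.get(feature, ()) for pos in window):
            edited += 1
    return MreEditingOverlap(n_mres_considered=considered, n_mres_edited=edited)


def one_off_conservation_comparison(
    alignments,
    mre_octamers: Sequence[str],
    n_controls_per_mre: int = 5,
    shuffle_seed: int = 0,
    min_occurrences: int = 10,
) -> dict[str, list[float]]:
    """Conservation-rate panels for one-off MREs, shuffled controls and G-to-A controls.

    One-off MREs are genomic octamers a single A-to-I event away from a real
    MRE; G-to-A controls are octamers one (editing-impossible) G-to-A
    substitution away. Shuffled controls preserve dinucleotide composition of
    the one-off set. Rates come from :func:`octomir.conservation.conservation_rates`
    on each class; octamers below the occurrence floor are dropped.
    """
    from .conservation import conservation_rates
    from .seed_targets import ControlOctamer, Mre, dinucleotide_shuffle

    mre_set = set(mre_octamers)
    one_off: list[str] = []
    gtoa: list[str] = []
    for octamer in mre_octamers:
        one_off.extend(o for o in seed_targets.one_off_precursors(octamer) if o not in mre_set)
        gtoa.extend(o for o in seed_targets.g_to_a_controls(octamer) if o not in mre_set)
    shuffled: list[str] = []
    for octamer in one_off:
        # one-off precursors keep the trailing A, so the MRE shuffle applies
        mre = Mre(mirna_name="one-off", octamer=octamer)
        shuffled.extend(
            c.octamer
            for c in dinucleotide_shuffle(mre, n_controls_per_mre, mre_set, seed=shuffle_seed)
        )
    panels: dict[str, list[float]] = {}
    alignments = list(alignments)
    for name, octs in (("one_off", one_off), ("shuffled", shuffled), ("g_to_a", gtoa)):
        uniq = list(dict.fromkeys(octs))
        if not uniq:
            panels[name] = []
            continue
        records = conservation_rates(alignments, uniq, min_occurrences=min_occurrences)
        panels[name] = [r.rate for r in records if not r.excluded]
    return panels
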