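"""Mappability-adjusted exon-skipping (rES) and intron-retention (rIR) rates.

For every internal exon E2 with neighbours E1 and E3, three junction
sequences are built by concatenating up to 42 nt from each side: E1E2, E2E3
(inclusion) and E1E3 (skipping). Intron-retention triplets (E1, intron, E2)
yield E1I, IE2 (retention) and E1E2 (splicing). Effective mappability of a
junction is the number of its fully contained 50-mers that occur exactly once
across the whole junction set (at most 84 - 50 + 1 = 35 for a full-length
junction); read counts are adjusted by 35/m, and triplets with any junction
below mappability 20 are excluded.

    rES = N_E1E3 / ((N_E1E2 + N_E2E3)/2 + N_E1E3)
    rIR = mean(N_E1I, N_IE2) / (mean(N_E1I, N_IE2) + N_E1E2)

on adjusted counts. The cross-tissue protocol subsamples 1000 eligible
triplets and exactly 25,000 reads per repetition, 100 repetitions per tissue.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

FLANK = 42
KMER = 50
MAX_MAPPABILITY = 2 * FLANK - KMER + 1  # 35
MIN_MAPPABILITY = 20
MIN_MAJOR_READS = 5

ES = "ES"
IR = "IR"


@dataclass
class JunctionTriplet:
    """Three junctions of an exon-skipping or intron-retention triplet.

    For ES the junction order is (E1E2, E2E3, E1E3); for IR it is
    (E1I, IE2, E1E2). ``counts`` are raw junction read counts; ``mappability``
    holds the per-junction effective mappability (0-35).
    """

    triplet_id: str
    kind: str  # ES or IR
    junctions: tuple[str, str, str]
    counts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mappability: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (ES, IR):
            raise ValueError(f"kind must be ES or IR, got {self.kind!r}")
        if any(len(j) > 2 * FLANK for j in self.junctions):
            raise ValueError("junction longer than 84 nt")

    @property
    def passes_mappability(self) -> bool:
        return self.mappability is not None and min(self.mappability) >= MIN_MAPPABILITY

    def adjusted_counts(self) -> tuple[float, float, float]:
        """Raw counts scaled by 35/mappability per junction."""
        if self.mappability is None:
            raise ValueError(f"mappability not computed for {self.triplet_id}")
        out = []
        for n, m in zip(self.counts, self.mappability):
            if m == 0:
                out.append(float("nan") if n else 0.0)
            else:
                out.append(n * MAX_MAPPABILITY / m)
        return tuple(out)

    @property
    def major_reads(self) -> float:
        """Raw reads on the major junctions (inclusion for ES, intron for IR)."""
        return self.counts[0] + self.counts[1]


@dataclass(frozen=True)
class RateEstimate:
    triplet_id: str
    rate: float | None
    n_effective_reads: float


def _junction(left: str, right: str) -> str:
    return left[-FLANK:] + right[:FLANK]


def build_triplets(
    transcripts: Mapping[str, Sequence[tuple[str, str]]] | Mapping[str, Sequence[str]],
    kind: str = ES,
) -> list[JunctionTriplet]:
    """Build nonredundant junction triplets from per-transcript sequence lists.

    ``transcripts`` maps transcript id to its ordered exon sequences (for ES)
    or to the ordered alternation exon1, intron1, exon2, ... (for IR). Triplets
    shared between transcripts (identical junction sequences) are emitted once.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[JunctionTriplet] = []
    for tx, parts in transcripts.items():
        parts = list(parts)
        if kind == ES:
            exons = parts
            for i in range(len(exons) - 2):
                e1, e2, e3 = exons[i], exons[i + 1], exons[i + 2]
                js = (_junction(e1, e2), _junction(e2, e3), _junction(e1, e3))
                if js in seen:
                    continue
                seen.add(js)
                out.append(JunctionTriplet(f"{tx}:ES:{i}", ES, js))
        elif kind == IR:
            # parts alternate exon, intron, exon, intron, ...
            if len(parts) % 2 == 0:
                raise ValueError(f"transcript {tx!r}: IR input must alternate exon/intron/exon")
            for i in range(0, len(parts) - 2, 2):
                e1, intron, e2 = parts[i], parts[i + 1], parts[i + 2]
                js = (_junction(e1, intron), _junction(intron, e2), _junction(e1, e2))
                if js in seen:
                    continue
                seen.add(js)
                out.append(JunctionTriplet(f"{tx}:IR:{i // 2}", IR, js))
        else:
            raise ValueError(f"kind must be ES or IR, got {kind!r}")
    return out


def triplets_from_gff(gff_path: str, genome: Mapping[str, str], kind: str = ES) -> list[JunctionTriplet]:
    """Extract triplets from a GFF3 annotation and a genome sequence dict."""
    import gffutils

    db = gffutils.create_db(
        gff_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: dict[str, list[str]] = {}
    for tx in db.features_of_type("mRNA"):
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
        seqs: list[str] = []
        prev_end = None
        for ex in exons:
            if prev_end is not None and kind == IR:
                seqs.append(genome[ex.seqid][prev_end : ex.start - 1])  # intron
            seqs.append(genome[ex.seqid][ex.start - 1 : ex.end])
            prev_end = ex.end
        transcripts[tx.id] = seqs
    return build_triplets(transcripts, kind=kind)


def effective_mappability(
    triplet: JunctionTriplet,
    kmer_occurrences: Mapping[str, int],
) -> tuple[int, int, int]:
    """Per-junction count of uniquely occurring contained 50-mers.

    ``kmer_occurrences`` maps each 50-mer to its total occurrence count across
    the full junction set (see :func:`count_kmer_occurrences`). A 50-mer counts
    toward mappability only when it occurs exactly once in the whole set.
    """
    ms = []
    for j in triplet.junctions:
        m = 0
        for i in range(len(j) - KMER + 1):
            if kmer_occurrences.get(j[i : i + KMER], 0) == 1:
                m += 1
        ms.append(m)
    return tuple(ms)


def count_kmer_occurrences(triplets: Iterable[JunctionTriplet]) -> Counter:
    """Occurrence count of every contained 50-mer across all junctions."""
    counts: Counter = Counter()
    for t in triplets:
        for j in t.junctions:
            for i in range(len(j) - KMER + 1):
                counts[j[i : i + KMER]] += 1
    return counts


def annotate_mappability(triplets: Sequence[JunctionTriplet]) -> list[JunctionTriplet]:
    """Compute and attach effective mappability for a whole triplet set."""
    occ = count_kmer_occurrences(triplets)
    return [replace(t, mappability=effective_mappability(t, occ)) for t in triplets]


def _rate(major_mean: float, alt: float, triplet_id: str) -> RateEstimate:
    denom = major_mean + alt
    if denom == 0:
        return RateEstimate(triplet_id, None, 0.0)
    return RateEstimate(triplet_id, alt / denom, denom)


def res_rate(triplet: JunctionTriplet) -> RateEstimate:
    """Exon-skipping rate on mappability-adjusted counts."""
    if triplet.kind != ES:
        raise ValueError(f"{triplet.triplet_id} is not an ES triplet")
    if any(c < 0 for c in triplet.counts):
        raise ValueError("negative junction counts")
    n12, n23, n13 = triplet.adjusted_counts()
    return _rate((n12 + n23) / 2, n13, triplet.triplet_id)


def rir_rate(triplet: JunctionTriplet) -> RateEstimate:
    """Intron-retention rate on mappability-adjusted counts."""
    if triplet.kind != IR:
        raise ValueError(f"{triplet.triplet_id} is not an IR triplet")
    if any(c < 0 for c in triplet.counts):
        raise ValueError("negative junction counts")
    n_e1i, n_ie2, n_e1e2 = triplet.adjusted_counts()
    intron_mean = (n_e1i + n_ie2) / 2
    return _rate(n_e1e2, intron_mean, triplet.triplet_id)


def rate(triplet: JunctionTriplet) -> RateEstimate:
    return res_rate(triplet) if triplet.kind == ES else rir_rate(triplet)


def eligible_triplets(
    triplets: Sequence[JunctionTriplet],
    min_major_reads: int = MIN_MAJOR_READS,
) -> list[JunctionTriplet]:
    """Triplets passing the mappability filter with enough major-junction reads."""
    return [
        t
        for t in triplets
        if t.passes_mappability and t.major_reads >= min_major_reads
    ]


def subsample_tissue_rates(
    triplets_by_tissue: Mapping[str, Sequence[JunctionTriplet]],
    n_triplets: int = 1000,
    n_reads: int = 25000,
    n_reps: int = 100,
    seed: int = 0,
    min_major_reads: int = MIN_MAJOR_READS,
) -> dict[str, np.ndarray]:
    """Per-tissue distributions of mean splicing rates under read subsampling.

    Each repetition samples ``n_triplets`` eligible triplets without
    replacement, draws exactly ``n_reads`` reads multinomially over the raw
    junction counts of the sampled triplets, applies the mappability
    adjustment to the drawn counts, computes each triplet's rate and records
    the mean over defined rates. Returns ``n_reps`` values per tissue;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for tissue in triplets_by_tissue:
        eligible = eligible_triplets(triplets_by_tissue[tissue], min_major_reads)
        if len(eligible) < n_triplets:
            raise ValueError(
                f"tissue {tissue!r}: only {len(eligible)} eligible triplets, "
                f"need {n_triplets}"
            )
        raw = np.array([t.counts for t in eligible], dtype=float)  # (T, 3)
        mapp = np.array([t.mappability for t in eligible], dtype=float)
        kinds = np.array([t.kind for t in eligible])
        means = np.empty(n_reps)
        for rep in range(n_reps):
            idx = rng.choice(len(eligible), size=n_triplets, replace=False)
            probs = raw[idx].ravel()
            total = probs.sum()
            if total == 0:
                raise ValueError(f"tissue {tissue!r}: sampled triplets carry no reads")
            drawn = rng.multinomial(n_reads, probs / total).reshape(n_triplets, 3)
            adj = drawn * MAX_MAPPABILITY / mapp[idx]
            major = (adj[:, 0] + adj[:, 1]) / 2
            with np.errstate(invalid="ignore"):
                is_es = kinds[idx] == ES
                rates = np.where(
                    is_es,
                    adj[:, 2] / (major + adj[:, 2]),
                    major / (major + adj[:, 2]),
                )
            means[rep] = np.nanmean(rates)
        out[tissue] = means
    return out
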