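"""Clustering of 3'-end tags into cleavage sites and poly(A)-signal assignment.

Long-read 3'-end tags (one genomic position + molecule count each) are merged
in two passes: single-linkage merging of tags closer than 20 bp, assigning all
counts to the most supported member ("most implicated site", ties broken
toward the 3'-most position on the tag's strand); then clusters whose
representatives lie less than 40 nt apart are merged, keeping the
higher-count representative. Retained cleavage sites must connect to an
upstream gene either through continuous short-read coverage of at least five
reads down to the stop codon or through a member read overlapping the stop
codon. The poly(A) signal is the hexamer in the 50 nt upstream of the
cleavage site, choosing the dataset-wide most abundant motif when several
match.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TAG_MERGE_DISTANCE = 20  # pass 1: tags closer than this are merged
CLUSTER_MERGE_DISTANCE = 40  # pass 2: representatives closer than this are merged
MIN_SPAN_COVERAGE = 5
PAS_WINDOW = 50

# Canonical metazoan poly(A) signal hexamers, strongest first.
DEFAULT_PAS_MOTIFS = (
    "AATAAA",
    "ATTAAA",
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
)


@dataclass(frozen=True)
class Tag:
    """One 3'-end tag: a cleavage position supported by ``count`` molecules."""

    contig: str
    position: int  # 0-based
    strand: str
    count: int
    read_start: int | None = None  # 5' end of a representative member read


@dataclass
class TagCluster:
    contig: str
    strand: str
    representative_position: int
    total_count: int
    member_positions: list[int]
    member_tags: list[Tag] = field(default_factory=list)


def _more_3prime(pos_a: int, pos_b: int, strand: str) -> bool:
    """True when pos_a is strictly 3' of pos_b on the given strand."""
    return pos_a > pos_b if strand == "+" else pos_a < pos_b


def _pick_representative(tags: Sequence[Tag]) -> int:
    best = tags[0]
    for t in tags[1:]:
        if t.count > best.count or (
            t.count == best.count and _more_3prime(t.position, best.position, t.strand)
        ):
            best = t
    return best.position


def cluster_tags(tags: Iterable[Tag]) -> list[TagCluster]:
    """Two-pass merge of 3'-end tags into cleavage-site clusters.

    Pass 1 chains tags on the same contig/strand with pairwise distance
    < 20 bp (single linkage) and assigns the chain's counts to its
    highest-count member. Pass 2 merges clusters whose representatives are
    < 40 nt apart, keeping the higher-count representative. Total counts are
    conserved by both passes. Deterministic.
    """
    by_group: dict[tuple[str, str], list[Tag]] = {}
    for t in tags:
        by_group.setdefault((t.contig, t.strand), []).append(t)

    clusters: list[TagCluster] = []
    for (contig, strand), group in sorted(by_group.items()):
        group = sorted(group, key=lambda t: t.position)
        # pass 1: single-linkage chains of tags < 20 bp apart
        chains: list[list[Tag]] = []
        for t in group:
            if chains and t.position - chains[-1][-1].position < TAG_MERGE_DISTANCE:
                chains[-1].append(t)
            else:
                chains.append([t])
        pass1 = [
            TagCluster(
                contig=contig,
                strand=strand,
                representative_position=_pick_representative(chain),
                total_count=sum(t.count for t in chain),
                member_positions=[t.position for t in chain],
                member_tags=list(chain),
            )
            for chain in chains
        ]
        # pass 2: merge clusters with representatives < 40 nt apart
        pass1.sort(key=lambda c: c.representative_position)
        merged: list[TagCluster] = []
        for c in pass1:
            if (
                merged
                and c.representative_position - merged[-1].representative_position
                < CLUSTER_MERGE_DISTANCE
            ):
                prev = merged[-1]
                keep_new = c.total_count > prev.total_count or (
                    c.total_count == prev.total_count
                    and _more_3prime(c.representative_position, prev.representative_position, strand)
                )
                rep = c.representative_position if keep_new else prev.representative_position
                merged[-1] = TagCluster(
                    contig=contig,
                    strand=strand,
                    representative_position=rep,
                    total_count=prev.total_count + c.total_count,
                    member_positions=prev.member_positions + c.member_positions,
                    member_tags=prev.member_tags + c.member_tags,
                )
            else:
                merged.append(c)
        clusters.extend(merged)
    return clusters


@dataclass(frozen=True)
class StopCodon:
    gene: str
    contig: str
    strand: str
    position: int  # 0-based first base of the stop codon


def _assign_upstream_stop(cluster: TagCluster, stops: Sequence[StopCodon]) -> StopCodon | None:
    """Nearest stop codon 5' of the cluster representative on the same contig/strand."""
    best: StopCodon | None = None
    for s in stops:
        if s.contig != cluster.contig or s.strand != cluster.strand:
            continue
        if not _more_3prime(cluster.representative_position, s.position, cluster.strand):
            continue
        if best is None or _more_3prime(s.position, best.position, cluster.strand):
            best = s
    return best


def filter_clusters(
    clusters: Sequence[TagCluster],
    rna_coverage: Mapping[str, Sequence[float]],
    stop_codons: Sequence[StopCodon],
    min_coverage: int = MIN_SPAN_COVERAGE,
) -> list[tuple[TagCluster, StopCodon]]:
    """Keep clusters connected to an upstream gene.

    A cluster is retained iff short-read coverage is >= ``min_coverage`` at
    every base between its representative and the assigned upstream stop
    codon, or a member read overlaps the stop codon. Clusters with no
    assignable upstream gene are dropped with a log message.
    """
    kept: list[tuple[TagCluster, StopCodon]] = []
    for cluster in clusters:
        stop = _assign_upstream_stop(cluster, stop_codons)
        if stop is None:
            logger.info(
                "cluster %s:%d has no assignable upstream gene; dropped",
                cluster.contig,
                cluster.representative_position,
            )
            continue
        stop_iv = (stop.position, stop.position + 3)  # 3 nt codon
        overlaps = False
        for t in cluster.member_tags:
            lo, hi = t.position, t.position
            if t.read_start is not None:
                lo, hi = min(lo, t.read_start), max(hi, t.read_start)
            if lo < stop_iv[1] and hi >= stop_iv[0]:
                overlaps = True
                break
        if overlaps:
            kept.append((cluster, stop))
            continue
        cov = np.asarray(rna_coverage.get(cluster.contig, ()), dtype=float)
        lo = min(cluster.representative_position, stop.position)
        hi = max(cluster.representative_position, stop.position)
        span = cov[lo : hi + 1]
        if len(span) == hi - lo + 1 and np.all(span >= min_coverage):
            kept.append((cluster, stop))
    return kept


def pas_dataset_frequencies(
    windows: Iterable[str],
    motifs: Sequence[str] = DEFAULT_PAS_MOTIFS,
) -> Counter:
    """Dataset-wide occurrence count of each PAS motif over upstream windows."""
    freq: Counter = Counter()
    for w in windows:
        for motif in motifs:
            if motif in w:
                freq[motif] += 1
    return freq


def upstream_window(
    cluster: TagCluster,
    contig_seq: str,
    window: int = PAS_WINDOW,
) -> str:
    """The up-to-50-nt sequence 5' of the cleavage site, in sense orientation."""
    pos = cluster.representative_position
    if cluster.strand == "+":
        return contig_seq[max(0, pos - window) : pos]
    from .sequtils import reverse_complement_dna

    return reverse_complement_dna(contig_seq[pos + 1 : pos + 1 + window])


def assign_pas(
    window_seq: str,
    dataset_frequencies: Mapping[str, int],
    motifs: Sequence[str] = DEFAULT_PAS_MOTIFS,
) -> str | None:
    """The PAS motif of a cleavage site, or None.

    Scans the upstream window for motifs; with several matches, returns the
    motif most abundant in the whole dataset (ties broken by motif-table
    order).
    """
    matches = [m for m in motifs if m in window_seq]
    if not matches:
        return None
    return max(matches, key=lambda m: (dataset_frequencies.get(m, 0), -motifs.index(m)))
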