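"""Synthetic data generation with known planted parameters.

Every input the pipeline consumes can be generated here: mature miRNAs,
orthologous 3'UTR pairs with planted response elements and a tunable
conservation differential between codetected and non-codetected sites,
tissue CPM matrices realizing the codetection labels, editing pileups with
planted per-site editing fractions plus a DNA-variant exclusion set,
junction-count triplets with planted skipping/retention rates, and clustered
3'-end tags. Everything is deterministic for a fixed config and seed; each
generator draws from its own independent stream spawned from ``rng_seed``.

The generative model is deliberately simple: i.i.d. uniform background
sequence, per-site substitutions and short (1-3 nt) indels between orthologs,
no rate heterogeneity along the UTR, no sequencing error beyond binomial
read sampling. What it shares with real data is the statistical structure the
downstream estimators measure: planted sites are conserved with exactly the
configured probability per codetection arm, editing G counts are binomial at
the planted fraction, and junction reads are multinomial at the planted rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import splicing
from .editing import EditingPileup
from .seed_targets import AGE_CLASSES, MRE_LENGTH, MatureMiRNA, derive_mre
from .sequtils import random_seq

logger = logging.getLogger(__name__)

_STREAM_MIRNAS = 1
_STREAM_TISSUES = 2
_STREAM_UTRS = 3
_STREAM_EXPRESSION = 4
_STREAM_EDITING = 5
_STREAM_JUNCTIONS = 6
_STREAM_TAGS = 7


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted parameters of the synthetic dataset.

    ``planted_conservation_coexpressed`` / ``_noncoexpressed`` are the
    per-site probabilities that a planted MRE survives intact in the ortholog,
    by codetection arm; the default differential (0.6 vs 0.4) mirrors the
    direction of the real effect (codetected sites more conserved).
    """

    n_genes: int = 500
    utr_length_median: float = 350.0  # median 3'UTR length, nt
    utr_length_sigma: float = 0.4  # log-normal shape
    substitution_rate: float = 0.05  # per site, between orthologs
    indel_rate: float = 0.01  # per site; indels are 1-3 nt
    n_mirnas: int = 20
    sites_per_gene: int = 2
    p_codetected: float = 0.5
    planted_conservation_coexpressed: float = 0.6
    planted_conservation_noncoexpressed: float = 0.4
    n_tissues: int = 8
    editing_fraction_range: tuple[float, float] = (0.01, 0.2)
    editing_site_density: float = 0.02  # fraction of reference-A positions edited
    editing_coverage: int = 50
    dna_variant_fraction: float = 0.01  # A positions flagged as genomic SNPs
    n_triplets: int = 300
    reads_per_triplet: int = 200
    planted_rate_range: tuple[float, float] = (0.02, 0.5)
    rng_seed: int = 0
    allow_inverted_effect: bool = False

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "indel_rate",
            "p_codetected",
            "planted_conservation_coexpressed",
            "planted_conservation_noncoexpressed",
            "editing_site_density",
            "dna_variant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.editing_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("editing_fraction_range must be a subinterval of [0, 1]")
        if (
            self.planted_conservation_coexpressed
            < self.planted_conservation_noncoexpressed
            and not self.allow_inverted_effect
        ):
            raise ValueError(
                "planted conservation for coexpressed sites is below the "
                "non-coexpressed rate; set allow_inverted_effect=True to invert "
                "the expected effect direction deliberately"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _rng(config: SyntheticConfig, stream: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream, extra])


def generate_mirnas(config: SyntheticConfig) -> list[MatureMiRNA]:
    """Random mature miRNAs, 20-23 nt RNA, unique names, cycling age classes."""
    rng = _rng(config, _STREAM_MIRNAS)
    mirnas = []
    for i in range(config.n_mirnas):
        length = int(rng.integers(20, 24))
        seq = random_seq(rng, length, "ACGU")
        mirnas.append(
            MatureMiRNA(
                name=f"syn-mir-{i + 1:03d}",
                mature_seq=seq,
                family=f"fam-{i + 1:03d}",
                age_class=AGE_CLASSES[i % len(AGE_CLASSES)],
            )
        )
    return mirnas


def mirna_tissue_assignment(config: SyntheticConfig, mirnas: Sequence[MatureMiRNA]) -> dict[str, int]:
    """The single tissue in which each synthetic miRNA is highly expressed.

    Shared between the UTR and expression generators so that codetection truth
    labels and the CPM matrices agree.
    """
    rng = _rng(config, _STREAM_TISSUES)
    return {m.name: int(rng.integers(0, config.n_tissues)) for m in mirnas}


@dataclass(frozen=True)
class PlantedSite:
    gene: str
    position: int  # 0-based start in the reference UTR
    mirna_name: str
    octamer: str
    codetected: bool
    conserved: bool


@dataclass
class SyntheticOrthologSet:
    """Reference/ortholog UTR pairs, the generative alignment, and planted truth."""

    ref_utrs: dict[str, str]
    orth_utrs: dict[str, str]
    true_alignments: dict[str, tuple[str, str]]  # gene -> (gapped ref, gapped orth)
    truth: list[PlantedSite]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.truth])


def _substitute(base: str, rng: np.random.Generator) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(0, 3))]


def generate_ortholog_pairs(
    config: SyntheticConfig,
    mirnas: Sequence[MatureMiRNA],
) -> SyntheticOrthologSet:
    """Plant MREs into random reference UTRs and derive mutated orthologs.

    Each planted site carries a codetection truth label (consistent per
    miRNA-gene pair and per gene/tissue constraint) and survives intact in the
    ortholog with the arm's planted conservation probability; non-conserved
    sites receive at least one substitution inside the octamer. Indels never
    fall inside planted octamers, so conservation is decided by substitutions
    alone. The generative alignment (gap annotation of every indel) is kept.
    """
    if not mirnas:
        raise ValueError("mirnas must be nonempty")
    rng = _rng(config, _STREAM_UTRS)
    tissue_of = mirna_tissue_assignment(config, mirnas)
    mres = {m.name: derive_mre(m).octamer for m in mirnas}
    mirna_names = [m.name for m in mirnas]

    ref_utrs: dict[str, str] = {}
    orth_utrs: dict[str, str] = {}
    true_alignments: dict[str, tuple[str, str]] = {}
    truth: list[PlantedSite] = []
    # codetection label per (gene, tissue) constraint; keeps pair labels
    # consistent with the single-high-tissue expression model
    pair_label: dict[tuple[str, str], bool] = {}

    mu = np.log(config.utr_length_median)
    for gi in range(config.n_genes):
        gene = f"gene{gi + 1:05d}"
        length = max(int(round(rng.lognormal(mu, config.utr_length_sigma))), 30)
        seq = list(random_seq(rng, length))

        planted: list[tuple[int, str, bool, bool]] = []  # start, mirna, codet, cons
        occupied: list[tuple[int, int]] = []
        gene_tissue_label: dict[int, bool] = {}
        n_sites = config.sites_per_gene
        if length < MRE_LENGTH:
            logger.warning("gene %s too short (%d nt) for any planted site", gene, length)
            n_sites = 0
        for _ in range(n_sites):
            name = mirna_names[int(rng.integers(0, len(mirna_names)))]
            placed = False
            for _attempt in range(50):
                start = int(rng.integers(0, length - MRE_LENGTH + 1))
                if all(start + MRE_LENGTH <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                logger.warning("gene %s: no room for another planted site; skipped", gene)
                continue
            occupied.append((start, start + MRE_LENGTH))
            tissue = tissue_of[name]
            key = (gene, name)
            if key in pair_label:
                codetected = pair_label[key]
            elif tissue in gene_tissue_label:
                codetected = gene_tissue_label[tissue]
            else:
                codetected = bool(rng.random() < config.p_codetected)
            pair_label[key] = codetected
            gene_tissue_label[tissue] = codetected
            p_cons = (
                config.planted_conservation_coexpressed
                if codetected
                else config.planted_conservation_noncoexpressed
            )
            conserved = bool(rng.random() < p_cons)
            octamer = mres[name]
            seq[start : start + MRE_LENGTH] = octamer
            planted.append((start, name, codetected, conserved))

        ref = "".join(seq)
        in_site = np.zeros(length, dtype=bool)
        disrupt_at: dict[int, set[int]] = {}
        for start, name, codetected, conserved in planted:
            in_site[start : start + MRE_LENGTH] = True
            truth.append(
                PlantedSite(
                    gene=gene,
                    position=start,
                    mirna_name=name,
                    octamer=mres[name],
                    codetected=codetected,
                    conserved=conserved,
                )
            )
            if not conserved:
                # at least one forced substitution inside the octamer
                positions = {
                    start + j
                    for j in range(MRE_LENGTH)
                    if rng.random() < config.substitution_rate
                }
                if not positions:
                    positions = {start + int(rng.integers(0, MRE_LENGTH))}
                disrupt_at[start] = positions

        forced = set().union(*disrupt_at.values()) if disrupt_at else set()
        ref_row: list[str] = []
        orth_row: list[str] = []
        i = 0
        while i < length:
            base = ref[i]
            if in_site[i]:
                if i in forced:
                    ref_row.append(base)
                    orth_row.append(_substitute(base, rng))
                else:
                    ref_row.append(base)
                    orth_row.append(base)
                i += 1
                continue
            r = rng.random()
            if r < config.indel_rate:
                ilen = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    # deletion in the ortholog (but never into a planted site)
                    j = i
                    while j < min(i + ilen, length) and not in_site[j]:
                        ref_row.append(ref[j])
                        orth_row.append("-")
                        j += 1
                    i = j
                else:
                    ins = random_seq(rng, ilen)
                    ref_row.extend("-" * ilen)
                    orth_row.extend(ins)
                    # the current reference base is then copied below
            elif r < config.indel_rate + config.substitution_rate:
                ref_row.append(base)
                orth_row.append(_substitute(base, rng))
                i += 1
            else:
                ref_row.append(base)
                orth_row.append(base)
                i += 1
        aligned_ref = "".join(ref_row)
        aligned_orth = "".join(orth_row)
        ref_utrs[gene] = ref
        orth_utrs[gene] = aligned_orth.replace("-", "")
        true_alignments[gene] = (aligned_ref, aligned_orth)
    return SyntheticOrthologSet(ref_utrs, orth_utrs, true_alignments, truth)


def generate_expression(
    config: SyntheticConfig,
    mirnas: Sequence[MatureMiRNA],
    genes: Sequence[str],
    truth: Sequence[PlantedSite],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CPM matrices (miRNA x tissue, gene x tissue) realizing the truth labels.

    Each miRNA is >= 100 CPM in exactly one tissue. A codetected pair's gene
    is given >= 10 CPM in that tissue; a non-codetected pair's gene is forced
    below 10 CPM there. All other entries are unconstrained background.
    """
    if config.n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    rng = _rng(config, _STREAM_EXPRESSION)
    tissue_of = mirna_tissue_assignment(config, mirnas)
    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]

    mirna_mat = rng.uniform(0.0, 90.0, size=(len(mirnas), config.n_tissues))
    for i, m in enumerate(mirnas):
        mirna_mat[i, tissue_of[m.name]] = rng.uniform(100.0, 2000.0)

    gene_index = {g: i for i, g in enumerate(genes)}
    mrna_mat = rng.lognormal(np.log(5.0), 1.0, size=(len(genes), config.n_tissues))
    for site in truth:
        t = tissue_of[site.mirna_name]
        gi = gene_index[site.gene]
        if site.codetected:
            mrna_mat[gi, t] = rng.uniform(10.0, 1000.0)
        else:
            mrna_mat[gi, t] = rng.uniform(0.0, 9.99)

    mirna_df = pd.DataFrame(mirna_mat, index=[m.name for m in mirnas], columns=tissues)
    mrna_df = pd.DataFrame(mrna_mat, index=list(genes), columns=tissues)
    return mirna_df, mrna_df


@dataclass
class SyntheticEditingSet:
    pileups: list[EditingPileup]
    dna_variants: set[tuple[str, int]]
    planted_fractions: dict[tuple[str, int], float]


def generate_editing_pileups(
    config: SyntheticConfig,
    utrs: Mapping[str, str],
) -> SyntheticEditingSet:
    """Binomial editing pileups over the reference-A positions of the UTRs.

    A configurable fraction of A positions receives a planted editing fraction
    drawn from ``editing_fraction_range``; another fraction is written into
    the DNA-variant set with a heterozygous-looking G proportion (~0.5) and
    must be rejected downstream as genomic SNPs.
    """
    rng = _rng(config, _STREAM_EDITING)
    pileups: list[EditingPileup] = []
    variants: set[tuple[str, int]] = set()
    fractions: dict[tuple[str, int], float] = {}
    lo, hi = config.editing_fraction_range
    cov = config.editing_coverage
    for gene in sorted(utrs):
        seq = utrs[gene]
        for pos, base in enumerate(seq):
            if base != "A":
                continue
            r = rng.random()
            if r < config.dna_variant_fraction:
                g = rng.binomial(cov, 0.5)
                variants.add((gene, pos))
                in_dna = True
                fractions[(gene, pos)] = float("nan")  # SNP, not editing
            elif r < config.dna_variant_fraction + config.editing_site_density:
                f = rng.uniform(lo, hi)
                g = rng.binomial(cov, f)
                in_dna = False
                fractions[(gene, pos)] = f
            else:
                g = 0
                in_dna = False
            pileups.append(
                EditingPileup(
                    feature=gene,
                    position=pos,
                    ref_base="A",
                    a=cov - int(g),
                    c=0,
                    g=int(g),
                    t=0,
                    in_dna_variants=in_dna,
                )
            )
    return SyntheticEditingSet(pileups, variants, fractions)


@dataclass
class SyntheticJunctionSet:
    triplets_by_tissue: dict[str, list[splicing.JunctionTriplet]]
    planted_rates: dict[str, float]  # triplet_id -> planted rES/rIR


def generate_junction_counts(
    config: SyntheticConfig,
    kind: str = splicing.ES,
    n_tissues: int = 1,
) -> SyntheticJunctionSet:
    """Junction triplets with multinomial read counts at planted rates.

    The same triplet sequences (and hence mappabilities) are shared across
    tissues; counts are drawn independently per tissue at the same planted
    rate, so tissues are exchangeable by construction. Junctions are built
    from 42 nt flanks of random exon/intron sequences.
    """
    rng = _rng(config, _STREAM_JUNCTIONS)
    planted: dict[str, float] = {}
    base: list[splicing.JunctionTriplet] = []
    lo, hi = config.planted_rate_range
    for i in range(config.n_triplets):
        e1, mid, e2 = (random_seq(rng, int(rng.integers(60, 200))) for _ in range(3))
        js = (
            splicing._junction(e1, mid),
            splicing._junction(mid, e2),
            splicing._junction(e1, e2),
        )
        tid = f"syn-{kind}-{i + 1:04d}"
        planted[tid] = float(rng.uniform(lo, hi))
        base.append(splicing.JunctionTriplet(tid, kind, js))

    by_tissue: dict[str, list[splicing.JunctionTriplet]] = {}
    for t in range(n_tissues):
        tissue = f"tissue{t + 1}"
        triplets: list[splicing.JunctionTriplet] = []
        for trip in base:
            r = planted[trip.triplet_id]
            # expected-rate-preserving allocation over (major, major, alt):
            # ES order (E1E2, E2E3, E1E3): alt = skip junction, r = s/(1+s)
            # IR order (E1I, IE2, E1E2): major = intron junctions, r = s/(1+s)
            if r >= 1.0:
                probs = (
                    np.array([0.0, 0.0, 1.0])
                    if kind == splicing.ES
                    else np.array([0.5, 0.5, 0.0])
                )
            else:
                s = r / (1.0 - r)
                probs = (
                    np.array([1.0, 1.0, s]) if kind == splicing.ES else np.array([s, s, 1.0])
                )
                probs = probs / probs.sum()
            counts = rng.multinomial(config.reads_per_triplet, probs)
            triplets.append(
                splicing.JunctionTriplet(
                    trip.triplet_id, kind, trip.junctions, tuple(float(c) for c in counts)
                )
            )
        by_tissue[tissue] = splicing.annotate_mappability(triplets)
    return SyntheticJunctionSet(by_tissue, planted)


def generate_tag_clusters(
    config: SyntheticConfig,
    n_sites: int = 50,
    contig_length: int = 100_000,
    tags_per_site: int = 5,
    site_spread: int = 8,
) -> tuple[list, list[int]]:
    """3'-end tags scattered around well-separated true cleavage sites.

    True sites are >= 200 bp apart, so the 20 bp / 40 nt merge rules must
    recover exactly one cluster per site. Returns (tags, true site positions).
    """
    from .polya import Tag

    rng = _rng(config, _STREAM_TAGS)
    sites = np.sort(
        rng.choice(np.arange(1000, contig_length - 1000, 200), size=n_sites, replace=False)
    )
    tags: list[Tag] = []
    for s in sites:
        offsets = rng.integers(-site_spread, site_spread + 1, size=tags_per_site)
        for off in np.unique(offsets):
            tags.append(
                Tag(
                    contig="chr1",
                    position=int(s + off),
                    strand="+",
                    count=int(rng.integers(1, 20)),
                )
            )
    return tags, [int(s) for s in sites]
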