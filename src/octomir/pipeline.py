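"""End-to-end orchestration of the synthetic-or-user-data analyses.

``run_conservation_analysis`` chains MRE derivation -> UTR alignment ->
occurrence scanning -> codetection classification -> contingency tables,
per-miRNA conservation scores, Z panels and Mann-Whitney group comparisons
(coexpressed vs non-coexpressed vs shuffled controls, and age-class strata).
``run_all`` additionally exercises the editing, splicing and poly(A) stages
on synthetic inputs and emits one machine-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, coexpression, conservation, editing, polya, seed_targets, splicing
from .synthetic import SyntheticConfig, SyntheticOrthologSet
from . import synthetic

logger = logging.getLogger(__name__)


def alignments_for(
    ortho: SyntheticOrthologSet,
    use_true_alignments: bool = False,
) -> dict[str, conservation.OrthologUtrAlignment]:
    """Pairwise alignments per gene, recomputed or taken from the generator."""
    out: dict[str, conservation.OrthologUtrAlignment] = {}
    for gene, ref in ortho.ref_utrs.items():
        if use_true_alignments:
            g_ref, g_orth = ortho.true_alignments[gene]
            out[gene] = conservation.OrthologUtrAlignment(gene, gene, g_ref, g_orth)
        else:
            out[gene] = conservation.align_pair(ref, ortho.orth_utrs[gene], gene, gene)
    return out


@dataclass
class ConservationAnalysisResult:
    per_mirna: pd.DataFrame  # mirna, age_class, cells, scores
    comparisons: list[coexpression.GroupComparison]
    age_comparisons: list[coexpression.GroupComparison]
    zscores: list[tuple[str, float]]
    control_rates: list[float]
    groups: dict[str, list[float]]


def run_conservation_analysis(
    config: SyntheticConfig,
    use_true_alignments: bool = False,
    n_controls_per_mre: int = 3,
) -> ConservationAnalysisResult:
    """The full coexpression-conditioned MRE conservation analysis on synthetic data."""
    mirnas = synthetic.generate_mirnas(config)
    if not mirnas:
        raise ValueError("conservation analysis requires at least one miRNA")
    ortho = synthetic.generate_ortholog_pairs(config, mirnas)
    mirna_expr, mrna_expr = synthetic.generate_expression(
        config, mirnas, list(ortho.ref_utrs), ortho.truth
    )
    alns = alignments_for(ortho, use_true_alignments)

    rule = coexpression.CodetectionRule()
    codet_cache: dict[tuple[str, str], bool] = {}

    def codetected(mirna_name: str, gene: str) -> bool:
        key = (mirna_name, gene)
        if key not in codet_cache:
            codet_cache[key] = coexpression.classify_codetection(
                mirna_expr.loc[mirna_name], mrna_expr.loc[gene], rule
            )
        return codet_cache[key]

    rows = []
    mre_octamers = []
    for mirna in mirnas:
        mre = seed_targets.derive_mre(mirna)
        mre_octamers.append(mre.octamer)
        sites = []
        for gene, aln in alns.items():
            for pos in seed_targets.scan_utr(aln.ref_seq, mre):
                sites.append(
                    coexpression.MreSite(
                        mirna_name=mirna.name,
                        gene=gene,
                        position=pos,
                        conserved=conservation.is_conserved_occurrence(aln, pos, mre.octamer),
                        codetected=codetected(mirna.name, gene),
                    )
                )
        table = coexpression.build_table(sites)
        score_co, score_nonco = coexpression.conservation_scores(table)
        rows.append(
            {
                "mirna": mirna.name,
                "age_class": mirna.age_class,
                "octamer": mre.octamer,
                "n_sites": table.total,
                "n_codetect_match": table.n_codetect_match,
                "n_codetect_mismatch": table.n_codetect_mismatch,
                "n_nocodetect_match": table.n_nocodetect_match,
                "n_nocodetect_mismatch": table.n_nocodetect_mismatch,
                "score_codetected": score_co,
                "score_noncodetected": score_nonco,
            }
        )
    per_mirna = pd.DataFrame(rows)

    # dinucleotide-preserving control octamers, pooled over all MREs
    controls: list[str] = []
    annotated = set(mre_octamers)
    for octamer in mre_octamers:
        mre = seed_targets.Mre(mirna_name="pooled", octamer=octamer)
        controls.extend(
            c.octamer
            for c in seed_targets.dinucleotide_shuffle(
                mre, n_controls_per_mre, annotated, seed=config.rng_seed
            )
        )
    controls = list(dict.fromkeys(controls))
    control_rates: list[float] = []
    if controls:
        records = conservation.conservation_rates(alns.values(), controls)
        control_rates = [r.rate for r in records if not r.excluded]

    groups = {
        "coexpressed": [float(r) for r in per_mirna["score_codetected"] if pd.notna(r)],
        "non_coexpressed": [
            float(r) for r in per_mirna["score_noncodetected"] if pd.notna(r)
        ],
    }
    if control_rates:
        groups["control"] = control_rates
    comparisons = coexpression.compare_groups(groups)

    panel = [("coexpressed:" + m, r) for m, r in zip(per_mirna["mirna"], per_mirna["score_codetected"])]
    panel += [(f"control:{o}", r) for o, r in zip(controls, control_rates)]
    try:
        zscores = coexpression.zscore_panel(panel)
    except ValueError:
        zscores = []

    age_groups: dict[str, list[float]] = {}
    for age, score in zip(per_mirna["age_class"], per_mirna["score_codetected"]):
        if score is not None:
            age_groups.setdefault(age, []).append(score)
    age_groups = {k: v for k, v in age_groups.items() if v}
    age_comparisons = (
        coexpression.compare_groups(age_groups) if len(age_groups) >= 2 else []
    )

    return ConservationAnalysisResult(
        per_mirna=per_mirna,
        comparisons=comparisons,
        age_comparisons=age_comparisons,
        zscores=zscores,
        control_rates=control_rates,
        groups=groups,
    )


@dataclass
class PlantedRecovery:
    rate_codetected: float
    rate_noncodetected: float
    n_codetected: int
    n_noncodetected: int
    per_mirna_codetected: dict[str, float]
    per_mirna_noncodetected: dict[str, float]
    comparison: coexpression.GroupComparison


def recover_planted_rates(
    config: SyntheticConfig,
    use_true_alignments: bool = False,
) -> PlantedRecovery:
    """Parameter recovery: measure conservation of the planted truth sites.

    Generates a synthetic dataset, measures each planted site's conservation
    through alignment and its codetection through the CPM matrices, and
    aggregates per arm. With enough sites the recovered rates estimate the
    planted per-arm conservation probabilities, and the per-miRNA score
    groups separate accordingly.
    """
    mirnas = synthetic.generate_mirnas(config)
    ortho = synthetic.generate_ortholog_pairs(config, mirnas)
    mirna_expr, mrna_expr = synthetic.generate_expression(
        config, mirnas, list(ortho.ref_utrs), ortho.truth
    )
    alns = alignments_for(ortho, use_true_alignments)
    rule = coexpression.CodetectionRule()

    arm_counts = {True: [0, 0], False: [0, 0]}  # codetected -> [conserved, total]
    per_mirna: dict[tuple[str, bool], list[int]] = {}
    codet_cache: dict[tuple[str, str], bool] = {}
    for site in ortho.truth:
        aln = alns[site.gene]
        conserved = conservation.is_conserved_occurrence(aln, site.position, site.octamer)
        key = (site.mirna_name, site.gene)
        if key not in codet_cache:
            codet_cache[key] = coexpression.classify_codetection(
                mirna_expr.loc[site.mirna_name], mrna_expr.loc[site.gene], rule
            )
        codet = codet_cache[key]
        arm_counts[codet][0] += int(conserved)
        arm_counts[codet][1] += 1
        acc = per_mirna.setdefault((site.mirna_name, codet), [0, 0])
        acc[0] += int(conserved)
        acc[1] += 1

    def _per_mirna_rates(codet: bool) -> dict[str, float]:
        return {
            m: c / n
            for (m, flag), (c, n) in per_mirna.items()
            if flag == codet and n > 0
        }

    rates_co = _per_mirna_rates(True)
    rates_nonco = _per_mirna_rates(False)
    comparison = coexpression.compare_groups(
        {"coexpressed": list(rates_co.values()), "non_coexpressed": list(rates_nonco.values())}
    )[0]
    return PlantedRecovery(
        rate_codetected=arm_counts[True][0] / max(arm_counts[True][1], 1),
        rate_noncodetected=arm_counts[False][0] / max(arm_counts[False][1], 1),
        n_codetected=arm_counts[True][1],
        n_noncodetected=arm_counts[False][1],
        per_mirna_codetected=rates_co,
        per_mirna_noncodetected=rates_nonco,
        comparison=comparison,
    )


def run_all(config: SyntheticConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on synthetic inputs; return (and optionally write) a report."""
    report: dict = {
        "version": __version__,
        "seed": config.rng_seed,
        "config_hash": config.config_hash(),
    }

    cons = run_conservation_analysis(config)
    report["conservation"] = {
        "n_mirnas": int(len(cons.per_mirna)),
        "n_sites": int(cons.per_mirna["n_sites"].sum()),
        "comparisons": [
            {
                "pair": f"{c.group_a} vs {c.group_b}",
                "p_raw": c.p_raw,
                "p_bonferroni": c.p_bonferroni,
                "label": c.label,
            }
            for c in cons.comparisons
        ],
    }

    mirnas = synthetic.generate_mirnas(config)
    ortho = synthetic.generate_ortholog_pairs(config, mirnas)
    edit_set = synthetic.generate_editing_pileups(config, ortho.ref_utrs)
    sites = editing.call_editing_sites(edit_set.pileups)
    by_feature: dict[str, list] = {}
    for p in edit_set.pileups:
        by_feature.setdefault(p.feature, []).append(p)
    indices = [editing.editing_index(ps) for ps in by_feature.values()]
    indices = [i for i in indices if i is not None]
    report["editing"] = {
        "n_pileup_positions": len(edit_set.pileups),
        "n_sites_called": len(sites),
        "mean_editing_index": float(np.mean(indices)) if indices else None,
    }

    jset = synthetic.generate_junction_counts(config, kind=splicing.ES, n_tissues=2)
    rates = {
        tissue: [
            r.rate
            for r in map(splicing.rate, splicing.eligible_triplets(trips))
            if r.rate is not None
        ]
        for tissue, trips in jset.triplets_by_tissue.items()
    }
    report["splicing"] = {
        tissue: {"n_triplets": len(v), "mean_rES": float(np.mean(v)) if v else None}
        for tissue, v in rates.items()
    }

    tags, true_sites = synthetic.generate_tag_clusters(config)
    clusters = polya.cluster_tags(tags)
    report["polya"] = {
        "n_tags": len(tags),
        "n_true_sites": len(true_sites),
        "n_clusters": len(clusters),
        "count_conserved": sum(c.total_count for c in clusters)
        == sum(t.count for t in tags),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_tsv

        write_tsv(
            outdir / "per_mirna_conservation.tsv",
            cons.per_mirna,
            config_hash=config.config_hash(),
            seed=config.rng_seed,
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
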