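"""Determinism, truth-table round trips and parameter recovery of the generators."""

import math

import numpy as np
import pytest

from octomir import coexpression, pipeline, synthetic
from octomir.synthetic import SyntheticConfig


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SyntheticConfig(substitution_rate=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=0)

    def test_inverted_effect_needs_explicit_override(self):
        with pytest.raises(ValueError, match="inverted"):
            SyntheticConfig(
                planted_conservation_coexpressed=0.3,
                planted_conservation_noncoexpressed=0.5,
            )
        cfg = SyntheticConfig(
            planted_conservation_coexpressed=0.3,
            planted_conservation_noncoexpressed=0.5,
            allow_inverted_effect=True,
        )
        assert cfg.planted_conservation_coexpressed == 0.3


class TestGenerateMirnas:
    def test_reproducible_and_well_formed(self):
        cfg = SyntheticConfig(n_mirnas=10, rng_seed=7)
        a = synthetic.generate_mirnas(cfg)
        b = synthetic.generate_mirnas(cfg)
        assert [m.mature_seq for m in a] == [m.mature_seq for m in b]
        assert len({m.name for m in a}) == 10
        for m in a:
            assert 20 <= len(m.mature_seq) <= 23
            assert set(m.mature_seq) <= set("ACGU")

    def test_zero_mirnas(self):
        assert synthetic.generate_mirnas(SyntheticConfig(n_mirnas=0)) == []

    def test_different_seeds_differ(self):
        # collision probability for ten 20+ nt sequences is < 4^-15
        a = synthetic.generate_mirnas(SyntheticConfig(n_mirnas=10, rng_seed=1))
        b = synthetic.generate_mirnas(SyntheticConfig(n_mirnas=10, rng_seed=2))
        assert {m.mature_seq for m in a} != {m.mature_seq for m in b}


class TestOrthologPairs:
    def test_byte_identical_under_fixed_seed(self):
        cfg = SyntheticConfig(n_genes=20, n_mirnas=4, rng_seed=5)
        mirnas = synthetic.generate_mirnas(cfg)
        a = synthetic.generate_ortholog_pairs(cfg, mirnas)
        b = synthetic.generate_ortholog_pairs(cfg, mirnas)
        assert a.ref_utrs == b.ref_utrs
        assert a.orth_utrs == b.orth_utrs
        assert a.truth == b.truth

    def test_true_alignment_ungaps_to_sequences(self):
        cfg = SyntheticConfig(n_genes=20, n_mirnas=4, indel_rate=0.05, rng_seed=6)
        mirnas = synthetic.generate_mirnas(cfg)
        out = synthetic.generate_ortholog_pairs(cfg, mirnas)
        for gene, (g_ref, g_orth) in out.true_alignments.items():
            assert g_ref.replace("-", "") == out.ref_utrs[gene]
            assert g_orth.replace("-", "") == out.orth_utrs[gene]
            assert len(g_ref) == len(g_orth)

    def test_planted_octamer_present_in_reference(self):
        cfg = SyntheticConfig(n_genes=30, n_mirnas=4, rng_seed=8)
        mirnas = synthetic.generate_mirnas(cfg)
        out = synthetic.generate_ortholog_pairs(cfg, mirnas)
        for s in out.truth:
            assert out.ref_utrs[s.gene][s.position : s.position + 8] == s.octamer

    def test_no_mutation_all_conserved_round_trip(self):
        """Mutation rates 0 and planted probabilities 1: every downstream
        classification matches the truth table exactly."""
        cfg = SyntheticConfig(
            n_genes=30,
            n_mirnas=4,
            substitution_rate=0.0,
            indel_rate=0.0,
            planted_conservation_coexpressed=1.0,
            planted_conservation_noncoexpressed=1.0,
            rng_seed=9,
        )
        rec = pipeline.recover_planted_rates(cfg)
        assert rec.rate_codetected == 1.0
        assert rec.rate_noncodetected == 1.0

    def test_all_disrupted_gives_rate_zero(self):
        cfg = SyntheticConfig(
            n_genes=30,
            n_mirnas=4,
            planted_conservation_coexpressed=0.0,
            planted_conservation_noncoexpressed=0.0,
            rng_seed=10,
        )
        rec = pipeline.recover_planted_rates(cfg)
        assert rec.rate_codetected == 0.0
        assert rec.rate_noncodetected == 0.0

    def test_parameter_recovery_within_3se(self):
        """Planted (0.6, 0.4) recovered within 3 binomial SE per arm."""
        cfg = SyntheticConfig(n_genes=600, sites_per_gene=4, rng_seed=12)
        rec = pipeline.recover_planted_rates(cfg, use_true_alignments=True)
        for rate, p, n in (
            (rec.rate_codetected, 0.6, rec.n_codetected),
            (rec.rate_noncodetected, 0.4, rec.n_noncodetected),
        ):
            assert n >= 1000
            assert abs(rate - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestExpression:
    def test_truth_labels_realized(self):
        cfg = SyntheticConfig(n_genes=50, n_mirnas=6, rng_seed=3)
        mirnas = synthetic.generate_mirnas(cfg)
        ortho = synthetic.generate_ortholog_pairs(cfg, mirnas)
        mi, mr = synthetic.generate_expression(cfg, mirnas, list(ortho.ref_utrs), ortho.truth)
        assert (mi.values >= 0).all() and (mr.values >= 0).all()
        for s in ortho.truth:
            got = coexpression.classify_codetection(mi.loc[s.mirna_name], mr.loc[s.gene])
            assert got == s.codetected

    def test_single_tissue_satisfiable(self):
        cfg = SyntheticConfig(n_genes=40, n_mirnas=3, n_tissues=1, rng_seed=4)
        mirnas = synthetic.generate_mirnas(cfg)
        ortho = synthetic.generate_ortholog_pairs(cfg, mirnas)
        mi, mr = synthetic.generate_expression(cfg, mirnas, list(ortho.ref_utrs), ortho.truth)
        labels = {s.codetected for s in ortho.truth}
        for s in ortho.truth:
            got = coexpression.classify_codetection(mi.loc[s.mirna_name], mr.loc[s.gene])
            assert got == s.codetected
        assert labels  # at least one label realized with a single tissue


class TestEditingPileups:
    def test_planted_fraction_binomial(self):
        f = 0.1
        cfg = SyntheticConfig(
            editing_site_density=1.0,
            dna_variant_fraction=0.0,
            editing_fraction_range=(f, f),
            editing_coverage=100,
            rng_seed=2,
        )
        out = synthetic.generate_editing_pileups(cfg, {"g": "A" * 200})
        gs = np.array([p.g for p in out.pileups])
        assert abs(gs.mean() - 10) < 3 * math.sqrt(100 * f * (1 - f) / 200)

    def test_zero_fraction_means_no_g(self):
        cfg = SyntheticConfig(
            editing_site_density=1.0,
            dna_variant_fraction=0.0,
            editing_fraction_range=(0.0, 0.0),
            rng_seed=2,
        )
        out = synthetic.generate_editing_pileups(cfg, {"g": "A" * 100})
        assert all(p.g == 0 for p in out.pileups)

    def test_dna_variants_excluded_from_calling(self):
        from octomir import editing

        cfg = SyntheticConfig(
            editing_site_density=0.0,
            dna_variant_fraction=1.0,
            editing_coverage=100,
            rng_seed=2,
        )
        out = synthetic.generate_editing_pileups(cfg, {"g": "A" * 50})
        assert out.dna_variants  # every A position flagged
        assert editing.call_editing_sites(out.pileups) == []


class TestJunctionCounts:
    def test_planted_zero_rate_no_skip_reads(self):
        cfg = SyntheticConfig(n_triplets=20, planted_rate_range=(0.0, 0.0), rng_seed=5)
        jset = synthetic.generate_junction_counts(cfg)
        for t in jset.triplets_by_tissue["tissue1"]:
            assert t.counts[2] == 0

    def test_planted_rate_one_all_skip_reads(self):
        from octomir import splicing

        cfg = SyntheticConfig(n_triplets=20, planted_rate_range=(1.0, 1.0), rng_seed=5)
        jset = synthetic.generate_junction_counts(cfg, kind=splicing.IR)
        for t in jset.triplets_by_tissue["tissue1"]:
            assert t.counts[2] == 0  # no spliced E1E2 reads
            assert splicing.rir_rate(t).rate == 1.0

    def test_determinism(self):
        cfg = SyntheticConfig(n_triplets=15, rng_seed=6)
        a = synthetic.generate_junction_counts(cfg)
        b = synthetic.generate_junction_counts(cfg)
        ta = a.triplets_by_tissue["tissue1"]
        tb = b.triplets_by_tissue["tissue1"]
        assert [(t.junctions, t.counts) for t in ta] == [(t.junctions, t.counts) for t in tb]
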