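"""Junction triplets, effective mappability, rES/rIR and tissue subsampling."""

import numpy as np
import pytest

from octomir import coexpression, splicing as sp
from octomir import synthetic

from .oracles import kmer_unique_counts


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestBuildTriplets:
    def test_three_exon_transcript_one_es_triplet(self, rng):
        tx = {"t1": [_random_seq(rng, 80) for _ in range(3)]}
        assert len(sp.build_triplets(tx, sp.ES)) == 1

    def test_two_exon_transcript(self, rng):
        exons = [_random_seq(rng, 80) for _ in range(2)]
        assert sp.build_triplets({"t1": exons}, sp.ES) == []
        parts = [exons[0], _random_seq(rng, 90), exons[1]]  # exon, intron, exon
        assert len(sp.build_triplets({"t1": parts}, sp.IR)) == 1

    def test_shared_triplet_nonredundant(self, rng):
        exons = [_random_seq(rng, 80) for _ in range(3)]
        trips = sp.build_triplets({"t1": exons, "t2": exons}, sp.ES)
        assert len(trips) == 1

    def test_short_exons_contribute_full_length(self, rng):
        tx = {"t1": [_random_seq(rng, 20), _random_seq(rng, 15), _random_seq(rng, 80)]}
        (t,) = sp.build_triplets(tx, sp.ES)
        assert len(t.junctions[0]) == 35  # 20 + 15
        assert all(len(j) <= 84 for j in t.junctions)


class TestGffExtraction:
    def test_triplets_from_gff3(self, rng, tmp_path):
        genome = {"chr1": _random_seq(rng, 2000)}
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t1000\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\t.\texon\t1\t100\t.\t+\t.\tID=e1;Parent=t1\n"
            "chr1\t.\texon\t201\t300\t.\t+\t.\tID=e2;Parent=t1\n"
            "chr1\t.\texon\t401\t500\t.\t+\t.\tID=e3;Parent=t1\n"
        )
        es = sp.triplets_from_gff(str(gff), genome, sp.ES)
        ir = sp.triplets_from_gff(str(gff), genome, sp.IR)
        assert len(es) == 1 and len(ir) == 2
        # E1E2 junction: 42 nt from the end of exon 1 + 42 nt from exon 2
        assert es[0].junctions[0] == genome["chr1"][58:100] + genome["chr1"][200:242]


class TestEffectiveMappability:
    def test_unique_84nt_junction_is_35(self, rng):
        tx = {"t1": [_random_seq(rng, 100) for _ in range(3)]}
        trips = sp.annotate_mappability(sp.build_triplets(tx, sp.ES))
        assert trips[0].mappability == (35, 35, 35)

    def test_duplicate_junctions_zero(self, rng):
        seq = _random_seq(rng, 84)
        t1 = sp.JunctionTriplet("a", sp.ES, (seq, _random_seq(rng, 84), _random_seq(rng, 84)))
        t2 = sp.JunctionTriplet("b", sp.ES, (seq, _random_seq(rng, 84), _random_seq(rng, 84)))
        out = sp.annotate_mappability([t1, t2])
        assert out[0].mappability[0] == 0 and out[1].mappability[0] == 0

    def test_60nt_junction_is_11(self, rng):
        tx = {"t1": [_random_seq(rng, 30), _random_seq(rng, 30), _random_seq(rng, 100)]}
        trips = sp.annotate_mappability(sp.build_triplets(tx, sp.ES))
        assert trips[0].mappability[0] == 60 - 50 + 1

    def test_agrees_with_brute_force_dictionary(self, rng):
        """100-junction synthetic set with planted duplications."""
        cfg = synthetic.SyntheticConfig(n_triplets=30, rng_seed=17)
        jset = synthetic.generate_junction_counts(cfg)
        trips = list(jset.triplets_by_tissue["tissue1"])
        # plant a duplicated junction and a shared-kmer pair
        dup = trips[0].junctions[0]
        trips.append(sp.JunctionTriplet("dup", sp.ES, (dup, _random_seq(rng, 84), _random_seq(rng, 84))))
        annotated = sp.annotate_mappability(trips)
        all_junctions = [j for t in annotated for j in t.junctions]
        assert len(all_junctions) >= 90
        counts = kmer_unique_counts(all_junctions)
        for t in annotated:
            for j, m in zip(t.junctions, t.mappability):
                expected = sum(
                    1
                    for i in range(len(j) - 50 + 1)
                    if counts[j[i : i + 50]] == 1
                )
                assert m == expected


class TestRates:
    def _trip(self, kind, counts, mapp=(35, 35, 35)):
        rng = np.random.default_rng(0)
        js = tuple(_random_seq(rng, 84) for _ in range(3))
        return sp.JunctionTriplet("t", kind, js, counts, mapp)

    def test_res_balanced_counts(self):
        assert sp.res_rate(self._trip(sp.ES, (10, 10, 10))).rate == pytest.approx(0.5)

    def test_res_zero_skipping(self):
        assert sp.res_rate(self._trip(sp.ES, (10, 10, 0))).rate == 0.0

    def test_res_mappability_adjustment_hand_case(self):
        # skip junction: 10 raw at m=20 -> 17.5 adjusted; inclusion 35 at m=35
        t = self._trip(sp.ES, (35, 35, 10), mapp=(35, 35, 20))
        assert sp.res_rate(t).rate == pytest.approx(1 / 3)

    def test_rir_balanced(self):
        assert sp.rir_rate(self._trip(sp.IR, (4, 4, 4))).rate == pytest.approx(0.5)

    def test_rir_zero_intron(self):
        assert sp.rir_rate(self._trip(sp.IR, (0, 0, 10))).rate == 0.0

    def test_rir_asymmetric_intron_counts(self):
        assert sp.rir_rate(self._trip(sp.IR, (6, 2, 4))).rate == pytest.approx(0.5)

    def test_rir_one_with_zero_splicing(self):
        assert sp.rir_rate(self._trip(sp.IR, (5, 5, 0))).rate == 1.0

    def test_denominator_zero_undefined(self):
        assert sp.res_rate(self._trip(sp.ES, (0, 0, 0))).rate is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sp.res_rate(self._trip(sp.ES, (-1, 1, 1)))

    def test_scale_invariance(self):
        a = sp.res_rate(self._trip(sp.ES, (3, 5, 7))).rate
        b = sp.res_rate(self._trip(sp.ES, (30, 50, 70))).rate
        assert a == pytest.approx(b)

    def test_res_monotone_in_skip_counts(self):
        rates = [sp.res_rate(self._trip(sp.ES, (10, 10, n))).rate for n in (0, 5, 10, 50)]
        assert rates == sorted(rates)

    def test_adjustment_identity_at_full_mappability(self):
        t = self._trip(sp.ES, (10, 20, 30))
        assert t.adjusted_counts() == (10, 20, 30)


class TestSubsampling:
    def _two_tissue_set(self, seed):
        cfg = synthetic.SyntheticConfig(
            n_triplets=400, reads_per_triplet=200, rng_seed=seed
        )
        return synthetic.generate_junction_counts(cfg, n_tissues=2)

    def test_deterministic_given_seed(self):
        jset = self._two_tissue_set(2)
        kwargs = dict(n_triplets=100, n_reads=5000, n_reps=3, seed=7)
        a = sp.subsample_tissue_rates(jset.triplets_by_tissue, **kwargs)
        b = sp.subsample_tissue_rates(jset.triplets_by_tissue, **kwargs)
        for tissue in a:
            np.testing.assert_array_equal(a[tissue], b[tissue])

    def test_identical_tissues_indistinguishable(self):
        """Tissues generated at the same planted parameters: Mann-Whitney
        n.s. in at least 2 of 3 seeds."""
        ns = 0
        for seed in (0, 1, 2):
            jset = self._two_tissue_set(seed)
            dists = sp.subsample_tissue_rates(
                jset.triplets_by_tissue, n_triplets=300, n_reads=10_000, n_reps=50, seed=seed
            )
            (cmp,) = coexpression.compare_groups(
                {t: list(v) for t, v in dists.items()}
            )
            ns += cmp.label == "n.s."
        assert ns >= 2

    def test_too_few_eligible_triplets_rejected(self):
        jset = self._two_tissue_set(3)
        with pytest.raises(ValueError, match="eligible"):
            sp.subsample_tissue_rates(jset.triplets_by_tissue, n_triplets=10_000)

    def test_planted_rate_recovered_per_triplet(self):
        """rES on generated counts matches the planted rate; the bound is a
        conservative 6x binomial SE covering the ratio's delta-method
        variance."""
        cfg = synthetic.SyntheticConfig(
            n_triplets=50, reads_per_triplet=10_000, planted_rate_range=(0.5, 0.5), rng_seed=4
        )
        jset = synthetic.generate_junction_counts(cfg)
        for trip in jset.triplets_by_tissue["tissue1"]:
            r = sp.res_rate(trip).rate
            assert abs(r - 0.5) < 6 * np.sqrt(0.5 * 0.5 / 10_000)
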