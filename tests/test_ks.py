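from __future__ import annotations

import math

import numpy as np
import pytest

from helpers import oracle_ng86, oracle_pair_diffs, oracle_syn_sites, random_codons
from paleoploid.aligner import CodonAlignment
from paleoploid.ks import (
    KsEstimate,
    PairKs,
    codon_pair_differences,
    filter_pairs,
    ks_for_pair,
    ks_ml,
    ks_ng86,
    pick_frame,
    syn_site_fraction,
)
from paleoploid.seq_io import SENSE_CODONS, SequenceRecord


def _aln(codons_a, codons_b):
    return CodonAlignment("a", "b", "".join(codons_a), "".join(codons_b))


class TestSynSiteFraction:
    @pytest.mark.parametrize(
        ("codon", "expected"),
        [("TTT", 1 / 3), ("GCC", 1.0), ("GAT", 1 / 3)],
    )
    def test_hand_enumerated_examples(self, codon, expected):
        assert syn_site_fraction(codon) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_enumeration_oracle_on_all_sense_codons(self):
        for codon in SENSE_CODONS:
            assert syn_site_fraction(codon) == pytest.approx(
                oracle_syn_sites(codon), abs=1e-12
            )

    @pytest.mark.parametrize("bad", ["TAA", "TGA", "ANT"])
    def test_stop_and_ambiguous_codons_rejected(self, bad):
        with pytest.raises(ValueError):
            syn_site_fraction(bad)


class TestPairDifferences:
    def test_agrees_with_path_enumeration_oracle(self, rng):
        codons = random_codons(rng, 300)
        partners = random_codons(rng, 300)
        for c1, c2 in zip(codons, partners):
            assert codon_pair_differences(c1, c2) == pytest.approx(
                oracle_pair_diffs(c1, c2), abs=1e-12
            )

    def test_total_differences_equal_mismatch_count(self, rng):
        for c1, c2 in zip(random_codons(rng, 100), random_codons(rng, 100)):
            sd, nd = codon_pair_differences(c1, c2)
            assert sd + nd == pytest.approx(
                sum(x != y for x, y in zip(c1, c2)), abs=1e-12
            )


class TestKsNg86:
    def test_identical_alignment_is_zero(self):
        est = ks_ng86(_aln(["ATG", "GCC", "TTT"], ["ATG", "GCC", "TTT"]))
        assert est.sd == est.nd == 0
        assert est.ks == 0.0 and est.ka == 0.0
        assert not est.saturated

    def test_single_synonymous_difference_hand_example(self):
        est = ks_ng86(_aln(["TTT", "GAT", "GCC"], ["TTC", "GAT", "GCC"]))
        assert est.s_sites == pytest.approx(5 / 3, abs=1e-12)
        assert est.sd == 1.0
        assert est.p_s == pytest.approx(0.6, abs=1e-12)
        assert est.ks == pytest.approx(-0.75 * math.log(0.2), abs=1e-9)
        assert est.ka == 0.0

    def test_saturation_flags_and_hides_ks(self):
        # TTT->TTC at every codon: one full synonymous difference against
        # only a third of a synonymous site per codon, far past saturation
        est = ks_ng86(_aln(["TTT"] * 10, ["TTC"] * 10))
        assert est.p_s == pytest.approx(3.0)
        assert est.saturated and est.ks is None

    def test_site_conservation_and_symmetry(self, rng):
        for _ in range(20):
            ca = random_codons(rng, 50)
            cb = random_codons(rng, 50)
            est = ks_ng86(_aln(ca, cb))
            assert est.s_sites + est.n_sites == pytest.approx(150.0, abs=1e-9)
            rev = ks_ng86(_aln(cb, ca))
            assert est.sd == pytest.approx(rev.sd, abs=1e-12)
            assert est.ks == rev.ks or (est.ks is None and rev.ks is None)

    def test_matches_brute_force_oracle_on_random_alignments(self, rng):
        for _ in range(50):
            ca = random_codons(rng, 40)
            cb = random_codons(rng, 40)
            est = ks_ng86(_aln(ca, cb))
            S, N, sd, nd, ks, ka = oracle_ng86(ca, cb)
            assert est.s_sites == pytest.approx(S, abs=1e-9)
            assert est.sd == pytest.approx(sd, abs=1e-9)
            assert est.nd == pytest.approx(nd, abs=1e-9)
            if ks is None:
                assert est.ks is None
            else:
                assert est.ks == pytest.approx(ks, abs=1e-9)

    def test_gap_and_n_columns_excluded(self):
        aln = CodonAlignment("a", "b", "TTT---GCNATG", "TTC AAAGCCATG".replace(" ", ""))
        est = ks_ng86(aln)
        # only TTT/TTC and ATG/ATG columns count
        assert est.s_sites + est.n_sites == pytest.approx(6.0, abs=1e-9)

    def test_empty_counting_rejected(self):
        with pytest.raises(ValueError):
            ks_ng86(CodonAlignment("a", "b", "---", "ATG"))

    def test_mean_estimate_increases_with_divergence(self, rng):
        from paleoploid.simulate import generate_ancestral_cds, mutate_to_ks

        means = []
        for target in (0.05, 0.2, 0.6):
            vals = []
            for _ in range(25):
                anc = generate_ancestral_cds(1, 150, rng)[0].seq
                der = mutate_to_ks(anc, target, 0.1, rng)
                est = ks_ng86(CodonAlignment("a", "b", anc, der))
                vals.append(est.ks)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestKsMl:
    def test_identical_alignment_is_zero(self):
        est = ks_ml(_aln(["ATG", "GCC", "TTT"] * 10, ["ATG", "GCC", "TTT"] * 10))
        assert est.ks == 0.0

    def test_recovers_simulated_divergence(self, rng):
        """Mean ML Ks across replicate pairs simulated at Ks 0.2."""
        from paleoploid.simulate import generate_ancestral_cds, mutate_to_ks

        vals = []
        for _ in range(100):
            anc = generate_ancestral_cds(1, 500, rng)[0].seq
            der = mutate_to_ks(anc, 0.2, 0.1, rng)
            est = ks_ml(CodonAlignment("a", "b", anc, der))
            assert est.converged
            vals.append(est.ks)
        assert np.mean(vals) == pytest.approx(0.2, abs=0.03)

    def test_agrees_with_ng86_at_moderate_divergence(self, rng):
        from paleoploid.simulate import generate_ancestral_cds, mutate_to_ks

        for target in (0.1, 0.3):
            diffs = []
            for _ in range(10):
                anc = generate_ancestral_cds(1, 300, rng)[0].seq
                der = mutate_to_ks(anc, target, 0.1, rng)
                aln = CodonAlignment("a", "b", anc, der)
                diffs.append(abs(ks_ml(aln).ks - ks_ng86(aln).ks))
            assert np.mean(diffs) < 0.05


class TestFilterPairs:
    def _pair(self, aligned_aa, sd, s_sites=100.0):
        est = KsEstimate(s_sites=s_sites, n_sites=300.0 - s_sites, sd=sd, nd=0.0)
        return PairKs("a", "b", est, aligned_aa, None)

    def test_strict_boundaries(self):
        exactly_30 = self._pair(30, 1.0)
        long_small_ks = self._pair(50, 1.0)
        kept = filter_pairs([exactly_30, long_small_ks])
        assert kept == [long_small_ks]

    def test_large_and_saturated_ks_excluded(self):
        # p_s = 0.9 saturates; p_s such that ks >= 2 excluded too
        saturated = self._pair(50, 90.0)
        p_for_ks2 = 0.75 * (1 - math.exp(-8 / 3))
        big = self._pair(50, p_for_ks2 * 100 + 0.2)
        ok = self._pair(50, 10.0)
        assert filter_pairs([saturated, big, ok]) == [ok]


class TestKsForPair:
    def test_frame_selection_prefers_stop_free_frame(self, rng):
        from paleoploid.simulate import generate_ancestral_cds

        cds = generate_ancestral_cds(1, 100, rng)[0].seq
        assert pick_frame(cds) == 0
        assert pick_frame("G" + cds) == 1
        assert pick_frame("GG" + cds) == 2

    def test_full_path_on_simulated_pair(self, rng):
        from paleoploid.simulate import generate_ancestral_cds, mutate_to_ks

        anc = generate_ancestral_cds(1, 200, rng)[0].seq
        der = mutate_to_ks(anc, 0.2, 0.1, rng)
        res = ks_for_pair(SequenceRecord("x", anc), SequenceRecord("y", der))
        assert res is not None
        assert res.aligned_aa > 150
        assert res.estimate.ks == pytest.approx(0.2, abs=0.08)
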