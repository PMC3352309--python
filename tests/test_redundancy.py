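from __future__ import annotations

import pytest

from helpers import oracle_longest_common_substring
from paleoploid.redundancy import (
    EvaluationReport,
    RedundancyPair,
    collapse,
    evaluate_vs_truth,
    find_redundant_pairs,
    longest_shared_run,
)
from paleoploid.seq_io import SequenceRecord


def _random_nt(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant_block(rng, len_a, len_b, block_len):
    """Two records sharing one identical block inside random flanks."""
    block = _random_nt(rng, block_len)
    pa = rng.integers(0, len_a - block_len + 1)
    pb = rng.integers(0, len_b - block_len + 1)
    sa = _random_nt(rng, pa) + block + _random_nt(rng, len_a - pa - block_len)
    sb = _random_nt(rng, pb) + block + _random_nt(rng, len_b - pb - block_len)
    return SequenceRecord("a", sa), SequenceRecord("b", sb)


class TestFindRedundantPairs:
    def test_shared_150bp_block_detected(self, rng):
        a, b = _plant_block(rng, 500, 300, 150)
        (pair,) = find_redundant_pairs([a, b])
        assert pair.block_length >= 150
        assert pair.key == ("a", "b")

    def test_99bp_block_is_below_threshold(self, rng):
        # embed a 99-bp shared block and confirm both the detector and the
        # brute-force longest-common-substring oracle sit below 100
        for _ in range(5):
            a, b = _plant_block(rng, 400, 400, 99)
            if oracle_longest_common_substring(a.seq, b.seq) >= 100:
                continue  # flanks extended the block by chance; skip draw
            assert find_redundant_pairs([a, b]) == []

    def test_unrelated_sequences_share_nothing(self, rng):
        records = [
            SequenceRecord(f"s{i}", _random_nt(rng, 500)) for i in range(6)
        ]
        assert find_redundant_pairs(records) == []

    @pytest.mark.parametrize("block_len", [100, 130, 200])
    def test_exact_scan_agrees_with_lcs_oracle(self, rng, block_len):
        """k-mer anchoring finds exactly the longest shared run."""
        for _ in range(10):
            a, b = _plant_block(rng, 600, 500, block_len)
            run = longest_shared_run(a.seq, b.seq, min_block=100)
            lcs = oracle_longest_common_substring(a.seq, b.seq)
            assert run == (lcs if lcs >= 100 else 0)

    def test_diverged_duplicates_are_not_redundant(self, rng):
        """A ~1%-diverged gene duplicate shares long exact runs, but its
        best alignment carries mismatches, so it must be kept."""
        base = _random_nt(rng, 900)
        mutated = list(base)
        for pos in rng.choice(900, size=9, replace=False):
            mutated[pos] = rng.choice([c for c in "ACGT" if c != base[pos]])
        records = [SequenceRecord("g1", base), SequenceRecord("g2", "".join(mutated))]
        assert longest_shared_run(base, records[1].seq, 100) >= 100
        assert find_redundant_pairs(records) == []

    def test_min_block_validation(self):
        with pytest.raises(ValueError):
            find_redundant_pairs([], min_block=0)


class TestCollapse:
    def _records(self, rng, lengths):
        return [
            SequenceRecord(name, _random_nt(rng, n))
            for name, n in lengths.items()
        ]

    def test_longest_member_retained(self, rng):
        recs = self._records(rng, {"long": 500, "short": 300})
        retained, mapping = collapse(recs, [RedundancyPair("long", "short", 150)])
        assert [r.id for r in retained] == ["long"]
        assert mapping == {"short": "long"}

    def test_no_pairs_keeps_everything(self, rng):
        recs = self._records(rng, {"x": 100, "y": 200})
        retained, mapping = collapse(recs, [])
        assert [r.id for r in retained] == ["x", "y"]
        assert mapping == {}

    def test_chain_is_single_component(self, rng):
        recs = self._records(rng, {"A": 400, "B": 600, "C": 500})
        pairs = [RedundancyPair("A", "B", 120), RedundancyPair("B", "C", 120)]
        retained, mapping = collapse(recs, pairs)
        assert [r.id for r in retained] == ["B"]
        assert mapping == {"A": "B", "C": "B"}

    def test_length_tie_keeps_smallest_id(self, rng):
        recs = self._records(rng, {"zz": 300, "aa": 300})
        retained, _ = collapse(recs, [RedundancyPair("zz", "aa", 150)])
        assert [r.id for r in retained] == ["aa"]

    def test_idempotent_on_own_output(self, rng):
        recs = self._records(rng, {"A": 400, "B": 600, "C": 500, "D": 100})
        pairs = [RedundancyPair("A", "B", 120), RedundancyPair("B", "C", 120)]
        retained, _ = collapse(recs, pairs)
        again, mapping = collapse(retained, find_redundant_pairs(retained))
        assert [r.id for r in again] == [r.id for r in retained]
        assert mapping == {}

    def test_unknown_id_rejected(self, rng):
        recs = self._records(rng, {"A": 400})
        with pytest.raises(KeyError):
            collapse(recs, [RedundancyPair("A", "ghost", 150)])

    def test_representative_at_least_as_long_as_members(self, rng):
        recs = [
            SequenceRecord(f"s{i}", _random_nt(rng, int(n)))
            for i, n in enumerate(rng.integers(150, 900, size=12))
        ]
        pairs = [
            RedundancyPair(recs[i].id, recs[j].id, 100)
            for i, j in [(0, 3), (3, 5), (1, 2), (7, 8)]
        ]
        retained, mapping = collapse(recs, pairs)
        by_id = {r.id: r for r in recs}
        for collapsed_id, rep_id in mapping.items():
            assert by_id[rep_id].length >= by_id[collapsed_id].length


class TestEvaluateVsTruth:
    def test_splice_assessment_arithmetic(self):
        """Detected 31,957 vs 36,087 truth pairs with 28,434 shared gives
        ~79% sensitivity and 11% error rate."""
        truth = {(f"t{i}", f"u{i}") for i in range(36_087)}
        shared = {(f"t{i}", f"u{i}") for i in range(28_434)}
        false_pos = {(f"f{i}", f"g{i}") for i in range(31_957 - 28_434)}
        rep = evaluate_vs_truth(shared | false_pos, truth)
        assert rep.detected == 31_957
        assert rep.sensitivity == pytest.approx(0.788, abs=0.0005)
        assert rep.error_rate == pytest.approx(0.110, abs=0.0005)

    def test_perfect_and_disjoint_detection(self):
        truth = {("a", "b"), ("c", "d")}
        perfect = evaluate_vs_truth(truth, truth)
        assert perfect.sensitivity == 1.0 and perfect.error_rate == 0.0
        disjoint = evaluate_vs_truth({("x", "y")}, truth)
        assert disjoint.sensitivity == 0.0 and disjoint.error_rate == 1.0

    def test_empty_truth_rejected_and_empty_detected_ok(self):
        with pytest.raises(ValueError):
            evaluate_vs_truth({("a", "b")}, set())
        rep = evaluate_vs_truth(set(), {("a", "b")})
        assert rep.error_rate == 0.0 and rep.sensitivity == 0.0

    def test_report_invariants(self):
        with pytest.raises(ValueError):
            EvaluationReport(detected=1, truth=1, true_positive=2)
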