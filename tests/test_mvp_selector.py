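import numpy as np
import pandas as pd
import pytest

from mhcequity.lno_protocol import TrainingDataSummary
from mhcequity.mvp_selector import (
    ImpactVector,
    compute_impact_vector,
    frequency_baseline,
    global_ppv_improvement,
    greedy_mvp,
    simulate_data_addition,
    supertype_baseline,
)
from mhcequity.perf_estimator import featurize


def _summary(counts):
    return TrainingDataSummary(
        counts=counts,
        pseudosequences={a: "A" * 34 if i == 0 else "W" * i + "A" * (34 - i)
                         for i, a in enumerate(sorted(set(counts)))},
    )


class TestSimulateDataAddition:
    def test_existing_allele_incremented(self):
        s = _summary({"A": 100})
        out = simulate_data_addition(s, "A", 4000)
        assert out.counts == {"A": 4100}
        assert s.counts == {"A": 100}  # original untouched

    def test_absent_allele_inserted(self):
        s = _summary({"A": 100})
        out = simulate_data_addition(s, "B", 4000, pseudosequences={"B": "C" * 34})
        assert out.counts == {"A": 100, "B": 4000}

    def test_unknown_pseudosequence_rejected(self):
        with pytest.raises(ValueError):
            simulate_data_addition(_summary({"A": 1}), "Z")

    def test_featurization_changes_only_through_counts(self):
        s = _summary({"A": 100, "B": 50})
        query = "W" * 3 + "A" * 31
        before = featurize(query, s)
        after = featurize(query, simulate_data_addition(s, "A", 4000))
        # distance block (g1) unchanged: same set of data alleles
        assert np.array_equal(before[:10], after[:10])
        assert not np.array_equal(before[10:], after[10:])


class TestImpactVector:
    def test_above_median_allele_gets_zero(self):
        iv = compute_impact_vector("j", {"i": 0.7}, {"i": 0.9}, median_ppv=0.6)
        assert iv.entries["i"] == 0.0

    def test_improvement_below_cap(self):
        iv = compute_impact_vector("j", {"i": 0.5}, {"i": 0.58}, median_ppv=0.6)
        assert iv.entries["i"] == pytest.approx(0.08)

    def test_improvement_capped_by_gap_to_median(self):
        iv = compute_impact_vector("j", {"i": 0.55}, {"i": 0.65}, median_ppv=0.6)
        assert iv.entries["i"] == pytest.approx(0.05)

    def test_negative_improvement_floored(self):
        iv = compute_impact_vector("j", {"i": 0.5}, {"i": 0.45}, median_ppv=0.6)
        assert iv.entries["i"] == 0.0

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_impact_vector("j", {"i": 0.5}, {"x": 0.5}, 0.6)

    def test_entries_bounded_by_median_gap(self, rng):
        cur = {f"a{i}": rng.uniform(0.2, 0.9) for i in range(20)}
        aft = {a: v + rng.uniform(-0.1, 0.2) for a, v in cur.items()}
        med = float(np.median(list(cur.values())))
        iv = compute_impact_vector("j", cur, aft, med)
        for a, e in iv.entries.items():
            assert 0.0 <= e <= max(0.0, med - cur[a]) + 1e-12


def _greedy_oracle(vectors, k):
    """Independent straight-line re-implementation of the greedy rule."""
    vecs = {j: dict(v.entries) for j, v in vectors.items()}
    picked, scores = [], []
    available = sorted(vecs)
    for _ in range(min(k, len(available))):
        totals = [(-(sum(vecs[j].values())), j) for j in available]
        totals.sort()
        neg_total, best = totals[0]
        if -neg_total <= 0:
            break
        picked.append(best)
        scores.append(-neg_total)
        vm = vecs[best]
        available.remove(best)
        for j in available:
            for a in vecs[j]:
                vecs[j][a] = max(vecs[j][a] - vm.get(a, 0.0), 0.0)
    return picked, scores


class TestGreedyMVP:
    def test_update_rule_subtracts_and_floors(self):
        vectors = {
            "m": ImpactVector("m", {"x": 0.10, "y": 0.02, "z": 0.05}),
            "j": ImpactVector("j", {"x": 0.08, "y": 0.05, "z": 0.0}),
        }
        result = greedy_mvp(vectors, k=2)
        assert result.selected == ["m", "j"]
        # after subtraction j = (max(0.08-0.10,0), 0.05-0.02, 0) -> total 0.03
        assert result.scores[1] == pytest.approx(0.03)

    def test_single_candidate(self):
        result = greedy_mvp({"j": ImpactVector("j", {"x": 0.1})}, k=1)
        assert result.selected == ["j"]

    def test_stops_when_scores_exhausted(self):
        vectors = {
            "a": ImpactVector("a", {"x": 0.1}),
            "b": ImpactVector("b", {"x": 0.05}),
        }
        result = greedy_mvp(vectors, k=5)
        assert result.selected == ["a"]  # b's vector zeroes out after a

    def test_matches_independent_oracle_on_random_instances(self):
        """50 random instances of <= 12 candidates: greedy path must equal
        a straight-line re-implementation exactly."""
        for trial in range(50):
            rng = np.random.default_rng(trial)
            n_cand = int(rng.integers(2, 13))
            n_all = int(rng.integers(3, 10))
            alleles = [f"i{t}" for t in range(n_all)]
            vectors = {
                f"c{j:02d}": ImpactVector(
                    f"c{j:02d}",
                    {a: float(np.round(rng.uniform(0, 0.2), 3)) for a in alleles},
                )
                for j in range(n_cand)
            }
            k = int(rng.integers(1, n_cand + 1))
            result = greedy_mvp(vectors, k)
            expected_sel, expected_scores = _greedy_oracle(vectors, k)
            assert result.selected == expected_sel
            assert np.allclose(result.scores, expected_scores, atol=1e-12)

    def test_scores_non_increasing_across_iterations(self):
        rng = np.random.default_rng(99)
        vectors = {
            f"c{j}": ImpactVector(f"c{j}", {f"i{t}": float(rng.uniform(0, 0.2))
                                            for t in range(8)})
            for j in range(10)
        }
        result = greedy_mvp(vectors, k=10)
        assert all(a >= b - 1e-12 for a, b in zip(result.scores, result.scores[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_mvp({}, 1)


class TestGlobalImprovement:
    def test_zero_when_unchanged(self):
        m = {"a": 0.5, "b": 0.6}
        assert global_ppv_improvement(m, dict(m)) == 0.0

    def test_sums_differences(self):
        before = {"a": 0.5, "b": 0.6}
        after = {"a": 0.6, "b": 0.65}
        assert global_ppv_improvement(before, after) == pytest.approx(0.15)

    def test_matches_vectorized_recomputation(self, rng):
        before = {f"a{i}": float(rng.random()) for i in range(100)}
        after = {a: float(rng.random()) for a in before}
        keys = sorted(before)
        expected = float(
            np.asarray([after[k] for k in keys]).sum()
            - np.asarray([before[k] for k in keys]).sum()
        )
        assert global_ppv_improvement(before, after) == pytest.approx(expected, abs=1e-9)

    def test_key_mismatch_rejected(self):
        with pytest.raises(ValueError):
            global_ppv_improvement({"a": 0.1}, {"b": 0.1})


class TestBaselines:
    def _freq(self, rows):
        return pd.DataFrame(rows, columns=["group", "allele", "frequency"])

    def test_frequency_top_k_by_mean(self):
        t = self._freq([
            ("g1", "A", 0.5), ("g1", "B", 0.3), ("g1", "C", 0.2),
            ("g2", "A", 0.1), ("g2", "B", 0.6), ("g2", "C", 0.3),
        ])
        # means: A 0.3, B 0.45, C 0.25
        assert frequency_baseline(t, k=2) == ["B", "A"]
        assert frequency_baseline(t, k=1) == ["B"]
        assert set(frequency_baseline(t, k=3)) == {"A", "B", "C"}

    def test_frequency_empty_rejected(self):
        with pytest.raises(ValueError):
            frequency_baseline(self._freq([]), k=1)

    def test_supertype_least_data_selection(self):
        s = _summary({"A1": 0, "A2": 100, "B1": 500})
        st_map = {"A1": "S1", "A2": "S1", "B1": "S2"}
        # S1 total 100 < S2 total 500; least-data allele in S1 is A1
        assert supertype_baseline(st_map, s, k=1) == ["A1"]
        assert supertype_baseline(st_map, s, k=2) == ["A1", "B1"]

    def test_supertype_handles_fewer_than_k(self):
        s = _summary({"A1": 5})
        assert supertype_baseline({"A1": "S1"}, s, k=3) == ["A1"]
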