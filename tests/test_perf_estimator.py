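import numpy as np
import pytest

from mhcequity.encoders import blosum62_distance
from mhcequity.lno_protocol import LNOExperiment, TrainingDataSummary
from mhcequity.perf_estimator import (
    FEATURE_NAMES,
    N_FEATURES,
    PerfRegressor,
    evaluate_correlations,
    featurize,
    featurize_raw,
    nearest_neighbor_baseline,
    ppv_balanced_folds,
)


def _pseudo(n_subs, base="A" * 34):
    s = list(base)
    for p in range(n_subs):
        s[p] = "W"
    return "".join(s)


def _summary(spec):
    """spec: {allele: (n_subs, count)}."""
    return TrainingDataSummary(
        counts={a: c for a, (_, c) in spec.items()},
        pseudosequences={a: _pseudo(k) for a, (k, _) in spec.items()},
    )


QUERY = "A" * 34


class TestFeaturize:
    def test_layout_is_63_in_five_blocks(self):
        s = _summary({"B": (1, 10), "C": (2, 20), "D": (3, 5)})
        f = featurize(QUERY, s)
        assert f.shape == (N_FEATURES,) == (63,)
        assert len(FEATURE_NAMES) == 63
        raw = featurize_raw(QUERY, s)
        assert [len(raw[g]) for g in ("g1", "g2", "g3", "g4", "g5")] == [10, 10, 8, 34, 1]

    def test_empty_summary_pads_distances_with_one(self):
        s = TrainingDataSummary(counts={}, pseudosequences={})
        f = featurize(QUERY, s)
        assert np.all(f[:10] == 1.0)
        assert np.all(f[10:] == 0.0)

    def test_single_neighbor_placement(self):
        ps = _pseudo(1)
        d = blosum62_distance(QUERY, ps)
        s = TrainingDataSummary(counts={"B": 200}, pseudosequences={"B": ps})
        raw = featurize_raw(QUERY, s)
        assert raw["g1"][0] == pytest.approx(d)
        assert np.all(raw["g1"][1:] == 1.0)
        assert raw["g2"][0] == 200
        bin_idx = int(d // 0.1)
        assert raw["g3"][bin_idx] == 200
        assert raw["g5"][0] == 200
        # every position where B matches the query counts B's records
        assert np.all(raw["g4"][1:] == 200) and raw["g4"][0] == 0.0

    def test_g1_sorted_and_zero_count_alleles_ignored(self):
        s = _summary({"B": (3, 10), "C": (1, 20), "D": (2, 0)})
        raw = featurize_raw(QUERY, s)
        assert list(raw["g1"][:2]) == sorted(raw["g1"][:2])
        # D has no data: only two neighbor slots filled
        assert raw["g1"][2] == 1.0
        assert raw["g2"][2] == 0.0

    def test_bin_counts_conserve_total(self):
        s = _summary({chr(66 + i): (i % 8, 10 * i) for i in range(10)})
        raw = featurize_raw(QUERY, s)
        assert raw["g3"].sum() == pytest.approx(raw["g5"][0])

    def test_wrong_query_length_rejected(self):
        with pytest.raises(ValueError):
            featurize("A" * 33, _summary({"B": (1, 5)}))


class TestPerfRegressor:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 63))
        y = np.full(40, 0.7)
        model = PerfRegressor(seed=1, max_epochs=400, patience=50)
        model.fit(X, y)
        pred = model.predict(X)
        assert np.all(np.abs(pred - 0.7) < 0.05)

    def test_monotone_synthetic_mapping_recovered(self):
        """PPV that falls linearly with nearest-neighbor distance must be
        recoverable from the g1 block with held-out correlation > 0.8."""
        rng = np.random.default_rng(2)
        X = np.zeros((200, 63))
        X[:, 0] = rng.uniform(0, 1, 200)  # nearest-neighbor distance
        X[:, 1:10] = 1.0
        y = np.clip(0.9 - 0.6 * X[:, 0] + rng.normal(0, 0.02, 200), 0, 1)
        model = PerfRegressor(seed=3)
        model.fit(X[:150], y[:150])
        pred = model.predict(X[150:])
        pearson, _ = evaluate_correlations(pred, y[150:])
        assert pearson > 0.8

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = rng.random((30, 63)), rng.random(30)
        p1 = PerfRegressor(seed=5, max_epochs=50).fit(X, y).predict(X)
        p2 = PerfRegressor(seed=5, max_epochs=50).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(6)
        X, y = rng.random((20, 63)), rng.random(20)
        model = PerfRegressor(seed=7, max_epochs=20).fit(X, y)
        pred = model.predict(rng.random((50, 63)))
        assert np.all((pred > 0) & (pred < 1))

    def test_shape_validation(self):
        model = PerfRegressor(seed=0, max_epochs=5)
        rng = np.random.default_rng(1)
        model.fit(rng.random((10, 63)), rng.random(10))
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            model.fit(np.zeros((3, 63)), np.zeros(2))
        with pytest.raises(ValueError):
            model.fit(np.zeros((3, 63)), np.array([0.5, 0.2, 1.7]))


def _experiments(ppvs_by_allele):
    out = []
    s = TrainingDataSummary(counts={}, pseudosequences={})
    for allele, ppvs in ppvs_by_allele.items():
        for i, p in enumerate(ppvs, 1):
            out.append(
                LNOExperiment(allele, i, (allele,), s, measured_ppv=p)
            )
    return out


class TestFolds:
    def test_round_robin_after_ppv_sort(self):
        exps = _experiments({"A": [0.9], "B": [0.7], "C": [0.5], "D": [0.3]})
        folds = ppv_balanced_folds(exps, k=2)
        assert folds == {"A": 0, "B": 1, "C": 0, "D": 1}

    def test_all_experiments_of_one_allele_share_fold(self):
        exps = _experiments({"A": [0.9, 0.1], "B": [0.5, 0.4], "C": [0.3, 0.2]})
        folds = ppv_balanced_folds(exps, k=3)
        assert len(set(folds.values())) == 3

    def test_k_exceeding_alleles_rejected(self):
        exps = _experiments({"A": [0.5], "B": [0.4]})
        with pytest.raises(ValueError):
            ppv_balanced_folds(exps, k=3)


class TestNearestNeighborBaseline:
    def _experiments_with_pseqs(self):
        exps = []
        s = TrainingDataSummary(counts={}, pseudosequences={})
        pseqs = {"Q": _pseudo(0), "B": _pseudo(1), "C": _pseudo(5)}
        exps += [LNOExperiment("B", 1, ("B",), s, measured_ppv=0.6),
                 LNOExperiment("B", 2, ("B",), s, measured_ppv=0.8),
                 LNOExperiment("C", 1, ("C",), s, measured_ppv=0.2)]
        return exps, pseqs

    def test_nearest_allele_mean_ppv(self):
        exps, pseqs = self._experiments_with_pseqs()
        assert nearest_neighbor_baseline(pseqs["Q"], exps, pseqs) == pytest.approx(0.7)

    def test_removing_nearest_falls_back_to_next(self):
        exps, pseqs = self._experiments_with_pseqs()
        val = nearest_neighbor_baseline(pseqs["Q"], exps, pseqs, exclude_allele="B")
        assert val == pytest.approx(0.2)

    def test_tie_broken_by_name(self):
        s = TrainingDataSummary(counts={}, pseudosequences={})
        pseqs = {"Q": _pseudo(0), "B": _pseudo(2), "A": _pseudo(2)}
        exps = [LNOExperiment("B", 1, ("B",), s, measured_ppv=0.9),
                LNOExperiment("A", 1, ("A",), s, measured_ppv=0.3)]
        assert nearest_neighbor_baseline(pseqs["Q"], exps, pseqs) == pytest.approx(0.3)

    def test_no_other_allele_rejected(self):
        s = TrainingDataSummary(counts={}, pseudosequences={})
        exps = [LNOExperiment("B", 1, ("B",), s, measured_ppv=0.9)]
        with pytest.raises(ValueError):
            nearest_neighbor_baseline(_pseudo(0), exps, {"B": _pseudo(1)},
                                      exclude_allele="B")


class TestCorrelations:
    def test_perfect_and_inverted(self):
        x = [0.1, 0.4, 0.7, 0.9]
        assert evaluate_correlations(x, x) == pytest.approx((1.0, 1.0))
        y = [1 - v for v in x]
        assert evaluate_correlations(x, y) == pytest.approx((-1.0, -1.0))

    def test_matches_direct_formula_on_hand_example(self):
        x = np.array([0.2, 0.5, 0.1, 0.9])
        y = np.array([0.3, 0.4, 0.2, 0.7])
        pearson, spearman = evaluate_correlations(x, y)
        # direct product-moment formula
        xm, ym = x - x.mean(), y - y.mean()
        expected_p = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert pearson == pytest.approx(expected_p, abs=1e-12)
        # ranks are exact here; spearman = pearson of ranks
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        rxm, rym = rx - rx.mean(), ry - ry.mean()
        expected_s = (rxm @ rym) / np.sqrt((rxm @ rxm) * (rym @ rym))
        assert spearman == pytest.approx(expected_s, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluate_correlations([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
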