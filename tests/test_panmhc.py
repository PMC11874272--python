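import numpy as np
import pytest

import mhcequity.synthetic_data as sd
from mhcequity._nn import censored_mse, encode_inequalities
from mhcequity.binding_data import (
    TransformedLabel,
    assign_qualitative_labels,
    generate_synthetic_negatives,
    transform_affinity,
)
from mhcequity.panmhc import (
    BindingNetRegressor,
    BindingPredictor,
    Ensemble,
    NetworkConfig,
    encode_dataset,
    inequality_mse,
    select_ensemble,
)


class TestInequalityMSE:
    def test_satisfied_inequality_is_free(self):
        y = transform_affinity(100)  # elution positive: ">= y" on the unit scale
        assert inequality_mse(0.80, TransformedLabel(y, ">=")) == 0.0

    def test_equality_is_plain_squared_error(self):
        assert inequality_mse(0.3, TransformedLabel(0.5, "=")) == pytest.approx(0.04)

    def test_violated_inequality_penalized_quadratically(self):
        y = transform_affinity(100)
        assert inequality_mse(y - 0.1, TransformedLabel(y, ">=")) == pytest.approx(0.01)
        assert inequality_mse(0.5, TransformedLabel(0.3, "<=")) == pytest.approx(0.04)
        assert inequality_mse(0.2, TransformedLabel(0.3, "<=")) == 0.0

    def test_continuous_at_boundary_and_nonnegative(self):
        for ineq in (">=", "<="):
            assert inequality_mse(0.5, TransformedLabel(0.5, ineq)) == 0.0
        with pytest.raises(ValueError):
            inequality_mse(0.5, TransformedLabel(0.5, "!"))

    def test_vectorized_loss_matches_scalar(self, rng):
        preds = rng.random(50)
        ys = rng.random(50)
        syms = rng.choice([">=", "=", "<="], 50)
        scalar = np.mean([inequality_mse(p, TransformedLabel(y, s))
                          for p, y, s in zip(preds, ys, syms)])
        vector = censored_mse(preds, ys, encode_inequalities(list(syms)))
        assert vector == pytest.approx(scalar, abs=1e-12)


def _toy_training_set(oracle, allele, n=120, seed=0):
    recs = sd.sample_binding_dataset(oracle, {allele: n}, ba_fraction=0.5, seed=seed)
    proteome = sd.sample_proteome(n_proteins=10, length=200, seed=seed + 1)
    recs = assign_qualitative_labels(recs)
    return recs + generate_synthetic_negatives(recs, proteome, seed=seed + 2)


@pytest.fixture(scope="module")
def toy_fit(small_universe, oracle):
    """One small member trained on a single data-rich allele."""
    allele = small_universe.alleles[0]
    records = _toy_training_set(oracle, allele)
    cfg = NetworkConfig(hidden_units=(16,), skip_connections=(False,),
                        learning_rate=3e-3, batch_size=64, max_epochs=60,
                        patience=10, init_seed=5)
    predictor = BindingPredictor(cfg, small_universe.pseudosequences)
    predictor.fit(records, split_seed=1)
    return allele, records, predictor


class TestTraining:
    def test_retraining_is_bit_identical(self, small_universe, oracle, toy_fit):
        allele, records, predictor = toy_fit
        clone = BindingPredictor(predictor.config, small_universe.pseudosequences)
        clone.fit(records, split_seed=1)
        probe = [r.peptide for r in records[:20]]
        p1 = predictor.score_peptides(allele, probe)
        p2 = clone.score_peptides(allele, probe)
        assert np.array_equal(p1, p2)

    def test_training_reduces_loss(self, small_universe, oracle, toy_fit):
        allele, records, predictor = toy_fit
        X, y, q = encode_dataset(records, small_universe.pseudosequences)
        trained_loss = censored_mse(predictor.net.predict(X), y, q)
        fresh = BindingNetRegressor(predictor.config)
        # untrained reference: initial parameters, zero epochs
        from mhcequity._nn import forward, init_params

        init = init_params(X.shape[1], (16,), (False,), 5)
        init_pred, _ = forward(init, X.astype(np.float64), (False,))
        initial_loss = censored_mse(init_pred, y, q)
        assert trained_loss < initial_loss

    def test_learned_model_separates_binders_from_decoys(
        self, small_universe, oracle, toy_fit, rng
    ):
        allele, _, predictor = toy_fit
        binders = [oracle.sample_binder(allele, 9, rng) for _ in range(30)]
        decoys = ["".join(rng.choice(list(sd.AMINO_ACIDS), 9)) for _ in range(30)]
        sb = predictor.score_peptides(allele, binders)
        sd_ = predictor.score_peptides(allele, decoys)
        assert sb.mean() > sd_.mean() + 0.1

    def test_empty_validation_rejected(self):
        net = BindingNetRegressor(NetworkConfig())
        with pytest.raises(ValueError):
            net.fit(np.zeros((4, 10)), np.zeros(4))


class _Const:
    """Stub member returning a fixed score for every peptide."""

    def __init__(self, value, pseudosequences):
        self.value = value
        self.pseudosequences = pseudosequences

    def score_peptides(self, allele, peptides):
        return np.full(len(peptides), self.value)

    def predict(self, allele, peptide):
        return self.value


class TestEnsemble:
    def test_prediction_is_member_mean(self):
        members = [_Const(v, {}) for v in (0.2, 0.4, 0.6)]
        ens = Ensemble(members=members)
        assert ens.predict("A" * 34, "ACDEFGHIK") == pytest.approx(0.4)

    def test_singleton_passthrough_and_bounds(self):
        ens = Ensemble(members=[_Const(0.7, {})])
        assert ens.predict("A" * 34, "ACDEFGHIK") == pytest.approx(0.7)
        with pytest.raises(ValueError):
            Ensemble(members=[])

    def test_invalid_peptide_length_rejected(self):
        ens = Ensemble(members=[_Const(0.5, {})])
        with pytest.raises(ValueError):
            ens.predict("A" * 34, "SHORT")


class TestSelectEnsemble:
    def _calibration(self, y_true):
        from mhcequity.binding_data import BindingRecord, SOURCE_BA, inverse_transform

        aas = "ACDEFGHIKLMNPQRSTVWY"
        return [
            BindingRecord("Q", "ACDEFGHI" + aas[i % 20], inverse_transform(min(max(y, 0), 1)),
                          "=", SOURCE_BA)
            for i, y in enumerate(y_true)
        ]

    def test_single_candidate_selected(self):
        cal = self._calibration([0.5] * 5)
        ens = select_ensemble([_Const(0.4, {"Q": "A" * 34})], cal, {"Q": "A" * 34})
        assert len(ens.members) == 1

    def test_complementary_biases_average_out(self):
        """Two oppositely biased members beat either alone; greedy should
        pick both — verified against brute force over all subsets."""
        y = [0.5] * 8
        cal = self._calibration(y)
        pseqs = {"Q": "A" * 34}
        lo, hi = _Const(0.4, pseqs), _Const(0.6, pseqs)
        candidates = [lo, hi]

        def subset_loss(subset):
            mean = np.mean([c.value for c in subset])
            return (mean - 0.5) ** 2

        import itertools

        best = min(
            (s for r in range(1, 3) for s in itertools.combinations(candidates, r)),
            key=subset_loss,
        )
        ens = select_ensemble(candidates, cal, pseqs)
        assert {m.value for m in ens.members} == {c.value for c in best} == {0.4, 0.6}

    def test_duplicate_member_not_added(self):
        cal = self._calibration([0.5] * 5)
        pseqs = {"Q": "A" * 34}
        ens = select_ensemble([_Const(0.45, pseqs), _Const(0.45, pseqs)], cal, pseqs)
        assert len(ens.members) == 1

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_ensemble([], [], {})
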