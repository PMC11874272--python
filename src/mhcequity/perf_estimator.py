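"""Allele-level performance estimation from training-data summaries.

Given a query allele's pseudosequence and a summary of the binding data
a pan-allele predictor was trained on, a shallow regressor predicts the
PPV the predictor would achieve on that allele. The 63-dimensional
featurization captures the query's relationship to the training data in
five groups:

* g1 (10): BLOSUM62 distances to the 10 most similar alleles with data,
  sorted ascending, padded with 1.0 when fewer than 10 exist;
* g2 (10): positive-record counts of those same 10 alleles;
* g3 (8): total positive counts of training alleles falling in eight
  distance bins [0,0.1), [0.1,0.2), ..., [0.7, inf);
* g4 (34): for each pseudosequence position, total positives of training
  alleles whose residue at that position matches the query's;
* g5 (1): total positive records in the training set.

Counts are scaled log10(1 + count) — real per-allele counts span five
orders of magnitude — and distances enter raw.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import _nn
from .encoders import PSEUDOSEQUENCE_LENGTH, Pseudosequence, distances_to_query
from .lno_protocol import LNOExperiment, TrainingDataSummary

N_NEIGHBORS = 10
N_BINS = 8
BIN_EDGES = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, np.inf])
N_FEATURES = N_NEIGHBORS + N_NEIGHBORS + N_BINS + PSEUDOSEQUENCE_LENGTH + 1  # 63

FEATURE_NAMES = (
    [f"g1_d{i + 1:02d}" for i in range(N_NEIGHBORS)]
    + [f"g2_n{i + 1:02d}" for i in range(N_NEIGHBORS)]
    + [f"g3_b{i + 1}" for i in range(N_BINS)]
    + [f"g4_p{i + 1:02d}" for i in range(PSEUDOSEQUENCE_LENGTH)]
    + ["g5_total"]
)


def _scale(count) -> np.ndarray:
    return np.log10(1.0 + np.asarray(count, dtype=np.float64))


def _query_residues(query) -> str:
    if isinstance(query, Pseudosequence):
        return query.residues
    return str(query)


def featurize_raw(query, summary: TrainingDataSummary) -> dict[str, np.ndarray]:
    """Unscaled feature groups (counts as raw integers); see module doc."""
    q = _query_residues(query)
    if len(q) != PSEUDOSEQUENCE_LENGTH:
        raise ValueError(
            f"query pseudosequence has length {len(q)}, expected {PSEUDOSEQUENCE_LENGTH}"
        )
    alleles = summary.data_alleles()
    counts = np.array([summary.counts[a] for a in alleles], dtype=np.float64)
    if alleles:
        d = distances_to_query(q, [summary.pseudosequences[a] for a in alleles])
    else:
        d = np.zeros(0)

    # g1/g2: ten nearest data alleles (distance then name; names presorted)
    order = np.argsort(d, kind="stable")[:N_NEIGHBORS]
    g1 = np.full(N_NEIGHBORS, 1.0)
    g2_raw = np.zeros(N_NEIGHBORS)
    g1[: len(order)] = d[order]
    g2_raw[: len(order)] = counts[order]

    # g3: counts into distance bins (half-open, last unbounded)
    g3_raw = np.zeros(N_BINS)
    if alleles:
        bins = np.digitize(d, BIN_EDGES[1:-1], right=False)
        for b, c in zip(bins, counts):
            g3_raw[b] += c

    # g4: counts of alleles matching the query residue at each position
    g4_raw = np.zeros(PSEUDOSEQUENCE_LENGTH)
    for a, c in zip(alleles, counts):
        ps = summary.pseudosequences[a]
        for p in range(PSEUDOSEQUENCE_LENGTH):
            if ps[p] == q[p]:
                g4_raw[p] += c

    g5_raw = float(counts.sum())
    return {"g1": g1, "g2": g2_raw, "g3": g3_raw, "g4": g4_raw, "g5": np.array([g5_raw])}


def featurize(query, summary: TrainingDataSummary) -> np.ndarray:
    """The 63-feature vector (10 + 10 + 8 + 34 + 1) for one query allele."""
    raw = featurize_raw(query, summary)
    return np.concatenate(
        [raw["g1"], _scale(raw["g2"]), _scale(raw["g3"]), _scale(raw["g4"]), _scale(raw["g5"])]
    )


def featurize_experiments(
    experiments: Sequence[LNOExperiment],
    pseudosequences: Mapping[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack (features, measured PPV) over a list of LNO experiments."""
    X = np.stack(
        [featurize(pseudosequences[e.test_allele], e.training_summary) for e in experiments]
    )
    y = np.array([e.measured_ppv for e in experiments], dtype=np.float64)
    if np.any(np.isnan(y)):
        raise ValueError("experiments must carry measured PPVs")
    return X, y


class PerfRegressor(BaseEstimator, RegressorMixin):
    """Shallow PPV regressor: 10 ReLU units, dropout 0.25, sigmoid output.

    Trained with RMSProp on mean squared error, minibatches of 10, up to
    1000 epochs, early-stopped when the validation loss stalls for 100
    epochs. A validation set can be passed explicitly (e.g. one
    PPV-balanced fold); otherwise ``validation_fraction`` of the rows is
    held out deterministically.
    """

    def __init__(
        self,
        hidden_units: int = 10,
        dropout: float = 0.25,
        learning_rate: float = 1e-3,
        rho: float = 0.9,
        batch_size: int = 10,
        max_epochs: int = 1000,
        patience: int = 100,
        min_delta: float = 0.0,
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.rho = rho
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
        if len(y) < 2:
            raise ValueError("need at least two training examples")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("targets must lie in [0, 1]")
        if X_val is None:
            rng = np.random.default_rng(self.seed)
            n_val = max(1, int(self.validation_fraction * len(y)))
            idx = rng.permutation(len(y))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            if len(tr_idx) == 0:
                tr_idx = val_idx
            X, X_val, y, y_val = X[tr_idx], X[val_idx], y[tr_idx], y[val_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=np.float64)
        eq = np.zeros(len(y), dtype=np.int8)
        eq_val = np.zeros(len(y_val), dtype=np.int8)
        init = _nn.init_params(X.shape[1], (self.hidden_units,), (False,), self.seed)
        result = _nn.train_rmsprop(
            init,
            (False,),
            X, y, eq,
            X_val, y_val, eq_val,
            learning_rate=self.learning_rate,
            rho=self.rho,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            dropout=self.dropout,
            seed=self.seed,
        )
        self.params_ = result.params
        self.n_epochs_ = result.n_epochs
        self.best_val_loss_ = result.best_val_loss
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        pred, _ = _nn.forward(self.params_, X, (False,))
        return pred

    def predict_ppv(self, features) -> float:
        """Scalar convenience wrapper around :meth:`predict`."""
        return float(self.predict(np.asarray(features))[0])


def ppv_balanced_folds(
    experiments: Sequence[LNOExperiment], k: int = 10
) -> dict[str, int]:
    """Assign test alleles to folds balanced on mean measured PPV.

    All experiments of one test allele share a fold. Alleles are sorted
    by mean measured PPV (descending, name ties) and dealt round-robin
    to folds 0..k-1.
    """
    by_allele: dict[str, list[float]] = {}
    for e in experiments:
        if e.measured_ppv is None:
            raise ValueError("experiments must carry measured PPVs")
        by_allele.setdefault(e.test_allele, []).append(e.measured_ppv)
    if k > len(by_allele):
        raise ValueError(f"k={k} exceeds {len(by_allele)} distinct test alleles")
    ranked = sorted(by_allele, key=lambda a: (-float(np.mean(by_allele[a])), a))
    return {a: i % k for i, a in enumerate(ranked)}


def nearest_neighbor_baseline(
    query,
    experiments: Sequence[LNOExperiment],
    pseudosequences: Mapping[str, str],
    exclude_allele: str | None = None,
) -> float:
    """Mean measured PPV of the most pseudosequence-similar other allele.

    Distance ties break by allele name (first wins).
    """
    q = _query_residues(query)
    by_allele: dict[str, list[float]] = {}
    for e in experiments:
        if e.test_allele != exclude_allele and e.measured_ppv is not None:
            by_allele.setdefault(e.test_allele, []).append(e.measured_ppv)
    others = sorted(a for a in by_allele if a != exclude_allele)
    if not others:
        raise ValueError("no other test allele with measured PPV")
    d = distances_to_query(q, [pseudosequences[a] for a in others])
    best = min(range(len(others)), key=lambda i: (d[i], others[i]))
    return float(np.mean(by_allele[others[best]]))


def evaluate_correlations(predicted, measured) -> tuple[float, float]:
    """(Pearson, Spearman) correlation between predictions and truth."""
    predicted = np.asarray(predicted, dtype=np.float64)
    measured = np.asarray(measured, dtype=np.float64)
    if len(predicted) != len(measured) or len(predicted) < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pearson = stats.pearsonr(predicted, measured).statistic
    spearman = stats.spearmanr(predicted, measured).statistic
    return float(pearson), float(spearman)


def cross_validated_evaluation(
    experiments: Sequence[LNOExperiment],
    pseudosequences: Mapping[str, str],
    k: int = 10,
    seed: int = 0,
    regressor_kwargs: Mapping | None = None,
) -> dict:
    """Out-of-fold comparison of the estimator against the NN baseline.

    Builds PPV-balanced folds, trains one regressor per held-out fold
    (one training fold serves as the early-stopping validation set) and
    collects out-of-fold predictions; the nearest-neighbor baseline for
    each experiment is the mean PPV of the closest allele outside the
    query itself. Returns predictions and (Pearson, Spearman) for both.
    """
    folds = ppv_balanced_folds(experiments, k)
    X, y = featurize_experiments(experiments, pseudosequences)
    fold_ids = np.array([folds[e.test_allele] for e in experiments])
    predicted = np.empty(len(experiments))
    kwargs = dict(regressor_kwargs or {})
    for f in range(k):
        test_mask = fold_ids == f
        val_fold = (f + 1) % k
        val_mask = fold_ids == val_fold
        train_mask = ~test_mask & ~val_mask
        if not train_mask.any():
            train_mask = ~test_mask
        reg = PerfRegressor(seed=seed + f, **kwargs)
        reg.fit(X[train_mask], y[train_mask], X_val=X[val_mask], y_val=y[val_mask])
        predicted[test_mask] = reg.predict(X[test_mask])
    baseline = np.array(
        [
            nearest_neighbor_baseline(
                pseudosequences[e.test_allele],
                experiments,
                pseudosequences,
                exclude_allele=e.test_allele,
            )
            for e in experiments
        ]
    )
    model_r = evaluate_correlations(predicted, y)
    base_r = evaluate_correlations(baseline, y)
    return {
        "predicted": predicted,
        "baseline": baseline,
        "measured": y,
        "model_pearson": model_r[0],
        "model_spearman": model_r[1],
        "baseline_pearson": base_r[0],
        "baseline_spearman": base_r[1],
    }


def save_perf_model(model: PerfRegressor, directory) -> None:
    """Persist a trained estimator: hyperparameter JSON plus weights."""
    import json
    from pathlib import Path

    from .panmhc import _save_params

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "config.json").write_text(json.dumps(model.get_params(), indent=2))
    _save_params(model.params_, d / "weights.npz")


def load_perf_model(directory) -> PerfRegressor:
    """Restore an estimator saved with :func:`save_perf_model`."""
    import json
    from pathlib import Path

    from .panmhc import _load_params

    d = Path(directory)
    model = PerfRegressor(**json.loads((d / "config.json").read_text()))
    model.params_ = _load_params(d / "weights.npz")
    model.n_features_in_ = model.params_.weights[0].shape[0]
    return model


def feature_importance_report(X, predictions) -> "np.ndarray":
    """Spearman correlation of each feature column with the predictions.

    A simple post-hoc check of which feature groups drive the estimator;
    returns one value per feature, nan for constant columns.
    """
    X = np.asarray(X, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    out = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) > 0 and np.ptp(predictions) > 0:
            out[j] = stats.spearmanr(X[:, j], predictions).statistic
    return out


def feature_matrix_to_tsv(X: np.ndarray, path) -> None:
    """Write a feature matrix with the 63 canonical column names."""
    import pandas as pd

    pd.DataFrame(X, columns=FEATURE_NAMES).to_csv(path, sep="\t", index=False)
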