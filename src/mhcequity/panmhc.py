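"""Pan-allele MHC binding predictor: censored loss, members, ensembles.

The predictor is an ensemble of small feed-forward networks. Each member
takes the concatenated encodings of the 34-residue MHC pseudosequence
and the 15-mer-framed peptide and outputs a transformed affinity in
(0, 1). Training minimizes an inequality-censored squared error: records
whose measurement inequality is already satisfied by the prediction
contribute no loss, so qualitative positives ("< 100 nM") and synthetic
negatives ("> 20000 nM") constrain the model only from one side. Member
weights are initialized deterministically from a per-member seed and the
identical initial state is reused whenever that member is retrained.
Ensemble predictions are the arithmetic mean of member outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _nn
from .binding_data import BindingRecord, transformed_label, split_train_validation
from .encoders import Pseudosequence, pad_peptide


def inequality_mse(prediction: float, label) -> float:
    """Inequality-censored squared error for one prediction.

    ``label`` is a :class:`~mhcequity.binding_data.TransformedLabel`
    (target ``y`` on [0, 1] plus the y-space inequality). With "=" this
    is plain squared error; with ">=" (an nM "<" record) predictions at
    or above y incur no loss; with "<=" (an nM ">") predictions at or
    below y incur none.
    """
    y = label.y
    ineq = label.inequality_on_y
    if ineq == "=":
        return (prediction - y) ** 2
    if ineq == ">=":
        return 0.0 if prediction >= y else (prediction - y) ** 2
    if ineq == "<=":
        return 0.0 if prediction <= y else (prediction - y) ** 2
    raise ValueError(f"invalid inequality symbol {ineq!r}")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimizer settings for one ensemble member."""

    hidden_units: tuple[int, ...] = (32,)
    skip_connections: tuple[bool, ...] = (False,)
    peptide_scheme: str = "onehot"
    mhc_scheme: str = "onehot"
    learning_rate: float = 1e-3
    rho: float = 0.9
    batch_size: int = 128
    init_seed: int = 0
    max_epochs: int = 200
    patience: int = 20
    min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_units) <= 3:
            raise ValueError("hidden layer count must be 1, 2 or 3")
        if len(self.skip_connections) != len(self.hidden_units):
            raise ValueError("one skip flag per hidden layer required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_units"] = list(self.hidden_units)
        d["skip_connections"] = list(self.skip_connections)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkConfig":
        d = dict(d)
        d["hidden_units"] = tuple(d["hidden_units"])
        d["skip_connections"] = tuple(bool(x) for x in d["skip_connections"])
        return cls(**d)


# ---------------------------------------------------------------------------
# encoding


def _embedding_table(scheme: str) -> np.ndarray:
    """256-row lookup table from ASCII code to a 20-vector encoding."""
    from .encoders import AMINO_ACIDS, BLOSUM62_MATRIX, PAD

    table = np.full((256, 20), np.nan, dtype=np.float32)
    table[ord(PAD)] = 0.0
    for i, aa in enumerate(AMINO_ACIDS):
        if scheme == "onehot":
            row = np.zeros(20, dtype=np.float32)
            row[i] = 1.0
        else:
            row = BLOSUM62_MATRIX[i].astype(np.float32)
        table[ord(aa)] = row
    return table


_EMB = {s: _embedding_table(s) for s in ("onehot", "blosum62row")}


def _encode_strings(strings: Sequence[str], length: int, scheme: str) -> np.ndarray:
    """Vectorized encoding of equal-length strings into (n, length*20)."""
    if scheme not in _EMB:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    codes = np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)
    out = _EMB[scheme][codes].reshape(len(strings), length * 20)
    if np.isnan(out).any():
        raise ValueError("sequence contains characters outside the 20-aa alphabet")
    return out


def encode_pair_matrix(
    pseudo_residues: Sequence[str],
    peptides: Sequence[str],
    peptide_scheme: str = "onehot",
    mhc_scheme: str = "onehot",
) -> np.ndarray:
    """Row-wise concatenated (pseudosequence, padded peptide) encodings."""
    padded = [pad_peptide(p) for p in peptides]
    mhc = _encode_strings(list(pseudo_residues), 34, mhc_scheme)
    pep = _encode_strings(padded, 15, peptide_scheme)
    return np.concatenate([mhc, pep], axis=1)


def encode_dataset(
    records: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str],
    peptide_scheme: str = "onehot",
    mhc_scheme: str = "onehot",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode records into (X, y, inequality-code) training arrays."""
    residues = [pseudosequences[r.allele] for r in records]
    peptides = [r.peptide for r in records]
    X = encode_pair_matrix(residues, peptides, peptide_scheme, mhc_scheme)
    labels = [transformed_label(r) for r in records]
    y = np.array([lb.y for lb in labels])
    ineq = _nn.encode_inequalities([lb.inequality_on_y for lb in labels])
    return X, y, ineq


# ---------------------------------------------------------------------------
# one member as a sklearn-style estimator


class BindingNetRegressor(BaseEstimator, RegressorMixin):
    """One ensemble member over pre-encoded (MHC, peptide) feature rows.

    sklearn-style estimator: `fit(X, y, inequality=..., X_val=...,
    y_val=..., inequality_val=...)` trains with RMSProp on the censored
    MSE; `predict(X)` returns transformed-affinity scores in (0, 1).
    Initial weights are a pure function of ``init_seed`` and the input
    width, so retraining on the same data reproduces the same model.
    """

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        self.config = config

    def fit(self, X, y, inequality=None, X_val=None, y_val=None, inequality_val=None):
        # float32 throughout: halves memory traffic at no practical cost
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if inequality is None:
            inequality = np.zeros(len(y), dtype=np.int8)
        if X_val is None or y_val is None:
            raise ValueError("a nonempty validation set is required for early stopping")
        X_val = np.asarray(X_val, dtype=np.float32)
        y_val = np.asarray(y_val, dtype=np.float32)
        if len(X_val) == 0:
            raise ValueError("validation set is empty")
        if inequality_val is None:
            inequality_val = np.zeros(len(y_val), dtype=np.int8)
        cfg = self.config
        init = _nn.init_params(
            X.shape[1], cfg.hidden_units, cfg.skip_connections, cfg.init_seed
        ).astype(np.float32)
        result = _nn.train_rmsprop(
            init,
            cfg.skip_connections,
            X,
            y,
            np.asarray(inequality, dtype=np.int8),
            X_val,
            y_val,
            np.asarray(inequality_val, dtype=np.int8),
            learning_rate=cfg.learning_rate,
            rho=cfg.rho,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            min_delta=cfg.min_delta,
            seed=cfg.init_seed,
        )
        self.params_ = result.params
        self.n_epochs_ = result.n_epochs
        self.best_val_loss_ = result.best_val_loss
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        pred, _ = _nn.forward(self.params_, np.asarray(X, dtype=np.float32),
                              self.config.skip_connections)
        return pred.astype(np.float64)


# ---------------------------------------------------------------------------
# the user-facing predictor over records


class BindingPredictor:
    """One trained member bound to its encoders and pseudosequence table."""

    def __init__(self, config: NetworkConfig, pseudosequences: Mapping[str, str]):
        self.config = config
        self.pseudosequences = dict(pseudosequences)
        self.net = BindingNetRegressor(config)

    def fit(
        self,
        records: Sequence[BindingRecord],
        validation: Sequence[BindingRecord] | None = None,
        split_seed: int = 0,
    ) -> "BindingPredictor":
        """Train on binding records; auto-splits 1/5 per allele if no
        validation set is given."""
        if validation is None:
            records, validation = split_train_validation(records, 0.2, split_seed)
            if not validation:
                raise ValueError("auto-split produced an empty validation set")
        cfg = self.config
        X, y, q = encode_dataset(records, self.pseudosequences,
                                 cfg.peptide_scheme, cfg.mhc_scheme)
        Xv, yv, qv = encode_dataset(validation, self.pseudosequences,
                                    cfg.peptide_scheme, cfg.mhc_scheme)
        self.net.fit(X, y, inequality=q, X_val=Xv, y_val=yv, inequality_val=qv)
        return self

    def _resolve(self, allele) -> str:
        if isinstance(allele, Pseudosequence):
            return allele.residues
        if allele in self.pseudosequences:
            return self.pseudosequences[allele]
        if isinstance(allele, str) and len(allele) == 34:
            return allele
        raise KeyError(f"unknown allele {allele!r}")

    def score_peptides(self, allele, peptides: Sequence[str]) -> np.ndarray:
        """Transformed-affinity scores for many peptides on one allele."""
        residues = self._resolve(allele)
        cfg = self.config
        X = encode_pair_matrix([residues] * len(peptides), list(peptides),
                               cfg.peptide_scheme, cfg.mhc_scheme)
        return self.net.predict(X)

    def predict(self, allele, peptide: str) -> float:
        if not 8 <= len(peptide) <= 15:
            raise ValueError(f"peptide length {len(peptide)} outside [8, 15]")
        return float(self.score_peptides(allele, [peptide])[0])


def _save_params(params, path) -> None:
    import numpy as _np

    arrays = {f"w{i}": w for i, w in enumerate(params.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(params.biases)})
    _np.savez(path, **arrays)


def _load_params(path):
    import numpy as _np

    from ._nn import MLPParams

    with _np.load(path) as z:
        n = sum(1 for k in z.files if k.startswith("w"))
        return MLPParams(
            weights=[z[f"w{i}"] for i in range(n)],
            biases=[z[f"b{i}"] for i in range(n)],
        )


def save_predictor(predictor: "BindingPredictor", directory) -> None:
    """Persist a trained predictor: config JSON, pseudosequence TSV, weights."""
    import json
    from pathlib import Path

    from .encoders import write_pseudosequences

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "config.json").write_text(json.dumps(predictor.config.to_dict(), indent=2))
    write_pseudosequences(predictor.pseudosequences, d / "pseudosequences.tsv")
    _save_params(predictor.net.params_, d / "weights.npz")


def load_predictor(directory) -> "BindingPredictor":
    """Restore a predictor saved with :func:`save_predictor`."""
    import json
    from pathlib import Path

    from .encoders import read_pseudosequences

    d = Path(directory)
    config = NetworkConfig.from_dict(json.loads((d / "config.json").read_text()))
    predictor = BindingPredictor(config, read_pseudosequences(d / "pseudosequences.tsv"))
    predictor.net.params_ = _load_params(d / "weights.npz")
    predictor.net.n_features_in_ = predictor.net.params_.weights[0].shape[0]
    return predictor


@dataclass
class Ensemble:
    """Mean-aggregated collection of trained members."""

    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def score_peptides(self, allele, peptides: Sequence[str]) -> np.ndarray:
        preds = [m.score_peptides(allele, peptides) for m in self.members]
        return np.mean(preds, axis=0)

    def predict(self, allele, peptide: str) -> float:
        if not 8 <= len(peptide) <= 15:
            raise ValueError(f"peptide length {len(peptide)} outside [8, 15]")
        return float(self.score_peptides(allele, [peptide])[0])


def ensemble_calibration_loss(member_preds: Sequence[np.ndarray], y, ineq) -> float:
    """Censored MSE of the mean of the given member prediction vectors."""
    mean_pred = np.mean(member_preds, axis=0)
    return _nn.censored_mse(mean_pred, y, ineq)


def select_ensemble(
    candidates: Sequence,
    calibration: Sequence[BindingRecord],
    pseudosequences: Mapping[str, str] | None = None,
) -> Ensemble:
    """Greedy forward selection of members on a calibration set.

    Starting from the single best candidate, repeatedly add the
    candidate whose inclusion most lowers the censored MSE of the
    ensemble mean; stop when no candidate strictly improves it.
    Candidates may repeat in principle but an exact duplicate of a
    selected member never strictly improves the mean and is not added.
    """
    if not candidates:
        raise ValueError("no candidate models")
    if pseudosequences is None:
        pseudosequences = getattr(candidates[0], "pseudosequences")
    labels = [transformed_label(r) for r in calibration]
    y = np.array([lb.y for lb in labels])
    ineq = _nn.encode_inequalities([lb.inequality_on_y for lb in labels])

    # score calibration set once per candidate
    by_allele: dict[str, list[int]] = {}
    for i, r in enumerate(calibration):
        by_allele.setdefault(r.allele, []).append(i)
    cand_preds = []
    for cand in candidates:
        pred = np.empty(len(calibration))
        for allele, idxs in by_allele.items():
            peptides = [calibration[i].peptide for i in idxs]
            pred[idxs] = cand.score_peptides(pseudosequences[allele], peptides)
        cand_preds.append(pred)

    selected: list[int] = []
    best_loss = np.inf
    while True:
        best_j, best_new = None, best_loss
        for j, pred in enumerate(cand_preds):
            trial = [cand_preds[i] for i in selected] + [pred]
            loss = ensemble_calibration_loss(trial, y, ineq)
            if loss < best_new:
                best_new, best_j = loss, j
        if best_j is None:
            break
        selected.append(best_j)
        best_loss = best_new
    return Ensemble(members=[candidates[j] for j in selected])
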