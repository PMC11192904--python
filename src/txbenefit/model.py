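"""The remission classifier and differential treatment benefit inference.

A dense network (default two hidden layers of 40 ELU units, dropout 0.15,
two-unit softmax head) maps a patient's harmonized features plus a one-hot
treatment encoding to a remission probability.  Differential prediction
re-runs inference with each candidate treatment's encoding switched on,
yielding a probability per treatment and a ranking; the variation of this
ranking across patients is the model's clinical payload.  A logistic
regression trained on the same design matrix serves as the linear
baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .nn import DenseNet, TrainingHistory

__all__ = [
    "NetConfig",
    "TrainedModel",
    "encode_design",
    "train",
    "predict_remission",
    "differential_predict",
    "baseline_logistic",
    "TREATMENT_PREFIX",
]

TREATMENT_PREFIX = "treatment::"


@dataclass
class NetConfig:
    """Architecture and training recipe for the dense classifier."""

    hidden_layers: list[int] = field(default_factory=lambda: [40, 40])
    activation: str = "elu"
    dropout: float = 0.15
    learning_rate: float = 0.001
    optimizer: str = "adam"
    max_epochs: int = 300
    early_stopping_patience: int = 100
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.early_stopping_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is implemented")


@dataclass
class TrainedModel:
    """Fitted network plus the ordered input schema it expects."""

    net: DenseNet
    schema: list[str]  # ordered column names incl. treatment one-hots
    config: NetConfig
    history: TrainingHistory

    @property
    def treatment_names(self) -> list[str]:
        return [c[len(TREATMENT_PREFIX) :] for c in self.schema if c.startswith(TREATMENT_PREFIX)]

    @property
    def clinical_features(self) -> list[str]:
        return [c for c in self.schema if not c.startswith(TREATMENT_PREFIX)]

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.schema if c not in X.columns]
            if missing:
                raise ValueError(f"input does not match model schema; missing {missing}")
            X = X[self.schema].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.schema):
            raise ValueError(
                f"input width {X.shape[1]} does not match schema width {len(self.schema)}"
            )
        return X

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = {
            "schema": self.schema,
            "config": asdict(self.config),
            "weights": [w.tolist() for w in self.net.W],
            "biases": [b.tolist() for b in self.net.b],
            "history": {
                "best_epoch": self.history.best_epoch,
                "stopped_epoch": self.history.stopped_epoch,
                "train_loss": self.history.train_loss,
                "val_loss": self.history.val_loss,
            },
        }
        payload.update(extra or {})
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        config = NetConfig(**payload["config"])
        schema = payload["schema"]
        net = DenseNet(
            len(schema),
            hidden=tuple(config.hidden_layers),
            dropout=config.dropout,
            seed=config.seed,
        )
        net.W = [np.asarray(w) for w in payload["weights"]]
        net.b = [np.asarray(b) for b in payload["biases"]]
        hist = TrainingHistory(
            train_loss=payload["history"]["train_loss"],
            val_loss=payload["history"]["val_loss"],
            best_epoch=payload["history"]["best_epoch"],
            stopped_epoch=payload["history"]["stopped_epoch"],
        )
        return cls(net=net, schema=schema, config=config, history=hist)


def encode_design(
    features: pd.DataFrame, treatments: pd.Series, treatment_names: list[str]
) -> pd.DataFrame:
    """Append a one-hot treatment encoding to the clinical feature matrix."""
    unknown = set(treatments.unique()) - set(treatment_names)
    if unknown:
        raise ValueError(f"unknown treatments {sorted(unknown)}")
    out = features.copy()
    for t in treatment_names:
        out[TREATMENT_PREFIX + t] = (treatments == t).astype(float)
    return out


def train(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame | None,
    y_val,
    config: NetConfig | None = None,
) -> TrainedModel:
    """Fit the classifier; early stopping restores the best validation epoch.

    ``X_train`` columns (clinical features plus ``treatment::*`` one-hots)
    define the model schema; validation columns must match.
    """
    config = config or NetConfig()
    schema = [str(c) for c in X_train.columns]
    if X_val is not None and [str(c) for c in X_val.columns] != schema:
        raise ValueError("validation schema does not match training schema")
    net = DenseNet(
        len(schema),
        hidden=tuple(config.hidden_layers),
        dropout=config.dropout,
        activation=config.activation,
        seed=config.seed,
    )
    hist = net.fit(
        X_train.to_numpy(dtype=float),
        np.asarray(y_train, dtype=int),
        X_val.to_numpy(dtype=float) if X_val is not None else None,
        np.asarray(y_val, dtype=int) if y_val is not None else None,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.early_stopping_patience,
        batch_size=config.batch_size,
    )
    return TrainedModel(net=net, schema=schema, config=config, history=hist)


def predict_remission(model: TrainedModel, X) -> np.ndarray | float:
    """Softmax probability of remission (class 1); dropout disabled."""
    probs = model.net.predict_proba(model._matrix(X))[:, 1]
    return float(probs[0]) if np.ndim(X) == 1 or isinstance(X, pd.Series) else probs


def differential_predict(
    model: TrainedModel, clinical: pd.Series | dict, treatments: list[str] | None = None
) -> tuple[dict[str, float], list[str]]:
    """Per-treatment remission probabilities and the descending ranking.

    The patient's clinical features are held fixed while the one-hot
    treatment encoding cycles through the candidates; ties in probability
    are broken by the model's configured treatment order.
    """
    if isinstance(clinical, dict):
        clinical = pd.Series(clinical)
    known = model.treatment_names
    treatments = list(treatments) if treatments is not None else list(known)
    unknown = set(treatments) - set(known)
    if unknown:
        raise ValueError(f"unknown treatments {sorted(unknown)}")
    rows = []
    for t in treatments:
        row = clinical.copy()
        for name in known:
            row[TREATMENT_PREFIX + name] = 1.0 if name == t else 0.0
        rows.append(row)
    X = pd.DataFrame(rows)
    probs = model.net.predict_proba(model._matrix(X))[:, 1]
    table = dict(zip(treatments, map(float, probs)))
    ranking = sorted(treatments, key=lambda t: (-table[t], known.index(t)))
    return table, ranking


def differential_predict_table(
    model: TrainedModel, clinical: pd.DataFrame, treatments: list[str] | None = None
) -> pd.DataFrame:
    """Vectorized :func:`differential_predict` for a whole cohort.

    Returns a patient x treatment table of remission probabilities.
    """
    known = model.treatment_names
    treatments = list(treatments) if treatments is not None else list(known)
    unknown = set(treatments) - set(known)
    if unknown:
        raise ValueError(f"unknown treatments {sorted(unknown)}")
    cols = {}
    for t in treatments:
        X = clinical.copy()
        for name in known:
            X[TREATMENT_PREFIX + name] = 1.0 if name == t else 0.0
        cols[t] = model.net.predict_proba(model._matrix(X))[:, 1]
    return pd.DataFrame(cols, index=clinical.index)


def baseline_logistic(
    X_train: pd.DataFrame,
    y_train,
    X_eval: pd.DataFrame,
    y_eval,
    C: float = 1.0,
) -> dict:
    """L2-regularized logistic regression on the same design matrix.

    Returns the evaluation AUC and fitted coefficients for comparison
    with the network.
    """
    from .evaluate import auroc

    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(X_train.to_numpy(dtype=float), np.asarray(y_train, dtype=int))
    prob = clf.predict_proba(X_eval.to_numpy(dtype=float))[:, 1]
    return {
        "auc": auroc(np.asarray(y_eval, dtype=int), prob),
        "coefficients": dict(zip([str(c) for c in X_train.columns], clf.coef_[0])),
        "intercept": float(clf.intercept_[0]),
        "probabilities": prob,
    }
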