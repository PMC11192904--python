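"""CancelOut feature selection.

A per-feature gate layer (inputs multiplied element-wise by a
sigmoid-squashed weight vector) is prepended to a network with the same
architecture as the final remission classifier.  The training loss adds
two regularizers to the cross-entropy::

    loss = CE + lambda1 * mean(sigmoid(w)) - lambda2 * var(w)

The first term pushes gates shut unless a feature earns its keep; the
second rewards spread among the gate weights so informative and
uninformative features separate.  After training, each feature's raw gate
weight is its relevance score and the top-k are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import DenseNet

__all__ = ["CancelOutResult", "cancelout_scores", "select_features"]


@dataclass
class CancelOutResult:
    """Per-feature gate scores and the deterministic top-k selection."""

    feature_ids: list[str]
    scores: np.ndarray
    k: int
    selected_ids: list[str] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)

    def ranking(self) -> list[str]:
        order = sorted(
            range(len(self.feature_ids)),
            key=lambda i: (-self.scores[i], self.feature_ids[i]),
        )
        return [self.feature_ids[i] for i in order]


def cancelout_scores(
    X,
    y,
    k: int | None = None,
    hidden: tuple[int, ...] = (40, 40),
    dropout: float = 0.15,
    learning_rate: float = 1e-3,
    epochs: int = 150,
    batch_size: int = 128,
    lambda1: float = 0.2,
    lambda2: float = 0.1,
    seed: int = 0,
) -> CancelOutResult:
    """Train the gated network and score every input feature.

    ``X`` must be complete (rows with missing candidate features are
    dropped and counted upstream).  Returns finite per-feature scores and,
    when ``k`` is given, the k highest-scoring features with ties broken
    by lexicographic feature id.
    """
    if isinstance(X, pd.DataFrame):
        ids = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        ids = [f"f{i:02d}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=int)
    if np.isnan(Xa).any():
        raise ValueError("X contains missing values; drop incomplete rows upstream")
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes to score features")

    net = DenseNet(
        Xa.shape[1], hidden=hidden, dropout=dropout, gate=True, seed=seed
    )
    hist = net.fit(
        Xa,
        y,
        learning_rate=learning_rate,
        max_epochs=epochs,
        batch_size=batch_size,
        lambda1=lambda1,
        lambda2=lambda2,
    )
    scores = net.gate_weights.copy()
    if not np.isfinite(scores).all():
        raise RuntimeError("non-finite CancelOut scores; training diverged")
    result = CancelOutResult(
        feature_ids=ids, scores=scores, k=k or len(ids), train_loss=hist.train_loss
    )
    result.selected_ids = select_features(result, result.k)
    return result


def select_features(result: CancelOutResult, k: int) -> list[str]:
    """Top-k features by score, descending; ties by lexicographic id."""
    if not 1 <= k <= len(result.feature_ids):
        raise ValueError(f"k={k} out of range [1, {len(result.feature_ids)}]")
    return result.ranking()[:k]
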