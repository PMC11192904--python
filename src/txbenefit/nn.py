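"""Minimal dense feed-forward network trained with Adam.

Implements exactly the pieces the remission classifier needs: fully
connected layers, ELU activations, inverted dropout, a two-class softmax
head trained with cross-entropy, Adam updates, and early stopping that
restores the parameters of the best validation epoch.  An optional
per-feature sigmoid gate (the CancelOut layer) can be prepended; its
regularized loss terms are handled inside :meth:`DenseNet.fit`.

Everything is plain numpy with hand-written gradients.  The network is
small (tens of units, thousands of rows) so vectorized batch updates on a
single CPU are more than fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenseNet", "TrainingHistory", "softmax", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _elu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad(z: np.ndarray, activated: np.ndarray) -> np.ndarray:
    # d/dz elu(z) = 1 for z>0, elu(z)+1 otherwise (alpha = 1)
    return np.where(z > 0, 1.0, activated + 1.0)


_ACTIVATIONS = {"elu": (_elu, _elu_grad)}


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


@dataclass
class TrainingHistory:
    """Per-epoch losses plus where early stopping landed."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class DenseNet:
    """Fully connected classifier with optional CancelOut input gate.

    Parameters
    ----------
    n_inputs : number of input features.
    hidden : widths of the hidden layers.
    n_outputs : softmax width (2 for binary remission).
    dropout : inverted-dropout rate applied after each hidden activation
        during training only.
    activation : hidden activation name; only ``"elu"`` is provided.
    gate : if True, prepend a per-feature gate ``x * sigmoid(w)`` whose
        learned weights ``w`` score feature relevance.
    seed : seeds weight init, batch shuffling and dropout masks.
    """

    def __init__(
        self,
        n_inputs: int,
        hidden: tuple[int, ...] = (40, 40),
        n_outputs: int = 2,
        dropout: float = 0.15,
        activation: str = "elu",
        gate: bool = False,
        seed: int = 0,
    ):
        if n_inputs < 1 or any(h < 1 for h in hidden):
            raise ValueError("layer widths must be >= 1")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        self.act, self.act_grad = _ACTIVATIONS[activation]
        sizes = [n_inputs, *hidden, n_outputs]
        # He-style init suits ELU's near-ReLU positive branch.
        self.W = [
            self.rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.gate_weights = np.full(n_inputs, 4.0) if gate else None
        self.history: TrainingHistory | None = None
        self._adam_state: dict | None = None

    # ---------------------------------------------------------------- params

    def _params(self) -> list[np.ndarray]:
        ps = list(self.W) + list(self.b)
        if self.gate_weights is not None:
            ps.append(self.gate_weights)
        return ps

    def _set_params(self, values: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [v.copy() for v in values[:n]]
        self.b = [v.copy() for v in values[n : 2 * n]]
        if self.gate_weights is not None:
            self.gate_weights = values[-1].copy()

    # --------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, training: bool):
        cache = {"inputs": [], "pre": [], "masks": []}
        h = np.asarray(X, dtype=float)
        if self.gate_weights is not None:
            cache["gate_in"] = h
            h = h * sigmoid(self.gate_weights)
        n_layers = len(self.W)
        for i in range(n_layers):
            cache["inputs"].append(h)
            z = h @ self.W[i] + self.b[i]
            if i < n_layers - 1:
                cache["pre"].append(z)
                h = self.act(z)
                if training and self.dropout > 0:
                    mask = (self.rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = z
        return softmax(h), cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities with dropout disabled (pure function)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("inputs contain missing or non-finite values")
        probs, _ = self._forward(X, training=False)
        return probs

    # -------------------------------------------------------------- backward

    def _backward(self, probs, y, cache, lambda1, lambda2):
        n = len(y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = cache["inputs"][i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                mask = cache["masks"][i - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * self.act_grad(cache["pre"][i - 1], self.act(cache["pre"][i - 1]))
        grads = gW + gb
        if self.gate_weights is not None:
            g = self.gate_weights
            s = sigmoid(g)
            d = len(g)
            # classification path: layer-0 input is x * sigmoid(g), so pull
            # delta (currently at layer-0 pre-activation) through W[0].
            delta_in = delta @ self.W[0].T
            dgate = (delta_in * cache["gate_in"]).sum(axis=0) * s * (1.0 - s)
            # + lambda1 * mean(sigmoid(g))  - lambda2 * var(g)
            dgate += lambda1 * s * (1.0 - s) / d
            dgate -= lambda2 * 2.0 * (g - g.mean()) / d
            grads.append(dgate)
        return grads

    def _gate_penalty(self, lambda1: float, lambda2: float) -> float:
        if self.gate_weights is None:
            return 0.0
        g = self.gate_weights
        return float(lambda1 * sigmoid(g).mean() - lambda2 * g.var())

    # -------------------------------------------------------------- training

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        learning_rate: float = 1e-3,
        max_epochs: int = 300,
        patience: int = 100,
        batch_size: int = 128,
        lambda1: float = 0.0,
        lambda2: float = 0.0,
    ) -> TrainingHistory:
        """Mini-batch Adam with early stopping on validation loss.

        The parameters from the epoch with the lowest validation loss are
        restored before returning; without a validation set the network
        simply trains for ``max_epochs``.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels are constant; a two-class softmax cannot be trained")
        if not np.isfinite(X).all():
            raise ValueError("training inputs contain missing or non-finite values")
        has_val = X_val is not None and y_val is not None and len(np.asarray(y_val)) > 0
        if has_val:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=int)

        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        hist = TrainingHistory()
        best_loss = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = -1
        n = len(y)

        for epoch in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs, cache = self._forward(X[idx], training=True)
                loss = _cross_entropy(probs, y[idx]) + self._gate_penalty(lambda1, lambda2)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(batch {start // batch_size}); lower the learning rate"
                    )
                epoch_loss += loss * len(idx)
                grads = self._backward(probs, y[idx], cache, lambda1, lambda2)
                t += 1
                params = self._params()
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1**t)
                    vhat = v[j] / (1 - beta2**t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            hist.train_loss.append(epoch_loss / n)

            if has_val:
                val_probs, _ = self._forward(X_val, training=False)
                val_loss = _cross_entropy(val_probs, y_val) + self._gate_penalty(lambda1, lambda2)
                hist.val_loss.append(val_loss)
                if val_loss < best_loss:
                    best_loss = val_loss
                    best_params = [p.copy() for p in self._params()]
                    best_epoch = epoch
                elif epoch - best_epoch >= patience:
                    hist.stopped_epoch = epoch
                    break
        if hist.stopped_epoch < 0:
            hist.stopped_epoch = len(hist.train_loss) - 1
        if has_val:
            self._set_params(best_params)
            hist.best_epoch = best_epoch
        else:
            hist.best_epoch = hist.stopped_epoch
        self.history = hist
        return hist
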