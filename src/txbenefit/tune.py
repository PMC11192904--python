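"""Bayesian optimization over network architecture and feature count.

Sequential model-based optimization with a Gaussian-process surrogate
(Matern 5/2 kernel) and expected improvement, maximizing validation AUC.
The search space mixes integers (number of layers, layer width, number of
features k), floats (dropout) and log-scale floats (learning rate); all
are mapped onto a unit cube for the surrogate.  The best configuration
reported is always the argmax over the trial log — never a surrogate
extrapolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel, ConstantKernel

__all__ = ["SearchSpace", "optimize", "default_search_space"]


@dataclass
class SearchSpace:
    """Parameter ranges: name -> ("int"|"float", lo, hi[, "log"]) or
    ("choice", [options])."""

    params: dict[str, tuple]
    budget: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        for name, spec in self.params.items():
            if spec[0] not in {"int", "float", "choice"}:
                raise ValueError(f"unknown parameter kind {spec[0]!r} for {name}")


def default_search_space(max_k: int, budget: int = 30, seed: int = 0) -> SearchSpace:
    """Ranges bracketing plausible optima for a tabular clinical classifier."""
    return SearchSpace(
        params={
            "n_layers": ("int", 1, 4),
            "width": ("int", 8, 128, "log"),
            "dropout": ("float", 0.0, 0.5),
            "learning_rate": ("float", 1e-4, 1e-2, "log"),
            "k": ("int", min(5, max_k), max_k),
        },
        budget=budget,
        seed=seed,
    )


def _decode(u: np.ndarray, space: SearchSpace) -> dict:
    cfg = {}
    for ui, (name, spec) in zip(u, space.params.items()):
        kind = spec[0]
        if kind == "choice":
            options = spec[1]
            cfg[name] = options[min(int(ui * len(options)), len(options) - 1)]
            continue
        lo, hi = float(spec[1]), float(spec[2])
        log = len(spec) > 3 and spec[3] == "log"
        if log:
            val = float(np.exp(np.log(lo) + ui * (np.log(hi) - np.log(lo))))
        else:
            val = lo + ui * (hi - lo)
        cfg[name] = int(round(val)) if kind == "int" else val
    return cfg


def _expected_improvement(gp, candidates: np.ndarray, best: float) -> np.ndarray:
    mu, sigma = gp.predict(candidates, return_std=True)
    sigma = np.maximum(sigma, 1e-9)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def optimize(space: SearchSpace, objective) -> tuple[dict, list[dict]]:
    """Maximize ``objective(config) -> score`` within ``space.budget`` trials.

    Starts with quasi-random exploration, then fits the GP surrogate to
    completed trials and proposes the expected-improvement argmax among
    random candidate draws.  A trial whose objective raises is logged as
    failed and skipped by the surrogate; if every trial fails the error is
    re-raised with the log attached.

    Returns (best observed config, full trial log).
    """
    rng = np.random.default_rng(space.seed)
    d = len(space.params)
    n_init = min(space.budget, max(4, space.budget // 3))
    log: list[dict] = []
    U, scores = [], []

    for trial in range(space.budget):
        if trial < n_init or len(scores) < 2:
            u = rng.random(d)
        else:
            kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5) + WhiteKernel(
                noise_level=1e-3
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=int(space.seed) % (2**31)
            )
            with warnings.catch_warnings():
                # surrogate hyperparameter fits on tiny trial logs may stop
                # early; the EI proposal only needs a rough fit
                warnings.simplefilter("ignore")
                gp.fit(np.asarray(U), np.asarray(scores))
            candidates = rng.random((512, d))
            ei = _expected_improvement(gp, candidates, max(scores))
            u = candidates[int(np.argmax(ei))]
        cfg = _decode(u, space)
        entry = {"trial": trial, "config": cfg}
        try:
            score = float(objective(cfg))
        except Exception as exc:  # log and continue
            entry.update(status="failed", error=str(exc))
            log.append(entry)
            continue
        entry.update(status="ok", score=score)
        log.append(entry)
        U.append(u)
        scores.append(score)

    if not scores:
        raise RuntimeError(f"every trial failed; trial log: {log}")
    best_entry = max(
        (e for e in log if e["status"] == "ok"), key=lambda e: (e["score"], -e["trial"])
    )
    return dict(best_entry["config"]), log
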