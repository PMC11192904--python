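"""Performance metrics, one-at-a-time sensitivity analysis, and the
subgroup bias audit.

The bias audit screens for harmful learned bias with a deliberately
simple rule: within each demographic or treatment subgroup, compare the
observed remission rate to the mean predicted probability and flag any
subgroup whose remission the model *under*-predicts by more than five
percentage points.  Over-prediction is not flagged; the concern is a
model that systematically talks down a group's chance of remitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MetricReport",
    "confusion_metrics",
    "auroc",
    "SensitivityCurve",
    "sensitivity_analysis",
    "bias_audit",
    "DEFAULT_AGE_BANDS",
    "age_band",
    "plot_sensitivity",
    "plot_bias",
]


@dataclass
class MetricReport:
    """Threshold metrics plus confusion counts for one data split.

    Metrics with an undefined denominator (e.g. PPV with no positive
    calls) are reported as None, never as 0.
    """

    split: str
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    f1: float | None = None
    auc: float | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(y_true, y_prob, threshold: float = 0.5, split: str = "") -> MetricReport:
    """Threshold predictions and fill the full confusion-based report."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_prob, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    ppv = _safe_ratio(tp, tp + fp)
    sens = _safe_ratio(tp, tp + fn)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    auc = auroc(y, p) if len(np.unique(y)) == 2 else None
    return MetricReport(
        split=split,
        threshold=threshold,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / len(y),
        sensitivity=sens,
        specificity=_safe_ratio(tn, tn + fp),
        ppv=ppv,
        npv=_safe_ratio(tn, tn + fn),
        f1=f1,
        auc=auc,
        n=len(y),
    )


def auroc(y_true, y_prob) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    The rank (Mann-Whitney) formulation, threshold-free and
    scale-invariant.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_prob, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ------------------------------------------------------------- sensitivity


@dataclass
class SensitivityCurve:
    """Observed vs counterfactual-predicted remission across one feature.

    For each support value: the observed remission proportion among
    patients who truly hold that value (with n), and the mean predicted
    probability when *every* patient's feature is overwritten to it.
    """

    feature_id: str
    values: list[float]
    observed: list[float | None]
    observed_n: list[int]
    predicted: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "observed_proportion": self.observed,
                "observed_n": self.observed_n,
                "mean_predicted": self.predicted,
            }
        )


def sensitivity_analysis(
    predict_fn,
    X: pd.DataFrame,
    y,
    feature_id: str,
    support: list[float] | None = None,
    max_support: int = 25,
) -> SensitivityCurve:
    """Vary one feature while holding everything else constant.

    ``predict_fn`` maps a schema-complete DataFrame to remission
    probabilities.  ``support`` defaults to the feature's distinct
    observed values (including the fractional values score equating
    creates); a continuous feature with more than ``max_support`` distinct
    values is binned into deciles.
    """
    if feature_id not in X.columns:
        raise ValueError(f"{feature_id!r} not in the model's input schema")
    y = np.asarray(y, dtype=int)
    col = X[feature_id].to_numpy(dtype=float)
    if support is None:
        uniq = np.unique(col[~np.isnan(col)])
        if len(uniq) > max_support:
            support = list(np.unique(np.quantile(col, np.linspace(0.05, 0.95, 10))))
        else:
            support = list(uniq)
    support = sorted(float(v) for v in support)

    values, observed, observed_n, predicted = [], [], [], []
    for v in support:
        at_v = np.isclose(col, v)
        n_v = int(at_v.sum())
        obs = float(y[at_v].mean()) if n_v else None
        X_cf = X.copy()
        X_cf[feature_id] = v
        pred = float(np.mean(predict_fn(X_cf)))
        values.append(v)
        observed.append(obs)
        observed_n.append(n_v)
        predicted.append(pred)
    return SensitivityCurve(feature_id, values, observed, observed_n, predicted)


# --------------------------------------------------------------- bias audit

DEFAULT_AGE_BANDS = [(18.0, 25.9), (26.0, 40.9), (41.0, 64.9), (65.0, 130.9)]


def age_band(age, bands=None) -> str:
    bands = bands or DEFAULT_AGE_BANDS
    for lo, hi in bands:
        if lo <= age <= hi + 0.0999:  # bands abut at .9 / next integer
            return f"{lo:g}-{hi:g}"
    return "other"


def bias_audit(
    y_true,
    y_prob,
    subgroups: pd.DataFrame,
    split: str = "",
    threshold: float = 0.05,
    age_bands=None,
    metric_threshold: float = 0.5,
) -> pd.DataFrame:
    """Observed vs mean-predicted remission per demographic subgroup.

    ``subgroups`` carries one column per factor (e.g. race, sex, age,
    treatment); an ``age`` column is binned into the configured bands.
    Each subgroup row reports the observed rate, mean predicted
    probability with its standard error, the under-prediction gap
    (observed - predicted) and a flag raised when the gap exceeds
    ``threshold`` (one-sided: over-prediction never flags).  Subgroup
    confusion metrics are attached for context; treat small-n rows with
    caution.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_prob, dtype=float)
    if len(subgroups) != len(y):
        raise ValueError("subgroup labels must cover all patients")
    rows = []
    for factor in subgroups.columns:
        labels = subgroups[factor]
        if factor == "age":
            labels = labels.map(lambda a: age_band(float(a), age_bands))
        if isinstance(labels.dtype, pd.CategoricalDtype):
            levels = [str(c) for c in labels.cat.categories]  # declared levels, even empty
        else:
            levels = sorted(labels.astype(str).unique())
        for level in levels:
            mask = (labels.astype(str) == level).to_numpy()
            n = int(mask.sum())
            row = {"split": split, "factor": factor, "subgroup": level, "n": n}
            if n == 0:
                row.update(
                    observed_rate=None,
                    mean_predicted=None,
                    se_predicted=None,
                    under_prediction=None,
                    flag=False,
                )
            else:
                obs = float(y[mask].mean())
                pred = float(p[mask].mean())
                se = float(p[mask].std(ddof=1) / np.sqrt(n)) if n > 1 else None
                gap = obs - pred
                row.update(
                    observed_rate=obs,
                    mean_predicted=pred,
                    se_predicted=se,
                    under_prediction=gap,
                    flag=bool(gap > threshold),
                )
                if len(np.unique(y[mask])) == 2:
                    m = confusion_metrics(y[mask], p[mask], metric_threshold, split)
                    row.update(
                        accuracy=m.accuracy, auc=m.auc, sensitivity=m.sensitivity,
                        specificity=m.specificity, ppv=m.ppv, npv=m.npv,
                    )
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- plotting


def plot_sensitivity(curve: SensitivityCurve, path) -> None:
    """Observed (dots with n) vs counterfactual-predicted remission."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    obs = [(v, o) for v, o in zip(curve.values, curve.observed) if o is not None]
    if obs:
        ax.scatter(*zip(*obs), color="tab:blue", label="observed proportion")
    ax.scatter(curve.values, curve.predicted, color="tab:red", label="mean predicted")
    ax.set_xlabel(curve.feature_id)
    ax.set_ylabel("P(remission)")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_bias(report: pd.DataFrame, path) -> None:
    """Observed vs mean-predicted remission per subgroup, with SE bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = report.dropna(subset=["observed_rate"])
    labels = rep["factor"] + ": " + rep["subgroup"].astype(str)
    x = np.arange(len(rep))
    fig, ax = plt.subplots(figsize=(max(5, 0.45 * len(rep)), 3.6))
    ax.bar(x - 0.2, rep["observed_rate"], width=0.4, label="observed", color="tab:blue")
    ax.bar(
        x + 0.2,
        rep["mean_predicted"],
        width=0.4,
        yerr=rep["se_predicted"].fillna(0.0),
        label="mean predicted",
        color="tab:red",
    )
    ax.set_xticks(x, labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("P(remission)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
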