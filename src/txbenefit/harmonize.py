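"""Transform grouped questionnaire items into harmonized per-patient features.

The core of dataset merging: items that query the same clinical dimension
but were administered on different response scales are placed on a common
scale by score equating, validity-checked, averaged into a single
transformed variable, and finally standard-scaled (with a positivity
offset) for network input.  Groups dominated by binary items are instead
binarized member-wise and combined with an any-endorsement rule.

Equating follows the classical linking conventions: linear (mean-sigma)
equating when both score distributions look normal, equipercentile
equating on +/-0.5-continuized percentile ranks otherwise.  Every
transformation is recorded with enough parameters to map a new patient's
raw responses to features bit-identically at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "choose_equating_method",
    "linear_equate",
    "equipercentile_equate",
    "EquatingRecord",
    "rescale_group",
    "variance_check",
    "VarianceCheck",
    "merge_group",
    "binarize_group",
    "default_binarization",
    "standard_scale",
    "ScalingRecord",
    "harmonize_dataset",
    "transform_with_records",
    "HarmonizedData",
]


# --------------------------------------------------------------- equating


def choose_equating_method(source_samples, target_samples, alpha: float = 0.05) -> str:
    """Pick "linear" iff a Shapiro-Wilk test fails to reject normality for
    BOTH samples at level ``alpha``; otherwise "equipercentile".

    Fewer than 20 non-missing values, or a degenerate (constant) sample,
    falls back to equipercentile on empirical ranks.
    """
    s = np.asarray(source_samples, dtype=float)
    t = np.asarray(target_samples, dtype=float)
    s = s[~np.isnan(s)]
    t = t[~np.isnan(t)]
    if len(s) == 0 or len(t) == 0:
        raise ValueError("all-missing sample passed to choose_equating_method")
    if len(s) < 20 or len(t) < 20:
        return "equipercentile"
    for sample in (s, t):
        if np.ptp(sample) == 0:
            return "equipercentile"  # normality undefined for constants
        # Shapiro-Wilk is defined for n <= 5000; subsample deterministically
        if len(sample) > 5000:
            sample = sample[:: len(sample) // 5000 + 1]
        if stats.shapiro(sample).pvalue <= alpha:
            return "equipercentile"
    return "linear"


def linear_equate(x, source_mean, source_sd, target_mean, target_sd):
    """Mean-sigma linear equating: match first two moments."""
    if source_sd <= 0:
        raise ValueError("linear equating requires source_sd > 0")
    return target_mean + (target_sd / source_sd) * (np.asarray(x, dtype=float) - source_mean)


def _percentile_rank(x: float, values: np.ndarray, counts: np.ndarray, n: int) -> float:
    """Continuized percentile rank (fraction in [0,1]) of score ``x``.

    Discrete scores are treated as uniform over +/-0.5 intervals, so the
    rank interpolates linearly across each score's probability mass.
    """
    p = counts / n
    full = p[values + 0.5 <= x].sum()
    inside = (values - 0.5 <= x) & (x < values + 0.5)
    partial = (p[inside] * (x - (values[inside] - 0.5))).sum()
    return float(min(full + partial, 1.0))


def _inverse_percentile(p: float, values: np.ndarray, counts: np.ndarray, n: int) -> float:
    """Continuized score at percentile rank ``p`` (fraction in [0,1])."""
    cum = np.cumsum(counts) / n
    idx = int(np.searchsorted(cum, p, side="right"))
    if idx >= len(values):  # p == 1 (or numerically above)
        return float(values[-1] + 0.5)
    F_prev = cum[idx - 1] if idx > 0 else 0.0
    f = counts[idx] / n
    return float((p - F_prev) / f + values[idx] - 0.5)


def equipercentile_equate(x, source_samples, target_samples):
    """Map ``x`` to the target-scale score with the same percentile rank.

    Uses the +/-0.5 continuization of discrete scores for both the rank
    lookup and its inverse; the output is clipped to the target sample's
    continuized observed range [min - 0.5, max + 0.5] (a discrete score
    occupies a unit interval under continuization, and clipping any
    tighter breaks round-trip equating at extreme scores with mismatched
    tail masses).  Monotone non-decreasing in ``x``.
    """
    s = np.asarray(source_samples, dtype=float)
    t = np.asarray(target_samples, dtype=float)
    s = s[~np.isnan(s)]
    t = t[~np.isnan(t)]
    if len(s) == 0 or len(t) == 0:
        raise ValueError("empty sample passed to equipercentile_equate")
    sv, sc = np.unique(s, return_counts=True)
    tv, tc = np.unique(t, return_counts=True)

    def _one(xi: float) -> float:
        p = _percentile_rank(float(xi), sv, sc, len(s))
        e = _inverse_percentile(p, tv, tc, len(t))
        return float(np.clip(e, tv[0] - 0.5, tv[-1] + 0.5))

    if np.ndim(x) == 0:
        return _one(x)
    return np.array([_one(xi) for xi in np.asarray(x, dtype=float)])


@dataclass
class EquatingRecord:
    """Frozen, re-applicable equating of one member onto the target scale."""

    method: str  # identity | linear | equipercentile
    source_question_id: str
    target_question_id: str
    # linear parameters
    source_mean: float | None = None
    source_sd: float | None = None
    target_mean: float | None = None
    target_sd: float | None = None
    # equipercentile lookup over admissible source scores
    table_scores: list[float] = field(default_factory=list)
    table_values: list[float] = field(default_factory=list)

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        if self.method == "identity":
            return x
        if self.method == "linear":
            return linear_equate(
                x, self.source_mean, self.source_sd, self.target_mean, self.target_sd
            )
        return np.interp(x, self.table_scores, self.table_values)


def _fit_equating(
    source_train: np.ndarray,
    target_train: np.ndarray,
    source_id: str,
    target_id: str,
    admissible_scores,
    alpha: float,
) -> EquatingRecord:
    method = choose_equating_method(source_train, target_train, alpha)
    s = source_train[~np.isnan(source_train)]
    t = target_train[~np.isnan(target_train)]
    if method == "linear" and np.std(s) > 0:
        return EquatingRecord(
            method="linear",
            source_question_id=source_id,
            target_question_id=target_id,
            source_mean=float(np.mean(s)),
            source_sd=float(np.std(s)),
            target_mean=float(np.mean(t)),
            target_sd=float(np.std(t)),
        )
    scores = np.asarray(sorted(set(admissible_scores) | set(np.unique(s))), dtype=float)
    values = equipercentile_equate(scores, s, t)
    return EquatingRecord(
        method="equipercentile",
        source_question_id=source_id,
        target_question_id=target_id,
        table_scores=scores.tolist(),
        table_values=np.asarray(values, dtype=float).tolist(),
    )


# ----------------------------------------------------------- group merging


def rescale_group(
    values: pd.DataFrame,
    scale_max: dict[str, int],
    train_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, EquatingRecord]]:
    """Equate every member of a continuous group onto the largest scale.

    ``values`` is patient x member-question; ``scale_max`` gives each
    member's admissible maximum.  The member with the largest admissible
    range is the equating target (ties: larger observed variance, then
    lexicographically smaller id); all other members are equated to it with
    the method chosen per member.  Equating parameters are estimated on
    ``train_mask`` rows only and applied to all rows; missing stays missing.
    """
    members = list(values.columns)
    if train_mask is None:
        train_mask = np.ones(len(values), dtype=bool)
    if len(members) == 1:
        qid = members[0]
        return values.copy(), {qid: EquatingRecord("identity", qid, qid)}

    def _tie_key(q):
        v = values.loc[train_mask, q]
        return (-scale_max[q], -float(np.nan_to_num(v.var(ddof=0))), q)

    target = sorted(members, key=_tie_key)[0]
    records: dict[str, EquatingRecord] = {}
    out = values.copy().astype(float)
    t_train = values.loc[train_mask, target].to_numpy(dtype=float)
    for q in members:
        if q == target:
            records[q] = EquatingRecord("identity", q, target)
            continue
        s_train = values.loc[train_mask, q].to_numpy(dtype=float)
        rec = _fit_equating(
            s_train, t_train, q, target, range(int(scale_max[q]) + 1), alpha
        )
        records[q] = rec
        col = values[q].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        res = np.full_like(col, np.nan)
        res[ok] = rec.apply(col[ok])
        out[q] = res
    return out, records


@dataclass
class VarianceCheck:
    """Cross-member agreement diagnostic for a rescaled group.

    A mean per-patient variance above 1 suggests members disagree by more
    than one severity level on average; the leave-one-out column pinpoints
    a member that does not belong (its exclusion lowers the mean most).
    """

    status: str  # pass | fail | indeterminate
    mean_variance: float | None
    n_patients: int
    leave_one_out: dict[str, float] = field(default_factory=dict)

    @property
    def outlier_member(self) -> str | None:
        if not self.leave_one_out:
            return None
        return min(self.leave_one_out, key=lambda q: (self.leave_one_out[q], q))


def variance_check(rescaled: pd.DataFrame, threshold: float = 1.0) -> VarianceCheck:
    """Mean per-patient variance across rescaled member values vs. ``threshold``."""
    arr = rescaled.to_numpy(dtype=float)
    n_obs = (~np.isnan(arr)).sum(axis=1)
    usable = n_obs >= 2
    if not usable.any():
        return VarianceCheck("indeterminate", None, 0)
    pvar = _rowvar(arr[usable])
    mean_var = float(np.mean(pvar))
    loo = {}
    if rescaled.shape[1] > 2:
        for q in rescaled.columns:
            sub = rescaled.drop(columns=[q]).to_numpy(dtype=float)
            ok = (~np.isnan(sub)).sum(axis=1) >= 2
            loo[q] = float(np.mean(_rowvar(sub[ok]))) if ok.any() else np.nan
    return VarianceCheck(
        "pass" if mean_var <= threshold else "fail",
        mean_var,
        int(usable.sum()),
        loo,
    )


def _rowvar(arr: np.ndarray) -> np.ndarray:
    """Sample variance per row over non-missing entries (ddof=1)."""
    n = (~np.isnan(arr)).sum(axis=1)
    mean = np.nanmean(arr, axis=1)
    ss = np.nansum((arr - mean[:, None]) ** 2, axis=1)
    return ss / np.maximum(n - 1, 1)


def merge_group(rescaled: pd.DataFrame) -> pd.Series:
    """Per-patient mean over non-missing rescaled members."""
    return rescaled.mean(axis=1, skipna=True)


# ------------------------------------------------------------ binarization


def default_binarization(scale_max: int) -> dict[int, int]:
    """Endorse (1) responses in the upper half of the scale."""
    return {v: int(v > scale_max / 2) for v in range(scale_max + 1)}


@dataclass
class BinarizationCheck:
    status: str  # pass | fail | indeterminate
    max_abs_difference: float | None
    member_rates: dict[str, float] = field(default_factory=dict)


def binarize_group(
    values: pd.DataFrame,
    mapping: dict[str, dict],
    native_binary: set[str],
    tolerance: float = 0.10,
) -> tuple[pd.Series, BinarizationCheck]:
    """Map every member response to 0/1 and combine with any-endorsement.

    ``mapping`` gives, per member, the response-value -> {0,1} map.  The
    distribution check compares each binarized categorical member's
    endorsement rate to the mean rate of the native binary members; the
    largest absolute difference beyond ``tolerance`` fails the check.
    """
    mapped = {}
    for q in values.columns:
        qmap = {float(k): v for k, v in mapping[q].items()}
        col = values[q]
        observed = set(col.dropna().astype(float).unique())
        unmapped = observed - set(qmap)
        if unmapped:
            raise ValueError(f"unmapped response values for {q}: {sorted(unmapped)}")
        mapped[q] = col.map(lambda v: np.nan if pd.isna(v) else qmap[float(v)])
    binar = pd.DataFrame(mapped, index=values.index)
    feature = binar.max(axis=1, skipna=True)  # endorsed on any member
    feature[binar.isna().all(axis=1)] = np.nan

    rates = {q: float(binar[q].mean(skipna=True)) for q in binar.columns}
    native = [rates[q] for q in binar.columns if q in native_binary]
    categorical = [q for q in binar.columns if q not in native_binary]
    if not native or not categorical:
        return feature, BinarizationCheck("indeterminate", None, rates)
    native_mean = float(np.mean(native))
    diffs = [abs(rates[q] - native_mean) for q in categorical]
    worst = float(max(diffs))
    return feature, BinarizationCheck(
        "pass" if worst <= tolerance else "fail", worst, rates
    )


# ----------------------------------------------------------------- scaling


@dataclass
class ScalingRecord:
    """Train-fit z-scoring plus positivity offset (a fixed affine map)."""

    mean: float
    sd: float
    offset: float

    def apply(self, values):
        v = np.asarray(values, dtype=float)
        return (v - self.mean) / self.sd + self.offset


def standard_scale(
    values, train_mask: np.ndarray | None = None
) -> tuple[np.ndarray, ScalingRecord]:
    """Z-score with train-split mean/sd (population denominator); if any
    train z-value is <= 0, shift the whole column so the minimum becomes
    exactly 0.01 (some activations treat non-positive inputs irregularly).
    """
    v = np.asarray(values, dtype=float)
    if train_mask is None:
        train_mask = np.ones(len(v), dtype=bool)
    train = v[train_mask]
    train = train[~np.isnan(train)]
    if len(np.unique(train)) < 2:
        raise ValueError("cannot standard-scale a constant feature")
    mean, sd = float(np.mean(train)), float(np.std(train))
    z_train = (train - mean) / sd
    offset = float(abs(z_train.min()) + 0.01) if z_train.min() <= 0 else 0.0
    rec = ScalingRecord(mean=mean, sd=sd, offset=offset)
    return rec.apply(v), rec


# --------------------------------------------------------- dataset-level


@dataclass
class HarmonizedData:
    """Patient x feature matrix plus full per-feature provenance."""

    features: pd.DataFrame
    records: dict
    diagnostics: dict


def harmonize_dataset(
    responses: pd.DataFrame,
    groups,
    questions,
    train_patients=None,
    binarization_map: dict | None = None,
    alpha: float = 0.05,
    variance_threshold: float = 1.0,
    binarization_tolerance: float = 0.10,
    merge_despite_variance: set | None = None,
) -> HarmonizedData:
    """Run the full per-group transformation over a long response table.

    ``groups`` are :class:`~txbenefit.taxonomy.FeatureGroup`-like objects;
    ``questions`` a mapping question_id -> StandardQuestion (or any object
    with ``response_scale`` and ``scale_type``).  Equating and scaling
    parameters are estimated on ``train_patients`` only (all patients when
    omitted) so validation/test rows see no leakage.  Groups failing the
    variance check are dropped unless listed in ``merge_despite_variance``.
    """
    wide = responses.pivot_table(
        index="patient_id", columns="question_id", values="response_value", aggfunc="first"
    )
    patients = wide.index
    if train_patients is None:
        train_mask = np.ones(len(patients), dtype=bool)
    else:
        train_mask = np.asarray(patients.isin(set(train_patients)))
    merge_despite_variance = merge_despite_variance or set()

    scale_max = {
        qid: int(max(q.response_scale)) if q.response_scale else int(wide[qid].max())
        for qid, q in questions.items()
        if qid in wide.columns
    }
    feats: dict[str, pd.Series] = {}
    records: dict[str, dict] = {}
    diagnostics: dict[str, dict] = {}
    for group in groups:
        members = [m for m in group.members if m in wide.columns]
        if not members:
            continue
        gvals = wide[members]
        diag: dict = {"members": members, "merge_mode": group.merge_mode}
        if group.merge_mode == "binarized":
            gmap = {
                q: (binarization_map or {}).get(q, default_binarization(scale_max[q]))
                for q in members
            }
            native = {q for q in members if questions[q].scale_type == "binary"}
            feature, check = binarize_group(
                gvals, gmap, native, tolerance=binarization_tolerance
            )
            diag["binarization_check"] = asdict(check)
            records[group.group_id] = {
                "kind": "binary",
                "members": members,
                "mapping": {q: {str(k): v for k, v in gmap[q].items()} for q in members},
            }
            feats[group.group_id] = feature
        else:
            rescaled, eq_records = rescale_group(gvals, scale_max, train_mask, alpha)
            check = variance_check(rescaled, threshold=variance_threshold)
            diag["variance_check"] = {
                "status": check.status,
                "mean_variance": check.mean_variance,
                "leave_one_out": check.leave_one_out,
            }
            if check.status == "fail" and group.group_id not in merge_despite_variance:
                diag["dropped"] = True
                diagnostics[group.group_id] = diag
                continue
            merged = merge_group(rescaled)
            try:
                scaled, srec = standard_scale(merged.to_numpy(), train_mask)
            except ValueError:
                diag["dropped"] = "constant feature"
                diagnostics[group.group_id] = diag
                continue
            feats[group.group_id] = pd.Series(scaled, index=patients)
            records[group.group_id] = {
                "kind": "continuous",
                "members": members,
                "equating": {q: asdict(r) for q, r in eq_records.items()},
                "scaling": asdict(srec),
            }
        diagnostics[group.group_id] = diag
    features = pd.DataFrame(feats, index=patients)
    return HarmonizedData(features=features, records=records, diagnostics=diagnostics)


def transform_with_records(responses: pd.DataFrame, records: dict) -> pd.DataFrame:
    """Re-apply frozen transformation records to new patients' raw responses.

    Produces the identical feature values the fitted pipeline would, which
    is what lets a deployed model score a new patient.
    """
    wide = responses.pivot_table(
        index="patient_id", columns="question_id", values="response_value", aggfunc="first"
    )
    feats = {}
    for fid, rec in records.items():
        members = [m for m in rec["members"] if m in wide.columns]
        if not members:
            feats[fid] = pd.Series(np.nan, index=wide.index)
            continue
        if rec["kind"] == "binary":
            mapped = {}
            for q in members:
                qmap = {float(k): v for k, v in rec["mapping"][q].items()}
                mapped[q] = wide[q].map(lambda v: np.nan if pd.isna(v) else qmap[float(v)])
            binar = pd.DataFrame(mapped, index=wide.index)
            feature = binar.max(axis=1, skipna=True)
            feature[binar.isna().all(axis=1)] = np.nan
            feats[fid] = feature
        else:
            cols = {}
            for q in members:
                er = EquatingRecord(**rec["equating"][q])
                col = wide[q].to_numpy(dtype=float)
                ok = ~np.isnan(col)
                res = np.full_like(col, np.nan)
                res[ok] = er.apply(col[ok])
                cols[q] = res
            merged = pd.DataFrame(cols, index=wide.index).mean(axis=1, skipna=True)
            srec = ScalingRecord(**rec["scaling"])
            feats[fid] = pd.Series(srec.apply(merged.to_numpy()), index=wide.index)
    return pd.DataFrame(feats, index=wide.index)
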