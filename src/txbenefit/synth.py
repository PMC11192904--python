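"""Seeded generator of multi-study antidepressant-trial questionnaire data.

Emulates the situation the harmonization pipeline exists for: several
clinical trials, each administering its own subset of questionnaire items
on heterogeneous response scales (binary, 0-3, 0-4, 0-6), all driven by a
small number of latent severity factors (depressed mood, anxiety,
insomnia, ...).  Binary remission at endpoint follows a logistic model
over the latent factors, treatment main effects and factor-by-treatment
interactions, so the best treatment genuinely differs across patients and
a differential-benefit model has something to find.

Demographic category frequencies default to values typical of pooled
antidepressant trial populations (~64% female, ~76% white, mean age ~44),
so the subgroup bias audit is exercised realistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import train_test_split

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_studies",
    "split_dataset",
    "planted_classification",
    "DEFAULT_FACTOR_NAMES",
    "DEFAULT_TREATMENTS",
]

DEFAULT_TREATMENTS = [
    "bupropion",
    "escitalopram",
    "venlafaxine",
    "fluoxetine",
    "paroxetine",
    "duloxetine",
]

DEFAULT_FACTOR_NAMES = [
    "depressed_mood",
    "anxiety",
    "insomnia",
    "cognitive_impairment",
    "somatic_symptoms",
]

# Pooled-trial demographic frequencies (female-majority, mostly white).
SEX_FREQS = {"Female": 0.6363, "Male": 0.3637}
RACE_FREQS = {
    "White": 0.7553,
    "Asian": 0.1506,
    "African Descent": 0.0488,
    "Hispanic": 0.0367,
    "Other": 0.0086,
}
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 43.6, 13.9, 18.0, 80.0


def _default_effects() -> dict[str, float]:
    # Higher severity lowers the odds of remission.
    return {"depressed_mood": -1.0, "anxiety": -0.6, "insomnia": -0.4}


def _default_interactions() -> dict[tuple[str, str], float]:
    return {
        ("depressed_mood", "venlafaxine"): 0.8,
        ("anxiety", "escitalopram"): 0.8,
        ("insomnia", "bupropion"): -0.8,
    }


def _default_treatment_effects() -> dict[str, float]:
    # Mild efficacy ordering; escitalopram slightly favoured at the margin.
    return {
        "bupropion": 0.0,
        "escitalopram": 0.25,
        "venlafaxine": 0.15,
        "fluoxetine": 0.05,
        "paroxetine": 0.10,
        "duloxetine": 0.05,
    }


@dataclass
class SynthConfig:
    """Study-condition knobs for the generator.

    ``effect_sizes`` maps latent factor name -> outcome log-odds weight;
    ``interaction_sizes`` maps (factor, treatment) -> log-odds weight;
    ``treatment_effects`` maps treatment -> main-effect log-odds shift.
    ``items_per_pool_factor`` items exist globally per factor (cycling
    through ``response_scales``); each study administers
    ``items_per_factor_per_study`` of them.
    """

    n_studies: int = 6
    patients_per_study: int = 500
    n_latent_factors: int = 5
    items_per_factor_per_study: int = 3
    items_per_pool_factor: int = 8
    # severity-factor items are categorical (the scales the merged
    # continuous features came from); binary items appear among the noise
    # pool and in explicitly binarized groups
    response_scales: list[int] = field(default_factory=lambda: [3, 4, 6])
    noise_scales: list[int] = field(default_factory=lambda: [1, 3, 4, 6])
    treatments: list[str] = field(default_factory=lambda: list(DEFAULT_TREATMENTS))
    effect_sizes: dict = field(default_factory=_default_effects)
    interaction_sizes: dict = field(default_factory=_default_interactions)
    treatment_effects: dict = field(default_factory=_default_treatment_effects)
    n_noise_features: int = 10
    noise_item_rate: float = 0.5
    missing_rate_per_study: float = 0.05
    base_remission_logit: float = -0.27
    item_loading: float = 1.0
    item_noise_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        # allow "factor:treatment" string keys (the YAML-friendly spelling)
        self.interaction_sizes = {
            (tuple(k.split(":", 1)) if isinstance(k, str) else tuple(k)): v
            for k, v in self.interaction_sizes.items()
        }
        for name in (
            "n_studies",
            "patients_per_study",
            "n_latent_factors",
            "items_per_factor_per_study",
            "items_per_pool_factor",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.missing_rate_per_study <= 1.0:
            raise ValueError("missing_rate_per_study must be in [0, 1]")
        if not 0.0 <= self.noise_item_rate <= 1.0:
            raise ValueError("noise_item_rate must be in [0, 1]")
        if self.items_per_factor_per_study > self.items_per_pool_factor:
            raise ValueError(
                "items_per_factor_per_study exceeds the per-factor item pool "
                f"({self.items_per_factor_per_study} > {self.items_per_pool_factor})"
            )
        unknown = {f for f in self.effect_sizes if f not in self.factor_names}
        unknown |= {f for f, _ in self.interaction_sizes if f not in self.factor_names}
        if unknown:
            raise ValueError(f"effect sizes reference unknown factors: {sorted(unknown)}")

    @property
    def factor_names(self) -> list[str]:
        names = []
        for i in range(self.n_latent_factors):
            base = DEFAULT_FACTOR_NAMES[i % len(DEFAULT_FACTOR_NAMES)]
            names.append(base if i < len(DEFAULT_FACTOR_NAMES) else f"{base}_{i}")
        return names


@dataclass
class GroundTruth:
    """What the generator knows and a fitted model should recover."""

    informative_feature_ids: set[str]
    latent_factors: pd.DataFrame  # patient x factor
    true_probabilities: pd.Series  # P(remit | assigned treatment)
    treatment_probabilities: pd.DataFrame  # patient x treatment
    item_catalog: pd.DataFrame  # question_id, factor, scale_max

    def best_treatment(self) -> pd.Series:
        return self.treatment_probabilities.idxmax(axis=1)

    def to_json(self, path) -> None:
        payload = {
            "informative_feature_ids": sorted(self.informative_feature_ids),
            "latent_factors": self.latent_factors.to_dict(orient="index"),
            "true_probabilities": self.true_probabilities.to_dict(),
            "treatment_probabilities": self.treatment_probabilities.to_dict(orient="index"),
            "item_catalog": self.item_catalog.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _build_item_catalog(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for f_idx, factor in enumerate(config.factor_names):
        for j in range(config.items_per_pool_factor):
            scale = config.response_scales[j % len(config.response_scales)]
            rows.append(
                {
                    "question_id": f"q_{factor}_{j:02d}",
                    "factor": factor,
                    "scale_max": scale,
                }
            )
    for j in range(config.n_noise_features):
        scale = config.noise_scales[j % len(config.noise_scales)]
        rows.append({"question_id": f"q_noise_{j:02d}", "factor": None, "scale_max": scale})
    return pd.DataFrame(rows)


def _discretize(latent_value: np.ndarray, scale_max: int, total_sd: float) -> np.ndarray:
    """Monotone discretization by fixed equal-probability cut-points."""
    from scipy.stats import norm

    probs = np.arange(1, scale_max + 1) / (scale_max + 1)
    cuts = norm.ppf(probs, scale=total_sd)
    return np.searchsorted(cuts, latent_value, side="right").astype(int)


def _outcome_logits(config: SynthConfig, Z: pd.DataFrame, treatments: np.ndarray) -> np.ndarray:
    logits = np.full(len(Z), config.base_remission_logit, dtype=float)
    for factor, w in config.effect_sizes.items():
        logits += w * Z[factor].to_numpy()
    tmain = np.array([config.treatment_effects.get(t, 0.0) for t in treatments])
    logits += tmain
    for (factor, treat), w in config.interaction_sizes.items():
        logits += w * Z[factor].to_numpy() * (treatments == treat)
    return logits


def generate_studies(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (long response table, subject table, ground truth).

    The response table is long-format ``patient_id, study_id, question_id,
    response_value``; the subject table is one row per patient with
    treatment, demographics and the binary remission outcome.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    catalog = _build_item_catalog(config)
    factor_items = {
        f: catalog.loc[catalog["factor"] == f, "question_id"].tolist()
        for f in config.factor_names
    }
    noise_items = catalog.loc[catalog["factor"].isna(), "question_id"].tolist()
    scale_of = dict(zip(catalog["question_id"], catalog["scale_max"]))
    factor_of = dict(zip(catalog["question_id"], catalog["factor"]))

    # per-study questionnaire subsets (structural missingness)
    study_items: dict[str, list[str]] = {}
    study_ids = [f"study_{i:02d}" for i in range(config.n_studies)]
    for sid in study_ids:
        items = []
        for f in config.factor_names:
            pick = rng.choice(
                factor_items[f], size=config.items_per_factor_per_study, replace=False
            )
            items.extend(pick.tolist())
        if noise_items:
            mask = rng.random(len(noise_items)) < config.noise_item_rate
            items.extend([q for q, m in zip(noise_items, mask) if m])
        study_items[sid] = sorted(items)

    n_total = config.n_studies * config.patients_per_study
    patient_ids = [f"p{idx:05d}" for idx in range(n_total)]
    study_col = np.repeat(study_ids, config.patients_per_study)

    Z = pd.DataFrame(
        rng.standard_normal((n_total, config.n_latent_factors)),
        index=patient_ids,
        columns=config.factor_names,
    )

    # treatment arms: two per study, cycling so all treatments are covered
    T = len(config.treatments)
    arms = {
        sid: (config.treatments[(2 * i) % T], config.treatments[(2 * i + 1) % T])
        for i, sid in enumerate(study_ids)
    }
    treat_col = np.empty(n_total, dtype=object)
    for i, sid in enumerate(study_ids):
        lo = i * config.patients_per_study
        hi = lo + config.patients_per_study
        treat_col[lo:hi] = rng.choice(arms[sid], size=config.patients_per_study)

    # demographics
    sex = rng.choice(list(SEX_FREQS), p=_normed(SEX_FREQS), size=n_total)
    race = rng.choice(list(RACE_FREQS), p=_normed(RACE_FREQS), size=n_total)
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n_total), AGE_MIN, AGE_MAX).round(1)

    # outcome
    logits = _outcome_logits(config, Z, treat_col)
    p_remit = expit(logits)
    remission = (rng.random(n_total) < p_remit).astype(int)

    # per-treatment true probabilities
    per_treat = {}
    for t in config.treatments:
        per_treat[t] = expit(
            _outcome_logits(config, Z, np.full(n_total, t, dtype=object))
        )
    treat_probs = pd.DataFrame(per_treat, index=patient_ids)

    # long-format responses
    total_sd = float(np.hypot(config.item_loading, config.item_noise_sd))
    frames = []
    for i, sid in enumerate(study_ids):
        lo = i * config.patients_per_study
        hi = lo + config.patients_per_study
        pids = patient_ids[lo:hi]
        items = study_items[sid]
        continuous = np.empty((len(pids), len(items)))
        for j, q in enumerate(items):
            f = factor_of[q]
            base = Z.loc[pids, f].to_numpy() * config.item_loading if f else 0.0
            continuous[:, j] = base + rng.normal(
                0.0, config.item_noise_sd if f else total_sd, size=len(pids)
            )
        keep = rng.random(continuous.shape) >= config.missing_rate_per_study
        for j, q in enumerate(items):
            vals = _discretize(continuous[:, j], scale_of[q], total_sd)
            mask = keep[:, j]
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.array(pids)[mask],
                        "study_id": sid,
                        "question_id": q,
                        "response_value": vals[mask],
                    }
                )
            )
    responses = pd.concat(frames, ignore_index=True)

    subjects = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "study_id": study_col,
            "treatment": treat_col,
            "age": age,
            "sex": sex,
            "race": race,
            "remission": remission,
        }
    )

    informative = {
        f
        for f in config.factor_names
        if config.effect_sizes.get(f)
        or any(ff == f and w for (ff, _), w in config.interaction_sizes.items())
    }
    truth = GroundTruth(
        informative_feature_ids=informative,
        latent_factors=Z,
        true_probabilities=pd.Series(p_remit, index=patient_ids),
        treatment_probabilities=treat_probs,
        item_catalog=catalog,
    )
    return responses, subjects, truth


def _normed(freqs: dict[str, float]) -> np.ndarray:
    p = np.array(list(freqs.values()), dtype=float)
    return p / p.sum()


# Default split fractions mirror pooled-trial practice: a large training
# set with small validation/test splits (~0.815/0.084/0.101).
DEFAULT_FRACTIONS = (0.815, 0.084, 0.101)


def split_dataset(
    subjects: pd.DataFrame,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Label rows train/validation/test, stratified by outcome x treatment.

    Returns a copy with a ``split`` column.  Raises if any treatment arm is
    too small to appear in every nonempty split.
    """
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any() or not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    out = subjects.copy()
    out["split"] = "train"
    strata = out["remission"].astype(str) + "|" + out["treatment"].astype(str)
    idx = out.index.to_numpy()
    holdout = fr[1] + fr[2]
    if holdout <= 0:
        return out
    try:
        train_idx, rest_idx = train_test_split(
            idx, test_size=holdout, stratify=strata.loc[idx], random_state=seed
        )
        if fr[1] <= 0:
            val_idx, test_idx = np.array([], dtype=idx.dtype), rest_idx
        elif fr[2] <= 0:
            val_idx, test_idx = rest_idx, np.array([], dtype=idx.dtype)
        else:
            val_idx, test_idx = train_test_split(
                rest_idx,
                test_size=fr[2] / holdout,
                stratify=strata.loc[rest_idx],
                random_state=seed,
            )
    except ValueError as exc:
        raise ValueError(
            "a treatment/outcome stratum is too small to stratify across splits"
        ) from exc
    out.loc[val_idx, "split"] = "validation"
    out.loc[test_idx, "split"] = "test"
    return out


def interaction_config(seed: int = 0, **overrides) -> SynthConfig:
    """A study condition isolating treatment-by-severity interactions.

    Treatment main effects are zeroed and the outcome hinges on the
    product of depressed-mood severity with a signed per-treatment weight,
    so which treatment is best genuinely flips with severity.  A logistic
    model with main effects only cannot represent this signal; it is the
    condition for probing differential-benefit detection and the
    nonlinearity advantage of the network over the linear baseline.
    """
    params = dict(
        effect_sizes={"anxiety": -0.4},
        treatment_effects={t: 0.0 for t in DEFAULT_TREATMENTS},
        interaction_sizes={
            ("depressed_mood", t): w
            for t, w in zip(DEFAULT_TREATMENTS, [1.2, -1.2, 0.9, -0.9, 0.6, -0.6])
        },
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def planted_classification(
    n: int = 2000,
    n_informative: int = 5,
    n_noise: int = 15,
    effect: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Feature-level planted-signal dataset for selection benchmarks.

    Standard-normal features; the label follows a logistic model with
    weight ``effect`` on each of the first ``n_informative`` features and
    zero on the rest.  Returns (X, y, informative feature ids).
    """
    rng = np.random.default_rng(seed)
    d = n_informative + n_noise
    X = rng.standard_normal((n, d))
    beta = np.zeros(d)
    beta[:n_informative] = effect
    y = (rng.random(n) < expit(X @ beta)).astype(int)
    cols = [f"f{i:02d}" for i in range(d)]
    return pd.DataFrame(X, columns=cols), y, cols[:n_informative]
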