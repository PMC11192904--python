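"""End-to-end pipeline: simulate -> taxonomize -> harmonize -> split ->
select features -> (tune) -> train -> evaluate -> sensitivity -> bias audit.

Each stage reads and writes plain-text artifacts (CSV/JSON/YAML) in a run
directory, so any stage can be re-run or inspected in isolation, and a
manifest records seeds, stage outputs and content hashes for
reproducibility.  The same frozen transformation records + model schema
used during training score new patients identically at inference time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import features as fs
from . import harmonize as hz
from . import model as md
from . import synth as sy
from . import taxonomy as tx
from . import tune as tn

__all__ = ["PipelineConfig", "run_pipeline", "predict_patients", "STAGES"]

log = logging.getLogger("txbenefit")

RACE_PREFIX = "race::"
DEMO_RECORD = "__demographics__"


@dataclass
class PipelineConfig:
    """Nested configuration for every stage; YAML-loadable."""

    run_dir: str = "txbenefit_run"
    seed: int = 0
    simulate: bool = True
    synth: dict = field(default_factory=dict)
    fractions: tuple = sy.DEFAULT_FRACTIONS
    harmonize: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    tune: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    taxonomy_path: str | None = None
    overrides_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, offset: int) -> int:
        return (int(self.seed) * 1000 + offset) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))


def _stringify_keys(obj):
    if isinstance(obj, dict):
        return {
            ":".join(map(str, k)) if isinstance(k, tuple) else str(k): _stringify_keys(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


# ------------------------------------------------------------------ stages


def stage_simulate(cfg: PipelineConfig, rundir: Path) -> dict:
    sconf = sy.SynthConfig(**{"seed": cfg.stage_seed(1), **cfg.synth})
    responses, subjects, truth = sy.generate_studies(sconf)
    responses.to_csv(rundir / "responses.csv", index=False)
    subjects.to_csv(rundir / "subjects.csv", index=False)
    truth.to_json(rundir / "ground_truth.json")

    # question catalog + taxonomy derived from the generator's item design
    catalog = truth.item_catalog
    questions = []
    for _, row in catalog.iterrows():
        questions.append(
            {
                "question_id": row["question_id"],
                "scale_max": int(row["scale_max"]),
                "scale_type": "binary" if row["scale_max"] == 1 else "categorical",
                "category": row["factor"] if pd.notna(row["factor"]) else row["question_id"],
            }
        )
    _write_json(rundir / "questions.json", questions)
    spec = {
        "symptoms": {f: None for f in sconf.factor_names},
        "misc": {
            q["question_id"]: None for q in questions if q["category"] == q["question_id"]
        },
    }
    (rundir / "taxonomy.yaml").write_text(yaml.safe_dump(spec))
    return {"n_patients": len(subjects), "n_responses": len(responses)}


def stage_split(cfg: PipelineConfig, rundir: Path) -> dict:
    subjects = pd.read_csv(rundir / "subjects.csv")
    subjects = sy.split_dataset(subjects, tuple(cfg.fractions), seed=cfg.stage_seed(2))
    subjects.to_csv(rundir / "subjects.csv", index=False)
    return subjects["split"].value_counts().to_dict()


def _load_questions(rundir: Path) -> dict[str, tx.StandardQuestion]:
    raw = json.loads((rundir / "questions.json").read_text())
    out = {}
    for q in raw:
        out[q["question_id"]] = tx.StandardQuestion(
            question_id=q["question_id"],
            response_scale=tuple(range(q["scale_max"] + 1)),
            scale_type=q["scale_type"],
            primary_category=q["category"],
        )
    return out


def stage_taxonomize(cfg: PipelineConfig, rundir: Path) -> dict:
    tax_path = Path(cfg.taxonomy_path) if cfg.taxonomy_path else rundir / "taxonomy.yaml"
    if not tax_path.exists():
        raise FileNotFoundError(f"taxonomy file not found: {tax_path}")
    tree = tx.build_taxonomy(tax_path.read_text())
    questions = _load_questions(rundir)
    tagged = [
        tx.tag_question(q, tree, q.primary_category) for q in questions.values()
    ]
    overrides = None
    if cfg.overrides_path:
        overrides = yaml.safe_load(Path(cfg.overrides_path).read_text())
    groups = tx.group_by_category(tagged, tree, overrides)
    _write_json(
        rundir / "groups.json",
        [asdict(g) for g in groups],
    )
    return {"n_groups": len(groups)}


def _load_groups(rundir: Path) -> list[tx.FeatureGroup]:
    raw = json.loads((rundir / "groups.json").read_text())
    return [tx.FeatureGroup(**g) for g in raw]


def stage_harmonize(cfg: PipelineConfig, rundir: Path) -> dict:
    responses = pd.read_csv(rundir / "responses.csv")
    subjects = pd.read_csv(rundir / "subjects.csv")
    questions = _load_questions(rundir)
    groups = _load_groups(rundir)
    train_patients = subjects.loc[subjects["split"] == "train", "patient_id"]
    hconf = dict(cfg.harmonize)
    data = hz.harmonize_dataset(
        responses,
        groups,
        questions,
        train_patients=train_patients,
        alpha=hconf.get("alpha", 0.05),
        variance_threshold=hconf.get("variance_threshold", 1.0),
        binarization_tolerance=hconf.get("binarization_tolerance", 0.10),
    )
    features, records = _append_demographics(
        data.features, subjects, data.records, set(train_patients)
    )
    features.to_csv(rundir / "features.csv")
    _write_json(rundir / "transform_records.json", records)
    _write_json(rundir / "harmonize_diagnostics.json", data.diagnostics)
    return {"n_features": features.shape[1], "n_groups_dropped": sum(
        1 for d in data.diagnostics.values() if d.get("dropped")
    )}


def _append_demographics(features, subjects, records, train_patients):
    sub = subjects.set_index("patient_id").loc[features.index]
    train_mask = features.index.isin(train_patients)
    age_scaled, age_rec = hz.standard_scale(sub["age"].to_numpy(float), train_mask)
    out = features.copy()
    out["age"] = age_scaled
    out["sex"] = (sub["sex"] == "Female").astype(float)
    races = sorted(sub["race"].unique())
    for r in races:
        out[RACE_PREFIX + r] = (sub["race"] == r).astype(float)
    records = dict(records)
    records[DEMO_RECORD] = {
        "kind": "demographics",
        "age_scaling": asdict(age_rec),
        "sex_positive": "Female",
        "race_levels": races,
    }
    return out, records


def _demographic_columns(features: pd.DataFrame) -> list[str]:
    return ["age", "sex"] + [c for c in features.columns if c.startswith(RACE_PREFIX)]


def stage_select(cfg: PipelineConfig, rundir: Path) -> dict:
    features = pd.read_csv(rundir / "features.csv", index_col=0)
    subjects = pd.read_csv(rundir / "subjects.csv").set_index("patient_id")
    sconf = dict(cfg.selection)
    min_cov = sconf.get("min_coverage", 0.7)
    coverage = features.notna().mean()
    candidates = sorted(coverage[coverage >= min_cov].index)
    dropped_features = sorted(set(features.columns) - set(candidates))

    cand = features[candidates]
    complete = cand.dropna()
    train_ids = subjects.index[subjects["split"] == "train"]
    rows = complete.index.intersection(train_ids)
    y = subjects.loc[rows, "remission"].to_numpy(int)
    k = int(sconf.get("k", min(10, len(candidates))))
    result = fs.cancelout_scores(
        complete.loc[rows],
        y,
        k=k,
        hidden=tuple(cfg.model.get("hidden_layers", [40, 40])),
        dropout=cfg.model.get("dropout", 0.15),
        epochs=sconf.get("epochs", 150),
        lambda1=sconf.get("lambda1", 0.2),
        lambda2=sconf.get("lambda2", 0.1),
        seed=cfg.stage_seed(3),
    )
    selected = list(result.selected_ids)
    if sconf.get("force_include_demographics", True):
        for c in _demographic_columns(features):
            if c in candidates and c not in selected:
                selected.append(c)
    payload = {
        "candidates": candidates,
        "low_coverage_excluded": dropped_features,
        "n_rows_used": int(len(rows)),
        "n_rows_dropped_missing": int(len(train_ids) - len(rows)),
        "k": k,
        "scores": dict(zip(result.feature_ids, result.scores)),
        "ranking": result.ranking(),
        "selected": selected,
    }
    _write_json(rundir / "selection.json", payload)
    return {"n_candidates": len(candidates), "n_selected": len(selected)}


def _design_matrices(cfg: PipelineConfig, rundir: Path):
    features = pd.read_csv(rundir / "features.csv", index_col=0)
    subjects = pd.read_csv(rundir / "subjects.csv").set_index("patient_id")
    selection = json.loads((rundir / "selection.json").read_text())
    selected = selection["selected"]
    X = features[selected].dropna()
    sub = subjects.loc[X.index]
    treatments = sorted(sub["treatment"].unique())
    design = md.encode_design(X, sub["treatment"], treatments)
    out = {}
    for split in ("train", "validation", "test"):
        m = sub["split"] == split
        out[split] = (design[m.to_numpy()], sub.loc[m, "remission"].to_numpy(int))
    return out, design, sub


def stage_tune(cfg: PipelineConfig, rundir: Path) -> dict:
    tconf = dict(cfg.tune)
    if not tconf.get("enabled", False):
        return {"skipped": True}
    features = pd.read_csv(rundir / "features.csv", index_col=0)
    subjects = pd.read_csv(rundir / "subjects.csv").set_index("patient_id")
    selection = json.loads((rundir / "selection.json").read_text())
    ranking = selection["ranking"]
    space = tn.default_search_space(
        max_k=len(ranking),
        budget=tconf.get("budget", 20),
        seed=cfg.stage_seed(4),
    )

    def objective(trial_cfg: dict) -> float:
        chosen = ranking[: trial_cfg["k"]]
        X = features[chosen].dropna()
        sub = subjects.loc[X.index]
        treatments = sorted(sub["treatment"].unique())
        design = md.encode_design(X, sub["treatment"], treatments)
        tr = sub["split"] == "train"
        va = sub["split"] == "validation"
        net_cfg = md.NetConfig(
            hidden_layers=[trial_cfg["width"]] * trial_cfg["n_layers"],
            dropout=round(trial_cfg["dropout"], 3),
            learning_rate=trial_cfg["learning_rate"],
            max_epochs=tconf.get("epochs", 60),
            early_stopping_patience=min(
                tconf.get("patience", 30), tconf.get("epochs", 60)
            ),
            seed=cfg.stage_seed(5),
        )
        m = md.train(
            design[tr.to_numpy()],
            sub.loc[tr, "remission"],
            design[va.to_numpy()],
            sub.loc[va, "remission"],
            net_cfg,
        )
        return ev.auroc(
            sub.loc[va, "remission"].to_numpy(int),
            md.predict_remission(m, design[va.to_numpy()]),
        )

    best, trial_log = tn.optimize(space, objective)
    _write_json(rundir / "tuning.json", {"best": best, "trials": trial_log})
    if tconf.get("apply_best", True):
        # the tuned feature count k becomes the final selection
        selected = ranking[: best["k"]]
        if dict(cfg.selection).get("force_include_demographics", True):
            for c in _demographic_columns(features):
                if c in selection["candidates"] and c not in selected:
                    selected.append(c)
        selection["selected"] = selected
        selection["k"] = best["k"]
        _write_json(rundir / "selection.json", selection)
    return {"best": best, "n_trials": len(trial_log)}


def stage_train(cfg: PipelineConfig, rundir: Path) -> dict:
    splits, design, sub = _design_matrices(cfg, rundir)
    mconf = dict(cfg.model)
    tuning_path = rundir / "tuning.json"
    if cfg.tune.get("enabled", False) and cfg.tune.get("apply_best", True) and tuning_path.exists():
        best = json.loads(tuning_path.read_text())["best"]
        mconf.setdefault("hidden_layers", [best["width"]] * best["n_layers"])
        mconf.setdefault("dropout", round(best["dropout"], 3))
        mconf.setdefault("learning_rate", best["learning_rate"])
    net_cfg = md.NetConfig(**{"seed": cfg.stage_seed(6), **mconf})
    Xtr, ytr = splits["train"]
    Xva, yva = splits["validation"]
    trained = md.train(Xtr, ytr, Xva if len(yva) else None, yva if len(yva) else None, net_cfg)
    trained.to_json(
        rundir / "model.json", extra={"transform_records": "transform_records.json"}
    )
    Xte, yte = splits["test"]
    baseline = md.baseline_logistic(Xtr, ytr, Xte if len(yte) else Xva, yte if len(yte) else yva)
    _write_json(
        rundir / "baseline.json",
        {
            "auc": baseline["auc"],
            "coefficients": baseline["coefficients"],
            "intercept": baseline["intercept"],
        },
    )
    return {
        "best_epoch": trained.history.best_epoch,
        "stopped_epoch": trained.history.stopped_epoch,
        "baseline_test_auc": baseline["auc"],
    }


def stage_evaluate(cfg: PipelineConfig, rundir: Path) -> dict:
    splits, _, _ = _design_matrices(cfg, rundir)
    trained = md.TrainedModel.from_json(rundir / "model.json")
    threshold = cfg.evaluate.get("threshold", 0.5)
    reports = {}
    for split, (X, y) in splits.items():
        if len(y) == 0:
            continue
        prob = md.predict_remission(trained, X)
        reports[split] = ev.confusion_metrics(y, prob, threshold, split).as_dict()
    _write_json(rundir / "metrics.json", reports)
    return {s: round(r["auc"], 4) for s, r in reports.items() if r["auc"] is not None}


def stage_sensitivity(cfg: PipelineConfig, rundir: Path) -> dict:
    splits, design, sub = _design_matrices(cfg, rundir)
    trained = md.TrainedModel.from_json(rundir / "model.json")
    feats = cfg.evaluate.get("sensitivity_features")
    if not feats:
        feats = [c for c in trained.clinical_features if not c.startswith(RACE_PREFIX)][:3]
    curves = {}
    Xtr, ytr = splits["train"]
    for fid in feats:
        curve = ev.sensitivity_analysis(
            lambda X: md.predict_remission(trained, X), Xtr, ytr, fid
        )
        curves[fid] = curve.to_frame().to_dict(orient="list")
    _write_json(rundir / "sensitivity.json", curves)
    return {"features": feats}


def stage_bias(cfg: PipelineConfig, rundir: Path) -> dict:
    splits, design, sub = _design_matrices(cfg, rundir)
    trained = md.TrainedModel.from_json(rundir / "model.json")
    frames = []
    for split, (X, y) in splits.items():
        if len(y) == 0:
            continue
        prob = md.predict_remission(trained, X)
        groups = sub.loc[X.index, ["race", "sex", "age", "treatment"]]
        frames.append(
            ev.bias_audit(
                y, prob, groups, split, threshold=cfg.evaluate.get("bias_threshold", 0.05)
            )
        )
    report = pd.concat(frames, ignore_index=True)
    report.to_csv(rundir / "bias_report.csv", index=False)
    flags = report.loc[report["flag"] == True]  # noqa: E712
    return {"n_flagged": int(len(flags))}


STAGES = [
    ("simulate", stage_simulate),
    ("split", stage_split),
    ("taxonomize", stage_taxonomize),
    ("harmonize", stage_harmonize),
    ("select-features", stage_select),
    ("tune", stage_tune),
    ("train", stage_train),
    ("evaluate", stage_evaluate),
    ("sensitivity", stage_sensitivity),
    ("bias-audit", stage_bias),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order; write a manifest; return the run dir.

    Pre-flight checks referenced input paths before any compute; a stage
    failure halts the run with stage-scoped diagnostics.
    """
    rundir = Path(config.run_dir)
    rundir.mkdir(parents=True, exist_ok=True)
    for path in (config.taxonomy_path, config.overrides_path):
        if path and not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")
    if not config.simulate and not (rundir / "responses.csv").exists():
        raise FileNotFoundError(
            "simulate=False but no responses.csv present in the run directory"
        )
    manifest = {"seed": config.seed, "config": _stringify_keys(asdict(config)), "stages": {}}
    before = {p.name for p in rundir.iterdir()}
    known = set(before)
    for name, fn in STAGES:
        if name == "simulate" and not config.simulate:
            continue
        t0 = time.time()
        try:
            info = fn(config, rundir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        outputs = {
            p.name: _sha256(p)
            for p in sorted(rundir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
        new = {k: v for k, v in outputs.items()}
        manifest["stages"][name] = {
            "elapsed_s": round(time.time() - t0, 3),
            "info": info,
            "outputs": new,
        }
        log.info("stage %s done in %.1fs: %s", name, time.time() - t0, info)
    _write_json(rundir / "manifest.json", manifest)
    return rundir


# --------------------------------------------------------------- inference


def predict_patients(
    rundir: Path | str,
    responses: pd.DataFrame,
    subjects: pd.DataFrame,
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Score new patients end-to-end from raw responses.

    Applies the run's frozen transformation records and model schema, then
    returns one row per patient with the remission probability under each
    candidate treatment (and, if the subject table carries a treatment
    column, under the assigned one).
    """
    rundir = Path(rundir)
    records = json.loads((rundir / "transform_records.json").read_text())
    trained = md.TrainedModel.from_json(rundir / "model.json")
    demo = records.pop(DEMO_RECORD)
    feats = hz.transform_with_records(responses, records)
    sub = subjects.set_index("patient_id").loc[feats.index]
    age_rec = hz.ScalingRecord(**demo["age_scaling"])
    feats["age"] = age_rec.apply(sub["age"].to_numpy(float))
    feats["sex"] = (sub["sex"] == demo["sex_positive"]).astype(float)
    for r in demo["race_levels"]:
        feats[RACE_PREFIX + r] = (sub["race"] == r).astype(float)
    clinical = feats[trained.clinical_features]
    incomplete = clinical.isna().any(axis=1)
    if incomplete.all():
        bad = clinical.columns[clinical.isna().any()].tolist()
        raise ValueError(f"no patient has complete model features; missing {bad}")
    if incomplete.any():
        # same rule as training: patients missing a selected feature are
        # dropped, not imputed
        log.warning(
            "dropping %d/%d patients with missing selected features",
            int(incomplete.sum()),
            len(clinical),
        )
        clinical = clinical[~incomplete]
        sub = sub[~incomplete]
    table = md.differential_predict_table(trained, clinical, treatments)
    # argmax takes the first maximum, i.e. ties break by treatment order
    best = table.columns[np.argmax(table.to_numpy(), axis=1)]
    out = table.rename(columns=lambda t: f"p_{t}")
    out["best_treatment"] = best
    if "treatment" in sub.columns:
        assigned = sub["treatment"]
        out["p_assigned"] = [
            table.loc[pid, t] if t in table.columns else np.nan
            for pid, t in assigned.items()
        ]
    return out
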