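import dataclasses
import json
from pathlib import Path

import pandas as pd
import pytest

from txbenefit import model as md
from txbenefit import pipeline as pl
from txbenefit import synth as sy
from txbenefit import taxonomy as tx


@pytest.fixture
def qol_tree() -> tx.TaxonomyTree:
    """Quality-of-life subtree with functional impairment and relationships."""
    return tx.build_taxonomy(
        {
            "quality_of_life": {
                "functional_impairment": {"self_care": None},
                "relationships": {"family": None, "social": None, "romantic": None},
            },
            "mood_symptoms": {"depressed_mood": None, "guilt": None},
        }
    )


def small_synth(seed: int = 0, **overrides) -> sy.SynthConfig:
    params = dict(n_studies=3, patients_per_study=150, n_noise_features=4, seed=seed)
    params.update(overrides)
    return sy.SynthConfig(**params)


def run_pipeline_in(
    tmp: Path,
    seed: int,
    synth_config: sy.SynthConfig | None = None,
    *,
    fast: bool = True,
    **config_overrides,
) -> Path:
    """Run the full pipeline into ``tmp`` and return the run directory."""
    synth_over = {}
    if synth_config is not None:
        synth_over = {
            f.name: getattr(synth_config, f.name)
            for f in dataclasses.fields(synth_config)
        }
    cfg = pl.PipelineConfig(
        run_dir=str(tmp / f"run_{seed}"),
        seed=seed,
        synth=synth_over,
        **config_overrides,
    )
    if fast and not cfg.model:
        cfg.model = {"max_epochs": 60, "early_stopping_patience": 30}
    if fast and not cfg.selection:
        cfg.selection = {"epochs": 60}
    return pl.run_pipeline(cfg)


def study_summary(rundir: Path) -> dict:
    """Collect the quantities the model-level checks assert on."""
    metrics = json.loads((rundir / "metrics.json").read_text())
    baseline = json.loads((rundir / "baseline.json").read_text())
    trained = md.TrainedModel.from_json(rundir / "model.json")
    feats = pd.read_csv(rundir / "features.csv", index_col=0)
    sel = json.loads((rundir / "selection.json").read_text())
    X = feats[sel["selected"]].dropna()
    table = md.differential_predict_table(trained, X)
    truth = json.loads((rundir / "ground_truth.json").read_text())
    tp = pd.DataFrame.from_dict(truth["treatment_probabilities"], orient="index").loc[
        X.index
    ]
    true_best = tp.idxmax(axis=1)
    pred_best = table.idxmax(axis=1)
    return {
        "val_auc": metrics["validation"]["auc"],
        "test_auc": metrics["test"]["auc"],
        "logistic_auc": baseline["auc"],
        "agree_model": float((pred_best == true_best).mean()),
        "agree_marginal": float((true_best == tp.mean().idxmax()).mean()),
        "spread": float((table.max(axis=1) - table.min(axis=1)).mean()),
    }
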