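"""Run the whole pipeline, then score new patients from raw responses.

The run directory holds every artifact (tables, transformation records,
model weights, reports) plus a manifest of stage hashes; the frozen
records let the deployed model score a new patient's raw questionnaire
responses end to end.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from txbenefit import pipeline as pl

with tempfile.TemporaryDirectory() as tmp:
    cfg = pl.PipelineConfig(run_dir=str(Path(tmp) / "run"), seed=11)
    rundir = pl.run_pipeline(cfg)

    manifest = json.loads((rundir / "manifest.json").read_text())
    for stage, entry in manifest["stages"].items():
        print(f"{stage:16s} {entry['elapsed_s']:7.1f}s  {entry['info']}")

    # pretend the last 10 patients are new arrivals
    responses = pd.read_csv(rundir / "responses.csv")
    subjects = pd.read_csv(rundir / "subjects.csv").tail(10)
    new_responses = responses[responses["patient_id"].isin(subjects["patient_id"])]
    preds = pl.predict_patients(rundir, new_responses, subjects)
    print("\nper-treatment remission probabilities for new patients:")
    print(preds.round(3).to_string())

# Each row gives one patient's predicted remission probability under
# every candidate treatment plus the top-ranked choice; patients missing
# a selected feature are dropped rather than imputed.
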