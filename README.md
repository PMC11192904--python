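# txbenefit

Merging depression clinical-trial questionnaire data into harmonized
features and training a **differential treatment benefit** model for
remission.

## The problem

Antidepressant selection still proceeds largely by trial and error. A
model that predicts, for one patient, the probability of remission under
each of several candidate drugs needs training data pooled across many
trials — and those trials administer *different* questionnaires on
*different* response scales (binary, 0–3, 0–4, 0–6), with study-specific
missingness. `txbenefit` implements the full path from heterogeneous
per-question responses to a deployable differential-benefit model:

1. **Taxonomy & grouping** (`txbenefit.taxonomy`) — items are tagged onto
   a hierarchical category tree (roots such as quality of life or symptom
   dimensions, with branches and leaves); items querying the same
   dimension are grouped at the deepest node covering all of them (their
   lowest common ancestor), with a declarative overrides file standing in
   for rater consensus.
2. **Harmonization** (`txbenefit.harmonize`) — within a group, each item
   is equated onto the largest member scale: *linear (mean–sigma)
   equating* `e(x) = μ_t + (σ_t/σ_s)(x − μ_s)` when both score
   distributions pass a Shapiro–Wilk normality check, otherwise
   *equipercentile equating* on ±0.5-continuized percentile ranks.
   A validity check requires the mean per-patient variance across
   rescaled members to stay ≤ 1 (one severity level); members are then
   averaged, z-scored on the training split, and shifted so the minimum
   is exactly 0.01. Binary-dominated groups are binarized per member and
   combined with an any-endorsement rule.
3. **Outcome** (`txbenefit.outcomes`) — remission = endpoint MADRS ≤ 10
   or HAM-D ≤ 7.
4. **Feature selection** (`txbenefit.features`) — a **CancelOut** gate
   layer (inputs × `sigmoid(w)`) prepended to the classifier
   architecture, trained with
   `loss = CE + λ₁·mean(sigmoid(w)) − λ₂·var(w)`;
   features are ranked by gate weight and the top *k* kept.
5. **Model** (`txbenefit.model`, `txbenefit.nn`) — a dense network
   (default two hidden layers of 40 ELU units, dropout 0.15, two-unit
   softmax head) over the selected features plus a one-hot treatment
   encoding; Adam (lr 0.001), up to 300 epochs, early stopping with
   patience 100 restoring the best-validation epoch. Differential
   prediction re-runs inference with each treatment's encoding switched
   on and ranks the candidates. A same-features logistic regression is
   the linear baseline.
6. **Tuning** (`txbenefit.tune`) — Bayesian optimization (GP surrogate +
   expected improvement) over depth, width, dropout, learning rate and
   the feature count *k*, maximizing validation AUROC.
7. **Evaluation** (`txbenefit.evaluate`) — accuracy / sensitivity /
   specificity / PPV / NPV / F1 / AUROC, one-at-a-time sensitivity
   curves (observed vs counterfactual-predicted remission across a
   feature's support), and a **bias audit** that flags any demographic or
   treatment subgroup whose observed remission rate exceeds its mean
   predicted probability by more than 5 percentage points.

The original pooled trial datasets are access-restricted, so
`txbenefit.synth` generates multi-study questionnaire data with known
ground truth (latent severity factors, planted treatment-by-severity
interactions, realistic demographics and missingness); every stage is
validated against that ground truth.

## Worked example

```bash
python examples/05_train_and_rank_treatments.py
```

runs the whole pipeline on the default synthetic study (3000 patients,
6 studies, 6 treatment arms) and ranks treatments for one patient:

```
train      AUC 0.750  accuracy 0.685
validation AUC 0.710  accuracy 0.625
test       AUC 0.724  accuracy 0.680

patient p00000:
  venlafaxine    p(remission) = 0.273
  escitalopram   p(remission) = 0.218
  duloxetine     p(remission) = 0.203
  paroxetine     p(remission) = 0.200
  fluoxetine     p(remission) = 0.190
  bupropion      p(remission) = 0.171
```

The AUCs say the model separates remitters from non-remitters well
beyond chance on held-out patients; the per-treatment probabilities are
this (severely depressed) patient's predicted chances of remission under
each drug, and their ordering — which varies across patients because of
the planted severity-by-treatment interactions — is the differential
treatment benefit prediction. The other scripts in `examples/`
demonstrate each capability in isolation (generation, taxonomy
grouping, equating, CancelOut selection, sensitivity/bias reporting,
end-to-end prediction from raw responses).

A thin CLI wraps the same pipeline: `txbenefit --config cfg.yaml run-all`,
plus per-stage subcommands and `predict` for scoring new patients.

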