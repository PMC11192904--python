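# Methods

This note documents the models and procedures `txbenefit` implements,
the defaults it ships, and what the synthetic study conditions do and do
not establish.

## Harmonization model

**Taxonomy and grouping.** Questionnaire items are tagged onto a forest
of named category nodes (node names are globally unique, so an item can
be tagged by bare name or full path). A group of items is merged at the
deepest node that is an ancestor-or-self of every member's category
(lowest common ancestor on primary tags; a secondary tag participates
only when an override opts the item in). Items under different roots are
never merged. Rater consensus — inherently qualitative — is replaced by
a declarative overrides list (add/remove/veto/force merge mode), making
the grouping deterministic given its inputs. A group is **binarized**
when all members are binary or binary members form a strict majority
("preponderance" is not quantified in the source methodology; strict
majority is this package's operationalization), otherwise merged on a
continuous scale.

**Score equating.** Continuous groups are equated member-by-member onto
the member with the largest admissible range (ties: larger observed
variance, then lexicographically smaller id). The method per member:

* *linear (mean–sigma)*: `e(x) = μ_t + (σ_t/σ_s)(x − μ_s)`, used when a
  Shapiro–Wilk test fails to reject normality for **both** samples at
  α = 0.05 (the test is a package choice; the methodology only requires
  "a normality check"). Moments use the population (n) denominator.
* *equipercentile*: the target score whose ±0.5-continuized percentile
  rank equals the source score's rank (Kolen–Brennan convention),
  used otherwise, for samples under 20 values, and for degenerate
  (constant) samples where normality is undefined. Outputs are clipped
  to the target's continuized observed range `[min − 0.5, max + 0.5]`:
  a discrete score occupies a unit interval under continuization, and a
  tighter clip breaks round-trip equating at extreme scores with
  mismatched tail masses. Equated scores are therefore fractional —
  values between whole numbers are expected.

Equating parameters (and the per-admissible-score equipercentile lookup
table) are estimated on the training split only and frozen into a
transformation record, so validation/test patients and future patients
are transformed by a fixed map with no leakage.

**Validity checks.** For each rescaled continuous group, the mean over
patients of the per-patient sample variance across members must not
exceed 1 — one unit is one severity level, so members disagreeing by
more than a level on average do not belong together. (Whether the rule
aggregates per patient, per pair, or on pooled values was ambiguous in
the source; per-patient mean is this package's choice.) Leave-one-out
diagnostics identify the member whose exclusion lowers the mean most.
Failing groups are dropped unless explicitly overridden. Binarized
groups get a distribution check instead: each binarized categorical
member's endorsement rate must sit within 10 percentage points
(configurable) of the native binary members' mean rate.

**Merging and scaling.** Continuous features are the per-patient mean
over non-missing rescaled members (all-missing stays missing); binary
features use an any-endorsement rule (max over members), preserving
symptom-presence semantics. Continuous features are z-scored with
train-split mean and population sd; if any train z-value is ≤ 0, the
whole column is shifted so the minimum is exactly 0.01 (ELU-family
activations treat non-positive inputs irregularly). The offset is part
of the frozen record, applied after z-scoring, so the transform is one
affine map at inference. Missing features are passed through and
reported, never imputed; the pipeline drops patients missing a selected
feature and counts them.

## Outcome

Remission is endpoint severity at or below the scale cutoff: MADRS ≤ 10
(admissible 0–60) or HAM-D ≤ 7 (0–52). Cutoffs are configurable;
inclusivity (≤) follows the standard convention.

## Feature selection (CancelOut)

A per-feature gate — inputs multiplied element-wise by
`sigmoid(w)` — is prepended to a network with the same architecture as
the final classifier, and trained with

```
loss = cross-entropy + λ₁ · mean(sigmoid(w)) − λ₂ · var(w)
```

with λ₁ = 0.2, λ₂ = 0.1 (the reference formulation's defaults,
user-configurable) and gates initialized at w = 4 (open,
sigmoid ≈ 0.98). The sparsity term closes gates that do not earn their
keep; the variance term rewards separation between kept and discarded
features. A feature's score is its raw gate weight; the top-k are
selected with lexicographic tie-breaks. Demographics (age, sex, race)
can be force-included regardless of score, since the bias audit needs
them. Before selection, features observed in fewer than 70% of patients
(configurable) are excluded: selection requires a complete-case matrix,
low-coverage features would otherwise evict most rows, and features
without a representative population cannot be collected reliably in
deployment.

## Classifier and differential prediction

A dense network maps the selected features plus a one-hot treatment
encoding to a two-unit softmax. Defaults: hidden layers [40, 40], ELU,
dropout 0.15, Adam at lr 0.001, batch size 128 (unstated in the source;
a standard tabular choice), max 300 epochs, early stopping patience 100
restoring the best-validation-epoch parameters. No class re-weighting —
the ~43% remission rate is near-balanced. The implementation is plain
numpy with hand-written gradients; at these sizes (tens of units,
thousands of rows) vectorized batch updates on one CPU train in
seconds, and inference is a pure function of (weights, input).

Differential treatment benefit prediction holds the clinical features
fixed and cycles the treatment encoding through the candidates, giving a
remission probability per treatment and a descending ranking (ties break
by configured treatment order). One-hot *input* encoding was chosen over
per-treatment output heads; the training data's feature table carries no
treatment column, but differential prediction requires the treatment to
enter the model somewhere, and a shared trunk lets every arm borrow
strength from all patients.

The logistic baseline is an L2-regularized fit (scikit-learn, C = 1) on
the identical design matrix.

## Bayesian optimization

Sequential model-based optimization with a Gaussian-process surrogate
(Matern 5/2 + white noise, inputs mapped to the unit cube) and expected
improvement over random candidate draws; the first ~budget/3 trials are
random exploration. Integers round, learning-rate-like parameters move
on a log scale. Default ranges bracket plausible optima for a tabular
clinical classifier: 1–4 layers, widths 8–128, dropout 0–0.5, lr
1e-4–1e-2, k from 5 up to the candidate count. Each trial selects the
top-k features from the CancelOut ranking before training. The reported
best is always the argmax of the trial log.

## Evaluation

Threshold metrics use 0.5 by default (configurable): PPV = TP/(TP+FP),
NPV = TN/(TN+FN), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
F1 = 2·PPV·sens/(PPV+sens); undefined denominators are reported as
not-applicable, never 0. AUROC is the rank (Mann–Whitney) formulation
with ties counted ½.

*Sensitivity analysis*: for each value in a feature's support (distinct
observed values, including equating-induced fractions; deciles if more
than 25), report the observed remission proportion among patients truly
at that value (with n) and the mean prediction when every patient's
feature is overwritten to it.

*Bias audit*: per subgroup of race, sex, age band (18–25.9, 26–40.9,
41–64.9, 65–130.9) and treatment, per split: observed remission rate,
mean predicted probability with its standard error, and a one-sided flag
when observed − predicted > 0.05 (absolute percentage points;
over-prediction never flags). No multiplicity correction — the audit is
a screening rule. Subgroup confusion metrics are attached with small-n
caveats; in small splits, subgroups of a few dozen patients can flag
from sampling noise alone, which the reports surface via n.

## Synthetic study conditions

The generator emulates what makes pooled-trial harmonization hard:
6 studies × 500 patients; 5 independent standard-normal latent severity
factors (depressed mood, anxiety, insomnia, cognitive impairment,
somatic symptoms); per factor a pool of 8 categorical items on 0–3 /
0–4 / 0–6 scales of which each study administers 3 (structural
missingness), plus 10 noise items (including binary 0–1 scales) each
carried by a random half of studies; item = factor + N(0, 0.35) noise,
discretized by fixed equal-probability cut-points (monotone in
severity). The item noise level makes parallel items agree within about
one severity level — i.e. items raters would actually have judged
mergeable; at substantially higher noise, clean groups legitimately fail
the variance rule. Entries are further deleted completely at random at
5% per study.

Outcome: logit = −0.27 (targeting the ~43% pooled remission rate) + factor
effects (depressed mood −1.0, anxiety −0.6, insomnia −0.4) + small
treatment main effects (0 to +0.25) + interactions
(depressed_mood×venlafaxine +0.8, anxiety×escitalopram +0.8,
insomnia×bupropion −0.8). Two arms per study, cycling so all six drugs
are covered. Demographics: ~64% female; race ~75.5% white, 15.1% Asian,
4.9% African descent, 3.7% Hispanic, 0.9% other; age ~N(43.6, 13.9)
clipped to 18–80 — frequencies typical of pooled antidepressant trials,
so the audit sees realistic subgroup sizes. Splits default to
0.815/0.084/0.101, stratified by outcome × treatment.

`interaction_config` is a second named condition that isolates
treatment-by-severity interactions (treatment mains zero, signed
depressed-mood×treatment weights ±1.2/±0.9/±0.6, one small anxiety main
effect). A main-effects logistic model cannot represent a sign-flipping
severity×treatment product, so this condition cleanly separates the
network from the linear baseline and gives each patient a unique
ground-truth best treatment.

**What passing tests show — and don't.** The conditions plant linear
factor effects, monotone discretized items, MCAR-within-study
missingness and independent factors. Real trial data have correlated
severity dimensions, informative missingness, site effects, rater
idiosyncrasies in the taxonomy step, and semantic mismatch that no
variance check fully captures. Recovery of planted structure here
validates the machinery (equating, checks, selection, training, audit),
not clinical performance on real pooled trials.

## Numerical choices and degenerate inputs

Sample sizes in the shipped defaults (3000 patients per study condition;
n = 2000 for the feature-recovery probe; 10 seeds for stochastic
checks) were chosen so every stage's signal is comfortably above its
noise floor at desk scale. Other conventions: Shapiro–Wilk subsamples
deterministically above n = 5000 (its validity limit); constant samples
fall back to equipercentile equating; constant features cannot be
z-scored and the group is dropped with a diagnostic; a variance check
with no patient holding ≥ 2 members is "indeterminate", not a pass;
training aborts on non-finite loss with the epoch and batch in the
message; every stage seed derives from the single top-level seed.

## Known limitations

No imputation (by design); no visit-level trajectories or dropout over
time; no NLP matching of question text (tagging is input data); no
calibration post-processing; the numpy network has no GPU path and no
weight regularization beyond dropout and early stopping; with no
treatment signal in the data the network still fits a residual
per-patient probability spread of ~0.1 across treatments — rankings from
near-identical probabilities should not be over-read, which is why
reports carry the probabilities, not just the ranking.
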