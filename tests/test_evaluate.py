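import numpy as np
import pandas as pd
import pytest

from txbenefit import evaluate as ev


def brute_force_confusion(y, p, thr):
    tp = tn = fp = fn = 0
    for yi, pi in zip(y, p):
        call = pi >= thr
        if call and yi:
            tp += 1
        elif call and not yi:
            fp += 1
        elif not call and yi:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def brute_force_auc(y, p):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pi > ni) + 0.5 * (pi == ni) for pi in pos for ni in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_formula_example(self):
        # two positive calls correct, two positive calls wrong
        rep = ev.confusion_metrics([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.6])
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 2, 0, 0)
        assert rep.ppv == 0.5 and rep.sensitivity == 1.0

    def test_perfect_predictions(self):
        rep = ev.confusion_metrics([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "auc"):
            assert getattr(rep, m) == 1.0

    def test_undefined_denominator_reported_as_none(self):
        rep = ev.confusion_metrics([0, 0, 1], [0.1, 0.2, 0.3])  # no positive calls
        assert rep.ppv is None and rep.f1 is None
        assert rep.npv == pytest.approx(2 / 3)

    def test_matches_brute_force_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(10, 200)
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            rep = ev.confusion_metrics(y, p, 0.5)
            assert (rep.tp, rep.tn, rep.fp, rep.fn) == brute_force_confusion(y, p, 0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ev.confusion_metrics([], [])


class TestAuroc:
    def test_enumerated_example(self):
        assert ev.auroc([0, 0, 1, 1], [0.1, 0.6, 0.4, 0.8]) == 0.75

    def test_separated_and_tied(self):
        assert ev.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert ev.auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.auroc([1, 1], [0.5, 0.6])

    def test_matches_all_pairs_concordance(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(10, 200)
            y = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            p = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            assert ev.auroc(y, p) == pytest.approx(brute_force_auc(y, p))


class TestSensitivityAnalysis:
    def test_ignored_feature_gives_flat_curve(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"used": rng.normal(size=50), "ignored": rng.integers(0, 4, 50)})
        y = rng.integers(0, 2, 50)
        curve = ev.sensitivity_analysis(
            lambda Z: 1 / (1 + np.exp(-Z["used"])), X, y, "ignored"
        )
        assert len(set(np.round(curve.predicted, 12))) == 1

    def test_zero_count_support_still_predicted(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 1.0]})
        y = [0, 1, 1]
        curve = ev.sensitivity_analysis(
            lambda Z: np.full(len(Z), 0.4), X, y, "f", support=[0, 1, 2]
        )
        assert curve.observed_n == [1, 2, 0]
        assert curve.observed[2] is None
        assert curve.predicted[2] == pytest.approx(0.4)

    def test_continuous_feature_binned(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"f": rng.normal(size=500)})
        curve = ev.sensitivity_analysis(
            lambda Z: np.full(len(Z), 0.5), X, np.zeros(500, int), "f"
        )
        assert len(curve.values) <= 10

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            ev.sensitivity_analysis(
                lambda Z: np.zeros(len(Z)), pd.DataFrame({"a": [1]}), [0], "b"
            )


class TestBiasAudit:
    def make(self, n=2000, seed=4):
        rng = np.random.default_rng(seed)
        sub = pd.DataFrame(
            {
                "race": rng.choice(["w", "x", "y"], n),
                "sex": rng.choice(["Female", "Male"], n),
            }
        )
        p = rng.uniform(0.2, 0.7, n)
        y = (rng.random(n) < p).astype(int)
        return y, p, sub

    def test_flag_rule_examples(self):
        # observed 0.50 vs predicted 0.44 -> flagged; 0.47 -> not;
        # over-prediction never flags
        y = np.array([1, 0] * 50)
        for pred, expect in [(0.44, True), (0.47, False), (0.60, False)]:
            rep = ev.bias_audit(
                y, np.full(100, pred), pd.DataFrame({"g": ["all"] * 100})
            )
            assert bool(rep.loc[0, "flag"]) is expect

    def test_subgroup_rates_aggregate_to_overall(self):
        y, p, sub = self.make()
        rep = ev.bias_audit(y, p, sub)
        overall = y.mean()
        for factor, grp in rep.groupby("factor"):
            pooled = (grp["observed_rate"] * grp["n"]).sum() / grp["n"].sum()
            assert pooled == pytest.approx(overall)

    def test_planted_miscalibration_flags_that_subgroup_only(self):
        y, p, sub = self.make(n=4000)
        p2 = p.copy()
        p2[(sub["race"] == "x").to_numpy()] *= 0.8
        rep = ev.bias_audit(y, p2, sub)
        flagged = set(map(tuple, rep.loc[rep["flag"], ["factor", "subgroup"]].values))
        assert flagged == {("race", "x")}

    def test_empty_subgroup_row(self):
        y = np.array([0, 1])
        p = np.array([0.4, 0.6])
        sub = pd.DataFrame({"g": pd.Categorical(["a", "a"], categories=["a", "b"])})
        rep = ev.bias_audit(y, p, sub)
        empty = rep[rep["subgroup"] == "b"].iloc[0]
        assert empty["n"] == 0 and empty["flag"] == False  # noqa: E712
        assert pd.isna(empty["observed_rate"])

    def test_age_binned_into_bands(self):
        rng = np.random.default_rng(5)
        sub = pd.DataFrame({"age": rng.uniform(18, 80, 500)})
        p = np.full(500, 0.5)
        y = rng.integers(0, 2, 500)
        rep = ev.bias_audit(y, p, sub)
        assert set(rep["subgroup"]) <= {"18-25.9", "26-40.9", "41-64.9", "65-130.9"}

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            ev.bias_audit([0, 1], [0.5, 0.5], pd.DataFrame({"g": ["a"]}))
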