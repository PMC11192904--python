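import numpy as np
import pandas as pd
import pytest

from txbenefit import model as md


def toy_design(n=600, seed=0, treatments=("a", "b")):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["f1", "f2", "f3"])
    treat = pd.Series(rng.choice(treatments, n), index=X.index)
    logit = 1.5 * X["f1"] - X["f2"]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    design = md.encode_design(X, treat, list(treatments))
    return design, y


@pytest.fixture(scope="module")
def fitted():
    design, y = toy_design()
    cfg = md.NetConfig(max_epochs=60, early_stopping_patience=30, seed=1)
    model = md.train(design[:500], y[:500], design[500:], y[500:], cfg)
    return model, design, y


class TestNetConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="dropout"):
            md.NetConfig(dropout=1.0)
        with pytest.raises(ValueError, match="patience"):
            md.NetConfig(max_epochs=10, early_stopping_patience=20)
        with pytest.raises(ValueError, match="width"):
            md.NetConfig(hidden_layers=[0])


class TestTrain:
    def test_constant_labels_rejected(self):
        design, y = toy_design(n=100)
        with pytest.raises(ValueError, match="constant"):
            md.train(design, np.zeros(100), None, None, md.NetConfig(max_epochs=2, early_stopping_patience=1))

    def test_full_epochs_when_patience_covers_them(self):
        design, y = toy_design(n=300, seed=2)
        cfg = md.NetConfig(max_epochs=25, early_stopping_patience=25, seed=0)
        model = md.train(design[:250], y[:250], design[250:], y[250:], cfg)
        assert model.history.stopped_epoch == 24
        assert len(model.history.train_loss) == 25

    def test_early_stopping_restores_best_epoch(self, fitted):
        model, _, _ = fitted
        hist = model.history
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)
        assert hist.val_loss[hist.best_epoch] <= hist.val_loss[-1]

    def test_schema_mismatch_rejected(self):
        design, y = toy_design(n=100)
        bad_val = design.rename(columns={"f1": "other"})
        with pytest.raises(ValueError, match="schema"):
            md.train(design, y, bad_val, y, md.NetConfig(max_epochs=2, early_stopping_patience=1))


class TestPredict:
    def test_softmax_probabilities(self, fitted):
        model, design, _ = fitted
        p = md.predict_remission(model, design)
        assert ((p > 0) & (p < 1)).all()
        both = model.net.predict_proba(design[model.schema].to_numpy())
        np.testing.assert_allclose(both.sum(axis=1), 1.0, atol=1e-12)

    def test_inference_is_pure(self, fitted):
        model, design, _ = fitted
        row = design.iloc[[0]]
        a = md.predict_remission(model, row)
        b = md.predict_remission(model, row)
        np.testing.assert_array_equal(a, b)

    def test_zeroed_final_layer_gives_half(self, fitted):
        model, design, _ = fitted
        import copy

        m2 = copy.deepcopy(model)
        m2.net.W[-1][:] = 0.0
        m2.net.b[-1][:] = 0.0
        p = md.predict_remission(m2, design.iloc[:5])
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_schema_mismatch_rejected(self, fitted):
        model, design, _ = fitted
        with pytest.raises(ValueError, match="schema"):
            md.predict_remission(model, design.drop(columns=["f1"]))

    def test_roundtrip_serialization(self, fitted, tmp_path):
        model, design, _ = fitted
        model.to_json(tmp_path / "m.json")
        loaded = md.TrainedModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(
            md.predict_remission(model, design),
            md.predict_remission(loaded, design),
        )


class TestDifferentialPredict:
    def test_ablated_treatment_weights_give_identical_probs(self, fitted):
        import copy

        model, design, _ = fitted
        m2 = copy.deepcopy(model)
        for i, col in enumerate(m2.schema):
            if col.startswith(md.TREATMENT_PREFIX):
                m2.net.W[0][i, :] = 0.0
        table, ranking = md.differential_predict(m2, design.iloc[0])
        assert len(set(np.round(list(table.values()), 12))) == 1
        # ties resolve in configured treatment order
        assert ranking == m2.treatment_names

    def test_probabilities_and_ranking_shape(self, fitted):
        model, design, _ = fitted
        table, ranking = md.differential_predict(model, design.iloc[3])
        assert sorted(ranking) == sorted(model.treatment_names)
        assert all(0 < p < 1 for p in table.values())
        assert table[ranking[0]] == max(table.values())

    def test_unknown_treatment_rejected(self, fitted):
        model, design, _ = fitted
        with pytest.raises(ValueError, match="unknown"):
            md.differential_predict(model, design.iloc[0], ["mirtazapine"])

    def test_table_matches_per_patient_calls(self, fitted):
        model, design, _ = fitted
        clinical = design.iloc[:4]
        table = md.differential_predict_table(model, clinical)
        for i in range(4):
            single, _ = md.differential_predict(model, clinical.iloc[i])
            for t, p in single.items():
                assert table.iloc[i][t] == pytest.approx(p)


class TestBaselineLogistic:
    def test_separable_data_perfect_auc(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        out = md.baseline_logistic(X, y, X, y)
        assert out["auc"] == 1.0

    def test_null_data_auc_near_half(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((2000, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        y = rng.integers(0, 2, 2000)
        out = md.baseline_logistic(X[:1500], y[:1500], X[1500:], y[1500:])
        assert abs(out["auc"] - 0.5) < 0.05
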