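"""Dataset splitting, regressors, metrics and the estimation grid."""

import math

import numpy as np
import pandas as pd
import pytest

import texlai
from texlai.errors import ContractError, TooFewSamplesError
from texlai.models import ModelSpec, fit_model


class TestSplit:
    def test_ninety_samples_split_sixty_thirty(self):
        split = texlai.split_dataset(90, seed=1)
        assert len(split.modeling) == 60
        assert len(split.validation) == 30

    def test_partition(self):
        split = texlai.split_dataset(50, seed=3)
        union = np.union1d(split.modeling, split.validation)
        assert np.array_equal(union, np.arange(50))
        assert len(np.intersect1d(split.modeling, split.validation)) == 0

    def test_deterministic(self):
        a = texlai.split_dataset(90, seed=5)
        b = texlai.split_dataset(90, seed=5)
        assert np.array_equal(a.modeling, b.modeling)
        c = texlai.split_dataset(90, seed=6)
        assert not np.array_equal(a.modeling, c.modeling)

    def test_too_few_samples(self):
        with pytest.raises(TooFewSamplesError):
            texlai.split_dataset(2)


class TestEvaluate:
    def test_perfect_prediction(self):
        m = texlai.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.mre) == (1.0, 0.0, 0.0)

    def test_hand_computed_case(self):
        m = texlai.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.rmse == pytest.approx(math.sqrt(1.0 / 3.0), abs=1e-12)
        assert m.mre == pytest.approx(100.0 / 9.0, abs=1e-10)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = texlai.evaluate(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_random_vectors_against_hand_formulas(self, rng):
        y = rng.uniform(0.5, 4.0, 50)
        yhat = y + rng.normal(0, 0.3, 50)
        m = texlai.evaluate(y, yhat)
        ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert m.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
        assert m.rmse == pytest.approx(math.sqrt(ss_res / 50), abs=1e-10)
        assert m.mre == pytest.approx(
            100.0 / 50 * sum(abs(a - b) / a for a, b in zip(y, yhat)), abs=1e-10
        )

    def test_zero_variance_truth_flagged(self):
        m = texlai.evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert math.isnan(m.r2)


class TestFitPredict:
    def test_plsr_recovers_noise_free_linear_target(self, rng):
        X = rng.normal(size=(60, 4))
        y = 3.0 + 2.0 * X[:, 1]
        pred = texlai.fit_predict(ModelSpec("PLSR"), X[:40], y[:40], X[40:])
        m = texlai.evaluate(y[40:] + 10, pred + 10)  # shift to keep MRE defined
        assert m.r2 > 0.99

    def test_constant_target_constant_predictions(self, rng):
        X = rng.normal(size=(20, 3))
        pred = texlai.fit_predict(ModelSpec("SVM"), X[:15], np.full(15, 2.5), X[15:])
        assert np.allclose(pred, 2.5)

    def test_plsr_collinearity_robust(self, rng):
        """Duplicating a column leaves full-rank PLS predictions unchanged:
        fitted values depend only on the projection onto the predictor span."""
        X = rng.normal(size=(50, 3))
        y = 2.0 + X @ np.array([0.5, -0.2, 0.1]) + rng.normal(0, 0.05, 50)
        Xdup = np.hstack([X, X[:, [0]]])
        spec = ModelSpec("PLSR", pls_max_lv=3, pls_gain_threshold=-1e9)
        p1 = texlai.fit_predict(spec, X[:35], y[:35], X[35:])
        p2 = texlai.fit_predict(spec, Xdup[:35], y[:35], Xdup[35:])
        assert np.allclose(p1, p2, atol=1e-6)

    def test_svm_standardization_is_train_only(self, rng):
        """Pipeline predictions equal a hand-built train-only-scaler SVR."""
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR

        X = rng.normal(size=(40, 3)) * np.array([1.0, 10.0, 100.0])
        y = rng.uniform(1.0, 3.0, 40)
        Xtr, Xva = X[:30], X[30:]
        got = texlai.fit_predict(ModelSpec("SVM"), Xtr, y[:30], Xva)
        scaler = StandardScaler().fit(Xtr)  # never sees Xva
        ref = SVR(kernel="poly", C=20.0, gamma=0.02, degree=3)
        ref.fit(scaler.transform(Xtr), y[:30])
        want = ref.predict(scaler.transform(Xva))
        assert np.allclose(got, want, atol=1e-12)

    def test_feature_count_contract(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.uniform(1, 3, 30)
        model = fit_model(ModelSpec("XGBoost"), X, y)
        with pytest.raises(ContractError):
            model.predict(rng.normal(size=(5, 4)))


class TestGrid:
    @pytest.fixture()
    def toy_blocks(self, rng):
        n = 45
        lai = rng.uniform(0.5, 3.5, n)
        feats = pd.DataFrame(
            {
                "vi1": lai + rng.normal(0, 0.3, n),
                "vi2": rng.normal(size=n),
                "tf1": 2 * lai + rng.normal(0, 0.5, n),
                "ti1": lai**2 + rng.normal(0, 0.4, n),
                "tti1": lai + rng.normal(0, 0.2, n),
            }
        )
        blocks = {"VIs": ["vi1", "vi2"], "TFs": ["tf1"], "TIs": ["ti1"], "TTIs": ["tti1"]}
        return feats, lai, blocks

    def test_grid_has_45_cells(self, toy_blocks):
        feats, lai, blocks = toy_blocks
        split = texlai.split_dataset(len(feats), seed=2)
        results = texlai.run_grid(feats, lai, blocks, split)
        assert len(results) == 15 * 3
        table = texlai.grid_table(results)
        assert set(table["model"]) == set(texlai.MODEL_NAMES)
        assert table["validation_RMSE"].ge(0).all()

    def test_grid_deterministic(self, toy_blocks):
        feats, lai, blocks = toy_blocks
        split = texlai.split_dataset(len(feats), seed=2)
        t1 = texlai.grid_table(texlai.run_grid(feats, lai, blocks, split))
        t2 = texlai.grid_table(texlai.run_grid(feats, lai, blocks, split))
        pd.testing.assert_frame_equal(t1, t2)

    def test_combination_enumeration(self):
        blocks = {"VIs": ["a"], "TFs": ["b"], "TIs": ["c"], "TTIs": ["d"]}
        combos = texlai.enumerate_combinations(blocks)
        assert len(combos) == 15
        names = [c.name for c in combos]
        assert names[0] == "VIs" and names[-1] == "VIs + TFs + TIs + TTIs"
        full = combos[-1]
        assert full.columns == ["a", "b", "c", "d"]


class TestPredictMap:
    @pytest.fixture()
    def trained_on_scene(self, rng):
        radiative = texlai.CanopyRadiativeModel()
        img, mask = texlai.render_scene(2.0, radiative, (32, 32), seed=4)
        feats, rows, cols = texlai.window_texture_features(img, mask)
        table = pd.DataFrame(feats, columns=list(texlai.TEXTURE_LABELS))
        cols_used = ["MEA6", "VAR6", "CON6"]
        X = table[cols_used].to_numpy()
        y = rng.uniform(1.5, 2.5, len(X))
        model = fit_model(ModelSpec("XGBoost"), X, y)
        combo = texlai.InputCombination("TFs", ("TFs",), cols_used)
        return img, mask, model, combo

    def test_no_data_complements_mask(self, trained_on_scene):
        img, mask, model, combo = trained_on_scene
        out = texlai.predict_map(img, mask, model, combo)
        half = 3
        interior = np.zeros(img.shape, bool)
        interior[half:-half, half:-half] = True
        expected_valid = mask & interior
        assert np.array_equal(np.isfinite(out), expected_valid)

    def test_constant_scene_constant_map(self, rng):
        data = np.full((20, 20, 6), 0.3, dtype=np.float32)
        img = texlai.MultispectralImage(data)
        mask = np.ones((20, 20), bool)
        X = rng.normal(size=(30, 2))
        y = rng.uniform(1, 3, 30)
        model = fit_model(ModelSpec("XGBoost"), X, y)
        combo = texlai.InputCombination("TFs", ("TFs",), ["MEA6", "HOM6"])
        out = texlai.predict_map(img, mask, model, combo)
        vals = out[np.isfinite(out)]
        assert len(np.unique(vals)) == 1

    def test_requires_tuples_for_index_blocks(self, trained_on_scene):
        img, mask, model, _ = trained_on_scene
        combo = texlai.InputCombination("TIs", ("TIs",), ["NDTI_best"])
        with pytest.raises(ContractError):
            texlai.predict_map(img, mask, model, combo, best_tuples=None)
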