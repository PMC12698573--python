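"""Split arithmetic, metrics, the seven regression kinds, and grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

from hypyield import models as M
from hypyield.containers import SampleTable
from hypyield.errors import ConfigurationError, DataError, DimensionError
from hypyield.nn import LSTMRegressor, _Cell

FAST_NN = {"max_epochs": 30, "patience": 10, "hidden_size": 12}


class TestSplit:
    def test_200_samples_give_140_30_30(self):
        assert M.split_sizes(200) == (140, 30, 30)

    def test_10_samples_give_8_1_1_by_floor_remainder_rule(self):
        assert M.split_sizes(10) == (8, 1, 1)

    def test_labels_partition_and_determinism(self, small_table):
        a = M.split_dataset(small_table, M.SplitSpec(seed=4))
        b = M.split_dataset(small_table, M.SplitSpec(seed=4))
        assert np.array_equal(a.split, b.split)
        counts = pd.Series(a.split).value_counts()
        # floors 105/22/22 leave one remainder sample, assigned to train
        assert counts["train"] == 106 and counts["val"] == 22 and counts["test"] == 22

    def test_too_small_dataset_rejected(self):
        table = SampleTable(np.random.rand(5, 4), np.arange(4.0), np.random.rand(5))
        with pytest.raises(ConfigurationError):
            M.split_dataset(table)


class TestMetrics:
    def test_hand_case(self):
        y, y_hat = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        assert M.r_squared(y, y_hat) == pytest.approx(0.5)
        assert M.rmse(y, y_hat) == pytest.approx(np.sqrt(1.0 / 3.0))

    def test_perfect_fit(self, rng):
        y = rng.random(20)
        assert M.r_squared(y, y) == 1.0 and M.rmse(y, y) == 0.0

    def test_mean_prediction_gives_zero_r_squared(self, rng):
        y = rng.random(20)
        assert M.r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_constant_y_raises(self):
        with pytest.raises(DataError):
            M.r_squared(np.ones(5), np.zeros(5))


class TestFitPredict:
    def test_plsr_recovers_noiseless_linear_data(self, rng):
        X = rng.random((60, 8))
        y = X @ rng.random(8) + 1.0
        model = M.fit(M.ModelSpec("plsr", {"n_components": 8}), X, y)
        assert M.r_squared(y, model.predict(X)) == pytest.approx(1.0, abs=1e-8)

    def test_knnr_single_neighbour_memorises_training_set(self, rng):
        X, y = rng.random((30, 5)), rng.random(30)
        model = M.fit(M.ModelSpec("knnr", {"n_neighbors": 1}), X, y)
        assert M.rmse(y, model.predict(X)) == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_gives_empty_output(self, rng):
        model = M.fit(M.ModelSpec("rf", {"n_estimators": 10}), rng.random((20, 4)), rng.random(20))
        assert model.predict(np.empty((0, 4))).size == 0

    def test_row_permutation_permutes_predictions(self, rng):
        X, y = rng.random((30, 6)), rng.random(30)
        model = M.fit(M.ModelSpec("plsr", {"n_components": 3}), X, y)
        perm = rng.permutation(10)
        X_new = rng.random((10, 6))
        assert np.allclose(model.predict(X_new)[perm], model.predict(X_new[perm]))

    def test_feature_layout_mismatch_raises(self, rng):
        model = M.fit(M.ModelSpec("plsr"), rng.random((30, 6)), rng.random(30))
        with pytest.raises(DimensionError):
            model.predict(rng.random((5, 4)))

    def test_non_finite_training_data_rejected(self, rng):
        X = rng.random((20, 4))
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            M.fit(M.ModelSpec("plsr"), X, rng.random(20))

    @pytest.mark.parametrize("kind", M.MODEL_KINDS)
    def test_all_kinds_share_the_fit_predict_contract(self, rng, kind):
        X = rng.random((40, 10))
        y = X @ rng.random(10)
        model = M.fit(M.ModelSpec(kind), X, y, nn_options=FAST_NN)
        pred = model.predict(X)
        assert pred.shape == (40,) and np.all(np.isfinite(pred))


class TestRecurrent:
    def test_bptt_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        cell = _Cell(hidden=3, rng=rng)
        X = rng.standard_normal((2, 4))
        r = rng.standard_normal((2, 3))  # random readout direction

        def loss() -> float:
            h, _ = cell.forward(X)
            return float(np.sum(h * r))

        h, cache = cell.forward(X)
        grads = cell.backward(r, cache)
        eps = 1e-6
        for p, g in zip(cell.params(), grads):
            flat = p.ravel()
            for idx in [0, flat.size // 2, flat.size - 1]:
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                assert g.ravel()[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-7)

    def test_training_is_deterministic_under_seed(self, rng):
        X = rng.random((30, 8))
        y = X @ rng.random(8)
        preds = []
        for _ in range(2):
            model = LSTMRegressor(hidden_size=6, max_epochs=10, seed=3)
            model.fit(X, y)
            preds.append(model.predict(X))
        assert np.array_equal(preds[0], preds[1])

    def test_bilstm_symmetric_under_sequence_reversal(self, small_table):
        table = M.split_dataset(small_table, M.SplitSpec(seed=2))
        scores = []
        for reverse in (False, True):
            X = table.spectra[:, ::-1] if reverse else table.spectra
            res = M.YieldModel(
                X, table.y, table.split, kind="bilstm",
                nn_options={"max_epochs": 60, "patience": 15, "hidden_size": 16},
            ).fit()
            scores.append(res.RMSEp)
        assert abs(scores[0] - scores[1]) < 0.05


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X, y = rng.random((30, 5)), rng.random(30)
        best, surface = M.grid_search("rf", {"n_estimators": [25]}, X, y, folds=3, seed=0)
        assert best.hyperparameters["n_estimators"] == 25
        assert len(surface) == 1

    def test_argmin_matches_exhaustive_reevaluation_oracle(self, rng):
        X = rng.random((40, 6))
        y = X @ rng.random(6) + 0.05 * rng.standard_normal(40)
        grid = {
            "learning_rate": [1e-3, 3e-3, 1e-2, 3e-2],
            "hidden_layer_size": [4, 6, 8, 10],
        }
        nn_opts = {"max_epochs": 5, "patience": 3}
        best, surface = M.grid_search(
            "bilstm_gs", grid, X, y, folds=3, seed=7, nn_options=nn_opts
        )
        assert len(surface) == 16

        # independent re-evaluation of every grid point with the same folds
        cv = KFold(n_splits=3, shuffle=True, random_state=7)
        splits = list(cv.split(X))
        oracle = {}
        for lr in grid["learning_rate"]:
            for h in grid["hidden_layer_size"]:
                errs = []
                for tr, te in splits:
                    spec = M.ModelSpec(
                        "bilstm_gs",
                        {"learning_rate": lr, "hidden_layer_size": h},
                        training_seed=7,
                    )
                    m = M.fit(spec, X[tr], y[tr], nn_options=nn_opts)
                    errs.append(M.rmse(y[te], m.predict(X[te])))
                oracle[(lr, h)] = np.mean(errs)
        oracle_best = min(oracle, key=lambda k: (oracle[k],))
        got = (best.hyperparameters["learning_rate"], best.hyperparameters["hidden_layer_size"])
        assert got == oracle_best

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            M.grid_search("rf", {"n_estimators": []}, rng.random((20, 3)), rng.random(20))


class TestEvaluate:
    def test_noiseless_linear_data_perfect_on_both_splits(self, small_table):
        table = M.split_dataset(small_table, M.SplitSpec(seed=1))
        res = M.YieldModel.from_table(table, kind="plsr").fit()
        assert res.Rc2 == pytest.approx(1.0, abs=1e-6)
        assert res.Rp2 == pytest.approx(1.0, abs=1e-6)

    def test_mean_predictor_negative_on_shifted_test_split(self, rng):
        X = rng.random((40, 3))
        y = rng.random(40)
        split = np.array(["train"] * 30 + ["test"] * 10, dtype=object)
        y[30:] += 5.0  # shift the test mean well away from the training mean

        class MeanModel:
            spec = M.ModelSpec("plsr")

            def predict(self, Xq):
                return np.full(len(Xq), y[:30].mean())

        report = M.evaluate(MeanModel(), X, y, split)
        assert report.Rp2 <= 0

    def test_report_carries_metadata(self, small_table):
        table = M.split_dataset(small_table, M.SplitSpec(seed=1))
        res = M.YieldModel.from_table(
            table, kind="rf", hyperparameters={"n_estimators": 20}, input_code="A1"
        ).fit()
        assert res.report.input_code == "A1"
        assert res.report.hyperparameters["n_estimators"] == 20
        assert "A1" in res.summary() and "Rc2" in res.summary().replace("Rc2 ", "Rc2")

    def test_empty_split_rejected(self, rng):
        X, y = rng.random((10, 3)), rng.random(10)

        class Dummy:
            spec = M.ModelSpec("plsr")

            def predict(self, Xq):
                return np.zeros(len(Xq))

        with pytest.raises(ConfigurationError):
            M.evaluate(Dummy(), X, y, np.array(["train"] * 10, dtype=object))


class TestYieldModelFrontend:
    def test_from_dataframe(self, rng):
        df = pd.DataFrame(rng.random((40, 3)), columns=["b1", "b2", "b3"])
        df["yield"] = df["b1"] * 2.0
        df["split"] = ["train"] * 28 + ["val"] * 6 + ["test"] * 6
        res = M.YieldModel.from_dataframe(df, ["b1", "b2", "b3"], kind="plsr").fit()
        assert res.Rp2 > 0.99

    def test_unlabelled_table_rejected(self, small_table):
        with pytest.raises(DataError):
            M.YieldModel.from_table(small_table)
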