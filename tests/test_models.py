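"""Model zoo construction, metrics, search, and the prediction pipeline."""

import math

import numpy as np
import pytest

from cppuptake.models import (
    DEFAULT_CONFIGS,
    MODEL_KINDS,
    ModelConfig,
    UptakePredictor,
    build_model,
    evaluate,
    evaluate_predictions,
    hyperparameter_search,
    train,
)
from cppuptake.pipeline import build_schema
from cppuptake.schema_io import FeatureSchema

from conftest import make_record


# ------------------------------------------------------------- fixtures
@pytest.fixture(scope="module")
def linear_fixture():
    """Noiseless planted linear map: y = 3 x0 - 2 x3 + 0.5 x7."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(300, 10))
    y = 3 * X[:, 0] - 2 * X[:, 3] + 0.5 * X[:, 7]
    return X, y


# --------------------------------------------------------------- config
class TestModelConfig:
    def test_all_kinds_have_grids_and_defaults(self):
        for kind in MODEL_KINDS:
            ModelConfig(kind=kind, hyperparameters=DEFAULT_CONFIGS[kind])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            ModelConfig(kind="boltzmann_machine")

    def test_invalid_hyperparameter_named(self):
        with pytest.raises(ValueError, match="wingspan"):
            ModelConfig(kind="knn", hyperparameters={"wingspan": 3})


class TestBuildModel:
    def test_knn_honors_settings(self):
        m = build_model(
            ModelConfig(
                "knn",
                {"n_neighbors": 2, "p": 2, "algorithm": "brute"},
            )
        )
        assert m.n_neighbors == 2 and m.p == 2 and m.algorithm == "brute"

    def test_deep_net_single_hidden_layer(self, linear_fixture):
        X, y = linear_fixture
        m = build_model(
            ModelConfig(
                "deep_net",
                {"depth": 1, "layer_size": 500, "dropout_rate": 0.3,
                 "use_dropout": True, "epochs": 2, "learning_rate": 1e-3},
                seed=0,
            )
        )
        m.fit(X, y)
        assert m._core.dims == [10, 500, 1]

    def test_forked_net_toy_schema_branch_count(self):
        schema = FeatureSchema(
            blocks=[
                ("whole_peptide", ["a", "b"]),
                ("concentration", ["c"]),
                ("cargo", ["d", "e", "f"]),
            ]
        )
        m = build_model(
            ModelConfig("forked_net", {"depth": 1, "epochs": 1}), schema=schema
        )
        m.initialize(6)
        assert m.n_branches_ == 3

    def test_legacy_auto_max_features_shim(self):
        m = build_model(
            ModelConfig("decision_tree", {"max_features": "auto"})
        )
        assert m.max_features == 1.0

    def test_xgb_none_tokens_map_to_defaults(self):
        m = build_model(
            ModelConfig(
                "gradient_boosted_trees",
                {"learning_rate": None, "booster": None, "max_depth": None},
            )
        )
        params = m.get_params()
        assert params["booster"] == "gbtree"
        assert params["learning_rate"] is None  # xgboost default applies


class TestMetrics:
    def test_rmse_squared_equals_mse_on_random_evaluations(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            m = evaluate_predictions(
                rng.normal(size=50), rng.normal(size=50)
            )
            assert m.rmse**2 == pytest.approx(m.mse, abs=1e-9)
            assert abs(m.pearson) <= 1 and abs(m.spearman) <= 1
            assert m.r2 <= 1

    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 5.0, -1.0])
        m = evaluate_predictions(y, y)
        assert (m.rmse, m.mse, m.mae) == (0.0, 0.0, 0.0)
        assert m.pearson == pytest.approx(1.0, abs=1e-12)
        assert m.spearman == pytest.approx(1.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        m = evaluate_predictions([3.0, 4.0], [0.0, 0.0])
        assert m.rmse == pytest.approx(math.sqrt(12.5))
        assert m.mae == pytest.approx(3.5)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=80)
        pred = y + rng.normal(size=80)
        a = evaluate_predictions(y, pred).spearman
        b = evaluate_predictions(y, np.exp(pred)).spearman
        assert a == pytest.approx(b, abs=1e-12)

    def test_diverged_predictions_reported_as_failed(self):
        m = evaluate_predictions([1.0, 2.0], [np.inf, 0.0])
        assert m.status == "failed" and math.isnan(m.rmse)

    def test_fewer_than_two_samples_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            evaluate_predictions([1.0], [1.0])


class TestTrainAndSearch:
    def test_xgb_fits_planted_linear_map(self, linear_fixture):
        X, y = linear_fixture
        m = build_model(
            ModelConfig(
                "gradient_boosted_trees",
                {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.3,
                 "booster": "gbtree"},
                seed=0,
            )
        )
        train(m, X, y)
        assert evaluate(m, X, y, "train").r2 > 0.99

    def test_deep_net_loss_decreases(self, linear_fixture):
        X, y = linear_fixture
        m = build_model(
            ModelConfig(
                "deep_net",
                {"depth": 1, "layer_size": 64, "use_dropout": False,
                 "dropout_rate": 0.3, "epochs": 30, "learning_rate": 1e-3},
                seed=0,
            )
        )
        m.fit(X, y)
        assert m.loss_curve_[-1] < m.loss_curve_[0]

    def test_tree_refit_is_deterministic(self, linear_fixture):
        X, y = linear_fixture
        cfg = ModelConfig(
            "random_forest", {"n_estimators": 10, "max_depth": 5}, seed=3
        )
        p1 = build_model(cfg).fit(X, y).predict(X)
        p2 = build_model(cfg).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_non_finite_training_data_rejected(self):
        m = build_model(ModelConfig("knn", {"n_neighbors": 2}))
        with pytest.raises(ValueError, match="non-finite"):
            train(m, np.array([[np.nan]]), np.array([1.0]))

    def test_dominant_grid_point_wins(self, linear_fixture):
        X, y = linear_fixture
        best, log = hyperparameter_search(
            "knn",
            X,
            y,
            grid={"n_neighbors": [2, 150], "algorithm": ["brute"]},
            cv=3,
            seed=0,
        )
        assert best.hyperparameters["n_neighbors"] == 2
        assert len(log) == 2 and log["mean_cv_mse"].notna().all()

    def test_search_is_deterministic(self, linear_fixture):
        X, y = linear_fixture
        grid = {"n_neighbors": [2, 5, 9], "algorithm": ["brute"]}
        b1, l1 = hyperparameter_search("knn", X, y, grid=grid, cv=3, seed=7)
        b2, l2 = hyperparameter_search("knn", X, y, grid=grid, cv=3, seed=7)
        assert b1.hyperparameters == b2.hyperparameters
        assert l1.equals(l2)

    def test_net_search_honors_stated_ranges(self, linear_fixture):
        X, y = linear_fixture
        grid = {
            "depth": ("randint", 1, 2),
            "layer_size": ("quniform", 16, 32, 16),
            "use_dropout": ("choice", [False]),
            "dropout_rate": ("quniform", 0.1, 0.9, 0.1),
            "epochs": ("quniform", 5, 10, 5),
            "learning_rate": ("quniform", 0.00001, 0.001, 0.00001),
        }
        best, log = hyperparameter_search(
            "deep_net", X, y, grid=grid, cv=2, n_iter=4, seed=1
        )
        assert (log["learning_rate"] >= 0.00001 - 1e-12).all()
        assert (log["learning_rate"] <= 0.001 + 1e-12).all()
        assert set(log["depth"]) <= {1, 2}
        assert log["mean_cv_mse"].idxmin() == int(
            log.index[log["mean_cv_mse"] == log["mean_cv_mse"].min()][0]
        )

    def test_empty_grid_rejected(self, linear_fixture):
        X, y = linear_fixture
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_search("knn", X, y, grid={}, seed=0)


@pytest.fixture(scope="module")
def predictor(small_benchmark):
    bench = small_benchmark
    cfg = ModelConfig(
        "gradient_boosted_trees",
        {"n_estimators": 40, "max_depth": 4, "learning_rate": 0.3,
         "booster": "gbtree"},
        seed=2,
    )
    model = build_model(cfg, schema=bench["fm"].schema)
    feats = bench["feature_cols"]
    model.fit(
        bench["train"][feats].to_numpy(),
        bench["train"]["target"].to_numpy(),
    )
    return UptakePredictor(
        featurizer=bench["featurizer"],
        kept_columns=feats,
        stats=bench["stats"],
        model=model,
        config=cfg,
    )


class TestPredictionPipeline:
    def test_partial_failure_contract(self, predictor):
        records = [
            make_record("ok1"),
            make_record("bad", sequence="KK??KK"),
            make_record("ok2", sequence="RRRRRRRR"),
        ]
        out, failures = predictor.predict_records(records)
        assert list(out["record_id"]) == ["ok1", "ok2"]
        assert len(failures) == 1 and failures[0].record_id == "bad"

    def test_batch_order_invariance(self, predictor):
        records = [
            make_record("a"),
            make_record("b", sequence="KLWKKLLKW"),
            make_record("c", sequence="RRRRRR"),
        ]
        fwd, _ = predictor.predict_records(records)
        rev, _ = predictor.predict_records(records[::-1])
        merged = fwd.merge(rev, on="record_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(
            merged["predicted_log10_uptake_f"],
            merged["predicted_log10_uptake_r"],
        )

    def test_training_record_reprediction_matches_stored(
        self, predictor, small_benchmark
    ):
        bench = small_benchmark
        train_ids = set(bench["train"].index[:5])
        records = [
            r for r in bench["survivors"] if r.record_id in train_ids
        ]
        out, failures = predictor.predict_records(records)
        assert not failures
        stored = predictor.model.predict(
            bench["train"].loc[out["record_id"], bench["feature_cols"]]
            .to_numpy()
        )
        np.testing.assert_allclose(
            out["predicted_log10_uptake"].to_numpy(), stored, atol=1e-9
        )

    def test_provenance_columns_present(self, predictor):
        out, _ = predictor.predict_records(
            [make_record("x", sequence="Grk[Orn]KR")]
        )
        assert out.loc[0, "n_substitutions"] == 3
        assert out.loc[0, "genomics_match"] in (0.0, 1.0)

    def test_save_load_round_trip(self, predictor, tmp_path):
        records = [make_record("z1"), make_record("z2", sequence="KKKKKK")]
        before, _ = predictor.predict_records(records)
        predictor.save(tmp_path / "artifact")
        loaded = UptakePredictor.load(tmp_path / "artifact")
        after, _ = loaded.predict_records(records)
        np.testing.assert_allclose(
            before["predicted_log10_uptake"], after["predicted_log10_uptake"]
        )
        assert (tmp_path / "artifact" / "config.yaml").exists()
        assert (tmp_path / "artifact" / "normalization_stats.csv").exists()
        assert (tmp_path / "artifact" / "kept_columns.txt").exists()
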