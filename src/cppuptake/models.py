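"""Regression model zoo, hyperparameter search, metrics, and prediction.

Nine model kinds are supported: SVM, SGD, k-NN, decision tree, random
forest, extremely randomized trees, gradient-boosted trees (xgboost), a
deep MLP, and the forked multi-branch network. Hyperparameter grids are
declared in the models' published parameter vocabulary; a compatibility
shim maps legacy tokens (e.g. ``max_features="auto"``) onto their modern
library equivalents at build time.

Model selection defaults to 5-fold cross-validated MSE on the training
set — the test split never participates. Evaluation reports six metrics
(RMSE, MSE, MAE, Pearson, Spearman, r2); a diverged model (non-finite
predictions, an occasional SGD failure mode on wide inputs) yields a
structured ``failed`` metric set rather than an exception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import SGDRegressor
from sklearn.metrics import (
    mean_absolute_error,
    mean_squared_error,
    r2_score,
)
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from ._nn import (
    DEFAULT_BRANCH_SIZES,
    DeepNetRegressor,
    ForkedNetRegressor,
    forked_parameter_count,
    forked_trunk_widths,
)
from .pipeline import branch_block_indices, branch_indices_for_columns
from .schema_io import FeatureSchema

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "ModelConfig",
    "MetricSet",
    "PARAM_GRIDS",
    "DEFAULT_CONFIGS",
    "build_model",
    "hyperparameter_search",
    "train",
    "evaluate_predictions",
    "evaluate",
    "UptakePredictor",
    "DeepNetRegressor",
    "ForkedNetRegressor",
    "forked_parameter_count",
    "forked_trunk_widths",
]

MODEL_KINDS = (
    "svm",
    "sgd",
    "knn",
    "decision_tree",
    "random_forest",
    "extra_trees",
    "gradient_boosted_trees",
    "deep_net",
    "forked_net",
)

_TREE_CRITERIA = ["squared_error", "friedman_mse", "absolute_error"]

#: Exhaustive grids for the seven classical models; sampled ranges for the
#: two nets (``("randint", lo, hi)``, ``("quniform", lo, hi, q)``,
#: ``("choice", [...])``).
PARAM_GRIDS: dict[str, dict] = {
    "svm": {
        "kernel": ["linear", "poly", "rbf", "sigmoid"],
        "C": [0.5, 1.0, 1.5],
        "gamma": ["scale", "auto"],
    },
    "sgd": {
        "loss": ["squared_error"],
        "penalty": ["l2", "l1", "elasticnet"],
        "alpha": [0.00001, 0.0001, 0.001],
        "learning_rate": ["invscaling", "optimal", "constant", "adaptive"],
    },
    "knn": {
        "n_neighbors": [2, 3, 5, 7],
        "p": [1, 2],
        "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
    },
    "decision_tree": {
        "splitter": ["best", "random"],
        "criterion": _TREE_CRITERIA,
        "max_depth": [None, 3, 5, 10, 50, 100],
        "min_samples_split": [2, 3, 5, 7, 10],
        "min_samples_leaf": [2, 3, 5, 7, 10],
        "min_weight_fraction_leaf": [0.0, 0.25, 0.50],
        "max_features": ["auto", "sqrt", "log2", None],
    },
    "random_forest": {
        "n_estimators": [10, 50, 100, 250],
        "criterion": _TREE_CRITERIA,
        "max_depth": [3, 5, 10, 50, 100],
        "min_samples_split": [2, 3, 5, 7, 10],
        "min_samples_leaf": [2, 3, 5, 7, 10],
        "min_weight_fraction_leaf": [0.0, 0.25, 0.50],
    },
    "extra_trees": {
        "n_estimators": [10, 50, 100, 250],
        "criterion": _TREE_CRITERIA,
        "max_depth": [None, 3, 5, 10, 50, 100],
        "min_samples_split": [2, 3, 5, 7, 10],
        "min_samples_leaf": [2, 3, 5, 7, 10],
        "min_weight_fraction_leaf": [0.0, 0.25, 0.50],
    },
    "gradient_boosted_trees": {
        "n_estimators": [10, 50, 100, 250],
        "max_depth": [None, 3, 5, 10, 50, 100],
        "max_leaves": [None, 1, 3, 5, 10, 25],
        "learning_rate": [None, 0.15, 0.3, 0.46, 0.60, 0.76, 0.90],
        "booster": [None, "gbtree", "gblinear", "dart"],
        "alpha": [0, 1, 3, 5],
        "lambda": [1, 3, 5],
        "gamma": [0, 1, 3, 5],
    },
    "deep_net": {
        "depth": ("randint", 1, 10),
        "layer_size": ("quniform", 100, 1500, 100),
        "use_dropout": ("choice", [True, False]),
        "dropout_rate": ("quniform", 0.1, 0.9, 0.1),
        "epochs": ("quniform", 100, 1000, 10),
        "learning_rate": ("quniform", 0.00001, 0.001, 0.00001),
    },
    "forked_net": {
        "depth": ("randint", 1, 10),
        "dropout_rate": ("quniform", 0.1, 0.9, 0.1),
        "use_dropout": ("choice", [True, False]),
        "learning_rate": ("quniform", 0.00001, 0.001, 0.00001),
        "experimental_size": ("randint", 5, 50),
        "cargo_size": ("randint", 25, 250),
        "anomaly_type_size": ("randint", 5, 200),
        "whole_peptide_size": ("randint", 10, 300),
        "sequence_size": ("randint", 100, 1000),
        "genomics_size": ("randint", 100, 750),
        "anomaly_position_size": ("randint", 5, 50),
        "epochs": ("quniform", 100, 1000, 10),
    },
}

#: Tuned reference configurations per model kind.
DEFAULT_CONFIGS: dict[str, dict] = {
    "svm": {"kernel": "rbf", "C": 1.5, "gamma": "scale"},
    "sgd": {
        "loss": "squared_error",
        "penalty": "l2",
        "alpha": 0.00001,
        "learning_rate": "adaptive",
    },
    "knn": {"n_neighbors": 2, "p": 2, "algorithm": "brute"},
    "decision_tree": {
        "splitter": "best",
        "criterion": "friedman_mse",
        "max_depth": 10,
        "min_samples_split": 3,
        "min_samples_leaf": 7,
        "min_weight_fraction_leaf": 0.0,
        "max_features": "auto",
    },
    "random_forest": {
        "n_estimators": 50,
        "criterion": "squared_error",
        "max_depth": 50,
        "min_samples_split": 3,
        "min_samples_leaf": 3,
        "min_weight_fraction_leaf": 0.0,
    },
    "extra_trees": {
        "n_estimators": 10,
        "criterion": "friedman_mse",
        "max_depth": 100,
        "min_samples_split": 10,
        "min_samples_leaf": 7,
        "min_weight_fraction_leaf": 0.0,
    },
    "gradient_boosted_trees": {
        "n_estimators": 50,
        "max_depth": 10,
        "max_leaves": 10,
        "learning_rate": None,
        "booster": "dart",
        "alpha": 1,
        "lambda": 3,
        "gamma": 0,
    },
    "deep_net": {
        "depth": 1,
        "layer_size": 500,
        "use_dropout": True,
        "dropout_rate": 0.3,
        "epochs": 230,
        "learning_rate": 0.0005,
    },
    "forked_net": {
        "depth": 7,
        "dropout_rate": 0.9,
        "use_dropout": False,
        "learning_rate": 0.0001,
        "experimental_size": 39,
        "cargo_size": 239,
        "anomaly_type_size": 79,
        "whole_peptide_size": 155,
        "sequence_size": 850,
        "genomics_size": 687,
        "anomaly_position_size": 45,
        "epochs": 170,
    },
}


@dataclass
class ModelConfig:
    """Model kind + hyperparameters (published vocabulary) + seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}"
            )
        grid = PARAM_GRIDS[self.kind]
        bad = [k for k in self.hyperparameters if k not in grid]
        if bad:
            raise ValueError(
                f"invalid hyperparameter(s) for {self.kind}: {bad}; "
                f"known: {sorted(grid)}"
            )


def _shim_max_features(value):
    # sklearn removed "auto" for regressors; its documented legacy meaning
    # for regression trees was all features, i.e. 1.0
    if value == "auto":
        logger.info('max_features "auto" mapped to 1.0 (legacy equivalent)')
        return 1.0
    return value


def _build_xgb(params: dict, seed: int) -> XGBRegressor:
    p = dict(params)
    kw: dict = {"random_state": seed, "n_jobs": 1, "verbosity": 0}
    if p.get("n_estimators") is not None:
        kw["n_estimators"] = p["n_estimators"]
    if p.get("max_depth") is not None:
        kw["max_depth"] = p["max_depth"]
    if p.get("max_leaves") is not None:
        kw["max_leaves"] = p["max_leaves"]
    if p.get("learning_rate") is not None:
        kw["learning_rate"] = p["learning_rate"]
    kw["booster"] = p.get("booster") or "gbtree"
    if "alpha" in p:
        kw["reg_alpha"] = p["alpha"]
    if "lambda" in p:
        kw["reg_lambda"] = p["lambda"]
    if "gamma" in p:
        kw["gamma"] = p["gamma"]
    return XGBRegressor(**kw)


def build_model(
    config: ModelConfig,
    schema: Optional[FeatureSchema] = None,
    feature_columns: Optional[Sequence[str]] = None,
):
    """Instantiate an untrained estimator honoring the configuration.

    ``forked_net`` needs the feature schema to wire one input branch per
    feature-block group; pass ``feature_columns`` (block-prefixed names of
    a pruned matrix, in order) when the training matrix no longer carries
    every schema column.
    """
    p = dict(config.hyperparameters)
    seed = config.seed
    kind = config.kind
    if kind == "svm":
        return SVR(**p)
    if kind == "sgd":
        kw = dict(p)
        if kw.get("learning_rate") in ("constant", "invscaling", "adaptive"):
            kw.setdefault("eta0", 0.01)
        return SGDRegressor(random_state=seed, **kw)
    if kind == "knn":
        return KNeighborsRegressor(**p)
    if kind == "decision_tree":
        if "max_features" in p:
            p["max_features"] = _shim_max_features(p["max_features"])
        return DecisionTreeRegressor(random_state=seed, **p)
    if kind == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    if kind == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **p)
    if kind == "gradient_boosted_trees":
        return _build_xgb(p, seed)
    if kind == "deep_net":
        return DeepNetRegressor(random_state=seed, **{
            k: (int(v) if k in ("depth", "layer_size", "epochs") else v)
            for k, v in p.items()
        })
    if kind == "forked_net":
        if schema is None:
            raise ValueError("forked_net requires the feature schema")
        if feature_columns is not None:
            groups = branch_indices_for_columns(schema, feature_columns)
        else:
            groups = branch_block_indices(schema)
        blocks = [(name, idx) for name, idx in groups.items() if idx.size]
        sizes = {
            name: int(p.pop(f"{name}_size", DEFAULT_BRANCH_SIZES.get(name, 32)))
            for name in groups
        }
        return ForkedNetRegressor(
            blocks=blocks,
            branch_sizes=sizes,
            random_state=seed,
            **{
                k: (int(v) if k in ("depth", "epochs") else v)
                for k, v in p.items()
            },
        )
    raise ValueError(f"unknown model kind {kind!r}")  # pragma: no cover


@dataclass
class MetricSet:
    """The six regression metrics plus a subset label and status."""

    rmse: float
    mse: float
    mae: float
    pearson: float
    spearman: float
    r2: float
    subset: str = ""
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "rmse": self.rmse,
            "mse": self.mse,
            "mae": self.mae,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "r2": self.r2,
            "status": self.status,
        }


def evaluate_predictions(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    subset: str = "",
) -> MetricSet:
    """Compute the six-metric set; diverged predictions -> status 'failed'."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least 2 samples for correlation metrics")
    if not np.isfinite(y_pred).all():
        return MetricSet(
            *(float("nan"),) * 6, subset=subset, status="failed"
        )
    mse = mean_squared_error(y_true, y_pred)
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        pear = spear = float("nan")
        status = "degenerate"
    else:
        pear = float(sps.pearsonr(y_true, y_pred).statistic)
        spear = float(sps.spearmanr(y_true, y_pred).statistic)
        status = "ok"
    return MetricSet(
        rmse=math.sqrt(mse),
        mse=mse,
        mae=mean_absolute_error(y_true, y_pred),
        pearson=pear,
        spearman=spear,
        r2=r2_score(y_true, y_pred),
        subset=subset,
        status=status,
    )


def train(model, X, y):
    """Fit an estimator on a normalized train matrix (thin wrapper)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    return model.fit(X, y)


def evaluate(model, X, y, subset: str = "") -> MetricSet:
    """Predict and compute the six-metric set for a labeled matrix."""
    try:
        pred = model.predict(np.asarray(X, dtype=float))
    except Exception as e:  # diverged / unusable model
        logger.warning("prediction failed (%s); reporting failed metrics", e)
        return MetricSet(*(float("nan"),) * 6, subset=subset, status="failed")
    return evaluate_predictions(y, pred, subset=subset)


def _sample_net_config(grid: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in grid.items():
        if isinstance(spec, tuple):
            tag = spec[0]
            if tag == "randint":
                out[name] = int(rng.integers(spec[1], spec[2] + 1))
            elif tag == "quniform":
                lo, hi, q = spec[1], spec[2], spec[3]
                k = int(rng.integers(0, int(round((hi - lo) / q)) + 1))
                v = lo + k * q
                out[name] = round(v, 10)
            elif tag == "choice":
                out[name] = spec[1][int(rng.integers(len(spec[1])))]
            else:
                raise ValueError(f"unknown range tag {tag!r} for {name}")
        else:  # plain list = choice
            out[name] = spec[int(rng.integers(len(spec)))]
    return out


def hyperparameter_search(
    kind: str,
    X,
    y,
    grid: Optional[dict] = None,
    schema: Optional[FeatureSchema] = None,
    cv: int = 5,
    n_iter: int = 20,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Select the best configuration by cross-validated MSE on the train set.

    Classical kinds enumerate the grid exhaustively; the two nets sample
    ``n_iter`` configurations from their stated ranges. Returns the best
    config plus a full trial log (one row per configuration with its mean
    CV MSE). Deterministic for a fixed seed.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    grid = grid if grid is not None else PARAM_GRIDS[kind]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    if kind in ("deep_net", "forked_net"):
        rng = np.random.default_rng(seed)
        candidates = [_sample_net_config(grid, rng) for _ in range(n_iter)]
    else:
        keys = list(grid)
        candidates = [
            dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))
        ]

    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    rows = []
    best: tuple[float, int] | None = None
    for ci, params in enumerate(candidates):
        config = ModelConfig(kind=kind, hyperparameters=params, seed=seed)
        fold_mse = []
        for tr, va in folds.split(X):
            model = build_model(config, schema=schema)
            try:
                model.fit(X[tr], y[tr])
                pred = model.predict(X[va])
                if not np.isfinite(pred).all():
                    raise FloatingPointError("non-finite predictions")
                fold_mse.append(mean_squared_error(y[va], pred))
            except Exception as e:
                logger.info("trial %d failed on a fold: %s", ci, e)
                fold_mse.append(float("inf"))
        mean_mse = float(np.mean(fold_mse))
        rows.append({**params, "mean_cv_mse": mean_mse})
        if best is None or mean_mse < best[0]:
            best = (mean_mse, ci)
    log = pd.DataFrame(rows)
    best_params = candidates[best[1]]
    return ModelConfig(kind=kind, hyperparameters=best_params, seed=seed), log


class UptakePredictor:
    """End-to-end artifact bundle: featurize -> prune -> normalize -> predict.

    Built from a completed training run; persists as a directory with a
    YAML config, normalization stats CSV, kept-column list, and the
    serialized model, so any prediction is regenerable from artifacts.
    """

    def __init__(self, featurizer, kept_columns, stats, model, config):
        self.featurizer = featurizer
        self.kept_columns = list(kept_columns)
        self.stats = stats
        self.model = model
        self.config = config

    def predict_records(self, records):
        """Per-record predicted log10 uptake with provenance.

        Returns (DataFrame, failures): records failing featurization are
        reported individually and do not abort the batch.
        """
        fm, failures = self.featurizer.transform_with_failures(records)
        if fm.n_samples == 0:
            return (
                pd.DataFrame(
                    columns=["record_id", "predicted_log10_uptake",
                             "genomics_match", "n_substitutions"]
                ),
                failures,
            )
        df = fm.to_frame().set_index("row_id")
        X = self.stats.apply(df[self.kept_columns].to_numpy())
        preds = self.model.predict(X)
        names = fm.schema.column_names()
        match_col = fm.values[:, names.index("genomics_match")]
        anom = fm.schema.block_slices()["anomaly"]
        n_subs = fm.values[:, anom][:, :24].sum(axis=1)
        out = pd.DataFrame(
            {
                "record_id": fm.row_ids,
                "predicted_log10_uptake": preds,
                "genomics_match": match_col,
                "n_substitutions": n_subs,
            }
        )
        return out, failures

    def save(self, path) -> None:
        import joblib
        import yaml

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        cfg = {
            "kind": self.config.kind,
            "hyperparameters": self.config.hyperparameters,
            "seed": self.config.seed,
        }
        with open(path / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        pd.DataFrame(
            {
                "column": self.stats.columns,
                "mean": self.stats.mean,
                "sd": self.stats.sd,
                "zero_variance": self.stats.zero_variance,
            }
        ).to_csv(path / "normalization_stats.csv", index=False)
        (path / "kept_columns.txt").write_text(
            "\n".join(self.kept_columns) + "\n"
        )
        joblib.dump(
            {"featurizer": self.featurizer, "model": self.model,
             "stats": self.stats, "kept_columns": self.kept_columns,
             "config": self.config},
            path / "model.joblib",
        )

    @classmethod
    def load(cls, path) -> "UptakePredictor":
        import joblib

        blob = joblib.load(Path(path) / "model.joblib")
        return cls(
            featurizer=blob["featurizer"],
            kept_columns=blob["kept_columns"],
            stats=blob["stats"],
            model=blob["model"],
            config=blob["config"],
        )
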