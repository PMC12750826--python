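"""Gradient-boosted tree regression for logIE: training, tuning, metrics.

Both the fingerprint-based and the CNL-based models are leaf-wise-grown
gradient-boosted tree ensembles (LightGBM, whose native growth policy is
leaf-wise). Hyperparameters are tuned by randomized search over the
declared domains, scored by 5-fold cross-validated RMSE on the training
split only. Test-set accuracy is reported as Q² = 1 − SS_res/SS_tot with
the evaluated set's own mean as the centring constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.model_selection import KFold

__all__ = [
    "SearchSpace",
    "FP_SEARCH_SPACE",
    "CNL_SEARCH_SPACE",
    "DEFAULT_FP_PARAMS",
    "DEFAULT_CNL_PARAMS",
    "TrainedModel",
    "EvaluationReport",
    "randomized_search",
    "train",
    "predict",
    "evaluate",
    "feature_importance",
    "compare_fp_cnl",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# search spaces

Domain = tuple[str, float, float] | Sequence


@dataclass(frozen=True)
class SearchSpace:
    """Named hyperparameter domains: lists for discrete choices,
    ('uniform', lo, hi) for continuous ranges."""

    domains: Mapping[str, Domain]

    def __post_init__(self):
        for name, dom in self.domains.items():
            if not isinstance(dom, tuple) and len(list(dom)) == 0:
                raise ValueError(f"empty domain for {name!r}")

    def sample(self, rng: np.random.Generator) -> dict:
        params = {}
        for name, dom in self.domains.items():
            if isinstance(dom, tuple) and len(dom) == 3 and dom[0] == "uniform":
                params[name] = float(rng.uniform(dom[1], dom[2]))
            else:
                choices = list(dom)
                params[name] = choices[int(rng.integers(len(choices)))]
        return params


FP_SEARCH_SPACE = SearchSpace(
    {
        "n_trees": list(range(100, 1500, 100)),
        "min_samples_leaf": [4, 7, 10, 13, 25],
        "learning_rate": [0.05, 0.08, 0.1, 0.11, 0.15],
        "max_depth": [6, 7, 8, 9, 10],
        "subsample": ("uniform", 0.2, 0.9),
        "colsample": ("uniform", 0.4, 1.0),
        "random_state": [1, 2, 3, 4, 5],
    }
)

CNL_SEARCH_SPACE = SearchSpace(
    {
        "n_trees": [600, 800, 1000],
        "min_samples_leaf": [4, 7, 10, 13, 25],
        "learning_rate": [0.01, 0.03, 0.05, 0.07, 0.1],
        "max_depth": [6, 7, 8, 9, 10],
        "subsample": ("uniform", 0.05, 1.0),
        "colsample": ("uniform", 0.05, 1.0),
        "random_state": [1, 2, 3, 4, 5],
        # preprocessing hyperparameters, searched jointly with the model's
        "cnl_min": [0, 1, 2, 3, 4, 5],
        "s_min": [0.0, 0.1, 0.2, 0.25],
        "consensus_algorithm": ["replace", "filter"],
    }
)

# Shipped defaults are the mid-range of each search domain; they are this
# package's own defaults, not values tuned on any external dataset.
DEFAULT_FP_PARAMS = {
    "n_trees": 700,
    "min_samples_leaf": 10,
    "learning_rate": 0.1,
    "max_depth": 8,
    "subsample": 0.55,
    "colsample": 0.7,
    "random_state": 1,
}
DEFAULT_CNL_PARAMS = {
    "n_trees": 800,
    "min_samples_leaf": 10,
    "learning_rate": 0.05,
    "max_depth": 8,
    "subsample": 0.5,
    "colsample": 0.5,
    "random_state": 1,
    "cnl_min": 3,
    "s_min": 0.0,
    "consensus_algorithm": "filter",
}

_MODEL_KEYS = (
    "n_trees",
    "min_samples_leaf",
    "learning_rate",
    "max_depth",
    "subsample",
    "colsample",
    "random_state",
)


def _lgbm(params: Mapping) -> LGBMRegressor:
    depth = int(params.get("max_depth", 8))
    return LGBMRegressor(
        n_estimators=int(params.get("n_trees", 700)),
        min_child_samples=int(params.get("min_samples_leaf", 10)),
        learning_rate=float(params.get("learning_rate", 0.1)),
        max_depth=depth,
        num_leaves=min(2**depth, 255),
        subsample=float(params.get("subsample", 1.0)),
        subsample_freq=1,
        colsample_bytree=float(params.get("colsample", 1.0)),
        random_state=int(params.get("random_state", 1)),
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
        min_split_gain=0.0,
    )


# ---------------------------------------------------------------------------
# reports and the fitted-model bundle


@dataclass
class EvaluationReport:
    q2: float  # NaN when the evaluated targets have zero variance
    mae: float
    rmse: float
    residuals: np.ndarray
    n: int

    def as_dict(self) -> dict:
        return {
            "q2": None if np.isnan(self.q2) else float(self.q2),
            "mae": float(self.mae),
            "rmse": float(self.rmse),
            "n": self.n,
        }


@dataclass
class TrainedModel:
    booster: LGBMRegressor
    params: dict
    feature_names: list[str]
    train_metrics: EvaluationReport | None = None
    importance_method: str = "gain"
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def _raw_booster(model: "TrainedModel"):
    """The underlying lightgbm Booster (works for loaded models too)."""
    return model.booster._Booster


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)} targets")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite targets")
    return X, y


def train(X: pd.DataFrame, y, params: Mapping | None = None) -> TrainedModel:
    """Fit a leaf-wise gradient-boosted tree regressor."""
    params = dict(params or DEFAULT_FP_PARAMS)
    X, y = _check_xy(X, y)
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    booster = _lgbm(params)
    booster.fit(X.to_numpy(dtype=float), y)
    model = TrainedModel(
        booster=booster, params=params, feature_names=list(X.columns)
    )
    model.train_metrics = evaluate(y, predict(model, X))
    return model


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict logIE; raises on schema mismatch naming the columns."""
    missing = [c for c in model.feature_names if c not in X.columns]
    extra = [c for c in X.columns if c not in model.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature schema mismatch: missing={missing[:10]} extra={extra[:10]}"
        )
    out = _raw_booster(model).predict(
        X[model.feature_names].to_numpy(dtype=float)
    )
    return np.asarray(out, dtype=float)


def evaluate(y_true, y_pred) -> EvaluationReport:
    """Q² = 1 − SS_res/SS_tot (centred on y_true's mean), MAE, RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between targets and predictions")
    if len(y_true) < 2:
        raise ValueError("need at least 2 pairs to evaluate")
    residuals = y_true - y_pred
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum(residuals**2))
    q2 = float("nan") if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return EvaluationReport(
        q2=q2,
        mae=float(np.mean(np.abs(residuals))),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        residuals=residuals,
        n=len(y_true),
    )


def randomized_search(
    space: SearchSpace,
    X: pd.DataFrame,
    y,
    n_iter: int = 20,
    seed: int = 1,
    cv: int = 5,
) -> tuple[dict, list[dict]]:
    """Sample ``n_iter`` configurations; score by k-fold CV RMSE; argmin.

    Returns (best parameters, trace of {'params', 'cv_rmse'} dicts in
    sampling order). Ties keep the earliest sampled configuration.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X, y = _check_xy(X, y)
    rng = np.random.default_rng(seed)
    trace = []
    best, best_score = None, np.inf
    Xa = X.to_numpy(dtype=float)
    for _ in range(n_iter):
        params = space.sample(rng)
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        errs = []
        for tr, te in folds.split(Xa):
            booster = _lgbm(params)
            booster.fit(Xa[tr], y[tr])
            pred = booster.predict(Xa[te])
            errs.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
        score = float(np.mean(errs))
        trace.append({"params": params, "cv_rmse": score})
        if score < best_score:
            best, best_score = params, score
    return best, trace


def feature_importance(model: TrainedModel) -> pd.DataFrame:
    """Per-feature importance as percentages summing to 100, descending.

    Uses the backend's gain importance (total loss reduction from splits
    on each feature). If the model contains no splits at all, falls back
    to uniform zero importance with ``importance_method`` set to 'none'.
    """
    gains = np.asarray(
        _raw_booster(model).feature_importance(importance_type="gain"),
        dtype=float,
    )
    total = gains.sum()
    if total == 0:
        model.importance_method = "none"
        pct = np.zeros_like(gains)
    else:
        model.importance_method = "gain"
        pct = 100.0 * gains / total
    df = pd.DataFrame({"feature": model.feature_names, "percent": pct})
    return df.sort_values(
        ["percent", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def compare_fp_cnl(
    fp_preds, cnl_preds, abs_error_bound: float = 0.91
) -> dict:
    """Residual summary of CNL-model predictions against the FP model.

    The FP model acts as the structure-informed reference; residuals are
    cnl − fp. Error factors are 10^|residual|; the factor-3 and factor-10
    fractions use an inclusive (<=) boundary.
    """
    fp = np.asarray(fp_preds, dtype=float)
    cnl = np.asarray(cnl_preds, dtype=float)
    if len(fp) != len(cnl):
        raise ValueError("prediction vectors differ in length")
    residuals = cnl - fp
    factors = 10.0 ** np.abs(residuals)
    return {
        "residuals": residuals,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "frac_within_bound": float(
            np.mean(np.abs(residuals) <= abs_error_bound)
        ),
        "abs_error_bound": abs_error_bound,
        "frac_within_factor_3": float(np.mean(factors <= 3.0)),
        "frac_within_factor_10": float(np.mean(factors <= 10.0)),
    }


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Backend-native model text plus a JSON sidecar with the schema."""
    path = Path(path)
    _raw_booster(model).save_model(str(path))
    sidecar = {
        "params": model.params,
        "feature_names": model.feature_names,
        "importance_method": model.importance_method,
        "meta": model.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_model(path: str | Path) -> TrainedModel:
    import lightgbm

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    booster = LGBMRegressor(**{})
    booster._Booster = lightgbm.Booster(model_file=str(path))
    return TrainedModel(
        booster=booster,
        params=sidecar["params"],
        feature_names=sidecar["feature_names"],
        importance_method=sidecar.get("importance_method", "gain"),
        meta=sidecar.get("meta", {}),
    )
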