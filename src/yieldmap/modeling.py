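"""Regression model zoo, fitting and prediction with yield clipping and
uncertainty, and the descriptor x model grid search.

Seven families are supported; the three linear ones (ordinary least squares,
lasso, Bayesian ridge) expose a :class:`LinearFit` view whose coefficients are
the per-bit importances the attribution heat mapper consumes.  Predicted yields
are reported on the 0-100 percent scale with negatives clipped to 0; clipping
is applied to reported predictions only, never inside a training objective.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import BayesianRidge, Lasso, LinearRegression
from sklearn.neural_network import MLPRegressor

from .descriptors import DescriptorMatrix
from .exceptions import CapabilityError, ConfigurationError, SchemaError, ValidationError

__all__ = [
    "MODEL_FAMILIES",
    "LINEAR_FAMILIES",
    "ModelConfig",
    "LinearFit",
    "FitResult",
    "fit_model",
    "predict",
    "predict_with_uncertainty",
    "grid_search",
    "select_best_by_mae",
    "default_hyperparameters",
]

MODEL_FAMILIES = (
    "linear_least_squares",
    "lasso",
    "bayesian_ridge",
    "random_forest",
    "gaussian_process",
    "gradient_boosting",
    "mlp",
)
LINEAR_FAMILIES = ("linear_least_squares", "lasso", "bayesian_ridge")
UNCERTAINTY_FAMILIES = ("bayesian_ridge", "gaussian_process")

#: default seed for stochastic families, part of every ModelConfig
DEFAULT_SEED = 7


def default_hyperparameters() -> dict[str, dict[str, Any]]:
    """Frozen hyperparameter file shipped with the package."""
    text = resources.files("yieldmap.data").joinpath("model_defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ModelConfig:
    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(
                f"unknown model family {self.family!r}; known: {MODEL_FAMILIES}"
            )


@dataclass
class LinearFit:
    """Coefficients, intercept and posterior parameters of a linear model."""

    coefficients: np.ndarray
    intercept: float
    noise_variance: float
    coefficient_covariance: np.ndarray | None
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValidationError("coefficient vector length does not match feature names")
        if self.noise_variance < 0:
            raise ValidationError("noise variance must be non-negative")


@dataclass
class FitResult:
    config: ModelConfig
    model_state: Any
    feature_names: list[str]
    linear_view: LinearFit | None = None


def _build_estimator(config: ModelConfig):
    hp = dict(default_hyperparameters().get(config.family, {}))
    hp.update(config.hyperparameters)
    family = config.family
    if family == "linear_least_squares":
        return LinearRegression(**hp)
    if family == "lasso":
        return Lasso(**hp)
    if family == "bayesian_ridge":
        return BayesianRidge(**hp)
    if family == "random_forest":
        return RandomForestRegressor(random_state=config.seed, **hp)
    if family == "gradient_boosting":
        return GradientBoostingRegressor(random_state=config.seed, **hp)
    if family == "mlp":
        return MLPRegressor(random_state=config.seed, **hp)
    # gaussian_process: constant x Matern + white noise, >=5 restarts, normalized y
    kernel = ConstantKernel() * Matern(**hp.pop("matern", {})) + WhiteKernel()
    restarts = int(hp.pop("n_restarts_optimizer", 5))
    return GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=max(restarts, 5),
        normalize_y=True,
        random_state=config.seed,
        **hp,
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, DescriptorMatrix):
        return X.values, list(X.feature_names)
    arr = np.asarray(X, dtype=float)
    return arr, None


def fit_model(X, y: Sequence[float], config: ModelConfig) -> FitResult:
    """Fit one family on a feature matrix and 0-100 percent yields."""
    values, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != len(y):
        raise ValidationError("X and y have different numbers of rows")
    if np.any((y < 0) | (y > 100)):
        raise ValidationError("training yields must lie in [0, 100] percent")
    if names is None:
        names = [f"x{i}" for i in range(values.shape[1])]
    constant = np.flatnonzero(values.std(axis=0) == 0) if values.shape[0] > 1 else np.array([])
    if constant.size:
        warnings.warn(
            f"{constant.size} zero-variance feature columns retained "
            f"(first few: {[names[i] for i in constant[:5]]})",
            stacklevel=2,
        )
    est = _build_estimator(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence etc. are config concerns
        est.fit(values, y)

    linear_view = None
    if config.family in LINEAR_FAMILIES:
        resid = y - est.predict(values)
        if config.family == "bayesian_ridge":
            noise_var = 1.0 / est.alpha_
            cov = est.sigma_
        else:
            noise_var = float(np.mean(resid**2))
            cov = None
        linear_view = LinearFit(
            coefficients=np.asarray(est.coef_, dtype=float),
            intercept=float(est.intercept_),
            noise_variance=float(noise_var),
            coefficient_covariance=cov,
            feature_names=list(names),
        )
    return FitResult(config=config, model_state=est, feature_names=list(names), linear_view=linear_view)


def _check_columns(fit: FitResult, X) -> np.ndarray:
    values, names = _as_matrix(X)
    if names is not None and names != fit.feature_names:
        raise SchemaError("query feature columns do not match training feature names")
    if values.shape[1] != len(fit.feature_names):
        raise SchemaError(
            f"query has {values.shape[1]} columns, model expects {len(fit.feature_names)}"
        )
    return values


def predict(fit: FitResult, X) -> np.ndarray:
    """Predicted yields in percent; negative raw outputs are set to 0."""
    values = _check_columns(fit, X)
    raw = np.asarray(fit.model_state.predict(values), dtype=float)
    return np.maximum(raw, 0.0)


def predict_with_uncertainty(fit: FitResult, X) -> tuple[np.ndarray, np.ndarray]:
    """Clipped posterior-predictive mean plus pre-clipping standard deviation."""
    if fit.config.family not in UNCERTAINTY_FAMILIES:
        raise CapabilityError(
            f"family {fit.config.family!r} has no predictive distribution; "
            f"use one of {UNCERTAINTY_FAMILIES}"
        )
    values = _check_columns(fit, X)
    mean, std = fit.model_state.predict(values, return_std=True)
    return np.maximum(np.asarray(mean, dtype=float), 0.0), np.asarray(std, dtype=float)


def grid_search(
    dataset,
    descriptor_kinds: Sequence[str],
    model_configs: Sequence[ModelConfig],
    descriptor_options: Mapping[str, dict] | None = None,
    validation: str = "loo",
) -> pd.DataFrame:
    """LOO-validated table with one row per (descriptor, model) pair.

    Failing combinations are recorded with an ``error`` tag; the remaining grid
    completes.  Deterministic for fixed seeds.
    """
    from .descriptors import featurize_dataset  # local import to avoid cycle at module load
    from .evaluation import loo_evaluate

    if validation != "loo":
        raise ConfigurationError(f"unsupported validation scheme {validation!r}")
    y = dataset.yields
    if np.any(np.isnan(y)):
        raise ValidationError("grid search requires a fully labeled dataset")
    if len(y) < 2:
        raise ValidationError("grid search needs at least 2 records")
    rows = []
    for kind in descriptor_kinds:
        opts = dict((descriptor_options or {}).get(kind, {}))
        try:
            matrix = featurize_dataset(dataset, kind, opts)
        except Exception as exc:
            for config in model_configs:
                rows.append(
                    {"descriptor": kind, "model": config.family, "error": str(exc)}
                )
            continue
        for config in model_configs:
            try:
                _, report = loo_evaluate(matrix, y, config)
                rows.append(
                    {
                        "descriptor": kind,
                        "model": config.family,
                        "ae50": report.ae50,
                        "mae": report.mae,
                        "rmse": report.rmse,
                        "ae_max": report.ae_max,
                        "r2": report.r2,
                        "error": "",
                    }
                )
            except Exception as exc:
                rows.append({"descriptor": kind, "model": config.family, "error": str(exc)})
    return pd.DataFrame(rows)


def select_best_by_mae(table: pd.DataFrame, tie_tol: float = 1e-9) -> pd.DataFrame:
    """Per-model best descriptor by MAE; ties are listed, not silently broken."""
    ok = table[table.get("error", "") == ""].copy()
    out = []
    for model, group in ok.groupby("model", sort=False):
        best = group["mae"].min()
        tied = group[group["mae"] <= best + tie_tol]
        out.append(
            {
                "model": model,
                "best_descriptor": tied.iloc[0]["descriptor"],
                "mae": best,
                "tied_descriptors": ";".join(tied["descriptor"].tolist()),
                "n_tied": len(tied),
            }
        )
    return pd.DataFrame(out)


def save_fit(fit: FitResult, path) -> None:
    """Serialize a linear fit to a single-file JSON bundle (format version 1)."""
    if fit.linear_view is None:
        raise CapabilityError("only linear-family fits serialize to the JSON bundle")
    lv = fit.linear_view
    bundle = {
        "format_version": 1,
        "config": {
            "family": fit.config.family,
            "hyperparameters": dict(fit.config.hyperparameters),
            "seed": fit.config.seed,
        },
        "feature_names": fit.feature_names,
        "coefficients": lv.coefficients.tolist(),
        "intercept": lv.intercept,
        "noise_variance": lv.noise_variance,
        "coefficient_covariance": None
        if lv.coefficient_covariance is None
        else np.asarray(lv.coefficient_covariance).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_linear_fit(path) -> LinearFit:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format_version") != 1:
        raise ConfigurationError("unknown model-bundle format version")
    cov = bundle["coefficient_covariance"]
    return LinearFit(
        coefficients=np.array(bundle["coefficients"]),
        intercept=bundle["intercept"],
        noise_variance=bundle["noise_variance"],
        coefficient_covariance=None if cov is None else np.array(cov),
        feature_names=bundle["feature_names"],
    )
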