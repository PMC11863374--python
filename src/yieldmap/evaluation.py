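"""Metrics, data splitting, leave-one-out, k-fold CV, the leave-one-compound-out
(LOCO) protocol, and coefficient-shift analysis.

All error metrics are reported in yield percent and are computed on clipped
predictions (negative raw outputs set to 0), matching how predictions are
reported.  LOCO holds out every reaction involving one azole (or one amine),
measuring generalization to unseen reactants rather than unseen reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemdata import ReactionDataset
from .descriptors import DescriptorMatrix, featurize_dataset
from .exceptions import ConfigurationError, ProtocolError, SchemaError, ValidationError
from .modeling import FitResult, LinearFit, ModelConfig, fit_model, predict

__all__ = [
    "MetricReport",
    "SplitPlan",
    "LOCOResult",
    "compute_metrics",
    "split_train_test",
    "loo_evaluate",
    "kfold_cv",
    "loco_evaluate",
    "coefficient_shift",
]


@dataclass(frozen=True)
class MetricReport:
    """Median / mean / RMS / max absolute error (percent) plus R^2."""

    ae50: float
    mae: float
    rmse: float
    ae_max: float
    r2: float  # NaN when undefined (constant y_true)
    n: int

    @property
    def r2_defined(self) -> bool:
        return not np.isnan(self.r2)

    def as_dict(self) -> dict[str, float]:
        return {
            "ae50": self.ae50,
            "mae": self.mae,
            "rmse": self.rmse,
            "ae_max": self.ae_max,
            "r2": self.r2,
            "n": self.n,
        }


@dataclass(frozen=True)
class SplitPlan:
    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int
    strategy: str

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValidationError("train and test indices overlap")


@dataclass
class LOCOResult:
    held_out_compound_id: str
    role: str  # "azole" | "amine"
    record_indices: tuple[int, ...]
    predictions: np.ndarray
    metrics: MetricReport
    fit: FitResult | None = None


def compute_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> MetricReport:
    """AE50 = median |e|, MAE, RMSE, AEmax, and R^2 = 1 - SS_res/SS_tot.

    R^2 uses the sample mean of ``y_true`` in SS_tot; for constant ``y_true``
    it is undefined and reported as NaN while the error metrics are still
    returned.  The median of an even count is the midpoint of the two central
    values.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 1:
        raise ValidationError("y_true and y_pred must be equal-length 1-D arrays")
    err = np.abs(y_true - y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if len(y_true) >= 2 and ss_tot > 0:
        r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    else:
        r2 = float("nan")
    return MetricReport(
        ae50=float(np.median(err)),
        mae=float(np.mean(err)),
        rmse=float(np.sqrt(np.mean(err**2))),
        ae_max=float(np.max(err)),
        r2=r2,
        n=len(y_true),
    )


def split_train_test(
    dataset: ReactionDataset | int,
    test_size: int = 50,
    seed: int = 0,
    stratify_by_yield: bool = False,
) -> SplitPlan:
    """Seeded train/test split; optionally stratified over yield deciles.

    Stratification approximates a representative test set: records are binned
    into up to 10 yield quantile strata and sampled proportionally.
    """
    n = len(dataset) if not isinstance(dataset, int) else dataset
    if test_size >= n:
        raise ConfigurationError(f"test_size={test_size} must be smaller than n={n}")
    rng = np.random.default_rng(seed)
    if stratify_by_yield:
        if isinstance(dataset, int):
            raise ConfigurationError("stratified split needs a labeled dataset, not a size")
        y = dataset.yields
        if np.any(np.isnan(y)):
            raise ValidationError("stratified split requires labels on every record")
        n_bins = min(10, n)
        strata = pd.qcut(pd.Series(y), q=n_bins, labels=False, duplicates="drop").to_numpy()
        test: list[int] = []
        order = rng.permutation(n)
        # proportional allocation, largest strata first, remainder by shuffled order
        for s in np.unique(strata):
            members = [i for i in order if strata[i] == s]
            take = int(round(test_size * len(members) / n))
            test.extend(members[:take])
        pool = [i for i in order if i not in set(test)]
        while len(test) > test_size:
            test.pop()
        test.extend(pool[: test_size - len(test)])
        test_idx = tuple(sorted(test))
        strategy = "stratified_yield"
    else:
        perm = rng.permutation(n)
        test_idx = tuple(sorted(int(i) for i in perm[:test_size]))
        strategy = "random"
    train_idx = tuple(i for i in range(n) if i not in set(test_idx))
    return SplitPlan(train=train_idx, test=test_idx, seed=seed, strategy=strategy)


def loo_evaluate(
    X, y: Sequence[float], config: ModelConfig, min_success: float = 0.9
) -> tuple[np.ndarray, MetricReport]:
    """Leave-one-out: exactly n fits, prediction i from the model trained without i.

    Individual fit failures are tolerated up to ``1 - min_success`` of the
    records (failed indices predict NaN and are excluded from the metrics);
    beyond that the evaluation aborts.
    """
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValidationError("leave-one-out needs at least 2 records")
    preds = np.full(n, np.nan)
    failures: list[tuple[int, str]] = []
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        try:
            fit = fit_model(values[mask], y[mask], config)
            preds[i] = predict(fit, values[i : i + 1])[0]
        except Exception as exc:
            failures.append((i, str(exc)))
    if failures and len(failures) > (1 - min_success) * n:
        raise ProtocolError(f"{len(failures)}/{n} LOO fits failed; first: {failures[0]}")
    ok = ~np.isnan(preds)
    report = compute_metrics(y[ok], preds[ok])
    return preds, report


def kfold_cv(
    X, y: Sequence[float], config: ModelConfig, k: int = 5, seed: int = 0
) -> tuple[list[MetricReport], pd.DataFrame]:
    """Seeded k-fold CV; returns per-fold reports plus a mean/std summary table.

    Folds are shuffled contiguous blocks (a seeded permutation split into k
    nearly equal parts), disjoint and covering every record.
    """
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    reports: list[MetricReport] = []
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        fit = fit_model(values[mask], y[mask], config)
        reports.append(compute_metrics(y[fold], predict(fit, values[fold])))
    frame = pd.DataFrame([r.as_dict() for r in reports])
    frame.index = [f"fold_{i + 1}" for i in range(k)]
    summary = pd.concat(
        [frame, frame.agg(["mean", "std"]).rename(index={"mean": "mean_folds", "std": "std_folds"})]
    )
    return reports, summary


def loco_evaluate(
    dataset: ReactionDataset,
    descriptor_kind: str,
    config: ModelConfig,
    group_role: str,
    descriptor_options: dict | None = None,
    keep_fits: bool = False,
) -> list[LOCOResult]:
    """Leave-one-compound-out: hold out all reactions of one azole (or amine).

    One result per distinct compound in the chosen role; by construction no
    training record involves the held-out compound.  Sort results by ``r2`` to
    rank best/worst out-of-sample compounds.
    """
    if group_role not in ("azole", "amine"):
        raise ConfigurationError("group_role must be 'azole' or 'amine'")
    y = dataset.yields
    if np.any(np.isnan(y)):
        raise ValidationError("LOCO requires a fully labeled dataset")
    ids = [r.azole_id if group_role == "azole" else r.amine_id for r in dataset]
    distinct = list(dict.fromkeys(ids))
    if len(distinct) < 2:
        raise ProtocolError(f"need at least 2 distinct {group_role}s for LOCO")
    matrix = featurize_dataset(dataset, descriptor_kind, descriptor_options)
    values = matrix.values
    results: list[LOCOResult] = []
    for comp in distinct:
        held = np.array([i for i, cid in enumerate(ids) if cid == comp])
        train = np.array([i for i, cid in enumerate(ids) if cid != comp])
        if train.size == 0:
            raise ProtocolError(f"{group_role} {comp!r} appears in every record")
        fit = fit_model(values[train], y[train], config)
        preds = predict(fit, values[held])
        results.append(
            LOCOResult(
                held_out_compound_id=comp,
                role=group_role,
                record_indices=tuple(int(i) for i in held),
                predictions=preds,
                metrics=compute_metrics(y[held], preds),
                fit=fit if keep_fits else None,
            )
        )
    return results


def coefficient_shift(
    full_fit: LinearFit,
    loco_fit: LinearFit,
    on_bits: Sequence[int],
    provenance: dict[int, list[tuple[int, ...]]] | None = None,
) -> list[tuple[int, float, list[tuple[int, ...]]]]:
    """Per-bit coefficient differences (full - LOCO) on a molecule's on bits.

    Returns (bit, delta, provenance occurrences) sorted by |delta| descending —
    the bits whose learned importance changed most when the compound's
    reactions were excluded from training.
    """
    if full_fit.feature_names != loco_fit.feature_names:
        raise SchemaError("full and LOCO fits have different feature names")
    rows = []
    for bit in on_bits:
        delta = float(full_fit.coefficients[bit] - loco_fit.coefficients[bit])
        rows.append((int(bit), delta, (provenance or {}).get(int(bit), [])))
    rows.sort(key=lambda t: (-abs(t[1]), t[0]))
    return rows
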