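"""Postmenstrual-age regression from morphometric feature tables.

The default model is Bayesian ridge regression on z-scored features, after
keeping the k features most correlated (absolute Pearson) with age on the
training rows.  Alternative regressor families are pluggable behind the
same fit/predict surface.

Reported metrics: MAE, RMSE, squared Pearson correlation (``r2``) and the
coefficient of determination (``r2_cod``).  ``r2`` is the squared Pearson
correlation between truths and predictions — it is invariant to affine
miscalibration of the predictions, which is why ``r2_cod`` is reported
alongside.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import BayesianRidge, ElasticNet
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR as SVMRegressor

__all__ = [
    "FeatureTable",
    "FittedAgeModel",
    "EvalReport",
    "REGRESSOR_KINDS",
    "select_features",
    "fit_age_model",
    "predict_age",
    "evaluate",
]

REGRESSOR_KINDS = (
    "bayesian_ridge",
    "kernel_ridge",
    "elastic_net",
    "gradient_boosting",
    "svm",
    "mlp",
)

#: kinds whose fitted state is a plain linear map (JSON-serializable)
_LINEAR_KINDS = ("bayesian_ridge", "elastic_net")


@dataclass
class FeatureTable:
    """Subjects x features matrix with per-row PMA targets (weeks)."""

    subjects: list[tuple[str, str]]
    feature_names: list[str]
    values: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = [(str(a), str(b)) for a, b in self.subjects]
        self.feature_names = [str(n) for n in self.feature_names]
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.subjects), len(self.feature_names))
        self.ages = np.asarray(self.ages, dtype=float).ravel()
        n, p = self.values.shape
        if n != len(self.subjects) or n != len(self.ages):
            raise ValueError("rows, subjects and ages must align")
        if p != len(self.feature_names):
            raise ValueError("columns must align with feature_names")
        if np.isnan(self.values).any() or np.isnan(self.ages).any():
            raise ValueError("feature table contains missing values")

    @property
    def n_rows(self) -> int:
        return len(self.subjects)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"feature {name!r} not in table")
        return self.values[:, j]

    def select_rows(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            subjects=[self.subjects[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx],
            ages=self.ages[idx],
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureTable":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            subjects=list(self.subjects),
            feature_names=list(names),
            values=self.values[:, cols],
            ages=self.ages.copy(),
        )


def select_features(table: FeatureTable, k: int = 100) -> list[str]:
    """Top-k feature names by |Pearson r| with age on the given rows.

    Constant columns get correlation 0; ties keep table (scheme) order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.n_rows < 2:
        raise ValueError("need at least 2 rows to correlate")
    x = table.values
    z = table.ages
    xc = x - x.mean(axis=0)
    zc = z - z.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sz = np.sqrt((zc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * zc[:, None]).sum(axis=0) / (sx * sz)
    r = np.nan_to_num(r, nan=0.0)
    order = np.argsort(-np.abs(r), kind="stable")
    k = min(k, len(table.feature_names))
    return [table.feature_names[j] for j in order[:k]]


class _CenteredTarget:
    """Fit on mean-centered targets (for regressors with no intercept)."""

    def __init__(self, base):
        self.base = base
        self.offset_ = 0.0

    def fit(self, x, y):
        self.offset_ = float(np.mean(y))
        self.base.fit(x, np.asarray(y) - self.offset_)
        return self

    def predict(self, x):
        return self.base.predict(x) + self.offset_


def _make_regressor(kind: str, seed: int):
    if kind == "bayesian_ridge":
        return BayesianRidge()
    if kind == "kernel_ridge":
        return _CenteredTarget(KernelRidge())
    if kind == "elastic_net":
        return ElasticNet(random_state=seed)
    if kind == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed)
    if kind == "svm":
        return SVMRegressor()
    if kind == "mlp":
        return MLPRegressor(random_state=seed, max_iter=3000)
    raise ValueError(f"unknown regressor_kind {kind!r}; choose from {REGRESSOR_KINDS}")


@dataclass
class FittedAgeModel:
    """Selected features, training standardization and regressor state."""

    selected_features: list[str]
    means: np.ndarray
    sds: np.ndarray
    regressor_kind: str
    regressor: Any = None
    coef: np.ndarray | None = None
    intercept: float | None = None
    noise_precision: float | None = None  # alpha of the Gaussian likelihood
    prior_precision: float | None = None  # lambda of the coefficient prior
    training_meta: dict = field(default_factory=dict)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.means) / self.sds

    def predict(self, x: np.ndarray) -> np.ndarray:
        xs = self._standardize(np.atleast_2d(np.asarray(x, dtype=float)))
        if self.regressor is not None:
            return np.asarray(self.regressor.predict(xs), dtype=float)
        if self.coef is None:
            raise ValueError("model has neither a regressor nor linear coefficients")
        return xs @ self.coef + self.intercept

    def to_json(self, path: str | os.PathLike) -> None:
        """Serialize to JSON. Only linear kinds have portable state."""
        if self.regressor_kind not in _LINEAR_KINDS:
            raise ValueError(
                f"JSON serialization supports {_LINEAR_KINDS}; "
                f"got {self.regressor_kind!r}"
            )
        payload = {
            "selected_features": self.selected_features,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "regressor_kind": self.regressor_kind,
            "coef": np.asarray(self.coef).tolist(),
            "intercept": float(self.intercept),
            "noise_precision": self.noise_precision,
            "prior_precision": self.prior_precision,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FittedAgeModel":
        p = json.loads(Path(path).read_text())
        return cls(
            selected_features=list(p["selected_features"]),
            means=np.asarray(p["means"], dtype=float),
            sds=np.asarray(p["sds"], dtype=float),
            regressor_kind=p["regressor_kind"],
            regressor=None,
            coef=np.asarray(p["coef"], dtype=float),
            intercept=float(p["intercept"]),
            noise_precision=p.get("noise_precision"),
            prior_precision=p.get("prior_precision"),
            training_meta=dict(p.get("training_meta", {})),
        )


def fit_age_model(
    table: FeatureTable,
    selected: Sequence[str],
    regressor_kind: str = "bayesian_ridge",
    seed: int = 0,
) -> FittedAgeModel:
    """Standardize the selected columns on training rows and fit.

    Columns are z-scored with training mean/sd (sd 0 -> divisor 1).  For
    ``bayesian_ridge`` the posterior coefficient means and the fitted
    noise/prior precisions are retained, making the model serializable.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected feature list is empty")
    if table.n_rows < 3:
        raise ValueError("need at least 3 training rows")
    if np.ptp(table.ages) == 0:
        raise ValueError("ages are constant; nothing to regress")

    sub = table.select_columns(selected)
    means = sub.values.mean(axis=0)
    sds = sub.values.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)
    xs = (sub.values - means) / sds

    reg = _make_regressor(regressor_kind, seed)
    reg.fit(xs, sub.ages)

    model = FittedAgeModel(
        selected_features=selected,
        means=means,
        sds=sds,
        regressor_kind=regressor_kind,
        regressor=reg,
        training_meta={"seed": int(seed), "n_train": table.n_rows, "k_select": len(selected)},
    )
    if regressor_kind == "bayesian_ridge":
        model.coef = np.asarray(reg.coef_, dtype=float)
        model.intercept = float(reg.intercept_)
        model.noise_precision = float(reg.alpha_)
        model.prior_precision = float(reg.lambda_)
    elif regressor_kind == "elastic_net":
        model.coef = np.asarray(reg.coef_, dtype=float)
        model.intercept = float(reg.intercept_)
    return model


def predict_age(model: FittedAgeModel, features) -> np.ndarray:
    """Predict PMA (weeks) for a FeatureTable, mapping, or row array.

    Columns are aligned by name; a missing selected feature is an error.
    Outputs are not clipped.
    """
    if isinstance(features, FeatureTable):
        missing = [n for n in model.selected_features if n not in features.feature_names]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        x = features.select_columns(model.selected_features).values
    elif isinstance(features, Mapping):
        try:
            x = np.array([[float(features[n]) for n in model.selected_features]])
        except KeyError as e:
            raise KeyError(f"missing feature column: {e.args[0]!r}")
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(model.selected_features):
            raise ValueError(
                f"expected {len(model.selected_features)} columns, got {x.shape[1]}"
            )
    return model.predict(x)


@dataclass
class EvalReport:
    """Headline regression metrics, all age quantities in weeks."""

    mae: float
    r2: float
    r2_cod: float
    rmse: float
    per_interval_mae: dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "r2": self.r2,
            "r2_cod": self.r2_cod,
            "rmse": self.rmse,
            "per_interval_mae": self.per_interval_mae,
            "n": self.n,
        }


def evaluate(
    truths: Sequence[float],
    preds: Sequence[float],
    intervals: Sequence[tuple[float, float]] | None = None,
) -> EvalReport:
    """MAE, RMSE, squared-Pearson r2 and coefficient of determination.

    ``intervals`` default to 2-week bins spanning the truth range.
    """
    z = np.asarray(truths, dtype=float).ravel()
    zh = np.asarray(preds, dtype=float).ravel()
    if z.shape != zh.shape:
        raise ValueError("truths and preds must have equal length")
    if z.size < 2:
        raise ValueError("need at least 2 samples")

    err = zh - z
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))

    if np.ptp(z) == 0 or np.ptp(zh) == 0:
        r2 = 1.0 if np.allclose(z, zh) else 0.0
    else:
        r2 = float(stats.pearsonr(z, zh).statistic ** 2)

    sst = float(((z - z.mean()) ** 2).sum())
    r2_cod = 1.0 - float((err**2).sum()) / sst if sst > 0 else float("nan")

    if intervals is None:
        lo = 2.0 * np.floor(z.min() / 2.0)
        hi = 2.0 * np.ceil(z.max() / 2.0)
        edges = np.arange(lo, max(hi, lo + 2.0) + 1e-9, 2.0)
        intervals = list(zip(edges[:-1], edges[1:]))
    per_interval: dict[str, float] = {}
    for a, b in intervals:
        mask = (z >= a) & (z < b) if b < z.max() else (z >= a) & (z <= b)
        if mask.any():
            per_interval[f"[{a:g}, {b:g})"] = float(np.mean(np.abs(err[mask])))

    return EvalReport(
        mae=mae, r2=r2, r2_cod=r2_cod, rmse=rmse,
        per_interval_mae=per_interval, n=int(z.size),
    )
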