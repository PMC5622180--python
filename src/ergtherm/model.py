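"""Multivariable linear temperature regression with forward selection.

The temperature of the retina is modelled as a linear function of the
relative (37 °C-normalized) feature values,

    c = X beta + eps,

where c is the vector of measured temperatures (°C), X the design
matrix of relative features with an intercept column, beta the
coefficients and eps the residuals. Candidate models are built by
greedy forward selection: at each step the feature that minimizes the
leave-one-out cross-validated RMS temperature error of the augmented
set is added, and the model size is chosen by the Bayesian information
criterion

    BIC = n * ln(SSE / n) + k * ln(n),

with n observations, SSE the training sum of squared errors and k the
number of estimated coefficients (intercept included).

The module exposes both the low-level operations (``ols_fit``,
``loo_cv_rmse``, ``bic``, ``forward_select``) and a statsmodels-style
pair: :class:`TemperatureRegression` built from a relative feature
table, whose ``fit``/``fit_forward`` return a
:class:`TemperatureRegressionResults` with parameters, diagnostics and
a ``summary()`` table. Three published reference models (full, OS-only,
dim-flash-only) are available via :func:`published_model`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import FittingError, ParameterError, PredictionError

__all__ = [
    "RegressionModel",
    "SelectionStep",
    "SelectionPath",
    "ols_fit",
    "predict",
    "published_model",
    "PUBLISHED_MODELS",
    "loo_cv_rmse",
    "bic",
    "forward_select",
    "TemperatureRegression",
    "TemperatureRegressionResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionModel:
    """Ordered feature names, their coefficients and the intercept (°C)."""

    feature_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    provenance: str = "trained"

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ParameterError("one coefficient per named feature required")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )

    def predict(self, obs) -> float | np.ndarray:
        """Temperature estimate: intercept + sum(beta_i * x_i)."""
        if isinstance(obs, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in obs.columns]
            if missing:
                raise PredictionError(f"missing model features: {missing}")
            X = obs[list(self.feature_names)].to_numpy(dtype=float)
            return X @ np.array(self.coefficients) + self.intercept
        if isinstance(obs, (Mapping, pd.Series)):
            missing = [
                f for f in self.feature_names if f not in obs or _is_nan(obs[f])
            ]
            if missing:
                raise PredictionError(f"missing model features: {missing}")
            return self.intercept + sum(
                c * float(obs[f]) for f, c in zip(self.feature_names, self.coefficients)
            )
        raise ParameterError("obs must be a mapping, Series or DataFrame")

    def to_json(self, path) -> None:
        payload = {
            "features": list(self.feature_names),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feature_names=tuple(payload["features"]),
            coefficients=tuple(payload["coefficients"]),
            intercept=float(payload["intercept"]),
            provenance=str(payload.get("provenance", "trained")),
        )


def _is_nan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def predict(model: RegressionModel, obs) -> float | np.ndarray:
    """Functional alias for :meth:`RegressionModel.predict`."""
    return model.predict(obs)


#: The three reference models (coefficients as published).
PUBLISHED_MODELS: dict[str, RegressionModel] = {
    "full": RegressionModel(
        feature_names=("b70T", "LRS", "a10", "ba", "b20T"),
        coefficients=(-28.14, -2.794, -6.069, -1.836, 9.230),
        intercept=66.63,
        provenance="published:full",
    ),
    "os": RegressionModel(
        feature_names=("a20", "LRS", "aip", "a30"),
        coefficients=(-17.81, -10.61, 12.02, -18.17),
        intercept=71.59,
        provenance="published:os",
    ),
    "dim": RegressionModel(
        feature_names=("b70T", "LRS", "b20T", "ba", "b20L"),
        coefficients=(-31.75, -3.593, 11.86, -2.104, -3.134),
        intercept=65.75,
        provenance="published:dim",
    ),
}


def published_model(name: str) -> RegressionModel:
    """Reference model by name: 'full', 'os' (outer segment) or 'dim'."""
    try:
        return PUBLISHED_MODELS[name]
    except KeyError:
        raise ParameterError(
            f"unknown published model {name!r}; choose from "
            f"{sorted(PUBLISHED_MODELS)}"
        ) from None


# ---------------------------------------------------------------------------
# Fitting


def _design(table: pd.DataFrame, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing_cols = [f for f in features if f not in table.columns]
    if missing_cols:
        raise FittingError(f"feature columns not in table: {missing_cols}")
    sub = table[list(features) + ["temperature_C"]].astype(float)
    ok = sub.notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("excluding %d observations with missing feature values", dropped)
    sub = sub[ok]
    X = np.column_stack([np.ones(len(sub))] + [sub[f].to_numpy() for f in features])
    return X, sub["temperature_C"].to_numpy()


def _check_rank(X: np.ndarray, features: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        names = ["intercept"] + list(features)
        collinear = sorted(names[p] for p in piv[rank:])
        raise FittingError(f"rank-deficient design; collinear columns: {collinear}")


def ols_fit(table: pd.DataFrame, features: Sequence[str]) -> RegressionModel:
    """Ordinary least squares fit of temperature on the given features."""
    features = list(features)
    X, c = _design(table, features)
    if len(c) <= len(features) + 1:
        raise FittingError(
            f"need more than {len(features) + 1} complete observations, have {len(c)}"
        )
    _check_rank(X, features)
    beta, *_ = np.linalg.lstsq(X, c, rcond=None)
    return RegressionModel(
        feature_names=tuple(features),
        coefficients=tuple(beta[1:]),
        intercept=float(beta[0]),
    )


def bic(sse: float, n_obs: int, k_params: int) -> float:
    """Bayesian information criterion, n·ln(SSE/n) + k·ln(n)."""
    if n_obs < 1:
        raise ParameterError("n_obs must be >= 1")
    if sse <= 0:
        raise ParameterError("sse must be positive (perfect fits have no finite BIC)")
    return n_obs * math.log(sse / n_obs) + k_params * math.log(n_obs)


def loo_cv_rmse(
    table: pd.DataFrame, features: Sequence[str], unit: str = "retina"
) -> float:
    """Leave-one-out cross-validated RMS temperature error (°C).

    ``unit='retina'`` holds out whole retinas (no within-retina
    leakage); ``unit='observation'`` holds out single rows.
    """
    features = list(features)
    if unit not in ("retina", "observation"):
        raise ParameterError(f"unit must be 'retina' or 'observation', got {unit!r}")
    sub = table[["retina_id"] + features + ["temperature_C"]].copy()
    sub = sub[sub[features + ["temperature_C"]].notna().all(axis=1)]
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[f].to_numpy(dtype=float) for f in features]
    )
    c = sub["temperature_C"].to_numpy(dtype=float)
    if unit == "observation":
        folds = [np.array([i]) for i in range(len(sub))]
    else:
        ids = sub["retina_id"].to_numpy()
        folds = [np.nonzero(ids == rid)[0] for rid in pd.unique(ids)]
    if len(folds) < 3:
        raise FittingError(f"need >= 3 cross-validation folds, have {len(folds)}")
    errors = []
    for hold in folds:
        mask = np.ones(len(c), dtype=bool)
        mask[hold] = False
        Xtr, ctr = X[mask], c[mask]
        if Xtr.shape[0] <= Xtr.shape[1]:
            raise FittingError("cross-validation fold leaves too few observations")
        _check_rank(Xtr, features)
        beta, *_ = np.linalg.lstsq(Xtr, ctr, rcond=None)
        errors.append(X[hold] @ beta - c[hold])
    errors = np.concatenate(errors)
    return float(np.sqrt(np.mean(errors**2)))


@dataclass(frozen=True)
class SelectionStep:
    feature_added: str
    cv_rms_C: float
    sse: float
    n_obs: int
    k_params: int
    bic: float


@dataclass
class SelectionPath:
    """Per-step record of greedy forward selection."""

    steps: list[SelectionStep]
    selected_step: int

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(s.feature_added for s in self.steps[: self.selected_step + 1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def forward_select(
    table: pd.DataFrame,
    candidate_features: Sequence[str],
    max_steps: int = 12,
    cv_unit: str = "retina",
) -> SelectionPath:
    """Greedy forward selection by LOO-CV error, model size by min BIC.

    At each step the candidate minimizing the cross-validated RMS error
    of the augmented feature set is added (ties broken toward the
    lexicographically first name); the selected step is the global BIC
    minimum over the path (first minimum on ties).
    """
    candidates = sorted(set(candidate_features))
    if len(candidates) < 2:
        raise ParameterError("need at least 2 candidate features")
    chosen: list[str] = []
    steps: list[SelectionStep] = []
    for _ in range(min(max_steps, len(candidates))):
        best: tuple[float, str] | None = None
        for feat in candidates:
            if feat in chosen:
                continue
            try:
                cv = loo_cv_rmse(table, chosen + [feat], unit=cv_unit)
            except FittingError as exc:
                logger.warning("skipping candidate %s: %s", feat, exc)
                continue
            if best is None or cv < best[0]:
                best = (cv, feat)
        if best is None:
            break
        cv, feat = best
        chosen.append(feat)
        model = ols_fit(table, chosen)
        X, c = _design(table, chosen)
        resid = c - X @ np.concatenate([[model.intercept], model.coefficients])
        sse = float(resid @ resid)
        k = len(chosen) + 1
        steps.append(
            SelectionStep(
                feature_added=feat,
                cv_rms_C=cv,
                sse=sse,
                n_obs=len(c),
                k_params=k,
                bic=bic(sse, len(c), k),
            )
        )
    if not steps:
        raise FittingError("forward selection produced no usable model")
    selected = int(np.argmin([s.bic for s in steps]))
    return SelectionPath(steps=steps, selected_step=selected)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class TemperatureRegression:
    """Linear temperature model built from a relative feature table.

    Parameters
    ----------
    table : DataFrame
        Normalized feature table with ``retina_id`` and
        ``temperature_C`` columns plus feature columns.
    features : sequence of str, optional
        For :meth:`fit`, the fixed feature set; for
        :meth:`fit_forward`, the candidate pool (defaults to every
        feature column present).
    cv_unit : {'retina', 'observation'}
        Held-out unit for cross-validation.
    max_steps : int
        Maximum length of the forward-selection path.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: Sequence[str] | None = None,
        cv_unit: str = "retina",
        max_steps: int = 12,
    ) -> None:
        from .features import FEATURE_NAMES

        self.table = table
        if features is None:
            features = [f for f in FEATURE_NAMES if f in table.columns]
        self.features = list(features)
        self.cv_unit = cv_unit
        self.max_steps = max_steps

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "TemperatureRegression":
        return cls(table, **kwargs)

    def fit(self) -> "TemperatureRegressionResults":
        """OLS fit on the fixed feature set."""
        model = ols_fit(self.table, self.features)
        cv = loo_cv_rmse(self.table, self.features, unit=self.cv_unit)
        return TemperatureRegressionResults(self, model, cv_rms_C=cv)

    def fit_forward(self) -> "TemperatureRegressionResults":
        """Forward selection over the candidate pool, min-BIC model."""
        path = forward_select(
            self.table, self.features, max_steps=self.max_steps, cv_unit=self.cv_unit
        )
        chosen = list(path.selected_features)
        model = ols_fit(self.table, chosen)
        return TemperatureRegressionResults(
            self,
            model,
            cv_rms_C=path.steps[path.selected_step].cv_rms_C,
            selection_path=path,
        )


class TemperatureRegressionResults:
    """Fitted coefficients, residual diagnostics and the selection path."""

    def __init__(
        self,
        spec: TemperatureRegression,
        model: RegressionModel,
        cv_rms_C: float,
        selection_path: SelectionPath | None = None,
    ) -> None:
        self.model_spec = spec
        self.model = model
        self.cv_rms_C = cv_rms_C
        self.selection_path = selection_path
        X, c = _design(spec.table, list(model.feature_names))
        beta = np.concatenate([[model.intercept], model.coefficients])
        resid = c - X @ beta
        self.nobs = len(c)
        self.resid = resid
        self.sse = float(resid @ resid)
        self.rms_resid_C = float(np.sqrt(np.mean(resid**2)))
        k = len(model.feature_names) + 1
        self.bic = bic(self.sse, self.nobs, k) if self.sse > 0 else -math.inf
        # classical OLS standard errors
        dof = self.nobs - k
        if dof > 0:
            sigma2 = self.sse / dof
            cov = sigma2 * np.linalg.inv(X.T @ X)
            self.bse = pd.Series(
                np.sqrt(np.diag(cov)), index=["intercept"] + list(model.feature_names)
            )
        else:
            self.bse = pd.Series(
                np.nan, index=["intercept"] + list(model.feature_names)
            )

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.model.intercept], self.model.coefficients]),
            index=["intercept"] + list(self.model.feature_names),
        )

    def predict(self, obs) -> float | np.ndarray:
        return self.model.predict(obs)

    def evaluate(self, table: pd.DataFrame) -> dict[str, float]:
        """RMS and mean absolute error on a held-out feature table."""
        pred = np.asarray(self.model.predict(table), dtype=float)
        truth = table["temperature_C"].to_numpy(dtype=float)
        ok = np.isfinite(pred) & np.isfinite(truth)
        err = pred[ok] - truth[ok]
        return {
            "n": int(ok.sum()),
            "rms_C": float(np.sqrt(np.mean(err**2))),
            "mae_C": float(np.mean(np.abs(err))),
        }

    def summary(self) -> str:
        lines = [
            "Temperature regression results",
            "==============================",
            f"observations: {self.nobs}    features: {len(self.model.feature_names)}",
            f"residual RMS: {self.rms_resid_C:.3f} °C    "
            f"LOO-CV RMS ({self.model_spec.cv_unit}): {self.cv_rms_C:.3f} °C",
            f"SSE: {self.sse:.4f}    BIC: {self.bic:.2f}",
            "",
            f"{'term':>10} {'coef':>10} {'std err':>10}",
        ]
        for name, coef in self.params.items():
            lines.append(f"{name:>10} {coef:>10.4f} {self.bse[name]:>10.4f}")
        if self.selection_path is not None:
            lines += ["", "forward-selection path (min-BIC step marked *):"]
            for i, s in enumerate(self.selection_path.steps):
                mark = "*" if i == self.selection_path.selected_step else " "
                lines.append(
                    f" {mark} step {i + 1:2d}: +{s.feature_added:<5} "
                    f"cv_rms={s.cv_rms_C:.3f} °C  BIC={s.bic:.1f}"
                )
        return "\n".join(lines)
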