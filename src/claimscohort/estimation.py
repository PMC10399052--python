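"""Propensity scores, IPTW weights, bias-corrected mean responses, ATE.

The estimand is the average treatment effect (ATE) of belonging to the
untreated-insomnia cohort versus the non-insomnia cohort, on the 100
patient-year scale. Cohort assignment is modelled with an unpenalized
logistic regression on the baseline covariate profile (standardized age, sex
and the condition flags); inverse-probability weights are ``1/p`` for
exposed units and ``1/(1-p)`` for controls, which reweight both cohorts to
the combined-population covariate distribution.

Weighted (bias-corrected) cohort means:

* rate / annualized occurrence:  ``mu_c = sum(w y) / sum(w t)``
* prevalence:                    ``mu_c = sum(w y) / sum(w)``

followed by the scale conventions of :mod:`claimscohort.endpoints` (x100;
prevalence additionally x 365.25/reference_days). The ATE is the plain
difference ``mu_untreated - mu_control``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohorts import UNTREATED_INSOMNIA
from .endpoints import DAYS_PER_YEAR, UnitResponse
from .exceptions import EstimationError

#: Propensity scores are clipped into [EPS, 1-EPS]; guarantees finite
#: weights under positivity violations without touching interior scores.
SCORE_EPS = 1e-6

# effectively unpenalized: tiny ridge only stabilizes separable or singular
# resamples inside the bootstrap
_RIDGE_C = 1e8


@dataclass
class PropensityModel:
    """Fitted cohort-membership model and per-unit scores in (0, 1)."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    scores: np.ndarray
    dropped: list[str]

    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef, index=self.feature_names)


def _design_matrix(
    X: pd.DataFrame, continuous: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Standardize continuous columns, 0/1-encode the rest, drop constants."""
    cols, names, dropped = [], [], []
    for name in X.columns:
        col = np.asarray(X[name], dtype=float)
        if np.all(col == col[0]):
            dropped.append(name)
            continue
        if name in continuous:
            col = (col - col.mean()) / col.std()
        cols.append(col)
        names.append(name)
    if not cols:
        raise EstimationError("design matrix has no non-constant columns")
    return np.column_stack(cols), names, dropped


def fit_logistic_scores(
    design: np.ndarray, exposed: np.ndarray, eps: float = SCORE_EPS
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit P(exposed | design) by logistic regression; return clipped scores,
    coefficients and intercept. Low-level path shared with the bootstrap."""
    if exposed.all() or (~exposed).all():
        raise EstimationError("both cohorts must be present to fit propensity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(
            C=_RIDGE_C, solver="newton-cholesky", max_iter=100, tol=1e-8
        )
        model.fit(design, exposed.astype(int))
    scores = model.predict_proba(design)[:, 1]
    return np.clip(scores, eps, 1.0 - eps), model.coef_[0], float(model.intercept_[0])


def fit_propensity(
    X: pd.DataFrame,
    labels: Sequence[str] | np.ndarray,
    continuous: Sequence[str] = ("age",),
    eps: float = SCORE_EPS,
) -> PropensityModel:
    """Fit the propensity model on a covariate frame.

    ``labels`` are cohort names (or a boolean exposure vector). Continuous
    columns are standardized; constant columns are dropped; scores are
    clipped to ``[eps, 1-eps]``. Deterministic given the data.
    """
    exposed = _as_exposed(labels)
    design, names, dropped = _design_matrix(X, continuous)
    scores, coef, intercept = fit_logistic_scores(design, exposed, eps)
    return PropensityModel(
        feature_names=names,
        coef=coef,
        intercept=intercept,
        scores=scores,
        dropped=dropped,
    )


def _as_exposed(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    return labels == UNTREATED_INSOMNIA


def iptw_weights(
    scores: np.ndarray,
    labels,
    trim_percentiles: tuple[float, float] | None = None,
) -> np.ndarray:
    """ATE weights: ``1/p`` for exposed units, ``1/(1-p)`` for controls.

    Optional symmetric trimming caps weights at the given percentiles of the
    weight distribution (off by default).
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores <= 0) or np.any(scores >= 1):
        raise EstimationError("propensity scores must lie strictly in (0, 1)")
    exposed = _as_exposed(labels)
    w = np.where(exposed, 1.0 / scores, 1.0 / (1.0 - scores))
    if trim_percentiles is not None:
        lo, hi = np.percentile(w, trim_percentiles)
        w = np.clip(w, lo, hi)
    return w


@dataclass(frozen=True)
class WeightedEstimate:
    """IPTW bias-corrected cohort mean on the 100 patient-year scale."""

    cohort: str
    endpoint: str
    mu_hat: float
    raw_ratio: float
    n_units: int
    total_weighted_exposure: float


def mu_hat_exposure(
    responses: Sequence[UnitResponse],
    weights: np.ndarray,
    cohort: str = "",
    endpoint: str = "",
) -> WeightedEstimate:
    """``sum(w y) / sum(w t)`` on the 100 patient-year scale (rate and
    annualized-occurrence endpoints)."""
    y, t, w = _aligned_arrays(responses, weights)
    denom = float(np.sum(w * t))
    if denom <= 0:
        raise EstimationError("zero weighted exposure")
    ratio = float(np.sum(w * y)) / denom
    return WeightedEstimate(
        cohort=cohort,
        endpoint=endpoint,
        mu_hat=ratio * 100.0,
        raw_ratio=ratio,
        n_units=len(responses),
        total_weighted_exposure=denom,
    )


def mu_hat_prevalence(
    responses: Sequence[UnitResponse],
    weights: np.ndarray,
    reference_days: float | None = None,
    cohort: str = "",
    endpoint: str = "",
) -> WeightedEstimate:
    """``sum(w y) / sum(w)``, then the one-year normalization and the 100
    patient-year scale (prevalence endpoints).

    With ``reference_days=None`` the raw weighted proportion is scaled by
    100 only (no annual normalization).
    """
    y, _, w = _aligned_arrays(responses, weights)
    denom = float(np.sum(w))
    if denom <= 0:
        raise EstimationError("zero total weight")
    ratio = float(np.sum(w * y)) / denom
    scale = 100.0 if reference_days is None else (DAYS_PER_YEAR / reference_days) * 100.0
    return WeightedEstimate(
        cohort=cohort,
        endpoint=endpoint,
        mu_hat=ratio * scale,
        raw_ratio=ratio,
        n_units=len(responses),
        total_weighted_exposure=denom,
    )


def _aligned_arrays(responses: Sequence[UnitResponse], weights):
    if len(responses) == 0:
        raise EstimationError("empty response set")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(responses),):
        raise EstimationError(
            f"weights length {w.shape} does not match {len(responses)} responses"
        )
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise EstimationError("weights must be positive and finite")
    y = np.array([r.y for r in responses], dtype=float)
    t = np.array([r.t for r in responses], dtype=float)
    return y, t, w


def ate(mu_u: WeightedEstimate, mu_v: WeightedEstimate) -> float:
    """Average treatment effect ``mu_u - mu_v`` (untreated insomnia minus
    non-insomnia, per 100 patient-years)."""
    if mu_u.endpoint != mu_v.endpoint:
        raise EstimationError(
            f"endpoint mismatch: {mu_u.endpoint!r} vs {mu_v.endpoint!r}"
        )
    return mu_u.mu_hat - mu_v.mu_hat
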