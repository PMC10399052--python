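"""Bootstrap inference: resampling, balance diagnostics, tests, FDR control.

Patient-treatments are the resampling unit. Within every bootstrap resample
the propensity model is refit, so the weights are re-estimated rather than
frozen — weight-estimation uncertainty propagates into both the balance
diagnostics and the ATE distribution.

Balance: a covariate is *balanced* when the 95th percentile of its
bootstrapped absolute weighted standardized differences falls below a
threshold (default 0.15); a sample is balanced when every covariate is.

Testing: two-sided bootstrap test with percentile CIs. The p-value uses the
add-one tail count ``p = 2 * min(#{b <= 0} + 1, #{b >= 0} + 1) / (n_boot + 1)``
capped at 1, so the smallest attainable p is ``2 / (n_boot + 1)`` — with the
default 512 resamples p-values are discrete with floor ~0.0039. The
Benjamini-Hochberg step-up correction is applied across the full endpoint x
subgroup grid of a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimation import fit_logistic_scores, iptw_weights, _as_exposed
from .endpoints import PREVALENCE
from .exceptions import ConfigError, EstimationError


@dataclass(frozen=True)
class BootstrapSpec:
    """How to resample: number of draws and seed; unit = patient-treatment."""

    n_boot: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ConfigError(f"n_boot must be >= 2, got {self.n_boot}")


def bootstrap_indices(n_units: int, spec: BootstrapSpec) -> np.ndarray:
    """``(n_boot, n_units)`` index array of draws with replacement;
    reproducible under the spec's seed."""
    if n_units < 2:
        raise EstimationError("need at least 2 units to bootstrap")
    rng = np.random.default_rng(spec.seed)
    return rng.integers(0, n_units, size=(spec.n_boot, n_units))


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean and (population) variance along axis 0.

    ``x`` may be 1-D or (n, p); returns per-column moments.
    """
    sw = w.sum()
    mean = (w[:, None] * x).sum(axis=0) / sw if x.ndim == 2 else (w * x).sum() / sw
    centered = x - mean
    var = (
        (w[:, None] * centered**2).sum(axis=0) / sw
        if x.ndim == 2
        else (w * centered**2).sum() / sw
    )
    return mean, var


def _sd_columns(x: np.ndarray, w: np.ndarray, exposed: np.ndarray) -> np.ndarray:
    """Absolute weighted standardized difference per column of ``x``."""
    m1, v1 = _weighted_moments(x[exposed], w[exposed])
    m2, v2 = _weighted_moments(x[~exposed], w[~exposed])
    pooled = np.sqrt((v1 + v2) / 2.0)
    diff = np.abs(np.atleast_1d(m1 - m2))
    pooled = np.atleast_1d(pooled)
    out = np.full(diff.shape, np.inf)
    np.divide(diff, pooled, out=out, where=pooled > 0)
    out[(pooled == 0) & (diff == 0)] = 0.0
    return out


def standardized_difference(values, weights, labels) -> float:
    """``|m1 - m2| / sqrt((s1^2 + s2^2)/2)`` with weighted means and
    variances per cohort; binary flags enter as 0/1 numerics.

    Zero pooled variance with unequal means reports ``inf`` (maximal
    imbalance); with equal means, 0.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    exposed = _as_exposed(labels)
    if exposed.all() or (~exposed).all():
        raise EstimationError("both cohorts must be present")
    return float(_sd_columns(x[:, None], w, exposed)[0])


@dataclass
class BalanceReport:
    """Per-covariate balance diagnostics and the overall verdict."""

    covariates: list[str]
    point_sd: np.ndarray
    p95_sd: np.ndarray
    threshold: float
    n_boot: int

    @property
    def balanced_flags(self) -> np.ndarray:
        return self.p95_sd < self.threshold

    @property
    def balanced(self) -> bool:
        return bool(self.balanced_flags.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "standardized_difference": self.point_sd,
                "p95_bootstrap_sd": self.p95_sd,
                "balanced": self.balanced_flags,
            }
        )


WeightFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def refit_iptw_weights(design: np.ndarray, exposed: np.ndarray) -> np.ndarray:
    """Default per-resample weight rule: refit the propensity model on the
    resampled design and return fresh IPTW weights."""
    scores, _, _ = fit_logistic_scores(design, exposed)
    return iptw_weights(scores, exposed)


def balance_check(
    X: pd.DataFrame,
    weights: np.ndarray | None,
    labels,
    spec: BootstrapSpec,
    threshold: float = 0.15,
    weight_fn: WeightFn | None = None,
) -> BalanceReport:
    """Bootstrap balance diagnostics over the covariate frame.

    For every resample the weighted standardized difference of each covariate
    is recomputed; with ``weight_fn`` supplied (e.g.
    :func:`refit_iptw_weights`) the weights themselves are re-estimated per
    resample, otherwise the given ``weights`` are subset. A covariate is
    balanced iff the 95th percentile of its bootstrapped values is below the
    threshold.
    """
    x = np.asarray(X, dtype=float)
    exposed = _as_exposed(labels)
    if weights is None and weight_fn is None:
        weights = np.ones(len(x))
    w = None if weights is None else np.asarray(weights, dtype=float)
    point_w = w if w is not None else weight_fn(x, exposed)
    point = _sd_columns(x, point_w, exposed)

    idx = bootstrap_indices(len(x), spec)
    boots = np.full((spec.n_boot, x.shape[1]), np.nan)
    for b, rows in enumerate(idx):
        eb = exposed[rows]
        if eb.all() or (~eb).all():
            continue  # degenerate resample: one cohort absent
        xb = x[rows]
        wb = weight_fn(xb, eb) if weight_fn is not None else w[rows]
        boots[b] = _sd_columns(xb, wb, eb)
    p95 = np.nanpercentile(boots, 95, axis=0)
    return BalanceReport(
        covariates=list(X.columns),
        point_sd=point,
        p95_sd=p95,
        threshold=threshold,
        n_boot=spec.n_boot,
    )


def bootstrap_test(
    ate_point: float, ate_boot_values: Sequence[float]
) -> tuple[float, float, float]:
    """Two-sided bootstrap p-value and 95% percentile CI.

    ``p = 2 * min(#{b <= 0} + 1, #{b >= 0} + 1) / (n + 1)``, capped at 1.
    """
    boots = np.asarray(ate_boot_values, dtype=float)
    boots = boots[np.isfinite(boots)]
    if boots.size < 2:
        raise EstimationError("need at least 2 bootstrap values")
    n = boots.size
    n_le = int(np.sum(boots <= 0))
    n_ge = int(np.sum(boots >= 0))
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n + 1))
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return p, float(ci_low), float(ci_high)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Pooled bootstrap engine for the analyze stage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AteResult:
    """One endpoint x subgroup row of the results table."""

    endpoint: str
    subgroup: str
    mu_untreated: float
    mu_control: float
    ate: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    n_boot: int
    balanced: bool


def _weighted_mu(
    y: np.ndarray, t: np.ndarray, w: np.ndarray, metric: str, scale: float
) -> float:
    if metric == PREVALENCE:
        return (w @ y) / w.sum() * scale
    denom = w @ t
    if denom <= 0:
        return np.nan
    return (w @ y) / denom * 100.0


def bootstrap_cohort_analysis(
    design: np.ndarray,
    exposed: np.ndarray,
    Y: np.ndarray,
    T: np.ndarray,
    metrics: Sequence[str],
    prevalence_scales: Sequence[float],
    spec: BootstrapSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """One pass of the per-subgroup bootstrap.

    For each resample: refit the propensity model, rebuild IPTW weights,
    and recompute (a) the ATE of every endpoint (columns of ``Y``/``T``)
    and (b) the weighted standardized difference of every design column.

    Returns ``(ate_boot (n_boot, E), sd_boot (n_boot, p))`` with NaN rows
    for degenerate resamples (a cohort absent).
    """
    n = len(design)
    idx = bootstrap_indices(n, spec)
    n_endpoints = Y.shape[1]
    ate_boot = np.full((spec.n_boot, n_endpoints), np.nan)
    sd_boot = np.full((spec.n_boot, design.shape[1]), np.nan)
    for b, rows in enumerate(idx):
        eb = exposed[rows]
        if eb.all() or (~eb).all():
            continue
        xb = design[rows]
        try:
            wb = refit_iptw_weights(xb, eb)
        except EstimationError:
            continue
        sd_boot[b] = _sd_columns(xb, wb, eb)
        yb, tb = Y[rows], T[rows]
        for e in range(n_endpoints):
            mu_u = _weighted_mu(
                yb[eb, e], tb[eb, e], wb[eb], metrics[e], prevalence_scales[e]
            )
            mu_v = _weighted_mu(
                yb[~eb, e], tb[~eb, e], wb[~eb], metrics[e], prevalence_scales[e]
            )
            ate_boot[b, e] = mu_u - mu_v
    return ate_boot, sd_boot
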