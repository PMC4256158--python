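"""Gompertz-Makeham mortality model: hazard, survival, NLS fitting, and
derived lifespan summaries.

The hazard is M(x) = M0 e^{Gx} + Minf.  Its survival function, the exponential
of minus the cumulative hazard, is

    S(x) = exp[(M0/G)(1 - e^{Gx}) - Minf x]        (G > 0)
    S(x) = exp[-(M0 + Minf) x]                     (G = 0 limit)

M0 is the initial mortality rate (IMR, "frailty"), the intercept of the
log-mortality trajectory; G is the demographic rate of aging (RoA), its slope.
Fitting minimises the unweighted sum of squared differences between S(x) and
the Kaplan-Meier survival estimate at each observed day, using a bounded
trust-region-reflective least-squares solver initialised from an ordinary
linear regression of log force-of-mortality on age (with two additional
jittered restarts, keeping the lowest residual sum of squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq, least_squares

from .synthetic import GMParams

__all__ = [
    "GMFit",
    "ReplicateFits",
    "NonIdentifiableError",
    "gm_hazard",
    "gm_survival",
    "fit_gm",
    "derived_lifespans",
    "summarize_replicates",
]

# fit box constraints (per-day rates): generous envelopes for daily worm mortality
_BOUNDS_LO = np.array([1e-8, 0.0, 0.0])
_BOUNDS_HI = np.array([1.0, 2.0, 1.0])
_FTOL = 1e-10
# deterministic multiplicative jitters for the restart initialisations
_RESTART_JITTER = [(1.0, 1.0), (0.3, 1.3), (3.0, 0.7)]


class NonIdentifiableError(ValueError):
    """Raised when the survival curve carries no information about mortality."""


@dataclass(frozen=True)
class GMFit:
    """A fitted Gompertz-Makeham model with diagnostics."""

    params: GMParams
    rss: float
    n_points: int
    converged: bool

    @property
    def imr(self) -> float:
        """Initial mortality rate (alias of M0, per day)."""
        return self.params.m0

    @property
    def roa(self) -> float:
        """Demographic rate of aging (alias of G, per day)."""
        return self.params.g


@dataclass(frozen=True)
class ReplicateFits:
    """Per-replicate fits with across-replicate summary of IMR and RoA."""

    fits: tuple
    imr_mean: float
    imr_sd: float | None
    roa_mean: float
    roa_sd: float | None


def gm_hazard(params: GMParams, x) -> np.ndarray:
    """Age-specific mortality M(x) = M0 e^{Gx} + Minf (x in days, x >= 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be >= 0")
    return params.m0 * np.exp(params.g * x) + params.minf


def gm_survival(params: GMParams, x) -> np.ndarray:
    """Survival proportion S(x) = exp(-integral of the hazard from 0 to x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be >= 0")
    if params.g == 0.0:
        return np.exp(-(params.m0 + params.minf) * x)
    return np.exp(-(params.m0 / params.g) * np.expm1(params.g * x) - params.minf * x)


def _as_curve(survival_curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(survival_curve, pd.DataFrame):
        days = survival_curve["day"].to_numpy(dtype=float)
        surv = survival_curve["km"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(survival_curve), dtype=float)
        days, surv = arr[:, 0], arr[:, 1]
    order = np.argsort(days)
    return days[order], surv[order]


def _initial_guess(days: np.ndarray, surv: np.ndarray) -> np.ndarray:
    """Start values from the Gompertz log-linearity of the force of mortality.

    Interval death probabilities are reconstructed from successive survival
    ratios; days with q in (0, 1) contribute a point (x, ln m_x) to an
    ordinary least-squares line whose intercept/slope start (ln M0, G).
    """
    prev = np.concatenate([[1.0], surv[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(prev > 0, 1.0 - surv / prev, np.nan)
    ok = np.isfinite(q) & (q > 0) & (q < 1)
    if ok.sum() >= 2:
        m = -np.log1p(-q[ok])
        slope, intercept = np.polyfit(days[ok], np.log(m), 1)
        m0 = float(np.exp(intercept))
        g = float(slope)
    elif ok.sum() == 1:
        m0, g = float(-math.log1p(-q[ok][0])), 0.05
    else:  # only all-or-nothing intervals; crude scale from the last day
        m0, g = 1.0 / max(days.max(), 1.0), 0.05
    m0 = float(np.clip(m0, _BOUNDS_LO[0] * 10, _BOUNDS_HI[0] / 10))
    g = float(np.clip(g, 1e-4, _BOUNDS_HI[1] / 2))
    return np.array([m0, g, 0.0])


def fit_gm(survival_curve) -> GMFit:
    """Fit (M0, G, Minf) to a survival curve by bounded nonlinear least squares.

    ``survival_curve`` is a sequence of (day, survival) pairs or a DataFrame
    with columns ``day`` and ``km`` — normally the Kaplan-Meier estimate, which
    already accounts for censoring.  Points after the day survival first
    reaches 0 are dropped (the model never reaches exactly zero, and a run of
    exact zeros would overweight the tail).  Requires at least 4 distinct days
    and at least one survival value below 0.9; a flat curve at 1.0 raises
    :class:`NonIdentifiableError`.  Non-convergence is reported via the
    ``converged`` flag, not an exception.
    """
    days, surv = _as_curve(survival_curve)
    zero = np.nonzero(surv <= 0.0)[0]
    if len(zero) > 0:
        end = zero[0] + 1  # keep the first zero, drop the rest
        days, surv = days[:end], surv[:end]
    if len(np.unique(days)) < 4:
        raise ValueError("need >= 4 distinct days to fit a 3-parameter model")
    if surv.min() >= 0.9:
        raise NonIdentifiableError("survival never falls below 0.9; mortality not identifiable")

    def residuals(theta: np.ndarray) -> np.ndarray:
        m0, g, minf = theta
        if g == 0.0:
            model = np.exp(-(m0 + minf) * days)
        else:
            model = np.exp(-(m0 / g) * np.expm1(g * days) - minf * days)
        return model - surv

    x0 = _initial_guess(days, surv)
    best = None
    for jm, jg in _RESTART_JITTER:
        start = np.clip(
            np.array([x0[0] * jm, x0[1] * jg, x0[2]]), _BOUNDS_LO, _BOUNDS_HI
        )
        res = least_squares(
            residuals,
            start,
            bounds=(_BOUNDS_LO, _BOUNDS_HI),
            method="trf",
            ftol=_FTOL,
            xtol=1e-12,
            gtol=1e-12,
            max_nfev=2000,
        )
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    rss, res = best
    params = GMParams(m0=float(res.x[0]), g=float(res.x[1]), minf=float(res.x[2]))
    return GMFit(params=params, rss=rss, n_points=len(days), converged=bool(res.status > 0))


def _survival_quantile(params: GMParams, level: float) -> float:
    """Solve S(x) = level by monotone bracketed root-finding."""
    upper = 1.0
    while float(gm_survival(params, upper)) > level:
        upper *= 2.0
        if upper > 1e9:
            raise ArithmeticError("survival quantile out of range")
    return float(brentq(lambda x: float(gm_survival(params, x)) - level, 0.0, upper, xtol=1e-12))


def derived_lifespans(fit: GMFit) -> tuple[float, float, float]:
    """(median, mean, max1pct) lifespans in days from a converged fit.

    Median solves S(x) = 0.5 and "maximum lifespan" is defined as the age at
    1% estimated survival, S(x) = 0.01, both by root-finding on the strictly
    decreasing survival function.  Mean is the integral of S over [0, inf),
    evaluated by adaptive quadrature up to the 1e-12 survival quantile (the
    remaining tail is below 1e-12 of a day per day and is dropped).
    """
    if not fit.converged:
        raise ValueError("derived lifespans require a converged fit")
    p = fit.params
    median = _survival_quantile(p, 0.5)
    max1pct = _survival_quantile(p, 0.01)
    if p.g == 0.0:
        mean = 1.0 / (p.m0 + p.minf)
    else:
        upper = _survival_quantile(p, 1e-12)
        mean, _ = quad(lambda x: float(gm_survival(p, x)), 0.0, upper, limit=200)
    return median, float(mean), max1pct


def summarize_replicates(fits) -> ReplicateFits:
    """Across-replicate mean and sample standard deviation of IMR and RoA."""
    fits = tuple(fits)
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    if not all(f.converged for f in fits):
        raise ValueError("all replicate fits must have converged")
    imr = np.array([f.imr for f in fits])
    roa = np.array([f.roa for f in fits])
    sd = (lambda v: float(np.std(v, ddof=1))) if len(fits) >= 2 else (lambda v: None)
    return ReplicateFits(
        fits=fits,
        imr_mean=float(imr.mean()),
        imr_sd=sd(imr),
        roa_mean=float(roa.mean()),
        roa_sd=sd(roa),
    )
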