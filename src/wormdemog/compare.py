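"""Treatment-versus-control statistics and demographic-effect classification.

Survival curves are compared with a two-group log-rank test on the shared
daily grid; families of gene comparisons are adjusted with the Holm
(sequentially rejective Bonferroni step-down) procedure.  Scalar phenotypes
(reproductive lifespan, brood size, developmental time, per-replicate fitted
parameters) are compared with Student's two-sample t-test.  Fitted mortality
parameters across replicate experiments feed a four-group classification of
how a gene inactivation reshapes the mortality trajectory:

    Group 1 — RoA down, IMR unchanged, lifespan up
    Group 2 — IMR down, RoA unchanged, lifespan up
    Group 3 — IMR down, RoA up, lifespan unchanged
    Group 4 — no effect on IMR, RoA or lifespan

Any other pattern is reported as "unclassified" rather than forced into a
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gompertz import ReplicateFits
from .lifetables import mean_lifespan

__all__ = [
    "ComparisonResult",
    "DemographicCall",
    "logrank_test",
    "holm_adjust",
    "two_sample_t",
    "classify_demographic_group",
    "percent_change_params",
    "mean_lifespan_comparison",
    "logrank_oe_contributions",
]


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    percent_change: float
    test_name: str

    def adjusted(self, p_adjusted: float) -> "ComparisonResult":
        return ComparisonResult(
            self.statistic, self.p_raw, float(p_adjusted), self.percent_change, self.test_name
        )


@dataclass(frozen=True)
class DemographicCall:
    imr_effect: str  # down | none | up
    roa_effect: str
    lifespan_effect: str
    group: int | str  # 1..4 or "unclassified"


def _risk_table(events: pd.DataFrame, last: int) -> tuple[np.ndarray, np.ndarray]:
    """(at-risk, deaths) per day 1..last for one stratum."""
    days = events["event_day"].to_numpy()
    is_death = (events["status"] == "death").to_numpy()
    d = np.bincount(days[is_death], minlength=last + 1)[1:]
    removed = np.bincount(days, minlength=last + 1)[1:]
    n = len(events) - np.concatenate([[0], np.cumsum(removed)[:-1]])
    return n, d


def logrank_test(events_a: pd.DataFrame, events_b: pd.DataFrame) -> ComparisonResult:
    """Two-group log-rank chi-square (1 df) on the shared day grid.

    Censored individuals stay in the risk sets up to their censoring day.  The
    reported percent_change is the relative change in restricted mean lifespan
    of group a versus group b.  Identical curves with zero variance yield
    statistic 0 and p = 1.
    """
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both strata must be non-empty")
    last = int(max(events_a["event_day"].max(), events_b["event_day"].max()))
    n1, d1 = _risk_table(events_a, last)
    n2, d2 = _risk_table(events_b, last)
    n = n1 + n2
    d = d1 + d2
    if d.sum() == 0:
        raise ValueError("log-rank test undefined with zero deaths")
    ok = n > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        expected1 = np.where(ok, d * n1 / n, 0.0)
        var = np.where(
            (n > 1), d * (n1 / n) * (n2 / n) * (n - d) / np.maximum(n - 1.0, 1.0), 0.0
        )
    observed_minus_expected = float((d1 - expected1)[ok].sum())
    v = float(var[ok].sum())
    if v == 0.0:
        statistic, p = 0.0, 1.0
    else:
        statistic = observed_minus_expected**2 / v
        p = float(stats.chi2.sf(statistic, df=1))
    rm_a = mean_lifespan(events_a)
    rm_b = mean_lifespan(events_b)
    pct = 100.0 * (rm_a - rm_b) / rm_b
    return ComparisonResult(float(statistic), p, p, pct, "logrank")


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down (Bonferroni step-down) adjusted p-values.

    The i-th smallest p-value is multiplied by (m - i + 1); a running maximum
    enforces monotone non-decreasing adjusted values, capped at 1, returned in
    the original order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def two_sample_t(values_a, values_b) -> ComparisonResult:
    """Two-sided Student t-test; percent_change = (mean_a - mean_b)/mean_b x 100."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        stat, p = 0.0, 1.0  # degenerate: no variance, no difference
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()
    return ComparisonResult(float(stat), float(p), float(p), float(pct), "t_test")


def mean_lifespan_comparison(
    events: pd.DataFrame, treatment_group: str, control_group: str
) -> ComparisonResult:
    """t-test on per-replicate restricted mean lifespans (treatment vs control).

    The demographic group definitions speak about the *mean* lifespan, and the
    log-rank test answers a different question (equality of the whole survival
    distribution): a gene that reshapes the mortality trajectory while leaving
    the mean unchanged is rejected by log-rank at large n.  This comparison
    tests the mean itself, on the same per-replicate basis as the IMR and RoA
    effects.
    """
    t_means = [
        mean_lifespan(events, treatment_group, r)
        for r in sorted(events.loc[events["group"] == treatment_group, "replicate"].unique())
    ]
    c_means = [
        mean_lifespan(events, control_group, r)
        for r in sorted(events.loc[events["group"] == control_group, "replicate"].unique())
    ]
    return two_sample_t(t_means, c_means)


def _effect(treated: np.ndarray, control: np.ndarray, alpha: float) -> str:
    """down/none/up call: significance at alpha AND a consistent mean sign."""
    res = two_sample_t(treated, control)
    if res.p_raw >= alpha or treated.mean() == control.mean():
        return "none"
    return "down" if treated.mean() < control.mean() else "up"


_GROUP_TABLE = {
    ("none", "down", "up"): 1,
    ("down", "none", "up"): 2,
    ("down", "up", "none"): 3,
    ("none", "none", "none"): 4,
}


def classify_demographic_group(
    treatment: ReplicateFits,
    control: ReplicateFits,
    lifespan_comparison: ComparisonResult,
    alpha: float = 0.05,
) -> DemographicCall:
    """Assign a gene inactivation to demographic Groups 1-4.

    IMR and RoA effects come from two-sample t-tests on the per-replicate
    fitted parameters at level ``alpha`` with direction from the means; the
    lifespan effect comes from the supplied combined-experiment comparison
    (log-rank on pooled replicates), significant if its adjusted p-value is
    below ``alpha`` with direction from its percent change.
    """
    if len(treatment.fits) < 2 or len(control.fits) < 2:
        raise ValueError("need >= 2 replicates per arm")
    t_imr = np.array([f.imr for f in treatment.fits])
    c_imr = np.array([f.imr for f in control.fits])
    t_roa = np.array([f.roa for f in treatment.fits])
    c_roa = np.array([f.roa for f in control.fits])
    imr_effect = _effect(t_imr, c_imr, alpha)
    roa_effect = _effect(t_roa, c_roa, alpha)
    if lifespan_comparison.p_adjusted >= alpha or lifespan_comparison.percent_change == 0:
        lifespan_effect = "none"
    else:
        lifespan_effect = "up" if lifespan_comparison.percent_change > 0 else "down"
    group = _GROUP_TABLE.get((imr_effect, roa_effect, lifespan_effect), "unclassified")
    return DemographicCall(imr_effect, roa_effect, lifespan_effect, group)


def percent_change_params(
    treatment: ReplicateFits, control: ReplicateFits
) -> tuple[float, float]:
    """Percent reduction of IMR and RoA: 100 (mean_ctrl - mean_trt)/mean_ctrl.

    Positive values are reductions; an increase under treatment comes out
    negative.
    """
    if control.imr_mean == 0 or control.roa_mean == 0:
        raise ValueError("control means must be nonzero")
    imr_pct = 100.0 * (control.imr_mean - treatment.imr_mean) / control.imr_mean
    roa_pct = 100.0 * (control.roa_mean - treatment.roa_mean) / control.roa_mean
    return imr_pct, roa_pct


def logrank_oe_contributions(events_a: pd.DataFrame, events_b: pd.DataFrame) -> pd.DataFrame:
    """Per-day observed-minus-expected death contributions for both groups.

    Diagnostic companion to :func:`logrank_test`; the two columns sum to zero
    at every day (and hence overall) by construction of the expected counts.
    """
    last = int(max(events_a["event_day"].max(), events_b["event_day"].max()))
    n1, d1 = _risk_table(events_a, last)
    n2, d2 = _risk_table(events_b, last)
    n, d = n1 + n2, d1 + d2
    with np.errstate(invalid="ignore"):
        e1 = np.where(n > 0, d * n1 / n, 0.0)
        e2 = np.where(n > 0, d * n2 / n, 0.0)
    return pd.DataFrame(
        {"day": np.arange(1, last + 1), "oe_a": d1 - e1, "oe_b": d2 - e2}
    )
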