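"""Discrete-day lifetables and nonparametric survival estimates.

Adult lifespan is indexed from day 1 (first day of adulthood); interval ``x``
covers ``(x-1, x]``.  For each day the lifetable records N_x (number entering
the interval), d_x (deaths), c_x (censored), the interval death probability
q_x = d_x / N_x, the force of mortality m_x = -ln(1 - q_x), and the
Kaplan-Meier product-limit survival.  Censored individuals count in N_x for
their final day and leave the risk set afterwards; there is no actuarial
half-interval correction.  Days with q_x = 1 give m_x = +inf and are flagged
so regressions on log-mortality can exclude them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["EmptyCohortError", "make_lifetable", "km_survival", "mean_lifespan", "select_stratum"]

LIFETABLE_COLUMNS = ["day", "Nx", "dx", "cx", "qx", "mx", "km"]


class EmptyCohortError(ValueError):
    """Raised when a requested (group, replicate) stratum holds no records."""


def select_stratum(
    events: pd.DataFrame, group: str | None = None, replicate: str | None = None
) -> pd.DataFrame:
    """Subset an event table to one group and (optionally) one replicate."""
    sub = events
    if group is not None:
        sub = sub[sub["group"] == group]
    if replicate is not None:
        sub = sub[sub["replicate"] == replicate]
    if len(sub) == 0:
        raise EmptyCohortError(f"no records for group={group!r}, replicate={replicate!r}")
    return sub


def make_lifetable(
    events: pd.DataFrame, group: str | None = None, replicate: str | None = None
) -> pd.DataFrame:
    """Tally N_x, d_x, c_x per day and derive q_x, m_x and KM survival.

    The table runs from day 1 to the last day with anyone at risk and
    terminates as soon as N_x reaches 0.
    """
    sub = select_stratum(events, group, replicate)
    days = sub["event_day"].to_numpy()
    if np.any(days < 1):
        raise ValueError("event_day must be >= 1")
    last = int(days.max())
    is_death = (sub["status"] == "death").to_numpy()
    dx = np.bincount(days[is_death], minlength=last + 1)[1:]
    cx = np.bincount(days[~is_death], minlength=last + 1)[1:]
    n0 = len(sub)
    removed = np.concatenate([[0], np.cumsum(dx + cx)[:-1]])
    nx = n0 - removed
    keep = nx > 0
    nx, dx, cx = nx[keep], dx[keep], cx[keep]
    with np.errstate(divide="ignore"):
        qx = dx / nx
        mx = -np.log1p(-qx)  # +inf where qx == 1
    km = np.cumprod(1.0 - qx)
    return pd.DataFrame(
        {
            "day": np.arange(1, len(nx) + 1),
            "Nx": nx.astype(int),
            "dx": dx.astype(int),
            "cx": cx.astype(int),
            "qx": qx,
            "mx": mx,
            "km": km,
        }
    )


def km_survival(
    events: pd.DataFrame, group: str | None = None, replicate: str | None = None
) -> pd.DataFrame:
    """Kaplan-Meier survival S(x) = prod_{x' <= x} (1 - d_{x'} / N_{x'}).

    Returns columns (day, km); km at day x is the estimated probability of
    surviving beyond day x (KM(0) = 1 is implicit and not emitted).
    """
    return make_lifetable(events, group, replicate)[["day", "km"]]


def mean_lifespan(
    events: pd.DataFrame, group: str | None = None, replicate: str | None = None
) -> float:
    """Restricted mean lifespan: area under the KM step curve.

    Integrates the product-limit estimate from day 0 to the last observed day,
    the standard censoring-consistent mean.  Without censoring this equals the
    arithmetic mean of the death days.
    """
    lt = make_lifetable(events, group, replicate)
    km = lt["km"].to_numpy()
    # KM(0)=1 over (0,1], then KM(x) over (x, x+1] up to the last observed day
    return float(1.0 + km[:-1].sum())
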