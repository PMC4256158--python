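"""Synthetic survival cohorts and reproductive schedules.

Generates per-worm event tables (death/censoring on a daily scoring grid) and
daily progeny schedules with the statistical structure a C. elegans lifespan /
reproductive-lifespan assay produces: Gompertz-Makeham distributed lifetimes,
once-a-day scoring (so death days are ceilings of continuous death times),
independent per-day geometric censoring (worms lost at transfer), and Poisson
daily progeny counts up to an individual cessation day.

A single integer seed expands deterministically, via ``numpy.random
.SeedSequence.spawn``, into independent substreams for lifetimes, censoring and
progeny so each stage is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GMParams",
    "CohortSpec",
    "ReproSpec",
    "gm_cumulative_hazard",
    "sample_gm_lifetimes",
    "discretize_and_censor",
    "simulate_cohort",
    "simulate_repro_schedules",
]

#: tolerance (days) for the bracketed root-finding used to invert the
#: Gompertz-Makeham cumulative hazard
_INVERSION_XTOL = 1e-10


@dataclass(frozen=True)
class GMParams:
    """Gompertz-Makeham hazard parameters, all rates per day of adulthood.

    The hazard is ``M(x) = m0 * exp(g * x) + minf``: ``m0`` is the initial
    (age-zero) mortality rate, ``g`` the exponential rate of aging, and
    ``minf`` the age-independent (Makeham) mortality rate.
    """

    m0: float
    g: float
    minf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m0", "g", "minf"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"GMParams.{name} must be finite, got {v!r}")
        if self.m0 <= 0:
            raise ValueError(f"GMParams.m0 must be > 0, got {self.m0}")
        if self.g < 0:
            raise ValueError(f"GMParams.g must be >= 0, got {self.g}")
        if self.minf < 0:
            raise ValueError(f"GMParams.minf must be >= 0, got {self.minf}")


@dataclass(frozen=True)
class CohortSpec:
    """One simulated lifespan assay: replicated cohorts scored daily."""

    n_individuals: int
    n_replicates: int
    params: GMParams
    censor_prob_per_day: float = 0.0
    max_day: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.censor_prob_per_day < 1.0:
            raise ValueError("censor_prob_per_day must be in [0, 1)")
        if self.max_day < 1:
            raise ValueError("max_day must be >= 1")


@dataclass(frozen=True)
class ReproSpec:
    """One simulated reproductive-span assay.

    ``daily_counts[d-1]`` is the expected progeny laid on adult day ``d``
    while the individual is still reproducing.  ``cessation`` names the
    distribution of the last reproductive day: ``("fixed", day)``,
    ``("uniform", low, high)`` (inclusive integers) or ``("normal", mean, sd)``
    (rounded, clipped to >= 1).
    """

    daily_counts: Sequence[float]
    cessation: tuple = ("fixed", 7)
    n_individuals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.daily_counts) == 0:
            raise ValueError("daily_counts must be non-empty")
        if any(c < 0 for c in self.daily_counts):
            raise ValueError("daily_counts must be non-negative")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def _as_seedseq(seed) -> np.random.SeedSequence:
    """Accept plain integers or an existing SeedSequence as a seed."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def gm_cumulative_hazard(params: GMParams, t) -> np.ndarray:
    """Cumulative hazard H(t) = (m0/g)(e^{g t} - 1) + minf t (g=0: (m0+minf)t)."""
    t = np.asarray(t, dtype=float)
    if params.g == 0.0:
        return (params.m0 + params.minf) * t
    return (params.m0 / params.g) * np.expm1(params.g * t) + params.minf * t


def sample_gm_lifetimes(params: GMParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. continuous death times (days) by inverse transform.

    Solves H(t) = E with E ~ Exp(1).  For ``minf == 0`` the closed form
    ``t = (1/g) log(1 + g E / m0)`` is used; for ``g == 0`` the distribution is
    exponential with rate ``m0 + minf``; otherwise H is inverted by bracketed
    root-finding (H is strictly increasing, so the bracket is grown
    geometrically until it contains the root).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    e = rng.exponential(size=n)  # E = -ln U
    if params.g == 0.0:
        return e / (params.m0 + params.minf)
    if params.minf == 0.0:
        return np.log1p(params.g * e / params.m0) / params.g
    out = np.empty(n)
    for i, target in enumerate(e):
        upper = 1.0
        while gm_cumulative_hazard(params, upper) < target:
            upper *= 2.0
        out[i] = brentq(
            lambda t: float(gm_cumulative_hazard(params, t)) - target,
            0.0,
            upper,
            xtol=_INVERSION_XTOL,
        )
    return out


def discretize_and_censor(
    times: Sequence[float],
    censor_prob_per_day: float = 0.0,
    max_day: int | None = None,
    seed=0,
    group: str = "cohort",
    replicate: str = "r1",
    id_prefix: str = "w",
) -> pd.DataFrame:
    """Map continuous death times onto the daily scoring grid.

    Death is observed at the first daily inspection after it occurs, so the
    recorded death day is ``ceil(t)`` (a death in (0, 1] is scored on day 1).
    Censoring is an independent geometric process: on each day an individual
    still under observation is lost with probability ``censor_prob_per_day``;
    a loss on day ``c`` before the death day yields a censored record at day
    ``c``.  Individuals still alive and uncensored at ``max_day`` are censored
    there.  Returns event-table rows (individual_id, group, replicate,
    event_day, status).
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("death times must be positive and finite")
    if not 0.0 <= censor_prob_per_day < 1.0:
        raise ValueError("censor_prob_per_day must be in [0, 1)")
    n = len(times)
    death_day = np.ceil(times).astype(int)
    death_day[death_day < 1] = 1
    if censor_prob_per_day > 0.0:
        rng = np.random.default_rng(seed)
        censor_day = rng.geometric(censor_prob_per_day, size=n)
    else:
        censor_day = np.full(n, np.iinfo(np.int64).max)

    event_day = np.where(censor_day < death_day, censor_day, death_day)
    status = np.where(censor_day < death_day, "censored", "death")
    if max_day is not None:
        if max_day < 1:
            raise ValueError("max_day must be >= 1")
        over = event_day > max_day
        event_day = np.where(over, max_day, event_day)
        status = np.where(over, "censored", status)
    return pd.DataFrame(
        {
            "individual_id": [f"{id_prefix}{i+1}" for i in range(n)],
            "group": group,
            "replicate": replicate,
            "event_day": event_day.astype(int),
            "status": status,
        }
    )


def simulate_cohort(spec: CohortSpec, group: str = "cohort") -> pd.DataFrame:
    """Simulate an event table of ``n_replicates`` independent cohorts.

    Each replicate gets its own lifetime and censoring substreams spawned from
    ``spec.seed``, so outputs are reproducible and replicates are independent.
    """
    streams = _as_seedseq(spec.seed).spawn(spec.n_replicates)
    parts = []
    for r, ss in enumerate(streams, start=1):
        life_ss, cens_ss = ss.spawn(2)
        times = sample_gm_lifetimes(spec.params, spec.n_individuals, life_ss)
        parts.append(
            discretize_and_censor(
                times,
                spec.censor_prob_per_day,
                spec.max_day,
                seed=cens_ss,
                group=group,
                replicate=f"r{r}",
                id_prefix=f"r{r}w",
            )
        )
    return pd.concat(parts, ignore_index=True)


def _draw_cessation(cessation: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = cessation[0]
    if kind == "fixed":
        day = int(cessation[1])
        if day < 1:
            raise ValueError("cessation day must be >= 1")
        return np.full(n, day, dtype=int)
    if kind == "uniform":
        low, high = int(cessation[1]), int(cessation[2])
        if low < 1 or high < low:
            raise ValueError("uniform cessation needs 1 <= low <= high")
        return rng.integers(low, high + 1, size=n)
    if kind == "normal":
        mean, sd = float(cessation[1]), float(cessation[2])
        days = np.rint(rng.normal(mean, sd, size=n)).astype(int)
        return np.maximum(days, 1)
    raise ValueError(f"unknown cessation distribution {kind!r}")


def simulate_repro_schedules(
    spec: ReproSpec,
    group: str = "cohort",
    replicate: str = "r1",
    id_prefix: str = "w",
) -> pd.DataFrame:
    """Simulate daily progeny tables (individual_id, group, replicate, day,
    progeny_count).

    Per individual a cessation day is drawn from ``spec.cessation``; daily
    counts are Poisson around ``daily_counts`` for days up to and including
    the cessation day and exactly zero afterwards.  Rows are emitted for every
    day 1..cessation (zero counts included) so gap days are represented.
    """
    cess_ss, count_ss = _as_seedseq(spec.seed).spawn(2)
    cessation = _draw_cessation(spec.cessation, spec.n_individuals, np.random.default_rng(cess_ss))
    rng = np.random.default_rng(count_ss)
    rates = np.asarray(spec.daily_counts, dtype=float)
    rows: list[tuple] = []
    for i in range(spec.n_individuals):
        ind = f"{id_prefix}{i+1}"
        for day in range(1, int(cessation[i]) + 1):
            rate = rates[day - 1] if day <= len(rates) else 0.0
            rows.append((ind, group, replicate, day, int(rng.poisson(rate))))
    return pd.DataFrame(
        rows, columns=["individual_id", "group", "replicate", "day", "progeny_count"]
    )
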