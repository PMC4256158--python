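"""Reproductive-lifespan scoring, screen hit-calling, and pathway epistasis.

Reproductive lifespan (RLS) in self-fertilizing hermaphrodites runs from the
first day of reproduction (indexed 1) to the last day progeny are scored;
interior days with zero progeny do not end the span, since worms are only
declared post-reproductive after progeny stop appearing for good.  In mating
assays the absolute last day of live progeny production (the cessation day) is
the event fed to Kaplan-Meier / log-rank machinery as "reproductive survival".

A screen hit must extend the pooled mean RLS by more than a threshold (25% by
default) AND be individually significant (Student t-test) in every replicate
experiment — the "scored positive three times" rule.

Epistasis classification takes three wet-lab flags per gene — whether its
inactivation still delays reproductive senescence in daf-2 (insulin/IGF-1
receptor), daf-16 (FoxO) and sma-2 (TGF-beta Smad) mutants — and maps them to
a relationship with insulin/IGF-1 signaling (IIS) and a pathway class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import two_sample_t

__all__ = [
    "EpistasisCall",
    "ScreenCall",
    "NoReproductionError",
    "self_rls",
    "mated_cessation_day",
    "call_hit",
    "classify_epistasis",
    "total_brood",
]


class NoReproductionError(ValueError):
    """Raised for a progeny schedule with no nonzero counts."""


@dataclass(frozen=True)
class ScreenCall:
    gene: str
    mean_rls_treatment: float
    mean_rls_control: float
    extension_pct: float
    p: float  # worst (largest) per-replicate t-test p-value
    hit: bool


@dataclass(frozen=True)
class EpistasisCall:
    extends_daf2: bool
    extends_daf16: bool
    extends_sma2: bool
    iis_relation: str
    pathway_class: str


def _counts(schedule) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a schedule (mapping day->count, or DataFrame with day /
    progeny_count columns) to sorted day and count arrays."""
    if isinstance(schedule, pd.DataFrame):
        days = schedule["day"].to_numpy(dtype=int)
        counts = schedule["progeny_count"].to_numpy(dtype=float)
    elif isinstance(schedule, Mapping):
        days = np.array(sorted(schedule), dtype=int)
        counts = np.array([schedule[d] for d in sorted(schedule)], dtype=float)
    else:
        raise TypeError("schedule must be a mapping day->count or a DataFrame")
    if np.any(days < 1):
        raise ValueError("days must be >= 1")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("progeny counts must be finite and non-negative")
    order = np.argsort(days)
    return days[order], counts[order]


def self_rls(schedule) -> int:
    """Self-fertilizing reproductive lifespan in days.

    Day 1 is the first day of reproduction, so
    RLS = last nonzero day - first nonzero day + 1.  Interior zero-count days
    (gaps) are inside the span and do not terminate it.
    """
    days, counts = _counts(schedule)
    nz = days[counts > 0]
    if len(nz) == 0:
        raise NoReproductionError("schedule has no progeny")
    return int(nz[-1] - nz[0] + 1)


def mated_cessation_day(schedule) -> int:
    """Last absolute day of live progeny production (no re-indexing).

    These per-individual days are the events for reproductive-survival
    Kaplan-Meier curves and log-rank comparisons in mating assays.
    """
    days, counts = _counts(schedule)
    nz = days[counts > 0]
    if len(nz) == 0:
        raise NoReproductionError("schedule has no progeny")
    return int(nz[-1])


def call_hit(
    treatment_rls: Sequence[Sequence[float]],
    control_rls: Sequence[Sequence[float]],
    threshold_pct: float = 25.0,
    alpha: float = 0.05,
    gene: str = "gene",
) -> ScreenCall:
    """Call a screen hit from per-replicate RLS measurements.

    ``treatment_rls`` and ``control_rls`` are sequences of per-replicate
    sequences of per-individual RLS values (>= 2 individuals per arm per
    replicate).  The extension percentage is computed from pooled means; the
    hit flag additionally requires a significant increase (two-sample t-test
    p < alpha with treatment mean above control mean) within every replicate
    experiment.
    """
    if len(treatment_rls) == 0 or len(control_rls) == 0:
        raise ValueError("both arms need at least one replicate")
    if len(treatment_rls) != len(control_rls):
        raise ValueError("arms must have the same number of replicate experiments")
    t_pool = np.concatenate([np.asarray(r, dtype=float) for r in treatment_rls])
    c_pool = np.concatenate([np.asarray(r, dtype=float) for r in control_rls])
    mean_t, mean_c = float(t_pool.mean()), float(c_pool.mean())
    extension_pct = 100.0 * (mean_t - mean_c) / mean_c
    worst_p = 0.0
    all_positive = True
    for t_rep, c_rep in zip(treatment_rls, control_rls):
        res = two_sample_t(t_rep, c_rep)
        worst_p = max(worst_p, res.p_raw)
        if res.percent_change <= 0:
            all_positive = False
    hit = bool(extension_pct > threshold_pct and worst_p < alpha and all_positive)
    return ScreenCall(gene, mean_t, mean_c, extension_pct, worst_p, hit)


def classify_epistasis(
    extends_daf2: bool, extends_daf16: bool, extends_sma2: bool
) -> EpistasisCall:
    """Map extension flags in daf-2 / daf-16 / sma-2 mutants to pathway classes.

    A gene still extending reproductive lifespan in both daf-2 and daf-16
    mutants acts independently of IIS; failing in daf-2 only means its effect
    is non-additive with daf-2; failing in daf-16 only means it is
    daf-16-dependent but additive with daf-2; failing in both means it is
    fully IIS-dependent.  Crossing IIS-independence with the sma-2 flag gives
    the four pathway classes (independent of both pathways, TGF-beta-specific,
    IIS-specific, or acting through both pathways).
    """
    if extends_daf2 and extends_daf16:
        iis = "independent"
    elif extends_daf16 and not extends_daf2:
        iis = "non_additive_daf2"
    elif extends_daf2 and not extends_daf16:
        iis = "daf16_dependent_additive"
    else:
        iis = "fully_dependent"
    independent = iis == "independent"
    if independent:
        pathway = "independent_of_both" if extends_sma2 else "tgfb_specific"
    else:
        pathway = "iis_specific" if extends_sma2 else "both_pathways"
    return EpistasisCall(bool(extends_daf2), bool(extends_daf16), bool(extends_sma2), iis, pathway)


def total_brood(schedule) -> int:
    """Total progeny per hermaphrodite: the sum of all daily counts."""
    _, counts = _counts(schedule)
    return int(counts.sum())
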