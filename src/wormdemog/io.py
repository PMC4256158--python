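"""CSV/YAML/JSON interchange and the end-to-end pipeline.

CSV is the canonical interchange format; column orders are fixed so outputs
diff bit-exactly between runs:

    events CSV     individual_id, group, replicate, event_day, status
    progeny CSV    individual_id, group, replicate, day, progeny_count
    lifetable CSV  day, Nx, dx, cx, qx, mx, km
    flags CSV      gene, extends_daf2, extends_daf16, extends_sma2

``run_pipeline`` ties the stages together: lifetables and KM curves per
stratum, Gompertz-Makeham fits per replicate, log-rank comparisons of every
gene against the control with Holm adjustment across the whole run,
demographic group calls, reproductive-screen hit calls, and epistasis
classification.  All randomness flows from the config seed; gene-level
failures are isolated and recorded rather than aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    classify_demographic_group,
    holm_adjust,
    logrank_test,
    mean_lifespan_comparison,
)
from .gompertz import derived_lifespans, fit_gm, summarize_replicates
from .lifetables import LIFETABLE_COLUMNS, km_survival, make_lifetable
from .screen import call_hit, classify_epistasis, self_rls

__all__ = [
    "RunConfig",
    "read_event_table",
    "write_event_table",
    "read_progeny_table",
    "write_progeny_table",
    "write_lifetable",
    "read_epistasis_flags",
    "run_pipeline",
]

logger = logging.getLogger("wormdemog")

EVENT_COLUMNS = ["individual_id", "group", "replicate", "event_day", "status"]
PROGENY_COLUMNS = ["individual_id", "group", "replicate", "day", "progeny_count"]
FLAG_COLUMNS = ["gene", "extends_daf2", "extends_daf16", "extends_sma2"]
VALID_STATUS = {"death", "censored"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    out_dir: str
    control_label: str = "control"
    events_path: str | None = None
    progeny_path: str | None = None
    epistasis_path: str | None = None
    alpha: float = 0.05
    hit_threshold_pct: float = 25.0
    seed: int = 0
    do_lifetables: bool = True
    do_fits: bool = True
    do_compare: bool = True
    do_screen: bool = True
    do_epistasis: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.do_compare and not self.control_label:
            raise ValueError("comparisons require a control label")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _validate_rows(df: pd.DataFrame, path, day_col: str, count_col: str | None) -> None:
    """Row-level validation with 1-based data line numbers in messages."""
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        day = row[day_col]
        if not (np.isfinite(day) and float(day).is_integer() and day >= 1):
            problems.append(f"line {line}: {day_col}={day!r} must be an integer >= 1")
        if count_col is not None:
            c = row[count_col]
            if not (np.isfinite(c) and float(c).is_integer() and c >= 0):
                problems.append(f"line {line}: {count_col}={c!r} must be an integer >= 0")
        elif row["status"] not in VALID_STATUS:
            problems.append(f"line {line}: status={row['status']!r} not in {sorted(VALID_STATUS)}")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems[:20]))


def read_event_table(path) -> pd.DataFrame:
    """Read and validate a per-individual event CSV.

    Enforces the header, integer event days >= 1, status in {death, censored},
    and unique individual ids within each (group, replicate) stratum.
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "group": str, "replicate": str})
    if list(df.columns) != EVENT_COLUMNS:
        raise ValueError(f"{path}: expected columns {EVENT_COLUMNS}, got {list(df.columns)}")
    _validate_rows(df, path, "event_day", None)
    dup = df.duplicated(subset=["group", "replicate", "individual_id"])
    if dup.any():
        lines = [str(i + 2) for i in df.index[dup][:10]]
        raise ValueError(f"{path}: duplicate individual ids within a stratum at lines {lines}")
    df["event_day"] = df["event_day"].astype(int)
    return df


def write_event_table(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_progeny_table(path) -> pd.DataFrame:
    """Read and validate a daily progeny CSV (one row per individual-day)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "group": str, "replicate": str})
    if list(df.columns) != PROGENY_COLUMNS:
        raise ValueError(f"{path}: expected columns {PROGENY_COLUMNS}, got {list(df.columns)}")
    _validate_rows(df, path, "day", "progeny_count")
    df["day"] = df["day"].astype(int)
    df["progeny_count"] = df["progeny_count"].astype(int)
    return df


def write_progeny_table(progeny: pd.DataFrame, path) -> None:
    progeny[PROGENY_COLUMNS].to_csv(path, index=False)


def write_lifetable(lifetable: pd.DataFrame, path) -> None:
    lifetable[LIFETABLE_COLUMNS].to_csv(path, index=False)


def read_epistasis_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"gene": str})
    if list(df.columns) != FLAG_COLUMNS:
        raise ValueError(f"{path}: expected columns {FLAG_COLUMNS}, got {list(df.columns)}")
    for col in FLAG_COLUMNS[1:]:
        df[col] = df[col].astype(bool)
    return df


def _fit_group(events: pd.DataFrame, group: str) -> tuple[list[dict], object]:
    """Per-replicate GM fits for one group; returns fit rows + summary."""
    rows, fits = [], []
    for rep in sorted(events.loc[events["group"] == group, "replicate"].unique()):
        fit = fit_gm(km_survival(events, group, rep))
        if not fit.converged:
            logger.warning("unconverged fit: group=%s replicate=%s", group, rep)
        median, mean, max1 = derived_lifespans(fit) if fit.converged else (np.nan,) * 3
        rows.append(
            {
                "group": group,
                "replicate": rep,
                "M0": fit.params.m0,
                "G": fit.params.g,
                "Minf": fit.params.minf,
                "RSS": fit.rss,
                "converged": fit.converged,
                "median": median,
                "mean": mean,
                "max1pct": max1,
            }
        )
        fits.append(fit)
    return rows, summarize_replicates([f for f in fits if f.converged])


def run_pipeline(config: RunConfig) -> dict:
    """Run every requested stage and write the report bundle.

    Outputs under ``config.out_dir``: per-stratum lifetable CSVs, ``fits.csv``,
    ``comparisons.csv`` (Holm-adjusted across all genes in the run),
    ``screen.csv``, ``epistasis.csv`` and ``manifest.json``.  Returns the
    manifest dict.  Deterministic given the config: outputs are byte-identical
    across runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "hit_threshold_pct": config.hit_threshold_pct,
        "control_label": config.control_label,
        "stages": {},
        "gene_status": {},
    }

    events = None
    if config.events_path is not None:
        events = read_event_table(config.events_path)
        genes = sorted(g for g in events["group"].unique() if g != config.control_label)
    else:
        genes = []

    if events is not None and config.do_lifetables:
        lt_dir = out / "lifetables"
        lt_dir.mkdir(exist_ok=True)
        for group in sorted(events["group"].unique()):
            lt = make_lifetable(events, group)
            if np.isinf(lt["mx"]).any():
                logger.warning("group=%s has q_x=1 day(s); m_x flagged as +inf", group)
            write_lifetable(lt, lt_dir / f"{group}.csv")
            for rep in sorted(events.loc[events["group"] == group, "replicate"].unique()):
                write_lifetable(make_lifetable(events, group, rep), lt_dir / f"{group}__{rep}.csv")
        manifest["stages"]["lifetables"] = "done"

    summaries: dict[str, object] = {}
    if events is not None and config.do_fits:
        fit_rows: list[dict] = []
        for group in sorted(events["group"].unique()):
            try:
                rows, summary = _fit_group(events, group)
                fit_rows.extend(rows)
                summaries[group] = summary
            except Exception as exc:  # isolate per-group failures
                logger.warning("fit failed for group=%s: %s", group, exc)
                manifest["gene_status"][group] = f"fit_error: {exc}"
        pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        manifest["stages"]["fits"] = "done"

    if events is not None and config.do_compare and genes:
        ctrl_events = events[events["group"] == config.control_label]
        if len(ctrl_events) == 0:
            raise ValueError(f"control group {config.control_label!r} absent from events")
        comp_rows = []
        raw_ps = []
        per_gene = {}
        for gene in genes:
            try:
                res = logrank_test(events[events["group"] == gene], ctrl_events)
                per_gene[gene] = res
                raw_ps.append(res.p_raw)
            except Exception as exc:
                manifest["gene_status"][gene] = f"compare_error: {exc}"
                logger.warning("comparison failed for gene=%s: %s", gene, exc)
        adj = holm_adjust(raw_ps)
        for (gene, res), p_adj in zip(per_gene.items(), adj):
            res = res.adjusted(p_adj)
            group_call = ""
            if gene in summaries and config.control_label in summaries:
                # group calls test the mean lifespan itself (per-replicate
                # restricted means), not distributional equality
                life = mean_lifespan_comparison(events, gene, config.control_label)
                call = classify_demographic_group(
                    summaries[gene], summaries[config.control_label], life, config.alpha
                )
                group_call = str(call.group)
            comp_rows.append(
                {
                    "gene": gene,
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "percent_change": res.percent_change,
                    "group_call": group_call,
                }
            )
            manifest["gene_status"].setdefault(gene, "ok")
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
        manifest["stages"]["compare"] = "done"

    if config.progeny_path is not None and config.do_screen:
        progeny = read_progeny_table(config.progeny_path)
        rls = (
            progeny.groupby(["group", "replicate", "individual_id"])
            .apply(lambda g: self_rls(g), include_groups=False)
            .rename("rls")
            .reset_index()
        )
        ctrl = rls[rls["group"] == config.control_label]
        if len(ctrl) == 0:
            raise ValueError(f"control group {config.control_label!r} absent from progeny")
        ctrl_by_rep = [
            grp["rls"].to_numpy() for _, grp in ctrl.groupby("replicate", sort=True)
        ]
        screen_rows = []
        for gene in sorted(g for g in rls["group"].unique() if g != config.control_label):
            sub = rls[rls["group"] == gene]
            t_by_rep = [grp["rls"].to_numpy() for _, grp in sub.groupby("replicate", sort=True)]
            try:
                call = call_hit(
                    t_by_rep, ctrl_by_rep, config.hit_threshold_pct, config.alpha, gene
                )
                screen_rows.append(call.__dict__)
            except Exception as exc:
                manifest["gene_status"][gene] = f"screen_error: {exc}"
                logger.warning("screen failed for gene=%s: %s", gene, exc)
        pd.DataFrame(screen_rows).to_csv(out / "screen.csv", index=False)
        manifest["stages"]["screen"] = "done"

    if config.epistasis_path is not None and config.do_epistasis:
        flags = read_epistasis_flags(config.epistasis_path)
        epi_rows = []
        for _, row in flags.iterrows():
            call = classify_epistasis(
                row["extends_daf2"], row["extends_daf16"], row["extends_sma2"]
            )
            epi_rows.append({"gene": row["gene"], **call.__dict__})
        pd.DataFrame(epi_rows).to_csv(out / "epistasis.csv", index=False)
        manifest["stages"]["epistasis"] = "done"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
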