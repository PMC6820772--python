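"""Technical-validation metrics for a plate-based viability screen.

Three summaries of assay quality:

* pairwise Pearson correlation between biological replicates, computed on
  the normalised technical-mean value of every shared condition (all cell
  lines pooled into one vector per replicate);
* the per-condition coefficient of variation (sample SD / mean) across
  biological replicates and its screen-wide mean;
* the dispersion (sample SD) of each plate's normalised vehicle-control
  wells, flagged against a threshold (default 0.10, i.e. 10%).

Conditions near full kill are excluded from the CV summary (mean ≤ 0.01)
because the ratio is unstable as the mean approaches zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ingest_normalize import TREATMENT_KEYS, aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "replicate_correlation",
    "pairwise_replicate_correlations",
    "coefficient_of_variation",
    "control_dispersion",
    "qc_report",
    "write_qc_report",
]


@dataclass
class QCReport:
    """Bundle of screen-level quality metrics."""

    pairwise_replicate_r: dict[tuple[int, int], float]
    mean_cv: float
    cv_table: pd.DataFrame
    control_sd_by_plate: pd.DataFrame
    control_sd_threshold: float = 0.10
    scatter_tables: dict[tuple[int, int], pd.DataFrame] = field(default_factory=dict)


def replicate_correlation(x, y) -> float:
    """Pearson r between two replicates over their shared conditions.

    Pairs with either value missing are dropped. Returns NaN (with a
    warning) for fewer than three complete pairs or a zero-variance
    vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        logger.warning("replicate correlation needs >= 3 shared points, got %d", x.size)
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in a replicate vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _tech_mean_wide(points: pd.DataFrame) -> pd.DataFrame:
    """Conditions × biological replicates matrix of technical-mean effects."""
    tech = aggregate(points, "technical_mean")
    tech = tech[tech["kind"].isin(["single", "combination"])]
    # single-drug rows carry NaN drug_b/conc_b; fill so pivoting keeps them
    tech = tech.fillna({"drug_a": "", "conc_a": 0.0, "drug_b": "", "conc_b": 0.0})
    return tech.pivot_table(
        index=TREATMENT_KEYS, columns="bio_rep", values="mean", dropna=False
    )


def pairwise_replicate_correlations(
    points: pd.DataFrame, level: str = "tech_mean"
) -> dict[tuple[int, int], float]:
    """Pearson r for every biological-replicate pair of a normalised screen.

    ``level="tech_mean"`` (default) correlates per-condition technical
    means, pooling all cell lines; ``level="well"`` correlates raw
    well-level values matched by (condition, technical replicate).
    """
    if level == "tech_mean":
        wide = _tech_mean_wide(points)
    elif level == "well":
        pts = points[points["kind"].isin(["single", "combination"])].fillna(
            {"drug_a": "", "conc_a": 0.0, "drug_b": "", "conc_b": 0.0}
        )
        wide = pts.pivot_table(
            index=TREATMENT_KEYS + ["tech_rep"],
            columns="bio_rep",
            values="relative_effect",
            dropna=False,
        )
    else:
        raise ValueError(f"unknown correlation level {level!r}")
    reps = sorted(wide.columns)
    return {
        (int(i), int(j)): replicate_correlation(wide[i], wide[j])
        for i, j in itertools.combinations(reps, 2)
    }


def coefficient_of_variation(
    points: pd.DataFrame, min_mean: float = 0.01, level: str = "well"
) -> tuple[pd.DataFrame, float]:
    """Per-condition CV across replicates, plus its screen-wide mean.

    With ``level="well"`` (default) each condition's CV pools all its
    replicate wells, technical and biological, so the summary estimates
    the per-well assay noise directly. ``level="bio"`` instead takes the
    sample SD/mean over the per-biological-replicate technical means,
    which is attenuated by technical averaging. CV uses the sample
    (n−1) SD. Conditions with fewer than two contributors or mean at or
    below ``min_mean`` are skipped (count logged).
    """
    if level == "well":
        pts = points[points["kind"].isin(["single", "combination"])].fillna(
            {"drug_a": "", "conc_a": 0.0, "drug_b": "", "conc_b": 0.0}
        )
        grouped = pts.groupby(TREATMENT_KEYS, dropna=False)["relative_effect"]
        table = grouped.agg(
            mean="mean", sd=lambda s: s.std(ddof=1), n="count"
        ).reset_index()
    elif level == "bio":
        wide = _tech_mean_wide(points)
        mean = wide.mean(axis=1)
        sd = wide.std(axis=1, ddof=1)
        n = wide.notna().sum(axis=1)
        table = pd.DataFrame({"mean": mean, "sd": sd, "n": n}).reset_index()
    else:
        raise ValueError(f"unknown CV level {level!r}")
    eligible = (table["n"] >= 2) & (table["mean"] > min_mean)
    n_skipped = int((~eligible).sum())
    if n_skipped:
        logger.info("CV summary: %d conditions skipped (n < 2 or mean <= %g)",
                    n_skipped, min_mean)
    table["cv"] = np.where(eligible, table["sd"] / table["mean"], np.nan)
    mean_cv = float(table.loc[eligible, "cv"].mean()) if eligible.any() else float("nan")
    return table, mean_cv


def control_dispersion(
    points: pd.DataFrame, threshold: float = 0.10
) -> pd.DataFrame:
    """Sample SD of each plate's normalised vehicle-control wells.

    Plates whose SD exceeds ``threshold`` — or with a single usable
    control well, where the SD is undefined — are flagged.
    """
    ctrl = points[
        (points["kind"] == "vehicle_control") & points["relative_effect"].notna()
    ]
    per_plate = (
        ctrl.groupby("plate_id")["relative_effect"]
        .agg(sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    per_plate["flagged"] = per_plate["sd"].isna() | (per_plate["sd"] > threshold)
    return per_plate


def qc_report(points: pd.DataFrame, control_sd_threshold: float = 0.10) -> QCReport:
    """Assemble the full QC report from a normalised well table."""
    corr = pairwise_replicate_correlations(points)
    cv_table, mean_cv = coefficient_of_variation(points)
    ctrl = control_dispersion(points, control_sd_threshold)
    wide = _tech_mean_wide(points)
    scatters = {
        (int(i), int(j)): wide[[i, j]].dropna().rename(columns={i: "rep_i", j: "rep_j"})
        for i, j in corr
    }
    return QCReport(
        pairwise_replicate_r=corr,
        mean_cv=mean_cv,
        cv_table=cv_table,
        control_sd_by_plate=ctrl,
        control_sd_threshold=control_sd_threshold,
        scatter_tables=scatters,
    )


def write_qc_report(report: QCReport, out_dir: str | Path) -> list[Path]:
    """Emit the QC report as TSV tables plus a human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    corr_df = pd.DataFrame(
        [(i, j, r) for (i, j), r in report.pairwise_replicate_r.items()],
        columns=["rep_i", "rep_j", "pearson_r"],
    )
    for name, df in [
        ("replicate_correlations.tsv", corr_df),
        ("cv_per_condition.tsv", report.cv_table),
        ("control_dispersion.tsv", report.control_sd_by_plate),
    ]:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        written.append(path)
    for (i, j), df in report.scatter_tables.items():
        path = out_dir / f"scatter_rep{i}_vs_rep{j}.tsv"
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        written.append(path)

    n_flagged = int(report.control_sd_by_plate["flagged"].sum())
    summary = out_dir / "qc_summary.txt"
    lines = ["Screen QC summary", "=================", ""]
    for (i, j), r in report.pairwise_replicate_r.items():
        lines.append(f"Pearson r, biological replicate {i} vs {j}: {r:.3f}")
    lines += [
        f"Mean coefficient of variation: {report.mean_cv:.4f}",
        f"Plates with control-well SD > {report.control_sd_threshold:g} "
        f"(or undefined): {n_flagged} / {len(report.control_sd_by_plate)}",
        "",
    ]
    summary.write_text("\n".join(lines))
    written.append(summary)
    return written
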