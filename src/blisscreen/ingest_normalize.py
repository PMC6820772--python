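"""Raw-table ingest, per-plate vehicle-control normalisation, and
replicate aggregation.

The canonical in-memory container is a *well table*: a tidy
:class:`pandas.DataFrame` with one row per measured well and the columns
listed in :data:`WELL_COLUMNS`. Readouts (luminescence counts or %
confluency) are normalised per plate to the mean of that plate's DMSO
vehicle-control wells, yielding a ``relative_effect`` fraction where the
control mean is exactly 1. Missing readouts are carried as NaN (written as
"NA" on disk) and never imputed.

Aggregation is two-stage: technical replicates within a biological
replicate are averaged first, then biological replicates are averaged
across those technical means. With unbalanced technical replicate counts
this differs from pooling all wells, and the two-stage path is the
canonical one.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .screen_model import ScreenValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "WELL_COLUMNS",
    "TREATMENT_KEYS",
    "SchemaError",
    "PlateControlError",
    "read_screen_table",
    "read_exclusions",
    "apply_exclusions",
    "normalize_plates",
    "aggregate",
    "write_effect_tables",
]

#: Canonical well-table columns. ``conc_unit`` is optional and defaults to µM.
WELL_COLUMNS = [
    "plate_id",
    "well",
    "cell_line",
    "drug_a",
    "conc_a",
    "drug_b",
    "conc_b",
    "kind",
    "tech_rep",
    "bio_rep",
    "readout_kind",
    "raw_value",
]

#: Columns that identify one treatment condition within a cell line.
TREATMENT_KEYS = [
    "cell_line",
    "readout_kind",
    "kind",
    "drug_a",
    "conc_a",
    "drug_b",
    "conc_b",
]

_NUMERIC_COLS = ["conc_a", "conc_b", "raw_value"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class PlateControlError(ValueError):
    """A plate has no usable vehicle-control wells to normalise against."""


def read_screen_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    delimiter: str | None = None,
    exclusions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a raw screen table (CSV/TSV) into the canonical well table.

    Parameters
    ----------
    path
        Input file. The delimiter is inferred from the suffix
        (``.csv`` → comma, otherwise tab) unless given explicitly.
    schema
        Optional map from file column names to canonical
        :data:`WELL_COLUMNS` names, for deposits with their own headers.
    exclusions
        Optional hand-curated well drop list (see :func:`read_exclusions`);
        matching wells are removed before anything else, with a log entry.

    Unparseable numeric cells (including literal "NA") become missing with
    a logged warning; rows are never silently dropped for missingness.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    missing_cols = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")
    if df.empty:
        logger.warning("%s: empty screen table", path)

    out = df.copy()
    for col in _NUMERIC_COLS:
        parsed = pd.to_numeric(out[col].replace({"": np.nan, "NA": np.nan}), errors="coerce")
        n_bad = int((parsed.isna() & ~out[col].isin(["", "NA"])).sum())
        if n_bad:
            logger.warning("%s: %d unparseable cells in %r set to missing", path, n_bad, col)
        out[col] = parsed
    out["tech_rep"] = pd.to_numeric(out["tech_rep"], errors="coerce").astype("Int64")
    out["bio_rep"] = pd.to_numeric(out["bio_rep"], errors="coerce").astype("Int64")
    if "conc_unit" not in out.columns:
        out["conc_unit"] = "uM"
    out["conc_unit"] = out["conc_unit"].replace({"": "uM"})
    neg = out["raw_value"].dropna() < 0
    if neg.any():
        raise ScreenValidationError(f"{path}: {int(neg.sum())} negative raw readouts")
    if exclusions is not None:
        out = apply_exclusions(out, exclusions)
    return out.reset_index(drop=True)


def read_exclusions(path: str | Path) -> pd.DataFrame:
    """Read a well-exclusion list: TSV with plate_id, well, reason."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"plate_id", "well", "reason"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: exclusion list needs columns {sorted(required)}")
    return df


def apply_exclusions(wells: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop hand-curated wells, logging each excluded (plate, well, reason)."""
    key = ["plate_id", "well"]
    marked = wells.merge(exclusions[key].assign(_drop=True), on=key, how="left")
    n = int(marked["_drop"].notna().sum())
    if n:
        for _, r in exclusions.iterrows():
            logger.info("excluding %s/%s: %s", r["plate_id"], r["well"], r["reason"])
    return marked.loc[marked["_drop"].isna(), wells.columns].reset_index(drop=True)


def normalize_plates(
    wells: pd.DataFrame,
    control_stat: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Normalise every plate's readouts to its own DMSO controls.

    Each well's ``relative_effect`` is its raw readout divided by the
    mean (or, optionally, median) of the non-missing vehicle-control
    readouts measured on the same plate; the control wells themselves are
    normalised too, so their mean is exactly 1 per plate. Missing raw
    values stay missing.

    Raises
    ------
    PlateControlError
        Naming every plate that has no usable vehicle-control well.
    """
    if control_stat not in ("mean", "median"):
        raise ScreenValidationError(f"unknown control statistic {control_stat!r}")
    ctrl = wells[(wells["kind"] == "vehicle_control") & wells["raw_value"].notna()]
    stat = ctrl.groupby("plate_id")["raw_value"].agg(control_stat)
    bad = sorted(set(wells["plate_id"]) - set(stat.index))
    if bad:
        raise PlateControlError(f"plates without usable vehicle controls: {bad}")
    out = wells.copy()
    out["relative_effect"] = out["raw_value"] / out["plate_id"].map(stat)
    return out


def aggregate(
    points: pd.DataFrame,
    level: Literal["technical_mean", "biological_mean"],
) -> pd.DataFrame:
    """Average replicates at one of the two canonical levels.

    ``technical_mean`` averages a condition's technical-replicate wells
    within each biological replicate; ``biological_mean`` averages those
    technical means across biological replicates. Means and sample
    standard deviations are over non-missing contributors only; ``n``
    counts them, and a condition with no non-missing contributor keeps a
    missing mean with ``n = 0``. SD is reported only when ``n >= 2``.
    """
    if level == "technical_mean":
        keys = TREATMENT_KEYS + ["bio_rep"]
        values = points["relative_effect"]
        df = points.assign(_v=values)
    elif level == "biological_mean":
        if "mean" in points.columns and "level" in points.columns:
            tech = points[points["level"] == "technical_mean"]
        else:
            tech = aggregate(points, "technical_mean")
        keys = TREATMENT_KEYS
        df = tech.assign(_v=tech["mean"])
    else:
        raise ScreenValidationError(f"unknown aggregation level {level!r}")

    grouped = df.groupby(keys, dropna=False)["_v"]
    agg = grouped.agg(
        mean="mean",
        sd=lambda s: s.std(ddof=1),
        n="count",
    ).reset_index()
    agg.loc[agg["n"] < 2, "sd"] = np.nan
    agg["level"] = level
    return agg


def write_effect_tables(aggregates: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Write one TSV of mean effects per (cell line, aggregation level).

    Rows are ordered deterministically (combination label, then descending
    dose); floats carry 6 significant digits and missing values are "NA",
    so the files round-trip through :func:`pandas.read_csv`.
    """
    out_dir = Path(out_dir)
    if aggregates.empty:
        logger.warning("no aggregated effects to write")
        return []
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    df = aggregates.copy()
    df["_label"] = np.where(
        df["drug_b"].notna(),
        df["drug_a"].fillna("") + "-" + df["drug_b"].fillna(""),
        df["drug_a"].fillna("DMSO"),
    )
    for (cell_line, level), sub in df.groupby(["cell_line", "level"]):
        sub = sub.sort_values(
            ["_label", "conc_a", "conc_b"], ascending=[True, False, False]
        ).drop(columns="_label")
        suffix = "mean_Effect" if level == "biological_mean" else "tech-mean_Effect"
        path = out_dir / f"{cell_line}.{suffix}.tsv"
        sub.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        written.append(path)
    return written
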