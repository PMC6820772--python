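"""Bliss-independence synergy scoring.

Under Bliss independence two non-interacting drugs combine
multiplicatively: the expected fractional viability of the combination is
the product of the single-drug fractional viabilities,

    E[v_AB] = v_A * v_B.

The *Bliss excess* of an observed combination well is

    excess = v_AB - v_A * v_B,

so negative values indicate synergy (stronger-than-expected kill) and
positive values antagonism. Before any arithmetic, relative viabilities
are capped at one, which makes the score invariant to wells that grow
above the vehicle control.

Replicate handling follows the screen's structure exactly: within each
(cell line, dose, biological replicate) the Bliss expectation is the mean
over *all* cross products of drug A's and drug B's technical-replicate
viabilities (algebraically the product of the per-arm technical means),
and every non-missing technical replicate of the combination well
contributes one excess sample against that expectation. Expectations are
never borrowed across biological replicates.

For ray designs the combination at concentration c is compared against
both single agents at the same c; for matrix designs against the single
agents at the respective row/column concentrations. The secondary-screen
summary, the *cumulative Bliss score*, is the unweighted mean over the
per-dose-pair average excesses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .screen_model import ScreenValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "cap_viability",
    "bliss_expectation",
    "bliss_excess_samples",
    "compute_bliss_samples",
    "mean_bliss",
    "summarize_profiles",
    "cumulative_bliss",
    "cumulative_bliss_table",
    "write_sample_table",
]

#: Columns of a Bliss-sample table (one row per combination technical replicate).
SAMPLE_COLUMNS = [
    "cell_line",
    "pair",
    "drug_a",
    "drug_b",
    "conc_a",
    "conc_b",
    "bio_rep",
    "tech_rep",
    "excess",
]


def cap_viability(v):
    """Cap relative viability at one; missing stays missing.

    Accepts scalars or arrays. Negative viabilities are invalid input.
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ScreenValidationError("negative viability cannot be capped")
    capped = np.minimum(arr, 1.0)
    if np.isscalar(v) or arr.ndim == 0:
        return float(capped)
    return capped


def bliss_expectation(
    viab_a_reps: Sequence[float], viab_b_reps: Sequence[float]
) -> float:
    """Mean Bliss expectation over all technical-replicate cross products.

    Computes ``mean_{i,j}(a_i * b_j)`` over the non-missing replicate
    values of each arm — identical to the product of the two arm means.
    Returns NaN if either arm has no non-missing value. Inputs are
    expected to be capped already.
    """
    a = np.asarray(viab_a_reps, dtype=float)
    b = np.asarray(viab_b_reps, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    return float(np.mean(np.outer(a, b)))


def bliss_excess_samples(
    combo_reps: Sequence[float],
    viab_a_reps: Sequence[float],
    viab_b_reps: Sequence[float],
) -> list[float]:
    """Per-technical-replicate Bliss excesses for one (dose, biological replicate).

    All three inputs are capped here; each non-missing combination
    technical replicate yields ``capped combo - expectation`` where the
    expectation is shared within the biological replicate. Returns an
    empty list (logged) when either single-drug arm is entirely missing.
    """
    expectation = bliss_expectation(
        cap_viability(np.asarray(viab_a_reps, dtype=float)),
        cap_viability(np.asarray(viab_b_reps, dtype=float)),
    )
    if np.isnan(expectation):
        logger.info("no single-drug data for this dose/replicate; samples omitted")
        return []
    combo = np.asarray(combo_reps, dtype=float)
    combo = cap_viability(combo[~np.isnan(combo)])
    return [float(c - expectation) for c in np.atleast_1d(combo)]


def compute_bliss_samples(
    points: pd.DataFrame, readout_kind: str = "viability"
) -> pd.DataFrame:
    """Replicate-resolved Bliss excesses for a whole normalised screen.

    Parameters
    ----------
    points
        Normalised well table (output of
        :func:`blisscreen.ingest_normalize.normalize_plates`) containing
        single and combination wells.
    readout_kind
        Which readout to score; viability and confluency flow through the
        identical formula.

    Returns
    -------
    DataFrame with :data:`SAMPLE_COLUMNS`: one row per non-missing
    combination technical replicate with matchable single-drug arms.
    Combination wells whose (cell line, biological replicate, dose) lacks
    single-drug data are dropped with a logged count.
    """
    pts = points[
        (points["readout_kind"] == readout_kind)
        & (points.get("conc_unit", "uM") == "uM")
    ].copy()
    pts["capped"] = cap_viability(pts["relative_effect"].to_numpy())

    singles = pts[(pts["kind"] == "single") & pts["capped"].notna()]
    arm_means = (
        singles.groupby(["cell_line", "bio_rep", "drug_a", "conc_a"], dropna=False)[
            "capped"
        ]
        .mean()
        .reset_index()
        .rename(columns={"drug_a": "drug", "conc_a": "conc", "capped": "arm_mean"})
    )

    combos = pts[(pts["kind"] == "combination") & pts["capped"].notna()].copy()
    if combos.empty:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)

    merged = combos.merge(
        arm_means.rename(columns={"drug": "drug_a", "conc": "conc_a", "arm_mean": "_ma"}),
        on=["cell_line", "bio_rep", "drug_a", "conc_a"],
        how="left",
    ).merge(
        arm_means.rename(columns={"drug": "drug_b", "conc": "conc_b", "arm_mean": "_mb"}),
        on=["cell_line", "bio_rep", "drug_b", "conc_b"],
        how="left",
    )
    unmatched = merged["_ma"].isna() | merged["_mb"].isna()
    if unmatched.any():
        logger.info(
            "%d combination replicates without single-drug arms dropped",
            int(unmatched.sum()),
        )
    merged = merged[~unmatched].copy()
    merged["excess"] = merged["capped"] - merged["_ma"] * merged["_mb"]

    # canonical pair orientation: alphabetical by abbreviation
    flip = merged["drug_a"] > merged["drug_b"]
    for a_col, b_col in (("drug_a", "drug_b"), ("conc_a", "conc_b")):
        a = merged[a_col].where(~flip, merged[b_col])
        b = merged[b_col].where(~flip, merged[a_col])
        merged[a_col], merged[b_col] = a, b
    merged["pair"] = merged["drug_a"] + "-" + merged["drug_b"]
    return merged[SAMPLE_COLUMNS].reset_index(drop=True)


def mean_bliss(excesses: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD and count of a combination's excess samples.

    Pools all doses, technical and biological replicates of one
    (pair, cell line). Returns (NaN, NaN, 0) when no samples exist;
    SD is NaN for a single sample.
    """
    arr = np.asarray(excesses, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = int(arr.size)
    if n == 0:
        return float("nan"), float("nan"), 0
    sd = float(np.std(arr, ddof=1)) if n >= 2 else float("nan")
    return float(np.mean(arr)), sd, n


def summarize_profiles(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-(pair, cell line) mean/SD/count of Bliss excesses."""
    if samples.empty:
        return pd.DataFrame(
            columns=["cell_line", "pair", "drug_a", "drug_b", "mean_excess", "sd_excess", "n_samples"]
        )
    grouped = samples.groupby(["cell_line", "pair", "drug_a", "drug_b"], dropna=False)
    out = grouped["excess"].agg(
        mean_excess="mean", sd_excess=lambda s: s.std(ddof=1), n_samples="count"
    ).reset_index()
    return out


def cumulative_bliss(per_dose_means: Sequence[float]) -> float:
    """Cumulative Bliss score: unweighted mean of per-dose-pair mean excesses.

    Dose pairs with a missing mean are skipped (logged); each remaining
    dose pair carries equal weight regardless of its replicate count.
    """
    arr = np.asarray(per_dose_means, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    if n_missing:
        logger.info("cumulative Bliss: %d dose pairs missing, skipped", n_missing)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    return float(np.mean(arr))


def cumulative_bliss_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Cumulative Bliss score per (pair, cell line) from a sample table.

    Averages excesses within each dose pair first, then averages those
    per-dose-pair means with equal weight — unbalanced replicate counts
    therefore do not re-weight doses. Only dose pairs with both
    concentrations > 0 are present in sample tables by construction.
    """
    if samples.empty:
        return pd.DataFrame(columns=["cell_line", "pair", "cumulative_bliss", "n_dose_pairs"])
    per_dose = (
        samples.groupby(["cell_line", "pair", "conc_a", "conc_b"], dropna=False)["excess"]
        .mean()
        .reset_index()
    )
    out = (
        per_dose.groupby(["cell_line", "pair"])["excess"]
        .agg(cumulative_bliss="mean", n_dose_pairs="count")
        .reset_index()
    )
    return out


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> Path:
    """Write the long Bliss-sample table as TSV (missing as "NA")."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return path
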