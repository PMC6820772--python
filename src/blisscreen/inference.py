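"""Hit calling: significance testing and synergy classification.

For the primary (ray) screen, each (drug pair, cell line) yields a
distribution of replicate-resolved Bliss excesses pooled over doses.
A two-sided one-sample t-test asks whether that distribution deviates
from zero (the additivity null); p-values are Bonferroni-adjusted across
the family of all hypotheses tested in the run, and a combination is
called a synergy when its mean excess is at most −0.08 *and* its adjusted
p-value is at most 0.05 (both boundaries inclusive).

For the secondary (matrix) screen, where 25 dose pairs per combination
make the score far better sampled, the rule is simply a negative
cumulative Bliss score (strict inequality).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bliss_core import cumulative_bliss_table, summarize_profiles
from .screen_model import ScreenValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "EXCESS_THRESHOLD",
    "P_THRESHOLD",
    "one_sample_t_vs_zero",
    "bonferroni",
    "classify_primary",
    "classify_secondary",
    "run_screen_inference",
    "write_significance_tables",
]

#: Primary-screen synergy thresholds: mean Bliss excess and adjusted p.
EXCESS_THRESHOLD = -0.08
P_THRESHOLD = 0.05


def one_sample_t_vs_zero(samples) -> tuple[float, float]:
    """Two-sided one-sample t-test of a sample mean against zero.

    Returns ``(t, p)`` with ``t = mean / (sd / sqrt(n))`` and p from the
    t distribution with n−1 degrees of freedom. Degenerate cases:
    fewer than two samples → ``(nan, nan)`` (logged); zero variance with
    zero mean → ``(0, 1)``; zero variance with non-zero mean → p = 0
    with a warning (the test statistic diverges).
    """
    arr = np.asarray(samples, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n < 2:
        logger.info("t-test needs >= 2 samples, got %d; p undefined", n)
        return float("nan"), float("nan")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0 or np.all(arr == arr[0]):  # identical values: exact zero variance
        sd = 0.0
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("zero-variance sample with non-zero mean; p reported as 0")
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni family-wise adjustment: ``min(1, p * m)``."""
    if m < 1:
        raise ScreenValidationError("family size m must be >= 1")
    if not 0.0 <= p_raw <= 1.0:
        raise ScreenValidationError(f"p-value {p_raw} outside [0, 1]")
    return min(1.0, p_raw * m)


def classify_primary(
    mean_excess: float,
    p_adj: float,
    excess_threshold: float = EXCESS_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> str:
    """Primary-screen call: synergy iff mean ≤ −0.08 and adjusted p ≤ 0.05.

    Both boundaries are inclusive. Missing inputs yield a missing label
    (NaN), which downstream code treats as not-synergy.
    """
    if np.isnan(mean_excess) or np.isnan(p_adj):
        return float("nan")  # type: ignore[return-value]
    if mean_excess <= excess_threshold and p_adj <= p_threshold:
        return "synergy"
    return "not_synergy"


def classify_secondary(cumulative: float) -> str:
    """Secondary-screen call: synergy iff the cumulative Bliss score < 0."""
    if np.isnan(cumulative):
        return float("nan")  # type: ignore[return-value]
    return "synergy" if cumulative < 0.0 else "not_synergy"


def run_screen_inference(
    samples: pd.DataFrame,
    screen: str = "primary",
    m_override: int | None = None,
    excess_threshold: float = EXCESS_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Classify every (pair, cell line) of a screen from its Bliss samples.

    Parameters
    ----------
    samples
        Long Bliss-sample table from
        :func:`blisscreen.bliss_core.compute_bliss_samples`.
    screen
        ``"primary"`` (t-test + Bonferroni + dual threshold) or
        ``"secondary"`` (cumulative score < 0).
    m_override
        Fix the Bonferroni family size instead of using the number of
        hypotheses with a computable p in this run (e.g. 1368 for the
        full 171-pair × 8-cell-line design).

    Returns
    -------
    One row per (pair, cell line), ordered by mean excess ascending
    (most synergistic first). Hypotheses with fewer than two samples
    keep missing p and the conservative label ``not_synergy``.
    """
    if screen not in ("primary", "secondary"):
        raise ScreenValidationError(f"unknown screen kind {screen!r}")
    if samples.empty:
        return pd.DataFrame(
            columns=[
                "cell_line", "pair", "drug_a", "drug_b", "mean_excess", "sd_excess",
                "n_samples", "t_stat", "p_raw", "p_adj", "label", "screen",
            ]
        )
    res = summarize_profiles(samples)

    if screen == "secondary":
        cum = cumulative_bliss_table(samples)
        res = res.merge(cum, on=["cell_line", "pair"], how="left")
        res["t_stat"] = np.nan
        res["p_raw"] = np.nan
        res["p_adj"] = np.nan
        res["label"] = res["cumulative_bliss"].map(classify_secondary)
        res = res.sort_values("cumulative_bliss", kind="mergesort").reset_index(drop=True)
        res["screen"] = "secondary"
        return res

    # vectorised one-sample t against zero (same math as one_sample_t_vs_zero)
    mean = res["mean_excess"].to_numpy(float)
    sd = res["sd_excess"].to_numpy(float)
    n = res["n_samples"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 1, 1))
    degenerate = (n >= 2) & (sd == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(mean) * np.inf, t)
        p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    undef = n < 2
    t[undef] = np.nan
    p[undef] = np.nan
    res["t_stat"] = t
    res["p_raw"] = p

    m = m_override if m_override is not None else int(res["p_raw"].notna().sum())
    m = max(m, 1)
    res["p_adj"] = np.minimum(1.0, res["p_raw"] * m)
    res["label"] = [
        classify_primary(me, pa, excess_threshold, p_threshold)
        if not (np.isnan(me) or np.isnan(pa))
        else "not_synergy"
        for me, pa in zip(res["mean_excess"], res["p_adj"])
    ]
    res = res.sort_values("mean_excess", kind="mergesort").reset_index(drop=True)
    res["screen"] = "primary"
    res.attrs["family_size"] = m
    return res


def write_significance_tables(
    results: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the full significance table and the synergy-only subset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    full = out_dir / "bliss_significance.tsv"
    hits = out_dir / "bliss_synergies.tsv"
    results.to_csv(full, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    results[results["label"] == "synergy"].to_csv(
        hits, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    return full, hits
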