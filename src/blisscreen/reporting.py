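"""Report-ready synergy artefacts: clustered heatmap matrix, volcano
coordinates, and dose-response / combination-plot tables.

The tested surface is the tidy tables; rendered figures are a thin
optional layer over them. The heatmap matrix follows the screen's
display conventions: one row per drug pair, one column per cell line,
rows sorted by across-cell-line mean Bliss excess (most synergistic
first), columns ordered by hierarchical clustering of cell lines on
Euclidean distance between their synergy vectors, and a three-class
colour scheme with |excess| ≥ 0.11 as the synergy/antagonism display
boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

__all__ = [
    "HEATMAP_CLASS_THRESHOLD",
    "SynergyMatrix",
    "build_synergy_matrix",
    "heatmap_color_class",
    "volcano_coordinates",
    "combination_plot_table",
    "export_synergy_matrix",
    "export_cimbinator_long",
    "render_heatmap",
]

#: Display boundary for the heatmap colour classes (synergy blue / antagonism red).
HEATMAP_CLASS_THRESHOLD = 0.11


@dataclass
class SynergyMatrix:
    """Drug pairs × cell lines matrix of mean Bliss excesses."""

    values: pd.DataFrame  # index: pair label; columns: cell line; NaN allowed
    row_order: list[str]
    col_order: list[str]
    linkage: np.ndarray | None  # scipy linkage of the cell-line clustering


def _pairwise_complete_euclidean(mat: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances between columns over shared rows.

    Rows where either column is missing are dropped per column pair.
    Column pairs with no shared rows get the largest finite distance
    (plus a margin) so they merge last.
    """
    n = mat.shape[1]
    dists = np.full(n * (n - 1) // 2, np.nan)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(mat[:, i]) | np.isnan(mat[:, j]))
            if ok.any():
                diff = mat[ok, i] - mat[ok, j]
                dists[k] = float(np.sqrt(np.sum(diff * diff)))
            k += 1
    if np.isnan(dists).any():
        fill = (np.nanmax(dists) if np.isfinite(np.nanmax(dists)) else 1.0) * 1.01 + 1e-9
        dists = np.where(np.isnan(dists), fill, dists)
    return dists


def build_synergy_matrix(
    results: pd.DataFrame, linkage_method: str = "complete"
) -> SynergyMatrix:
    """Pivot screen results into the display matrix with row/column orders.

    Rows (pairs) are sorted by their missing-aware mean excess across
    cell lines, ascending and stably (ties keep input-relative order).
    Columns (cell lines) are ordered by hierarchical clustering on
    pairwise-complete Euclidean distances; with fewer than two cell
    lines carrying data, the natural (alphabetical) order is kept.
    Ties in the clustering input are made deterministic by starting from
    alphabetically sorted columns.
    """
    mat = results.pivot_table(index="pair", columns="cell_line", values="mean_excess")
    mat = mat[sorted(mat.columns)]
    # stable row sort by missing-aware mean
    row_means = mat.mean(axis=1, skipna=True)
    order_idx = np.argsort(row_means.to_numpy(), kind="stable")
    row_order = list(mat.index[order_idx])

    link = None
    col_order = list(mat.columns)
    usable = [c for c in mat.columns if mat[c].notna().any()]
    if len(usable) >= 2:
        sub = mat[usable]
        dists = _pairwise_complete_euclidean(sub.to_numpy(float))
        link = hierarchy.linkage(dists, method=linkage_method)
        leaves = hierarchy.leaves_list(link)
        clustered = [usable[i] for i in leaves]
        col_order = clustered + [c for c in mat.columns if c not in usable]
    mat = mat.loc[row_order, col_order]
    return SynergyMatrix(values=mat, row_order=row_order, col_order=col_order, linkage=link)


def heatmap_color_class(
    value: float, threshold: float = HEATMAP_CLASS_THRESHOLD
) -> str:
    """Three-class display colour: blue ≤ −0.11, red ≥ +0.11, neutral between."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    if value <= -threshold:
        return "synergy_blue"
    if value >= threshold:
        return "antagonism_red"
    return "neutral"


def volcano_coordinates(
    results: pd.DataFrame, p_floor_ceiling: float = 16.0
) -> pd.DataFrame:
    """Volcano-plot coordinates: mean excess vs −log10 adjusted p.

    Rows without an adjusted p are omitted (count logged); p = 1 maps to
    y = 0 and p = 0 to the configurable ceiling.
    """
    ok = results["p_adj"].notna()
    n_omitted = int((~ok).sum())
    if n_omitted:
        logger.info("volcano: %d results without adjusted p omitted", n_omitted)
    sub = results[ok]
    with np.errstate(divide="ignore"):
        y = -np.log10(sub["p_adj"].to_numpy(float))
    y = np.where(np.isinf(y), p_floor_ceiling, y)
    return pd.DataFrame(
        {
            "pair": sub["pair"].to_numpy(),
            "cell_line": sub["cell_line"].to_numpy(),
            "mean_excess": sub["mean_excess"].to_numpy(float),
            "neg_log10_p_adj": y,
            "label": sub["label"].to_numpy(),
        }
    )


def combination_plot_table(
    aggregates: pd.DataFrame, drug_a: str, drug_b: str, cell_line: str
) -> pd.DataFrame:
    """Tidy mean ± SD table for one combination's dose-response plot.

    Collects the biological-mean responses of the three arms — drug A
    alone, drug B alone, and the A+B combination — across the dose
    series of one cell line. Rows: (arm, conc_a, conc_b, mean, sd).
    An arm with no non-missing mean is omitted with a warning. For a
    5-dose ray this yields 15 rows; for a 5×5 matrix with single-drug
    margins, 35.
    """
    agg = aggregates[
        (aggregates["cell_line"] == cell_line)
        & (aggregates["level"] == "biological_mean")
    ]
    a, b = sorted((drug_a, drug_b))
    arms = {
        "A": agg[(agg["kind"] == "single") & (agg["drug_a"] == a)].assign(conc_b=0.0),
        "B": agg[(agg["kind"] == "single") & (agg["drug_a"] == b)].assign(conc_b=0.0),
        "A+B": agg[
            (agg["kind"] == "combination")
            & (
                ((agg["drug_a"] == a) & (agg["drug_b"] == b))
                | ((agg["drug_a"] == b) & (agg["drug_b"] == a))
            )
        ],
    }
    rows = []
    for arm, sub in arms.items():
        if sub.empty or sub["mean"].isna().all():
            logger.warning(
                "combination plot %s/%s-%s: arm %s absent", cell_line, a, b, arm
            )
            continue
        for _, r in sub.iterrows():
            conc_a = r["conc_a"] if arm != "B" else 0.0
            conc_b = r["conc_b"] if arm != "B" else r["conc_a"]
            rows.append((arm, conc_a, conc_b, r["mean"], r["sd"]))
    out = pd.DataFrame(rows, columns=["arm", "conc_a", "conc_b", "mean", "sd"])
    return out.sort_values(["arm", "conc_a", "conc_b"], ascending=[True, False, False]).reset_index(
        drop=True
    )


def export_synergy_matrix(matrix: SynergyMatrix, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the heatmap matrix TSV plus a JSON sidecar with the orders."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "synergy_matrix.tsv"
    matrix.values.to_csv(tsv, sep="\t", na_rep="NA", float_format="%.6g")
    sidecar = out_dir / "synergy_matrix.json"
    sidecar.write_text(
        json.dumps(
            {
                "row_order": matrix.row_order,
                "col_order": matrix.col_order,
                "linkage": None if matrix.linkage is None else matrix.linkage.tolist(),
            },
            indent=2,
        )
    )
    return tsv, sidecar


def export_cimbinator_long(aggregates: pd.DataFrame, path: str | Path) -> Path:
    """Plain long-format export of biological-mean effects for external tools."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sub = aggregates[aggregates["level"] == "biological_mean"]
    cols = ["cell_line", "drug_a", "conc_a", "drug_b", "conc_b", "kind", "mean", "sd", "n"]
    sub[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return path


def render_heatmap(matrix: SynergyMatrix, path: str | Path) -> Path:
    """Render the clustered synergy heatmap to PDF/PNG (optional layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = matrix.values.to_numpy(float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(matrix.col_order)), max(4, 0.12 * len(matrix.row_order)))
    )
    im = ax.imshow(vals, cmap="bwr", vmin=-0.3, vmax=0.3, aspect="auto")
    ax.set_xticks(range(len(matrix.col_order)), matrix.col_order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.row_order)), matrix.row_order, fontsize=4)
    fig.colorbar(im, ax=ax, label="mean Bliss excess")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
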