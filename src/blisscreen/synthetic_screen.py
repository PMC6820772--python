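"""Synthetic combination screens with known ground truth.

Generates complete raw well tables — plate layouts with DMSO vehicle
controls, optional positive-control series, technical and biological
replicates, multiplicative measurement noise and missing wells — from
per-drug Hill dose-response curves and injected pairwise interactions.

Single-drug viability follows a Hill curve

    v(c) = 1 - Emax * c^h / (c^h + EC50^h),

and a combination's true viability is the Bliss-independent product of
its single-drug viabilities plus an additive interaction shift ``delta``
(negative = synergy), floored at zero. With ``delta = 0`` the generator
reproduces exact Bliss independence, so the whole pipeline must recover
zero excess in the absence of noise — the null is exact by construction.

Noise is multiplicative log-normal with its σ chosen so the coefficient
of variation of the noise factor equals ``noise_cv``; luminescence noise
scales with signal and stays positive, which an additive Gaussian model
would not guarantee. Technical replicates share their biological
replicate's plate (hence its control normalisation); each biological
replicate gets independent control-well draws.

Every simulated screen ships a ground-truth sidecar (true viability and
delta per condition) so that parameter recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .bliss_core import compute_bliss_samples
from .ingest_normalize import normalize_plates
from .inference import run_screen_inference
from .qc_metrics import coefficient_of_variation
from .screen_model import (
    CONC_UNIT_UG_PER_ML,
    CONC_UNIT_UM,
    DoseDesign,
    ScreenValidationError,
    load_cell_line_table,
    load_drug_table,
    pair_label,
    ray_doses,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HillParams",
    "InteractionSpec",
    "SimConfig",
    "hill_viability",
    "true_combo_viability",
    "simulate_screen",
    "run_primary_pipeline",
    "recovery_experiment",
    "default_screen_config",
    "null_screen_config",
    "recovery_screen_config",
    "write_raw_tables",
    "config_to_yaml",
]


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response parameters: EC50 (µM), slope, maximal kill fraction."""

    ec50: float
    hill: float = 1.0
    emax: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0 or not 0.0 <= self.emax <= 1.0:
            raise ScreenValidationError(
                f"invalid Hill parameters ec50={self.ec50}, hill={self.hill}, emax={self.emax}"
            )


@dataclass(frozen=True)
class InteractionSpec:
    """Ground-truth pairwise interaction: additive Bliss-excess shift.

    ``cell_line=None`` applies the shift in every cell line;
    ``dose_mask=None`` at every dose pair of the design.
    """

    drug_a: str
    drug_b: str
    delta: float
    cell_line: str | None = None
    dose_mask: tuple[tuple[float, float], ...] | None = None

    @property
    def pair(self) -> str:
        return pair_label(self.drug_a, self.drug_b)


@dataclass
class SimConfig:
    """Full specification of one synthetic screen."""

    drugs: list[str]
    cell_lines: list[str]
    design: DoseDesign
    hill_params: dict[tuple[str, str], HillParams]  # (drug, cell_line) -> params
    interactions: list[InteractionSpec] = field(default_factory=list)
    n_bio: int = 3
    n_tech: int = 2
    noise_cv: float = 0.06
    na_rate: float = 0.0
    n_control_wells: int = 16
    control_raw_mean: float = 1e6
    seed: int = 0
    equimolar_split: bool = False  # combination wells get c/2 of each drug
    include_positive_controls: bool = False

    def validate(self) -> None:
        problems = []
        if not self.drugs or len(set(self.drugs)) != len(self.drugs):
            problems.append("drugs must be non-empty and unique")
        if not self.cell_lines:
            problems.append("cell_lines must be non-empty")
        if self.n_bio < 1:
            problems.append("n_bio must be >= 1")
        if self.n_tech < 1:
            problems.append("n_tech must be >= 1")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        if not 0.0 <= self.na_rate < 1.0:
            problems.append("na_rate must be in [0, 1)")
        if self.n_control_wells < 1:
            problems.append("n_control_wells must be >= 1")
        if self.control_raw_mean <= 0:
            problems.append("control_raw_mean must be > 0")
        missing = [
            (d, c)
            for d in self.drugs
            for c in self.cell_lines
            if (d, c) not in self.hill_params
        ]
        if missing:
            problems.append(f"hill_params missing for {missing[:5]}...")
        if problems:
            raise ScreenValidationError("; ".join(problems))


def hill_viability(c, params: HillParams):
    """Fractional viability of a single drug at concentration ``c`` (µM)."""
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0):
        raise ScreenValidationError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        ch = np.where(arr > 0, arr**params.hill, 0.0)
    v = 1.0 - params.emax * ch / (ch + params.ec50**params.hill)
    return float(v) if np.isscalar(c) else v


def true_combo_viability(
    c_a: float,
    c_b: float,
    params_a: HillParams,
    params_b: HillParams,
    delta: float = 0.0,
) -> float:
    """True combination viability: Bliss product plus interaction, floored at 0."""
    v = hill_viability(c_a, params_a) * hill_viability(c_b, params_b) + delta
    return max(0.0, v)


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _single_doses(design: DoseDesign) -> list[float]:
    if design.kind == "ray":
        return list(design.doses)
    return sorted(set(design.doses_a) | set(design.doses_b), reverse=True)


def _delta_lookup(config: SimConfig) -> dict[tuple[str, str], InteractionSpec]:
    table: dict[tuple[str, str], InteractionSpec] = {}
    for spec in config.interactions:
        lines = config.cell_lines if spec.cell_line is None else [spec.cell_line]
        for cl in lines:
            table[(spec.pair, cl)] = spec
    return table


def simulate_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full screen; returns (well table, ground-truth sidecar).

    The well table has the canonical columns of
    :data:`blisscreen.ingest_normalize.WELL_COLUMNS` (plus ``conc_unit``)
    and is byte-deterministic for a fixed config. The truth sidecar has
    one row per (cell line, condition) with the noiseless viability and
    the injected delta.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    deltas = _delta_lookup(config)
    drugs_sorted = sorted(config.drugs)

    # --- noiseless condition grid, one row per chemical condition per cell line
    cond_rows: list[tuple] = []
    for cl in config.cell_lines:
        for d in drugs_sorted:
            p = config.hill_params[(d, cl)]
            for c in _single_doses(config.design):
                cond_rows.append((cl, d, c, None, np.nan, "single", hill_viability(c, p), 0.0))
        for i, a in enumerate(drugs_sorted):
            for b in drugs_sorted[i + 1 :]:
                spec = deltas.get((pair_label(a, b), cl))
                pa, pb = config.hill_params[(a, cl)], config.hill_params[(b, cl)]
                for ca, cb in config.design.dose_pairs():
                    delta = 0.0
                    if spec is not None and (
                        spec.dose_mask is None or (ca, cb) in spec.dose_mask
                    ):
                        delta = spec.delta
                    wa, wb = (ca / 2, cb / 2) if config.equimolar_split else (ca, cb)
                    v = true_combo_viability(wa, wb, pa, pb, delta)
                    cond_rows.append((cl, a, wa, b, wb, "combination", v, delta))
    truth = pd.DataFrame(
        cond_rows,
        columns=["cell_line", "drug_a", "conc_a", "drug_b", "conc_b", "kind",
                 "true_viability", "delta"],
    )

    # --- expand to wells: plates are (cell line, biological replicate)
    frames: list[pd.DataFrame] = []
    for cl in config.cell_lines:
        cl_truth = truth[truth["cell_line"] == cl]
        for b in range(1, config.n_bio + 1):
            plate = f"{cl}__b{b}"
            treated = cl_truth.loc[cl_truth.index.repeat(config.n_tech)].copy()
            treated["tech_rep"] = np.tile(
                np.arange(1, config.n_tech + 1), len(cl_truth)
            )
            treated["bio_rep"] = b
            treated["plate_id"] = plate
            treated["conc_unit"] = CONC_UNIT_UM
            ctrl = pd.DataFrame(
                {
                    "cell_line": cl,
                    "drug_a": None,
                    "conc_a": np.nan,
                    "drug_b": None,
                    "conc_b": np.nan,
                    "kind": "vehicle_control",
                    "true_viability": 1.0,
                    "delta": 0.0,
                    "tech_rep": np.arange(1, config.n_control_wells + 1),
                    "bio_rep": b,
                    "plate_id": plate,
                    "conc_unit": CONC_UNIT_UM,
                }
            )
            parts = [treated, ctrl]
            if config.include_positive_controls:
                pos_doses = 100.0 * (0.02 / 100.0) ** (np.arange(9) / 8.0)
                pos_params = HillParams(ec50=5.0, hill=2.0, emax=1.0)
                parts.append(
                    pd.DataFrame(
                        {
                            "cell_line": cl,
                            "drug_a": "DIG",
                            "conc_a": pos_doses,
                            "drug_b": None,
                            "conc_b": np.nan,
                            "kind": "positive_control",
                            "true_viability": hill_viability(pos_doses, pos_params),
                            "delta": 0.0,
                            "tech_rep": 1,
                            "bio_rep": b,
                            "plate_id": plate,
                            "conc_unit": CONC_UNIT_UG_PER_ML,
                        }
                    )
                )
            frames.append(pd.concat(parts, ignore_index=True))
    wells = pd.concat(frames, ignore_index=True)
    wells["well"] = [f"w{i:05d}" for i in range(len(wells))]
    wells["readout_kind"] = "viability"

    factors = _noise(rng, config.noise_cv, len(wells))
    wells["raw_value"] = config.control_raw_mean * wells["true_viability"] * factors

    if config.na_rate > 0:
        treated_mask = wells["kind"].isin(["single", "combination"]).to_numpy()
        drop = rng.random(len(wells)) < config.na_rate
        wells.loc[treated_mask & drop, "raw_value"] = np.nan

    cols = ["plate_id", "well", "cell_line", "drug_a", "conc_a", "drug_b", "conc_b",
            "kind", "tech_rep", "bio_rep", "readout_kind", "raw_value", "conc_unit"]
    return wells[cols].copy(), truth


def run_primary_pipeline(
    wells: pd.DataFrame, m_override: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: normalise → Bliss samples → primary-screen inference.

    Returns (normalised points, sample table, results table).
    """
    points = normalize_plates(wells)
    samples = compute_bliss_samples(points)
    results = run_screen_inference(samples, screen="primary", m_override=m_override)
    return points, samples, results


def recovery_experiment(
    config: SimConfig,
    pipeline: Callable[[pd.DataFrame], tuple] | None = None,
) -> dict:
    """Simulate one screen and score the pipeline against the ground truth.

    Returns a dict with:

    ``per_pair``
        DataFrame per (pair, cell line): injected delta, estimated mean
        excess, adjusted p and label.
    ``confusion``
        Counts tp / fp / tn / fn of synergy calls against delta < 0.
    ``mean_cv`` / ``noise_cv``
        The measured replicate CV next to the configured one.
    """
    wells, truth = simulate_screen(config)
    points, samples, results = (pipeline or run_primary_pipeline)(wells)

    injected = pd.DataFrame(
        [
            {"cell_line": cl, "pair": spec.pair, "delta_true": spec.delta}
            for (pair, cl), spec in _delta_lookup(config).items()
        ],
        columns=["cell_line", "pair", "delta_true"],
    )
    per_pair = results.merge(injected, on=["cell_line", "pair"], how="left")
    per_pair["delta_true"] = per_pair["delta_true"].fillna(0.0)

    is_hit = per_pair["label"] == "synergy"
    is_true = per_pair["delta_true"] < 0
    confusion = {
        "tp": int((is_hit & is_true).sum()),
        "fp": int((is_hit & ~is_true).sum()),
        "tn": int((~is_hit & ~is_true).sum()),
        "fn": int((~is_hit & is_true).sum()),
    }
    _, mean_cv = coefficient_of_variation(points)
    return {
        "per_pair": per_pair,
        "confusion": confusion,
        "mean_cv": mean_cv,
        "noise_cv": config.noise_cv,
        "samples": samples,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Canned configurations


def default_screen_config(seed: int = 0, **overrides) -> SimConfig:
    """The full-scale synthetic fixture emulating the study design.

    8 cell lines × 19 drugs × 171 pairs on the 5-dose equimolar ray
    (10 → 0.016 µM, 5-fold), 3 biological × 2 technical replicates,
    6% noise CV, 14% missing wells, per-plate DMSO controls and a
    positive-control dilution series. Hill parameters are drawn once per
    (drug, cell line) from wide log-uniform/uniform ranges
    (EC50 ∈ [0.05, 20] µM, slope ∈ [0.8, 2.5], Emax ∈ [0.3, 1.0]); six
    drug pairs carry injected synergies (delta ∈ [−0.25, −0.1]) across
    all cell lines, echoing the few-percent synergy prevalence typical
    of such screens.
    """
    rng = np.random.default_rng(seed)
    drugs = sorted(d.abbrev for d in load_drug_table())
    cell_lines = [c.name for c in load_cell_line_table()]
    hill = {
        (d, c): HillParams(
            ec50=float(np.exp(rng.uniform(np.log(0.05), np.log(20.0)))),
            hill=float(rng.uniform(0.8, 2.5)),
            emax=float(rng.uniform(0.3, 1.0)),
        )
        for d in drugs
        for c in cell_lines
    }
    n_pairs = len(drugs) * (len(drugs) - 1) // 2
    pair_idx = rng.choice(n_pairs, size=6, replace=False)
    all_pairs = [
        (a, b) for i, a in enumerate(drugs) for b in drugs[i + 1 :]
    ]
    interactions = [
        InteractionSpec(
            drug_a=all_pairs[i][0],
            drug_b=all_pairs[i][1],
            delta=float(rng.uniform(-0.25, -0.1)),
        )
        for i in sorted(int(i) for i in pair_idx)
    ]
    cfg = SimConfig(
        drugs=drugs,
        cell_lines=cell_lines,
        design=ray_doses(10.0, 5.0, 5),
        hill_params=hill,
        interactions=interactions,
        n_bio=3,
        n_tech=2,
        noise_cv=0.06,
        na_rate=0.14,
        n_control_wells=16,
        seed=seed,
        include_positive_controls=True,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


_MIDRANGE = HillParams(ec50=2.0, hill=1.0, emax=0.6)


def null_screen_config(
    seed: int = 0,
    n_drugs: int = 5,
    n_cell_lines: int = 2,
    noise_cv: float = 0.06,
    **overrides,
) -> SimConfig:
    """Reduced no-interaction screen: 10 pairs × 2 cell lines = 20 hypotheses.

    All drugs share mid-range Hill parameters (EC50 2 µM, slope 1,
    Emax 0.6) so responses stay away from both the cap at 1 and the
    floor at 0 across the 5-dose ray.
    """
    drugs = [f"D{i:02d}" for i in range(1, n_drugs + 1)]
    cell_lines = [f"CL{i}" for i in range(1, n_cell_lines + 1)]
    cfg = SimConfig(
        drugs=drugs,
        cell_lines=cell_lines,
        design=ray_doses(10.0, 5.0, 5),
        hill_params={(d, c): _MIDRANGE for d in drugs for c in cell_lines},
        interactions=[],
        n_bio=3,
        n_tech=2,
        noise_cv=noise_cv,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def recovery_screen_config(
    seed: int = 0, delta: float = -0.15, noise_cv: float = 0.06, **overrides
) -> SimConfig:
    """Parameter-recovery screen: 4 drugs, 1 cell line, 6 pairs.

    Two pairs carry the injected delta, four are Bliss-independent.
    Mid-range Hill parameters keep the Bliss product above the clipping
    floor at every ray dose, so the injected shift is recoverable
    without attenuation.
    """
    drugs = ["D01", "D02", "D03", "D04"]
    cell_lines = ["CL1"]
    interactions = [
        InteractionSpec(drug_a="D01", drug_b="D02", delta=delta),
        InteractionSpec(drug_a="D03", drug_b="D04", delta=delta),
    ]
    cfg = SimConfig(
        drugs=drugs,
        cell_lines=cell_lines,
        design=ray_doses(10.0, 5.0, 5),
        hill_params={(d, c): _MIDRANGE for d in drugs for c in cell_lines},
        interactions=interactions,
        n_bio=3,
        n_tech=2,
        noise_cv=noise_cv,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Serialisation


def write_raw_tables(
    wells: pd.DataFrame, out_dir: str | Path, stem: str = "synthetic_HTS"
) -> list[Path]:
    """Write one raw TSV per biological replicate (deposit-style layout)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for b, sub in wells.groupby("bio_rep"):
        path = out_dir / f"{stem}_Repl{b}_raw.tsv"
        sub.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")
        written.append(path)
    return written


def write_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")
    return path


def config_to_yaml(config: SimConfig, path: str | Path) -> Path:
    """Echo the simulation config as YAML (hill params keyed 'drug|cell_line')."""
    payload = {
        "drugs": config.drugs,
        "cell_lines": config.cell_lines,
        "design": {
            "kind": config.design.kind,
            "doses": list(config.design.doses),
            "doses_a": list(config.design.doses_a),
            "doses_b": list(config.design.doses_b),
        },
        "hill_params": {
            f"{d}|{c}": asdict(p) for (d, c), p in config.hill_params.items()
        },
        "interactions": [
            {
                "drug_a": s.drug_a,
                "drug_b": s.drug_b,
                "delta": s.delta,
                "cell_line": s.cell_line,
                "dose_mask": None if s.dose_mask is None else [list(dp) for dp in s.dose_mask],
            }
            for s in config.interactions
        ],
        "n_bio": config.n_bio,
        "n_tech": config.n_tech,
        "noise_cv": config.noise_cv,
        "na_rate": config.na_rate,
        "n_control_wells": config.n_control_wells,
        "control_raw_mean": config.control_raw_mean,
        "seed": config.seed,
        "equimolar_split": config.equimolar_split,
        "include_positive_controls": config.include_positive_controls,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def config_from_yaml(path: str | Path) -> SimConfig:
    """Inverse of :func:`config_to_yaml`."""
    payload = yaml.safe_load(Path(path).read_text())
    d = payload["design"]
    design = DoseDesign(
        kind=d["kind"],
        doses=tuple(d.get("doses") or ()),
        doses_a=tuple(d.get("doses_a") or ()),
        doses_b=tuple(d.get("doses_b") or ()),
    )
    hill = {
        tuple(k.split("|", 1)): HillParams(**v)
        for k, v in payload["hill_params"].items()
    }
    interactions = [
        InteractionSpec(
            drug_a=s["drug_a"],
            drug_b=s["drug_b"],
            delta=s["delta"],
            cell_line=s.get("cell_line"),
            dose_mask=None
            if s.get("dose_mask") is None
            else tuple(tuple(dp) for dp in s["dose_mask"]),
        )
        for s in payload["interactions"]
    ]
    return SimConfig(
        drugs=payload["drugs"],
        cell_lines=payload["cell_lines"],
        design=design,
        hill_params=hill,
        interactions=interactions,
        n_bio=payload["n_bio"],
        n_tech=payload["n_tech"],
        noise_cv=payload["noise_cv"],
        na_rate=payload["na_rate"],
        n_control_wells=payload["n_control_wells"],
        control_raw_mean=payload["control_raw_mean"],
        seed=payload["seed"],
        equimolar_split=payload.get("equimolar_split", False),
        include_positive_controls=payload.get("include_positive_controls", False),
    )
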