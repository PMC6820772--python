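"""Domain vocabulary for plate-based drug-combination screens.

Defines the chemical and experimental entities of a pairwise combination
screen — drugs, cell lines, well treatments — and the two dose layouts used
throughout the package:

* *ray* design: both drugs co-diluted along a fixed equimolar series
  (e.g. 10, 2, 0.4, 0.08, 0.016 µM, a 5-fold series);
* *matrix* (checkerboard) design: the full Cartesian product of two
  concentration lists.

Concentrations are stored in µM throughout. Positive-control compounds
dosed in µg/ml carry an explicit unit tag and are excluded from synergy
arithmetic downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "ScreenValidationError",
    "Drug",
    "CellLine",
    "Treatment",
    "DoseDesign",
    "enumerate_pairs",
    "ray_doses",
    "matrix_dose_pairs",
    "pair_label",
    "load_drug_table",
    "load_cell_line_table",
    "CONC_UNIT_UM",
    "CONC_UNIT_UG_PER_ML",
]

CONC_UNIT_UM = "uM"
CONC_UNIT_UG_PER_ML = "ug_per_ml"

TreatmentKind = Literal["single", "combination", "vehicle_control", "positive_control"]


class ScreenValidationError(ValueError):
    """Raised when screen metadata violates a structural invariant."""


@dataclass(frozen=True)
class Drug:
    """A small-molecule inhibitor, identified by a short abbreviation."""

    abbrev: str
    name: str = ""
    nominal_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.abbrev:
            raise ScreenValidationError("drug abbreviation must be non-empty")


@dataclass(frozen=True)
class CellLine:
    """A screened cell line with its seeding density and doubling time."""

    name: str
    tissue: str = ""
    cells_per_well: int = 1000
    doubling_time_h: float = 24.0

    def __post_init__(self) -> None:
        if self.cells_per_well <= 0:
            raise ScreenValidationError(f"{self.name}: cells_per_well must be > 0")
        if self.doubling_time_h <= 0:
            raise ScreenValidationError(f"{self.name}: doubling_time_h must be > 0")


@dataclass(frozen=True)
class Treatment:
    """The chemical condition applied to one well.

    ``kind`` distinguishes single-drug wells, two-drug combination wells,
    solvent-only vehicle controls (0.5% DMSO) and cytotoxic positive
    controls. Invariants are enforced at construction.
    """

    kind: TreatmentKind
    drug_a: str | None = None
    conc_a: float = 0.0
    drug_b: str | None = None
    conc_b: float = 0.0
    conc_unit: str = CONC_UNIT_UM

    def __post_init__(self) -> None:
        if self.kind == "vehicle_control":
            if self.drug_a or self.drug_b:
                raise ScreenValidationError("vehicle control wells carry no drugs")
        elif self.kind == "single":
            if not self.drug_a or self.drug_b or self.conc_a <= 0:
                raise ScreenValidationError(
                    "single treatment requires exactly one drug at conc > 0"
                )
        elif self.kind == "combination":
            if (
                not self.drug_a
                or not self.drug_b
                or self.drug_a == self.drug_b
                or self.conc_a <= 0
                or self.conc_b <= 0
            ):
                raise ScreenValidationError(
                    "combination requires two distinct drugs, both at conc > 0"
                )
        elif self.kind == "positive_control":
            if not self.drug_a or self.conc_a <= 0:
                raise ScreenValidationError(
                    "positive control requires a compound at conc > 0"
                )
        else:
            raise ScreenValidationError(f"unknown treatment kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "vehicle_control":
            return "DMSO"
        if self.drug_b:
            return f"{self.drug_a}-{self.drug_b}"
        return str(self.drug_a)


@dataclass(frozen=True)
class DoseDesign:
    """Dose layout of a screen: an equimolar ray or a checkerboard matrix.

    For a ray design ``doses`` is the (strictly decreasing) shared series;
    for a matrix design ``doses_a`` × ``doses_b`` is the full grid and
    ``doses`` is unused.
    """

    kind: Literal["ray", "matrix"]
    doses: tuple[float, ...] = ()
    doses_a: tuple[float, ...] = ()
    doses_b: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "ray":
            _check_dose_series(self.doses, "doses")
        elif self.kind == "matrix":
            _check_dose_series(self.doses_a, "doses_a")
            _check_dose_series(self.doses_b, "doses_b")
        else:
            raise ScreenValidationError(f"unknown design kind {self.kind!r}")

    def dose_pairs(self) -> list[tuple[float, float]]:
        """Combination (conc_a, conc_b) pairs enumerated by this design."""
        if self.kind == "ray":
            return [(c, c) for c in self.doses]
        return matrix_dose_pairs(list(self.doses_a), list(self.doses_b))


def _check_dose_series(doses: Sequence[float], label: str) -> None:
    if len(doses) == 0:
        raise ScreenValidationError(f"{label}: empty dose list")
    if any(d <= 0 for d in doses):
        raise ScreenValidationError(f"{label}: doses must be positive")
    if any(a <= b for a, b in zip(doses, doses[1:])):
        raise ScreenValidationError(f"{label}: doses must be strictly decreasing")


def enumerate_pairs(drugs: Sequence[Drug]) -> list[tuple[Drug, Drug]]:
    """All n(n-1)/2 unordered drug pairs, each in canonical order.

    Canonical order is alphabetical by abbreviation, so e.g. the
    BI + PI combination is always the single record ("BI", "PI").
    """
    abbrevs = [d.abbrev for d in drugs]
    if len(set(abbrevs)) != len(abbrevs):
        dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
        raise ScreenValidationError(f"duplicate drug abbreviations: {dupes}")
    ordered = sorted(drugs, key=lambda d: d.abbrev)
    return list(itertools.combinations(ordered, 2))


def pair_label(abbrev_a: str, abbrev_b: str) -> str:
    """Canonical 'A-B' label with members sorted alphabetically."""
    a, b = sorted((abbrev_a, abbrev_b))
    return f"{a}-{b}"


def ray_doses(top: float, fold: float, n_levels: int) -> DoseDesign:
    """Serial-dilution ray design: ``[top, top/fold, ..., top/fold**(n-1)]``."""
    if top <= 0:
        raise ScreenValidationError("top dose must be positive")
    if fold <= 1:
        raise ScreenValidationError("dilution fold must exceed 1")
    if n_levels < 1:
        raise ScreenValidationError("need at least one dose level")
    doses = tuple(top / fold**i for i in range(n_levels))
    return DoseDesign(kind="ray", doses=doses)


def matrix_dose_pairs(
    levels_a: Sequence[float], levels_b: Sequence[float]
) -> list[tuple[float, float]]:
    """Full checkerboard: Cartesian product of two dose lists, row-major in a."""
    _check_dose_series(tuple(levels_a), "levels_a")
    _check_dose_series(tuple(levels_b), "levels_b")
    return [(a, b) for a in levels_a for b in levels_b]


def _packaged(name: str) -> Path:
    return Path(str(resources.files("blisscreen").joinpath("data", name)))


def load_drug_table(path: str | Path | None = None) -> list[Drug]:
    """Load the drug metadata table (TSV: abbrev, name, targets).

    The packaged default mirrors the screen's 19-inhibitor panel: the
    abbreviations, names and nominal targets that are public knowledge,
    completed with synthetic placeholder entries (file
    ``drugs_synthetic.tsv``) so that the full 19-drug layout can be
    enumerated without external identifiers.
    """
    path = _packaged("drugs_synthetic.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    drugs = [
        Drug(
            abbrev=str(r["abbrev"]),
            name=str(r["name"]),
            nominal_targets=tuple(t for t in str(r["targets"]).split(";") if t),
        )
        for _, r in df.iterrows()
    ]
    enumerate_pairs(drugs)  # uniqueness check
    return drugs


def load_cell_line_table(path: str | Path | None = None) -> list[CellLine]:
    """Load the cell-line panel (TSV: name, tissue, cells_per_well, doubling_time_h)."""
    path = _packaged("cell_lines.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t")
    return [
        CellLine(
            name=str(r["name"]),
            tissue=str(r["tissue"]),
            cells_per_well=int(r["cells_per_well"]),
            doubling_time_h=float(r["doubling_time_h"]),
        )
        for _, r in df.iterrows()
    ]
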