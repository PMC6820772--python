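"""Shared fixtures: small hand-built well tables and simulated screens."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import blisscreen as bs


def make_well(
    plate_id="P1",
    well="w1",
    cell_line="CL1",
    drug_a=None,
    conc_a=np.nan,
    drug_b=None,
    conc_b=np.nan,
    kind="vehicle_control",
    tech_rep=1,
    bio_rep=1,
    readout_kind="viability",
    raw_value=1000.0,
    conc_unit="uM",
):
    return dict(
        plate_id=plate_id,
        well=well,
        cell_line=cell_line,
        drug_a=drug_a,
        conc_a=conc_a,
        drug_b=drug_b,
        conc_b=conc_b,
        kind=kind,
        tech_rep=tech_rep,
        bio_rep=bio_rep,
        readout_kind=readout_kind,
        raw_value=raw_value,
        conc_unit=conc_unit,
    )


def well_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["well"] = [f"w{i:03d}" for i in range(len(df))]
    return df


@pytest.fixture
def toy_plate() -> pd.DataFrame:
    """One plate: 3 controls at 1000, one single at 500, one combo at 300."""
    return well_table(
        [
            make_well(raw_value=1000.0),
            make_well(raw_value=1000.0),
            make_well(raw_value=1000.0),
            make_well(drug_a="AA", conc_a=10.0, kind="single", raw_value=500.0),
            make_well(
                drug_a="AA", conc_a=10.0, drug_b="BB", conc_b=10.0,
                kind="combination", raw_value=300.0,
            ),
        ]
    )


@pytest.fixture(scope="session")
def noiseless_null_screen() -> pd.DataFrame:
    """Deterministic screen: no noise, no missing wells, zero interaction."""
    cfg = bs.null_screen_config(seed=11, noise_cv=0.0)
    wells, _ = bs.simulate_screen(cfg)
    return wells


@pytest.fixture(scope="session")
def small_noisy_screen() -> tuple[pd.DataFrame, bs.SimConfig]:
    cfg = bs.recovery_screen_config(seed=5)
    wells, _ = bs.simulate_screen(cfg)
    return wells, cfg
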