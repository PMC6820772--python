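"""Synthetic-screen generator: Hill curves, ground truth, determinism, recovery."""

import numpy as np
import pandas as pd
import pytest

import blisscreen as bs
from blisscreen.screen_model import ScreenValidationError
from blisscreen.synthetic_screen import (
    HillParams,
    InteractionSpec,
    config_from_yaml,
    config_to_yaml,
    hill_viability,
    recovery_experiment,
    simulate_screen,
    true_combo_viability,
    write_raw_tables,
)


class TestHillViability:
    def test_untreated_is_fully_viable(self):
        assert hill_viability(0.0, HillParams(ec50=1.0)) == 1.0

    def test_half_max_at_ec50(self):
        assert hill_viability(2.0, HillParams(ec50=2.0, hill=1.7, emax=1.0)) == pytest.approx(0.5)

    def test_asymptote_is_one_minus_emax(self):
        assert hill_viability(1e9, HillParams(ec50=1.0, emax=0.8)) == pytest.approx(0.2, abs=1e-6)

    def test_monotone_non_increasing(self):
        p = HillParams(ec50=0.5, hill=2.0, emax=0.9)
        doses = np.logspace(-3, 2, 50)
        v = hill_viability(doses, p)
        assert np.all(np.diff(v) <= 1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ScreenValidationError):
            hill_viability(-1.0, HillParams(ec50=1.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ScreenValidationError):
            HillParams(ec50=0.0)
        with pytest.raises(ScreenValidationError):
            HillParams(ec50=1.0, emax=1.2)


class TestTrueComboViability:
    def test_bliss_null_is_product(self):
        pa = HillParams(ec50=10 / 1.5, emax=1.0)  # contrived; checked via singles
        pb = HillParams(ec50=10.0, emax=1.0)
        ca = cb = 10.0
        expected = hill_viability(ca, pa) * hill_viability(cb, pb)
        assert true_combo_viability(ca, cb, pa, pb, 0.0) == pytest.approx(expected)

    def test_delta_shifts_additively(self):
        pa = pb = HillParams(ec50=10.0, emax=0.8)
        base = true_combo_viability(10, 10, pa, pb, 0.0)
        assert true_combo_viability(10, 10, pa, pb, -0.15) == pytest.approx(base - 0.15)

    def test_floor_clipping_at_zero(self):
        pa = pb = HillParams(ec50=0.01, hill=3.0, emax=1.0)  # near-full kill
        assert true_combo_viability(10, 10, pa, pb, -0.15) == 0.0


class TestSimulateScreen:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = bs.recovery_screen_config(seed=42)
        w1, t1 = simulate_screen(cfg)
        w2, t2 = simulate_screen(bs.recovery_screen_config(seed=42))
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(t1, t2)
        p1 = write_raw_tables(w1, tmp_path / "a")
        p2 = write_raw_tables(w2, tmp_path / "b")
        assert [p.read_bytes() for p in p1] == [p.read_bytes() for p in p2]

    def test_different_seeds_differ(self):
        w1, _ = simulate_screen(bs.recovery_screen_config(seed=1))
        w2, _ = simulate_screen(bs.recovery_screen_config(seed=2))
        assert not w1["raw_value"].equals(w2["raw_value"])

    def test_full_design_has_171_combination_series_per_cell_line(self):
        cfg = bs.default_screen_config(seed=0)
        wells, truth = simulate_screen(cfg)
        combos = truth[(truth["kind"] == "combination") & (truth["cell_line"] == cfg.cell_lines[0])]
        assert combos.groupby(["drug_a", "drug_b"]).ngroups == 171
        assert len(combos) == 171 * 5

    def test_na_rate_realised(self):
        cfg = bs.default_screen_config(seed=8)
        wells, _ = simulate_screen(cfg)
        treated = wells[wells["kind"].isin(["single", "combination"])]
        frac = treated["raw_value"].isna().mean()
        n = len(treated)
        ci = 1.96 * np.sqrt(0.14 * 0.86 / n)
        assert abs(frac - 0.14) < ci + 0.01

    def test_controls_and_positive_controls_present_per_plate(self):
        cfg = bs.default_screen_config(seed=0)
        wells, _ = simulate_screen(cfg)
        per_plate = wells.groupby("plate_id")["kind"].value_counts().unstack()
        assert (per_plate["vehicle_control"] == cfg.n_control_wells).all()
        assert (per_plate["positive_control"] == 9).all()
        pos = wells[wells["kind"] == "positive_control"]
        assert set(pos["conc_unit"]) == {"ug_per_ml"}

    def test_positive_controls_excluded_from_synergy(self):
        cfg = bs.default_screen_config(seed=0, na_rate=0.0)
        wells, _ = simulate_screen(cfg)
        points = bs.normalize_plates(wells)
        samples = bs.compute_bliss_samples(points)
        assert "DIG" not in set(samples["drug_a"]) | set(samples["drug_b"])

    def test_invalid_config_lists_offenders(self):
        cfg = bs.null_screen_config(seed=0)
        cfg.n_bio = 0
        cfg.na_rate = 1.5
        with pytest.raises(ScreenValidationError, match="n_bio.*na_rate"):
            simulate_screen(cfg)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = bs.recovery_screen_config(seed=3)
        path = config_to_yaml(cfg, tmp_path / "cfg.yaml")
        back = config_from_yaml(path)
        assert back.drugs == cfg.drugs
        assert back.design.doses == cfg.design.doses
        assert back.hill_params == cfg.hill_params
        assert back.interactions == cfg.interactions
        w1, _ = simulate_screen(cfg)
        w2, _ = simulate_screen(back)
        pd.testing.assert_frame_equal(w1, w2)


class TestNullByConstruction:
    def test_zero_noise_zero_delta_gives_exact_bliss_null(self, noiseless_null_screen):
        _, _, results = bs.run_primary_pipeline(noiseless_null_screen)
        assert np.allclose(results["mean_excess"], 0.0, atol=1e-12)
        assert (results["label"] == "not_synergy").all()

    def test_equimolar_split_halves_per_drug_doses(self):
        cfg = bs.recovery_screen_config(seed=0, equimolar_split=True)
        wells, _ = simulate_screen(cfg)
        combos = wells[wells["kind"] == "combination"]
        assert combos["conc_a"].max() == pytest.approx(5.0)


class TestRecoveryExperiment:
    def test_report_structure_and_confusion(self):
        rep = recovery_experiment(bs.recovery_screen_config(seed=12))
        pp = rep["per_pair"]
        assert len(pp) == 6
        assert set(pp[pp["delta_true"] < 0]["pair"]) == {"D01-D02", "D03-D04"}
        conf = rep["confusion"]
        assert sum(conf.values()) == 6

    def test_estimate_tracks_injected_delta(self):
        """Averaged over seeds, estimated mean excess approaches -0.15."""
        ests = []
        for s in range(15):
            rep = recovery_experiment(bs.recovery_screen_config(seed=200 + s))
            pp = rep["per_pair"]
            ests.extend(pp.loc[pp["delta_true"] < 0, "mean_excess"])
        assert np.mean(ests) == pytest.approx(-0.15, abs=0.03)

    def test_clipping_attenuates_never_amplifies(self):
        """Strong synergy on near-full-kill curves is under-, not over-estimated."""
        drugs = ["D01", "D02"]
        hill = {(d, "CL1"): HillParams(ec50=0.05, hill=2.0, emax=1.0) for d in drugs}
        cfg = bs.SimConfig(
            drugs=drugs,
            cell_lines=["CL1"],
            design=bs.ray_doses(10.0, 5.0, 5),
            hill_params=hill,
            interactions=[InteractionSpec("D01", "D02", delta=-0.2)],
            noise_cv=0.0,
            seed=0,
        )
        _, _, results = bs.run_primary_pipeline(simulate_screen(cfg)[0])
        est = results["mean_excess"].iloc[0]
        assert est > -0.2 - 1e-9  # attenuated toward zero
        assert est <= 0.0
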