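"""Kinetic simulator: mass balance, determinism, and study phenomenology."""

import numpy as np
import pytest

from zfpk.core_data import Compartment, Route, STANDARD_GRID
from zfpk.nca import AUCConfig, trapezoid_auc
from zfpk.synthetic_data import (
    KineticParams,
    compartment_amounts,
    make_study,
    permeability,
    simulate_timecourse,
)


class TestPermeability:
    def test_midpoint_is_half(self):
        assert permeability(1.4, logd50=1.4) == pytest.approx(0.5)

    def test_steep_slope_approaches_step_function(self):
        assert permeability(1.5, logd50=1.4, slope=1e4) == pytest.approx(1.0)
        assert permeability(1.3, logd50=1.4, slope=1e4) == pytest.approx(0.0, abs=1e-12)

    def test_default_values_at_panel_extremes(self):
        assert permeability(-1.96) < 1e-5
        assert permeability(1.73) == pytest.approx(0.789, abs=0.001)
        assert permeability(0.46) == pytest.approx(0.0228, abs=0.001)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            permeability(0.0, slope=0.0)


class TestKinetics:
    @pytest.mark.parametrize("route", [Route.IMM, Route.IY])
    def test_mass_balance_wb_equals_yolk_plus_rob(self, route):
        t = np.linspace(0.25, 120, 500)
        yolk, rob, wb = compartment_amounts(KineticParams(), route, 1.0, t)
        np.testing.assert_allclose(wb, yolk + rob, rtol=1e-12)
        assert (yolk >= 0).all() and (rob >= 0).all()

    def test_immersion_uptake_monotone_while_bath_present(self):
        params = KineticParams(k_elim=0.0)
        t = np.linspace(0.25, 72, 300)
        _, _, wb = compartment_amounts(params, Route.IMM, 1.5, t)
        assert (np.diff(wb) >= -1e-12).all()

    def test_washout_stops_immersion_accumulation(self):
        params = KineticParams(k_elim=0.0)
        _, _, wb = compartment_amounts(
            params, Route.IMM, 1.5, np.array([72.0, 96.0])
        )
        assert wb[1] == pytest.approx(wb[0], rel=1e-9)

    def test_late_elimination_reduces_rest_of_body(self):
        params = KineticParams(k_elim=0.05)
        _, rob, _ = compartment_amounts(
            params, Route.IY, 0.0, np.array([96.0, 120.0])
        )
        assert rob[1] < rob[0]

    def test_injected_depot_decays_into_rest_of_body(self):
        t = np.array([0.25, 24.0, 72.0])
        yolk, rob, wb = compartment_amounts(KineticParams(), Route.IY, 0.0, t)
        assert (np.diff(yolk) < 0).all()
        assert (np.diff(rob) > 0).all()
        np.testing.assert_allclose(wb, 1000.0, rtol=1e-12)


class TestSimulateTimecourse:
    def test_seed_determinism_bit_identical(self):
        for seed in (0, 7):
            a = simulate_timecourse(KineticParams(), Route.IY, seed=seed, noise_cv=0.2)
            b = simulate_timecourse(KineticParams(), Route.IY, seed=seed, noise_cv=0.2)
            assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_zero_dose_gives_zero_series(self):
        wb, yolk, rob, _ = simulate_timecourse(
            KineticParams(dose_iy=0.0), Route.IY, seed=0
        )
        assert all(v == 0 for v in wb.rfus + yolk.rfus + rob.rfus)

    def test_impermeant_compound_gives_zero_immersion_series(self):
        params = KineticParams(slope=1e6)  # hard cutoff at logd50
        wb, yolk, rob, truth = simulate_timecourse(
            params, Route.IMM, seed=0, logd=-1.0
        )
        assert all(v == 0 for v in wb.rfus)
        assert truth.auc["WB"] == 0.0

    def test_grid_outside_range_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            simulate_timecourse(KineticParams(), Route.IY, grid=[0.1, 1.0], seed=0)

    def test_observed_tables_satisfy_additivity_exactly(self):
        wb, yolk, rob, _ = simulate_timecourse(
            KineticParams(), Route.IY, seed=3, noise_cv=0.15
        )
        for pw, py, pr in zip(wb.points, yolk.points, rob.points):
            assert pw.rfu == pytest.approx(py.rfu + pr.rfu, rel=1e-12)

    def test_quench_suppresses_only_early_yolk_observations(self):
        clean = simulate_timecourse(
            KineticParams(quench_tau=0.0), Route.IY, seed=0
        )[1]
        quenched = simulate_timecourse(
            KineticParams(quench_tau=1.5), Route.IY, seed=0
        )[1]
        ratios = np.array(quenched.rfus) / np.array(clean.rfus)
        assert ratios[0] < 0.2  # strong suppression at 15 min
        assert ratios[-1] > 0.99  # fully recovered within the window
        assert (np.diff(ratios) > 0).all()

    @pytest.mark.parametrize(
        "route,tol",
        [(Route.IY, 0.01), (Route.IMM, 0.02)],
        ids=["injection", "immersion"],
    )
    def test_noiseless_quenchless_aucs_match_fine_grid_truth(self, route, tol):
        # residual error is 9-point trapezoid vs dense-grid quadrature;
        # the immersion rest-of-body curve is the most curved compartment
        config = AUCConfig()
        wb, yolk, rob, truth = simulate_timecourse(
            KineticParams(quench_tau=0.0), route, seed=0, logd=1.73
        )
        for series, key in ((wb, "WB"), (yolk, "Yolk"), (rob, "RoB")):
            observed = trapezoid_auc(series, config).auc
            assert observed == pytest.approx(truth.auc[key], rel=tol)


class TestMakeStudy:
    def test_truth_manifest_re_pattern_matches_lipophilicity(self, descriptors):
        study = make_study(descriptors, seed=0, noise_cv=0.0)
        re_wb = {name: t.re_wb for name, t in study.truth.items()}
        assert re_wb["CY3A"] > 1.0
        others = [v for k, v in re_wb.items() if k != "CY3A"]
        assert all(v < 1.0 for v in others)

    def test_impermeant_dyes_have_near_zero_relative_exposure(self, descriptors):
        study = make_study(descriptors, seed=0, noise_cv=0.0)
        assert study.truth["S-CY3A"].re_wb < 1e-3
        assert study.truth["S-CY5.5A"].re_wb < 1e-3

    def test_truth_rd_in_realistic_depot_band(self, descriptors):
        study = make_study(descriptors, seed=0, noise_cv=0.0)
        for t in study.truth.values():
            assert 0.17 <= t.rd <= 0.32

    def test_per_compound_redistribution_spread_optional(self, descriptors):
        study = make_study(
            descriptors, seed=1, noise_cv=0.0, redist_range=(0.0055, 0.0114)
        )
        ks = {p.k_redist for p in study.params.values()}
        assert len(ks) == len(descriptors)
        for t in study.truth.values():
            assert 0.17 <= t.rd <= 0.33

    def test_study_is_seed_deterministic(self, descriptors):
        a = make_study(descriptors, seed=9, noise_cv=0.1)
        b = make_study(descriptors, seed=9, noise_cv=0.1)
        assert a.series == b.series
        assert a.truth == b.truth
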