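"""Steady-state solver: conservation, oracles, profiles, calibration."""

import numpy as np
import pandas as pd
import pytest

import discregen as dr
from discregen.geometry import NP_LABEL
from discregen.species_params import BoundaryConditions, BoundaryValues
from discregen.synthetic import GeneratorSpec, generate_probe_dataset
from discregen.transport import SolverSettings, solve_uniform_slab

from conftest import FAST_SETTINGS


def uniform_bc(glucose, oxygen, ph):
    bv = BoundaryValues(glucose=glucose, oxygen=oxygen, ph=ph)
    return BoundaryConditions(periannular=bv, np_cep_interface=bv)


class TestSlabOracle:
    @pytest.mark.parametrize("n,rel_tol", [(40, 1e-9), (160, 1e-9)])
    def test_parabolic_midpoint_deficit(self, n, rel_tol):
        """Zero-order consumption in a 1-D slab with both ends fixed gives the
        closed-form parabola with midpoint deficit Q L^2 / 8 D."""
        L, D, Q, C0 = 2.0, 1.5, 3.0, 10.0
        x, c, _ = solve_uniform_slab(n, L, D, Q, C0)
        exact = C0 - Q / (2 * D) * x * (L - x)
        deficit = C0 - c.min()
        assert deficit == pytest.approx(Q * L**2 / (8 * D), rel=rel_tol)
        assert np.max(np.abs(c - exact)) / C0 < 1e-3

    def test_slab_flux_balance(self):
        _, _, balance = solve_uniform_slab(80, 2.0, 1.5, 3.0, 10.0)
        assert balance < 1e-6


class TestSteadyState:
    def test_zero_consumption_uniform_field(self, rat_params, coarse_rat_grid):
        """With all rates off and identical Dirichlet values everywhere, each
        field is uniformly the boundary value (Laplace with constant BC)."""
        doc = dr.dump_species_parameters(rat_params)
        for dom in ("np", "af"):
            doc["metabolic_rates"][dom]["vmax_o2"]["value"] = 0.0
            doc["metabolic_rates"][dom]["lpr"]["value"] = 0.0
        quiet = dr.load_species_parameters(doc)
        bc = uniform_bc(glucose=4.0, oxygen=50.0, ph=7.2)
        f = dr.solve_steady_state(coarse_rat_grid, quiet, FAST_SETTINGS, boundaries=bc)
        tissue = ~np.isnan(f.glucose)
        assert np.allclose(f.glucose[tissue], 4.0, rtol=1e-9)
        assert np.allclose(f.oxygen[tissue], 50.0, rtol=1e-9)
        # lactate inherits the single boundary value implied by pH 7.2
        assert np.allclose(f.ph[tissue], 7.2, rtol=1e-9)

    def test_flux_balance_at_convergence(self, rat_fields, goat_fields):
        for f in (rat_fields, goat_fields):
            assert max(f.flux_balance.values()) < 1e-6

    def test_fields_positive_and_bounded(self, rat_fields, rat_params):
        tissue = ~np.isnan(rat_fields.glucose)
        assert np.all(rat_fields.glucose[tissue] >= 0)
        assert np.all(rat_fields.oxygen[tissue] >= 0)
        peri = rat_params.boundaries.periannular
        assert rat_fields.glucose[tissue].max() <= peri.glucose * (1 + 1e-9)

    def test_integrated_stoichiometry(self, rat_fields, rat_params):
        cons = rat_fields.total_consumption
        assert cons["lactate"] == pytest.approx(
            rat_params.lactate_glucose_ratio * cons["glucose"], rel=1e-12)

    def test_density_monotonicity(self, rat_params, coarse_rat_grid):
        """More NP cells strictly deepen the central glucose/oxygen deficits
        and lower central pH."""
        f0 = dr.solve_steady_state(coarse_rat_grid, rat_params, FAST_SETTINGS)
        f1 = dr.solve_steady_state(coarse_rat_grid, rat_params, FAST_SETTINGS,
                                   extra_np_density=30e3)
        g0 = dr.central_concentrations(f0, coarse_rat_grid, rat_params.oxygen_solubility)
        g1 = dr.central_concentrations(f1, coarse_rat_grid, rat_params.oxygen_solubility)
        assert g1[0] < g0[0]  # glucose
        assert g1[1] < g0[1]  # pH
        assert g1[2] < g0[2]  # oxygen

    def test_initialization_independence(self, rat_params, coarse_rat_grid):
        """Two different initial guesses converge to the same fields (the
        fixed point is contractive at physiological parameters)."""
        tight = SolverSettings(tolerance=1e-12, relaxation=1.0)
        f1 = dr.solve_steady_state(coarse_rat_grid, rat_params, tight)
        # a second run with different relaxation follows a different iterate
        # path; the fixed point must agree
        f2 = dr.solve_steady_state(
            coarse_rat_grid, rat_params,
            SolverSettings(tolerance=1e-12, relaxation=0.5))
        tissue = ~np.isnan(f1.glucose)
        assert np.allclose(f1.glucose[tissue], f2.glucose[tissue], atol=1e-8)
        assert np.allclose(f1.oxygen[tissue], f2.oxygen[tissue], atol=1e-6)

    def test_mesh_refinement_convergence(self, rat_params):
        """Central concentrations move by < 1% when the default spacing is
        halved (glucose, pH, and oxygen alike)."""
        geo = dr.build_disc_geometry(rat_params.geometry, species="rat")
        vals = {}
        for h in (0.1, 0.05):
            grid = dr.rasterize(geo, h)
            f = dr.solve_steady_state(grid, rat_params, FAST_SETTINGS)
            vals[h] = dr.central_concentrations(f, grid, rat_params.oxygen_solubility)
        for a, b in zip(vals[0.1], vals[0.05]):
            assert abs(a - b) / abs(b) < 0.01

    def test_oxygen_never_evaluated_below_ph_floor(self, rat_fields):
        tissue = ~np.isnan(rat_fields.ph)
        assert np.all(rat_fields.ph[tissue] > 4.95)
        assert not rat_fields.ph_clamped


class TestProfile:
    def test_endpoints_are_boundary_values(self, rat_fields, rat_grid, rat_params):
        prof = dr.extract_ap_profile(rat_fields, rat_grid, rat_params)
        peri = rat_params.boundaries.periannular
        for col, val in (("glucose_mM", peri.glucose), ("ph", peri.ph)):
            assert prof[col].iloc[0] == pytest.approx(val)
            assert prof[col].iloc[-1] == pytest.approx(val)

    def test_symmetric_about_center(self, rat_fields, rat_grid, rat_params):
        prof = dr.extract_ap_profile(rat_fields, rat_grid, rat_params)
        g = prof["glucose_mM"].to_numpy()
        assert np.allclose(g, g[::-1])

    def test_center_matches_central_concentrations(self, rat_fields, rat_grid, rat_params):
        prof = dr.extract_ap_profile(rat_fields, rat_grid, rat_params)
        gluc, ph, o2 = dr.central_concentrations(rat_fields, rat_grid,
                                                 rat_params.oxygen_solubility)
        center = prof.loc[prof["position_mm"] == 0.0].iloc[0]
        assert center["glucose_mM"] == pytest.approx(gluc, rel=1e-12)
        assert center["ph"] == pytest.approx(ph, rel=1e-12)
        assert center["o2_pct"] == pytest.approx(o2, rel=1e-12)

    def test_domains_labeled_outward(self, rat_fields, rat_grid, rat_params):
        prof = dr.extract_ap_profile(rat_fields, rat_grid, rat_params)
        doms = prof["domain"].to_list()
        assert doms[0] == "boundary" and doms[-1] == "boundary"
        assert "np" in doms and "af" in doms
        # np samples are contiguous around the center
        npi = [i for i, d in enumerate(doms) if d == "np"]
        assert npi == list(range(npi[0], npi[-1] + 1))


class TestCalibration:
    def test_zero_noise_recovery(self, rat_params, coarse_rat_grid):
        """Probe data generated by the model at known boundary values is
        inverted back to those values from a perturbed initial guess."""
        truth_bc = rat_params.boundaries
        f = dr.solve_steady_state(coarse_rat_grid, rat_params, FAST_SETTINGS)
        spec = GeneratorSpec(seed=5, probe_cv=0.0, n_discs=1)
        probe, _ = generate_probe_dataset(f, coarse_rat_grid, rat_params, spec)
        wrong = BoundaryConditions(
            periannular=BoundaryValues(
                glucose=truth_bc.periannular.glucose * 1.3,
                oxygen=truth_bc.periannular.oxygen * 0.8,
                ph=truth_bc.periannular.ph + 0.12),
            np_cep_interface=BoundaryValues(
                glucose=truth_bc.np_cep_interface.glucose * 1.3,
                oxygen=truth_bc.np_cep_interface.oxygen * 0.8,
                ph=truth_bc.np_cep_interface.ph + 0.12),
        )
        res = dr.calibrate_boundaries(probe, wrong, coarse_rat_grid, rat_params)
        assert not res.zero_iteration
        got = res.boundaries
        assert got.periannular.glucose == pytest.approx(
            truth_bc.periannular.glucose, rel=1e-2)
        assert got.periannular.oxygen == pytest.approx(
            truth_bc.periannular.oxygen, rel=1e-2)
        assert got.periannular.ph == pytest.approx(truth_bc.periannular.ph, abs=0.01)

    def test_matching_measurements_zero_iterations(self, rat_params, coarse_rat_grid):
        f = dr.solve_steady_state(
            coarse_rat_grid, rat_params,
            SolverSettings(tolerance=1e-8, relaxation=1.0))
        spec = GeneratorSpec(seed=6, probe_cv=0.0, n_discs=1)
        probe, _ = generate_probe_dataset(f, coarse_rat_grid, rat_params, spec)
        res = dr.calibrate_boundaries(probe, rat_params.boundaries,
                                      coarse_rat_grid, rat_params, initial_tol=1e-4)
        assert res.zero_iteration
        assert res.n_solves == 1

    def test_noisy_recovery_within_ten_percent(self, rat_params, coarse_rat_grid):
        """With generator-default probe noise over 3 discs, recovered boundary
        glucose lands within 10% of the generating value."""
        truth_bc = rat_params.boundaries
        f = dr.solve_steady_state(coarse_rat_grid, rat_params, FAST_SETTINGS)
        spec = GeneratorSpec(seed=11, n_discs=3)
        probe, _ = generate_probe_dataset(f, coarse_rat_grid, rat_params, spec)
        wrong = BoundaryConditions(
            periannular=BoundaryValues(
                glucose=truth_bc.periannular.glucose * 1.4,
                oxygen=truth_bc.periannular.oxygen,
                ph=truth_bc.periannular.ph),
            np_cep_interface=BoundaryValues(
                glucose=truth_bc.np_cep_interface.glucose * 1.4,
                oxygen=truth_bc.np_cep_interface.oxygen,
                ph=truth_bc.np_cep_interface.ph),
        )
        res = dr.calibrate_boundaries(probe, wrong, coarse_rat_grid, rat_params,
                                      metabolites=("glucose",))
        assert res.boundaries.periannular.glucose == pytest.approx(
            truth_bc.periannular.glucose, rel=0.10)

    def test_missing_metabolite_rejected(self, rat_params, coarse_rat_grid):
        probe = pd.DataFrame({"disc_id": ["d1"], "metabolite": ["glucose"],
                              "value": [2.0], "location": ["central"]})
        with pytest.raises(Exception, match="oxygen"):
            dr.calibrate_boundaries(probe, rat_params.boundaries,
                                    coarse_rat_grid, rat_params)
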