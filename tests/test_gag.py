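"""GAG turnover: injury arithmetic, rate law, exact integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from discregen.gag import (
    InjectionScenario,
    InjuryModel,
    RegenerationError,
    RegenerationState,
    apply_injection,
    apply_injury,
    gag_rate,
    homeostatic_lambda1,
    lambda1_to_canonical,
    normalize_trajectory,
    simulate_gag,
)
from discregen.species_params import GagParameters
from discregen.units import HOURS_PER_YEAR


def make_gag_params(synthesis=9.08, half_life_years=11.0):
    return GagParameters(
        native_content_dw={"np": 335.0, "af": 95.0},
        degenerated_content_vol={"np": 47.4, "af": 26.9},
        synthesis_rate=synthesis,
        half_life=half_life_years * HOURS_PER_YEAR,
        dw_conversion=0.283,
        reference_content_vol=94.805,
    )


def healthy_state(np_gag=94.805, rho=6e3):
    return RegenerationState(np_gag=np_gag, af_gag=26.9, rho_res_np=rho,
                             rho_inj_np=0.0, rho_af=16e3)


class TestInjury:
    def test_rat_severity(self):
        # complete GAG loss + 75% cellularity loss
        state = healthy_state(np_gag=26.9416, rho=94e3)
        injured = apply_injury(state, InjuryModel(1.0, 0.75))
        assert injured.np_gag == 0.0
        assert injured.rho_res_np == pytest.approx(0.25 * 94e3)
        assert injured.af_gag == state.af_gag  # AF untouched

    def test_identity(self):
        state = healthy_state()
        assert apply_injury(state, InjuryModel(0.0, 0.0)) == state

    def test_goat_severity_reproduces_printed_content(self):
        # native 335 ug/mg DW, 50% loss, DW factor 0.283 -> 47.4 ug/mm^3
        state = healthy_state(np_gag=335.0 * 0.283)
        injured = apply_injury(state, InjuryModel(0.5, 0.5))
        assert injured.np_gag == pytest.approx(47.4, abs=0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(RegenerationError):
            InjuryModel(1.5, 0.0)


class TestInjection:
    def test_zero_cells_identity(self):
        state = healthy_state()
        new, frac = apply_injection(state, InjectionScenario(0), 555.6, rho_ref=6e3)
        assert new == state
        assert frac == 0.0

    def test_sequential_additivity(self):
        state = healthy_state()
        v = 555.6
        one, _ = apply_injection(state, InjectionScenario(2e6), v, rho_ref=6e3)
        a, _ = apply_injection(state, InjectionScenario(1e6), v, rho_ref=6e3)
        two, _ = apply_injection(a, InjectionScenario(1e6), v, rho_ref=6e3)
        assert two.rho_inj_np == pytest.approx(one.rho_inj_np, rel=1e-12)

    def test_goat_dose_fraction(self, goat_params):
        import discregen as dr

        geo = dr.build_disc_geometry(goat_params.geometry, species="goat")
        state = healthy_state()
        _, frac = apply_injection(state, InjectionScenario(5.5e6), geo.np_volume,
                                  rho_ref=goat_params.cell_densities.np_density)
        assert frac == pytest.approx(165.0, rel=1e-3)


class TestRateLaw:
    def test_homeostatic_closure_zero_rate(self):
        p = make_gag_params()
        lam1 = homeostatic_lambda1(94.805, 6e3, p.lambda2_per_h)
        state = healthy_state()
        assert gag_rate(state, p, lambda1_pg_cell_day=lam1) == pytest.approx(0.0, abs=1e-18)

    def test_empty_state_zero_rate(self):
        p = make_gag_params()
        state = RegenerationState(np_gag=0.0, af_gag=0.0, rho_res_np=0.0,
                                  rho_inj_np=0.0, rho_af=0.0)
        assert gag_rate(state, p) == 0.0

    def test_linear_in_density(self):
        p = make_gag_params()
        s1 = healthy_state(np_gag=0.0, rho=5e3)
        s2 = healthy_state(np_gag=0.0, rho=10e3)
        assert gag_rate(s2, p) == pytest.approx(2 * gag_rate(s1, p), rel=1e-12)

    def test_homeostatic_lambda1_proportional_in_c0(self):
        p = make_gag_params()
        a = homeostatic_lambda1(50.0, 6e3, p.lambda2_per_h)
        b = homeostatic_lambda1(100.0, 6e3, p.lambda2_per_h)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_goat_measured_vs_homeostatic_ratio(self):
        """The measured goat synthesis rate exceeds the homeostatic closure
        value by a large factor -- regenerating cells out-synthesize the
        equilibrium requirement (no equality is expected)."""
        p = make_gag_params()
        lam1_h = homeostatic_lambda1(94.805, 6e3, p.lambda2_per_h)
        ratio = 9.08 / lam1_h
        assert ratio > 1.0

    def test_zero_density_rejected(self):
        with pytest.raises(RegenerationError):
            homeostatic_lambda1(50.0, 0.0, 1e-5)


class TestIntegration:
    @given(
        lam1=st.floats(min_value=0.0, max_value=20.0),
        rho=st.floats(min_value=0.0, max_value=1e5),
        c0=st.floats(min_value=0.0, max_value=200.0),
        tau_years=st.floats(min_value=1.0, max_value=30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_closed_form(self, lam1, rho, c0, tau_years):
        """Integrator output equals c_ss + (c0 - c_ss) e^(-lambda2 t) to
        better than 1e-6 relative across random parameter draws."""
        p = make_gag_params(synthesis=lam1, half_life_years=tau_years)
        state = RegenerationState(np_gag=c0, af_gag=0.0, rho_res_np=rho,
                                  rho_inj_np=0.0, rho_af=0.0)
        horizon = 5.0 * HOURS_PER_YEAR
        traj = simulate_gag(state, p, horizon_h=horizon, step_h=horizon / 50)
        lam2 = p.lambda2_per_h
        c_ss = lambda1_to_canonical(lam1) * rho / lam2
        for s in traj:
            exact = c_ss + (c0 - c_ss) * math.exp(-lam2 * s.time_h)
            assert s.np_gag == pytest.approx(exact, rel=1e-6, abs=1e-12)

    def test_cell_free_half_life(self):
        """Without cells, GAG halves in exactly one half-life (11 years)."""
        p = make_gag_params()
        state = RegenerationState(np_gag=80.0, af_gag=0.0, rho_res_np=0.0,
                                  rho_inj_np=0.0, rho_af=0.0)
        tau = p.half_life
        traj = simulate_gag(state, p, horizon_h=tau, step_h=tau / 4)
        assert traj[-1].time_h == pytest.approx(tau)
        assert traj[-1].np_gag == pytest.approx(40.0, rel=1e-12)

    def test_equilibrium_stays_constant(self):
        p = make_gag_params()
        lam1 = homeostatic_lambda1(94.805, 6e3, p.lambda2_per_h)
        p_eq = make_gag_params(synthesis=lam1)
        traj = simulate_gag(healthy_state(), p_eq,
                            horizon_h=10 * HOURS_PER_YEAR, step_h=HOURS_PER_YEAR)
        for s in traj:
            assert s.np_gag == pytest.approx(94.805, rel=1e-12)

    def test_long_run_limit(self):
        """c(t) -> lambda1 rho / lambda2 from any start (checked at 100
        half-lives)."""
        p = make_gag_params()
        lam2 = p.lambda2_per_h
        c_ss = lambda1_to_canonical(p.synthesis_rate) * 6e3 / lam2
        for c0 in (0.0, 50.0, 400.0):
            state = RegenerationState(np_gag=c0, af_gag=0.0, rho_res_np=6e3,
                                      rho_inj_np=0.0, rho_af=0.0)
            traj = simulate_gag(state, p, horizon_h=100 * p.half_life,
                                step_h=10 * p.half_life)
            assert traj[-1].np_gag == pytest.approx(c_ss, rel=1e-9)

    def test_dose_monotone_in_cells(self):
        p = make_gag_params()
        results = []
        for n in (0.0, 1e6, 5.5e6):
            state = healthy_state(np_gag=47.4, rho=3e3)
            state, _ = apply_injection(state, InjectionScenario(n), 555.6, rho_ref=6e3)
            traj = simulate_gag(state, p, horizon_h=HOURS_PER_YEAR,
                                step_h=HOURS_PER_YEAR / 12)
            results.append(np.array([s.np_gag for s in traj]))
        assert np.all(results[1] >= results[0])
        assert np.all(results[2][1:] > results[1][1:])

    def test_invalid_steps_rejected(self):
        p = make_gag_params()
        with pytest.raises(RegenerationError):
            simulate_gag(healthy_state(), p, horizon_h=-1.0, step_h=1.0)
        with pytest.raises(RegenerationError):
            simulate_gag(healthy_state(), p, horizon_h=1.0, step_h=2.0)


class TestNormalization:
    def test_reference_is_hundred_percent(self):
        traj = [healthy_state(np_gag=94.805)]
        assert normalize_trajectory(traj, 94.805)[0] == pytest.approx(100.0)

    def test_preserves_ordering(self):
        lo = [healthy_state(np_gag=40.0)]
        hi = [healthy_state(np_gag=60.0)]
        assert normalize_trajectory(hi, 94.805)[0] > normalize_trajectory(lo, 94.805)[0]

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(RegenerationError):
            normalize_trajectory([healthy_state()], 0.0)
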