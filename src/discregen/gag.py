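"""Temporal GAG turnover: synthesis vs first-order degradation.

Per tissue compartment the GAG content c (ug/mm^3) obeys

    dc/dt = lambda1 * rho - lambda2 * c,

where lambda1 is the measured per-cell synthesis rate (pg/cell/day),
rho the viable cell density (resident + injected, cells/mm^3) and
lambda2 = ln 2 / tau the degradation rate from the GAG half-life
(tau = 11 years, species-independent).  With constant densities the ODE is
linear, so integration uses the exact exponential update

    c(t) = c_ss + (c0 - c_ss) exp(-lambda2 t),    c_ss = lambda1 rho / lambda2.

The advective term of the underlying conservation law (solid-matrix
velocity v_s) is retained in the state for forward compatibility but fixed
at zero: the simulated scenarios involve no matrix motion, which reduces
the field equation to independent per-compartment ODEs.

A healthy disc is in homeostasis: lambda1 = lambda2 * c0 / rho0 makes the
net rate vanish at the native state (this closure supplies the AF synthesis
rate, which is not measured).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .units import HOURS_PER_DAY
from .species_params import GagParameters, dose_fraction

__all__ = [
    "RegenerationError",
    "InjuryModel",
    "InjectionScenario",
    "RegenerationState",
    "apply_injury",
    "apply_injection",
    "gag_rate",
    "homeostatic_lambda1",
    "simulate_gag",
    "normalize_trajectory",
    "lambda1_to_canonical",
]

PG_PER_UG = 1.0e6


class RegenerationError(ValueError):
    pass


def lambda1_to_canonical(lambda1_pg_cell_day: float) -> float:
    """pg/cell/day -> ug/cell/h (the unit the volumetric rate law uses)."""
    return lambda1_pg_cell_day / PG_PER_UG / HOURS_PER_DAY


@dataclass(frozen=True)
class InjuryModel:
    """Fractional NP damage: GAG removed and resident cells lost."""

    gag_reduction: float
    cellularity_reduction: float

    def __post_init__(self) -> None:
        for name in ("gag_reduction", "cellularity_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise RegenerationError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class InjectionScenario:
    """Uniform-in-NP delivery of cells sharing the resident phenotype."""

    n_cells: float
    shares_resident_phenotype: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise RegenerationError("injected cell count must be non-negative")


@dataclass(frozen=True)
class RegenerationState:
    """Compartment GAG contents and cell densities at one time point."""

    np_gag: float  # ug/mm^3
    af_gag: float  # ug/mm^3
    rho_res_np: float  # cells/mm^3
    rho_inj_np: float  # cells/mm^3
    rho_af: float  # cells/mm^3
    time_h: float = 0.0
    vs: float = 0.0  # solid-matrix velocity (mm/h); scenarios use 0

    def __post_init__(self) -> None:
        if self.np_gag < 0 or self.af_gag < 0:
            raise RegenerationError("GAG contents must be non-negative")
        if min(self.rho_res_np, self.rho_inj_np, self.rho_af) < 0:
            raise RegenerationError("cell densities must be non-negative")

    @property
    def rho_np(self) -> float:
        return self.rho_res_np + self.rho_inj_np


def apply_injury(healthy: RegenerationState, injury: InjuryModel) -> RegenerationState:
    """Remove NP GAG and resident NP cells by the configured fractions; the
    AF is untouched."""
    return replace(
        healthy,
        np_gag=(1.0 - injury.gag_reduction) * healthy.np_gag,
        rho_res_np=(1.0 - injury.cellularity_reduction) * healthy.rho_res_np,
    )


def apply_injection(state: RegenerationState, scenario: InjectionScenario,
                    v_np: float, rho_ref: float | None = None
                    ) -> tuple[RegenerationState, float]:
    """Add ``n_cells / v_np`` to the injected NP density (uniform in NP).

    Returns the updated state and the dose fraction (percent of the
    reference population ``rho_ref * v_np``; default reference is the
    current resident density which only makes sense for healthy states, so
    callers normally pass the species' healthy or pre-treatment density).
    """
    if v_np <= 0:
        raise RegenerationError("NP volume must be positive")
    new = replace(state, rho_inj_np=state.rho_inj_np + scenario.n_cells / v_np)
    ref = rho_ref if rho_ref is not None else state.rho_res_np
    frac = dose_fraction(scenario.n_cells, ref, v_np) if ref > 0 else math.nan
    return new, frac


def gag_rate(state: RegenerationState, params: GagParameters,
             lambda1_pg_cell_day: float | None = None) -> float:
    """Net volumetric NP GAG rate (ug/mm^3 per h): lambda1*rho - lambda2*c."""
    lam1 = lambda1_to_canonical(
        params.synthesis_rate if lambda1_pg_cell_day is None else lambda1_pg_cell_day)
    return lam1 * state.rho_np - params.lambda2_per_h * state.np_gag


def homeostatic_lambda1(c0: float, rho0: float, lambda2_per_h: float) -> float:
    """Synthesis rate (pg/cell/day) that closes the healthy balance.

    lambda1 = lambda2 * c0 / rho0; plugging it into the rate law at
    (c0, rho0) yields zero net rate by construction.
    """
    if rho0 <= 0:
        raise RegenerationError("healthy cell density must be positive")
    if c0 < 0 or lambda2_per_h < 0:
        raise RegenerationError("c0 and lambda2 must be non-negative")
    return lambda2_per_h * c0 / rho0 * PG_PER_UG * HOURS_PER_DAY


def _exact_trajectory(c0: float, rho: float, lam1_ug_cell_h: float,
                      lam2: float, times_h: np.ndarray) -> np.ndarray:
    c_ss = lam1_ug_cell_h * rho / lam2
    return c_ss + (c0 - c_ss) * np.exp(-lam2 * times_h)


def simulate_gag(
    initial: RegenerationState,
    params: GagParameters,
    horizon_h: float,
    step_h: float,
    af_lambda1_pg_cell_day: float | None = None,
    np_lambda1_pg_cell_day: float | None = None,
) -> list[RegenerationState]:
    """Integrate compartment GAG with constant densities.

    Uses the exact exponential update per step (the ODE is linear), so the
    sampled trajectory matches the closed form to machine precision.  The
    NP uses the measured species lambda1 unless ``np_lambda1_pg_cell_day``
    overrides it (healthy baselines pass the homeostatic closure so the
    native state stays in equilibrium); the AF uses
    ``af_lambda1_pg_cell_day`` when given, else the homeostatic closure at
    its initial state (a healthy AF stays constant).  Returns states at
    0, step, 2*step, ..., horizon (the horizon is included even if not a
    step multiple).
    """
    if horizon_h <= 0 or step_h <= 0:
        raise RegenerationError("horizon and step must be positive")
    if step_h > horizon_h:
        raise RegenerationError("step must not exceed the horizon")
    lam2 = params.lambda2_per_h
    lam1_np = lambda1_to_canonical(
        params.synthesis_rate if np_lambda1_pg_cell_day is None
        else np_lambda1_pg_cell_day)
    if af_lambda1_pg_cell_day is not None:
        lam1_af = lambda1_to_canonical(af_lambda1_pg_cell_day)
    elif initial.rho_af > 0:
        lam1_af = lam2 * initial.af_gag / initial.rho_af  # homeostatic closure
    else:
        lam1_af = 0.0

    n_steps = int(math.ceil(horizon_h / step_h - 1e-12))
    times = np.minimum(np.arange(n_steps + 1) * step_h, horizon_h)
    if times[-1] < horizon_h:
        times = np.append(times, horizon_h)
    np_traj = _exact_trajectory(initial.np_gag, initial.rho_np, lam1_np, lam2, times)
    af_traj = _exact_trajectory(initial.af_gag, initial.rho_af, lam1_af, lam2, times)
    return [
        replace(initial, np_gag=float(cn), af_gag=float(ca),
                time_h=initial.time_h + float(t))
        for t, cn, ca in zip(times, np_traj, af_traj)
    ]


def normalize_trajectory(trajectory: list[RegenerationState],
                         reference: float) -> np.ndarray:
    """NP GAG as percent of *reference* (native NP for animals, the
    less-degenerated grade for human)."""
    if reference <= 0:
        raise RegenerationError("normalization reference must be positive")
    return np.array([100.0 * s.np_gag / reference for s in trajectory])
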