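"""Shared fixtures: species parameters, grids, and solved steady states.

Heavy objects (rasterized grids, converged nutrient fields, the human dose
sweep) are session-scoped so the suite performs each expensive solve once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import discregen as dr
from discregen.transport import SolverSettings

# property tests are deterministic: same examples on every run and machine
hyp_settings.register_profile("deterministic", derandomize=True, deadline=None,
                              database=None)
hyp_settings.load_profile("deterministic")

# the shipped default resolutions: fine enough for the 8-voxel NP criterion
# and for <1% central-value mesh convergence, coarse enough that every solve
# takes at most a few seconds
SPACINGS = {"rat": 0.1, "goat": 0.3, "human_grade3": 0.7}
COARSE_RAT_SPACING = 0.21  # calibration experiments re-solve dozens of times

FAST_SETTINGS = SolverSettings(tolerance=1.0e-9, relaxation=1.0)


@pytest.fixture(scope="session")
def rat_params():
    return dr.load_species_parameters(dr.builtin_config_path("rat"))


@pytest.fixture(scope="session")
def goat_params():
    return dr.load_species_parameters(dr.builtin_config_path("goat"))


@pytest.fixture(scope="session")
def human_params():
    return dr.load_species_parameters(dr.builtin_config_path("human_grade3"))


@pytest.fixture(scope="session")
def all_params(rat_params, goat_params, human_params):
    return {"rat": rat_params, "goat": goat_params, "human_grade3": human_params}


def _grid_for(params):
    geo = dr.build_disc_geometry(params.geometry, species=params.species)
    return geo, dr.rasterize(geo, SPACINGS[params.species])


@pytest.fixture(scope="session")
def rat_grid(rat_params):
    return _grid_for(rat_params)[1]


@pytest.fixture(scope="session")
def goat_grid(goat_params):
    return _grid_for(goat_params)[1]


@pytest.fixture(scope="session")
def rat_fields(rat_params, rat_grid):
    return dr.solve_steady_state(rat_grid, rat_params)


@pytest.fixture(scope="session")
def goat_fields(goat_params, goat_grid):
    return dr.solve_steady_state(goat_grid, goat_params)


@pytest.fixture(scope="session")
def coarse_rat_grid(rat_params):
    geo = dr.build_disc_geometry(rat_params.geometry, species="rat")
    return dr.rasterize(geo, COARSE_RAT_SPACING)


@pytest.fixture(scope="session")
def human_dose_sweep(human_params):
    from discregen.scenario import run_dose_sweep

    doses = [0, 1e6, 5e6, 10e6, 20e6, 40e6]
    return run_dose_sweep(
        {"species": human_params, "horizon_years": 10.0,
         "spacing_mm": SPACINGS["human_grade3"]},
        doses,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20230907)
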