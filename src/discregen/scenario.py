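"""End-to-end scenario runs: injury -> injection -> solve -> regeneration.

A scenario document names a species configuration plus a treatment block
(initial state, injected cell number, horizon) and run controls (grid
spacing, solver settings).  ``run_scenario`` executes

    geometry -> initial state -> injection -> steady-state nutrient solve
             -> temporal GAG simulation -> report

deterministically, and ``run_dose_sweep`` repeats it over a dose list
reusing the rasterized grid.  Reports carry the central microenvironment,
anterior-posterior profiles, the normalized GAG trajectory, minimum-NP
metabolite levels, and interpretive microenvironmental floor flags
(flags only — a dose is never rejected automatically).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import gag as gag_mod
from .geometry import NP_LABEL, LabeledGrid, build_disc_geometry, rasterize
from .species_params import (
    SpeciesParameters,
    dose_fraction,
    load_species_parameters,
    builtin_config_path,
)
from .transport import (
    SolverSettings,
    central_concentrations,
    extract_ap_profile,
    solve_steady_state,
)
from .units import years_to_hours

__all__ = [
    "ScenarioError",
    "ScenarioReport",
    "DEFAULT_FLOORS",
    "run_scenario",
    "run_dose_sweep",
    "time_to_threshold",
    "export_report",
    "import_report",
    "validate_summary",
]

REPORT_SCHEMA_VERSION = 1

# interpretive microenvironmental floors (glucose mM, pH, oxygen %O2);
# values below any floor flag the dose as stressing the niche
DEFAULT_FLOORS = {"glucose": 0.5, "ph": 6.8, "oxygen": 1.0}

_DEFAULT_SPACING = {"rat": 0.1, "goat": 0.3, "human_grade3": 0.7}


class ScenarioError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"scenario stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ScenarioReport:
    """Everything one configured run produced."""

    species: str
    dose_cells: float
    dose_fraction_pct: float
    initial_state: str  # "healthy" or "degenerated"
    spacing_mm: float
    horizon_years: float
    central_glucose_mM: float
    central_ph: float
    central_o2_pct: float
    min_np: dict[str, float]  # minimum glucose mM / pH / oxygen %O2 in the NP
    threshold_flags: dict[str, bool]
    floors: dict[str, float]
    ap_profile: pd.DataFrame = field(compare=False)
    times_years: np.ndarray = field(compare=False)
    gag_ug_mm3: np.ndarray = field(compare=False)
    gag_pct: np.ndarray = field(compare=False)
    reference_content: float = 0.0
    provenance: dict[str, str] = field(default_factory=dict, compare=False)


def _load_params(spec: Any) -> SpeciesParameters:
    if isinstance(spec, SpeciesParameters):
        return spec
    if isinstance(spec, str) and not Path(spec).exists() and "\n" not in spec:
        return load_species_parameters(builtin_config_path(spec))
    return load_species_parameters(spec)


def _initial_state(params: SpeciesParameters, kind: str) -> gag_mod.RegenerationState:
    g = params.gag
    dens = params.cell_densities
    if kind == "healthy":
        return gag_mod.RegenerationState(
            np_gag=g.native_content_dw["np"] * g.dw_conversion,
            af_gag=g.native_content_dw["af"] * g.dw_conversion,
            rho_res_np=dens.np_density,
            rho_inj_np=0.0,
            rho_af=dens.af_density,
        )
    if kind == "degenerated":
        return gag_mod.RegenerationState(
            np_gag=g.degenerated_content_vol["np"],
            af_gag=g.degenerated_content_vol["af"],
            rho_res_np=(1.0 - params.injury_cellularity_reduction) * dens.np_density,
            rho_inj_np=0.0,
            rho_af=dens.af_density,
        )
    raise ValueError(f"unknown initial state {kind!r}")


def _np_minima(fields, grid: LabeledGrid, solubility: float) -> dict[str, float]:
    mask = grid.labels == NP_LABEL
    return {
        "glucose": float(np.nanmin(fields.glucose[mask])),
        "ph": float(np.nanmin(fields.ph[mask])),
        "oxygen": float(np.nanmin(fields.oxygen[mask])) / solubility,
    }


def run_scenario(config: Mapping[str, Any],
                 _grid: LabeledGrid | None = None) -> ScenarioReport:
    """Execute one scenario document; deterministic for a fixed config.

    Keys: ``species`` (name of a shipped config, path, or mapping),
    ``initial_state`` ("healthy" | "degenerated", default degenerated),
    ``dose_cells`` (default 0), ``horizon_years`` (default 1),
    ``step_years`` (default horizon/120), ``spacing_mm`` (default
    per-species), ``floors`` (override DEFAULT_FLOORS), ``solver``
    (SolverSettings overrides).  Stage failures propagate as
    :class:`ScenarioError` naming the stage.
    """
    try:
        params = _load_params(config["species"])
    except Exception as e:  # noqa: BLE001 - stage attribution is the contract
        raise ScenarioError("load_parameters", e) from e

    initial_kind = str(config.get("initial_state", "degenerated"))
    dose = float(config.get("dose_cells", 0.0))
    horizon_y = float(config.get("horizon_years", 1.0))
    step_y = float(config.get("step_years", horizon_y / 120.0))
    spacing = float(config.get("spacing_mm",
                               _DEFAULT_SPACING.get(params.species, 0.5)))
    floors = {**DEFAULT_FLOORS, **dict(config.get("floors", {}))}
    settings = SolverSettings(**dict(config.get("solver", {})))

    try:
        geometry = build_disc_geometry(params.geometry, species=params.species)
        grid = _grid if _grid is not None else rasterize(geometry, spacing)
    except Exception as e:
        raise ScenarioError("geometry", e) from e

    try:
        state = _initial_state(params, initial_kind)
        v_np = geometry.np_volume
        state, frac = gag_mod.apply_injection(
            state, gag_mod.InjectionScenario(n_cells=dose), v_np,
            rho_ref=params.dose_reference_density)
        if dose == 0:
            frac = 0.0
    except Exception as e:
        raise ScenarioError("injection", e) from e

    try:
        extra = state.rho_np - params.cell_densities.np_density
        fields = solve_steady_state(grid, params, settings, extra_np_density=extra)
        gluc, ph, o2 = central_concentrations(fields, grid, params.oxygen_solubility)
        minima = _np_minima(fields, grid, params.oxygen_solubility)
        profile = extract_ap_profile(fields, grid, params)
    except Exception as e:
        raise ScenarioError("steady_state", e) from e

    try:
        # a healthy disc is in homeostasis: resident synthesis balances
        # turnover exactly (the measured lambda1 drives regeneration runs)
        np_lam1 = None
        if initial_kind == "healthy" and state.rho_np > 0:
            np_lam1 = gag_mod.homeostatic_lambda1(
                state.np_gag, state.rho_np, params.gag.lambda2_per_h)
        traj = gag_mod.simulate_gag(state, params.gag,
                                    horizon_h=years_to_hours(horizon_y),
                                    step_h=years_to_hours(step_y),
                                    np_lambda1_pg_cell_day=np_lam1)
        ref = params.gag.reference_content_vol
        pct = gag_mod.normalize_trajectory(traj, ref)
        times_y = np.array([(s.time_h) for s in traj]) / years_to_hours(1.0)
        contents = np.array([s.np_gag for s in traj])
    except Exception as e:
        raise ScenarioError("gag_simulation", e) from e

    flags = {
        "glucose": minima["glucose"] < floors["glucose"],
        "ph": minima["ph"] < floors["ph"],
        "oxygen": minima["oxygen"] < floors["oxygen"],
    }
    return ScenarioReport(
        species=params.species,
        dose_cells=dose,
        dose_fraction_pct=frac,
        initial_state=initial_kind,
        spacing_mm=spacing,
        horizon_years=horizon_y,
        central_glucose_mM=gluc,
        central_ph=ph,
        central_o2_pct=o2,
        min_np=minima,
        threshold_flags=flags,
        floors=floors,
        ap_profile=profile,
        times_years=times_y,
        gag_ug_mm3=contents,
        gag_pct=pct,
        reference_content=ref,
        provenance=dict(params.provenance),
    )


def run_dose_sweep(config: Mapping[str, Any], doses) -> list[ScenarioReport]:
    """One report per dose; the rasterized grid is shared across doses."""
    doses = list(doses)
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    if not doses:
        return []
    params = _load_params(config["species"])
    spacing = float(config.get("spacing_mm",
                               _DEFAULT_SPACING.get(params.species, 0.5)))
    geometry = build_disc_geometry(params.geometry, species=params.species)
    grid = rasterize(geometry, spacing)
    base = dict(config)
    base["species"] = params  # avoid re-loading per dose
    out = []
    for d in doses:
        cfg = dict(base)
        cfg["dose_cells"] = float(d)
        out.append(run_scenario(cfg, _grid=grid))
    return out


def time_to_threshold(report: ScenarioReport, threshold_pct: float) -> float:
    """First time (years) the normalized GAG trajectory reaches a threshold.

    Linear interpolation between samples; 0.0 if the run starts at or above
    the threshold; ``math.inf`` ("not reached") if the trajectory never
    attains it within the horizon and is not heading above it.
    """
    pct = report.gag_pct
    t = report.times_years
    if pct.size == 0:
        raise ValueError("empty trajectory")
    if pct[0] >= threshold_pct:
        return 0.0
    above = np.nonzero(pct >= threshold_pct)[0]
    if above.size == 0:
        return math.inf
    i = int(above[0])
    t0, t1, p0, p1 = t[i - 1], t[i], pct[i - 1], pct[i]
    if p1 == p0:
        return float(t1)
    return float(t0 + (threshold_pct - p0) * (t1 - t0) / (p1 - p0))


# --------------------------------------------------------------------------
# report I/O

_SUMMARY_REQUIRED = {
    "schema_version": int,
    "species": str,
    "dose_cells": (int, float),
    "dose_fraction_pct": (int, float),
    "initial_state": str,
    "spacing_mm": (int, float),
    "horizon_years": (int, float),
    "central_glucose_mM": (int, float),
    "central_ph": (int, float),
    "central_o2_pct": (int, float),
    "min_np": dict,
    "threshold_flags": dict,
    "floors": dict,
    "reference_content": (int, float),
}


def validate_summary(summary: Mapping[str, Any]) -> None:
    """Check a summary JSON object against the shipped schema; raises on
    missing keys, wrong types, or an unknown schema version."""
    for key, typ in _SUMMARY_REQUIRED.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} has wrong type")
    if summary["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {summary['schema_version']}")


def export_report(report: ScenarioReport, destination: str | Path) -> dict[str, Path]:
    """Write summary JSON + trajectory/profile CSVs; returns written paths."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    summary = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "species": report.species,
        "dose_cells": report.dose_cells,
        "dose_fraction_pct": report.dose_fraction_pct,
        "initial_state": report.initial_state,
        "spacing_mm": report.spacing_mm,
        "horizon_years": report.horizon_years,
        "central_glucose_mM": report.central_glucose_mM,
        "central_ph": report.central_ph,
        "central_o2_pct": report.central_o2_pct,
        "min_np": report.min_np,
        "threshold_flags": report.threshold_flags,
        "floors": report.floors,
        "reference_content": report.reference_content,
    }
    validate_summary(summary)
    paths = {
        "summary": dest / "summary.json",
        "trajectory": dest / "trajectory.csv",
        "profile": dest / "ap_profile.csv",
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    pd.DataFrame({
        "time_years": report.times_years,
        "gag_ug_mm3": report.gag_ug_mm3,
        "pct_of_reference": report.gag_pct,
        "dose_cells": report.dose_cells,
    }).to_csv(paths["trajectory"], index=False)
    report.ap_profile.to_csv(paths["profile"], index=False)
    return paths


def import_report(destination: str | Path) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Re-read an exported report: (summary, trajectory, profile)."""
    dest = Path(destination)
    summary = json.loads((dest / "summary.json").read_text())
    validate_summary(summary)
    trajectory = pd.read_csv(dest / "trajectory.csv")
    profile = pd.read_csv(dest / "ap_profile.csv")
    return summary, trajectory, profile
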