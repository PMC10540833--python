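"""Species parameter sets: loading, validation, unit conversion.

A species configuration is a YAML document in which **every numeric leaf
carries a ``units:`` annotation and a ``source:`` provenance tag**.  The
loader converts everything to the package's canonical unit system (see
:mod:`discregen.units`), rejects unknown keys, and returns an immutable
:class:`SpeciesParameters`.

Provenance vocabulary: ``table1``, ``table2``, ``measured`` (quantified in
the originating study), ``derived`` (back-computed or tuned to printed
anchors), ``literature`` (external sources), ``calibrated`` (produced by the
boundary-calibration procedure against in vivo probe targets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .units import HOURS_PER_YEAR, UnitError, to_canonical

__all__ = [
    "ValidationError",
    "DiffusionTensor",
    "MetabolicRates",
    "GagParameters",
    "CellDensities",
    "BoundaryValues",
    "BoundaryConditions",
    "PhCoupling",
    "SpeciesParameters",
    "load_species_parameters",
    "dump_species_parameters",
    "builtin_config_path",
    "half_life_to_decay_rate",
    "convert_dw_to_volume",
    "dose_fraction",
    "oxygen_percent_to_concentration",
    "oxygen_concentration_to_percent",
]

PH_FLOOR = 4.95  # oxygen kinetics validity floor (numerator offset)

_SOURCES = {"table1", "table2", "measured", "derived", "literature", "calibrated"}


class ValidationError(ValueError):
    """A configuration value failed validation; the message names the key."""


@dataclass(frozen=True)
class DiffusionTensor:
    """Effective diffusivity (mm^2/h): axial along the spine axis, radial in-plane."""

    axial: float
    radial: float

    def __post_init__(self) -> None:
        if self.axial <= 0 or self.radial <= 0:
            raise ValidationError(
                f"diffusivity must be strictly positive, got axial={self.axial}, "
                f"radial={self.radial}"
            )

    @property
    def isotropic(self) -> bool:
        return self.axial == self.radial


@dataclass(frozen=True)
class MetabolicRates:
    """Per-cell-population kinetics (nmol per 10^6 cells per h; Km in uM)."""

    vmax_o2: float
    lpr: float
    km_o2: float

    def __post_init__(self) -> None:
        for name in ("vmax_o2", "lpr", "km_o2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def vmax_gluc(self) -> float:
        """Maximal glucose consumption: LPR / 2 (2:1 lactate:glucose)."""
        return self.lpr / 2.0


@dataclass(frozen=True)
class GagParameters:
    """GAG turnover constants.

    ``native_content_dw``/``degenerated_content_vol`` are per-domain (NP, AF);
    ``synthesis_rate`` (lambda1) is measured for NP cells only; ``half_life``
    is stored in hours; ``reference_content_vol`` is the normalization
    reference for reported trajectories (native NP for animals, the
    less-degenerated human grade for human).
    """

    native_content_dw: dict[str, float]  # ug/mg DW
    degenerated_content_vol: dict[str, float]  # ug/mm^3
    synthesis_rate: float  # pg/cell/day (lambda1)
    half_life: float  # h
    dw_conversion: float  # mg DW/mm^3
    reference_content_vol: float  # ug/mm^3

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValidationError("half_life must be positive")
        for name in ("synthesis_rate", "dw_conversion", "reference_content_vol"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for mapping in (self.native_content_dw, self.degenerated_content_vol):
            for dom, v in mapping.items():
                if v < 0:
                    raise ValidationError(f"GAG content for {dom} must be non-negative")

    @property
    def lambda2_per_h(self) -> float:
        return half_life_to_decay_rate(self.half_life)

    @property
    def lambda2_per_year(self) -> float:
        return self.lambda2_per_h * HOURS_PER_YEAR

    @property
    def half_life_years(self) -> float:
        return self.half_life / HOURS_PER_YEAR


@dataclass(frozen=True)
class CellDensities:
    """Metabolically active cell densities (cells/mm^3)."""

    np_density: float
    af_density: float

    def __post_init__(self) -> None:
        for name in ("np_density", "af_density"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and non-negative")


@dataclass(frozen=True)
class BoundaryValues:
    """Dirichlet metabolite values on one boundary route."""

    glucose: float  # mM
    oxygen: float  # uM
    ph: float

    def __post_init__(self) -> None:
        if self.glucose < 0:
            raise ValidationError("boundary glucose must be non-negative")
        if self.oxygen < 0:
            raise ValidationError("boundary oxygen must be non-negative")
        if not (PH_FLOOR < self.ph < 9.0):
            raise ValidationError(
                f"boundary pH {self.ph} outside validity window ({PH_FLOOR}, 9.0)"
            )


@dataclass(frozen=True)
class BoundaryConditions:
    periannular: BoundaryValues
    np_cep_interface: BoundaryValues


@dataclass(frozen=True)
class PhCoupling:
    """Affine lactate -> pH map anchored at a reference pair.

    pH(c) = reference_ph - sensitivity * (c - reference_lactate); strictly
    decreasing and invertible for sensitivity > 0.
    """

    reference_lactate: float  # mM
    reference_ph: float
    sensitivity: float  # pH units per mM lactate

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValidationError("ph coupling sensitivity must be positive")


@dataclass(frozen=True)
class SpeciesParameters:
    """Everything the solvers need for one species, in canonical units."""

    species: str
    geometry: dict[str, float]  # mm; consumed by discregen.geometry
    diffusion: dict[str, dict[str, DiffusionTensor]]  # domain -> metabolite -> D
    metabolic_rates: dict[str, MetabolicRates]  # per cell type (np, af)
    gag: GagParameters
    cell_densities: CellDensities
    boundaries: BoundaryConditions
    oxygen_solubility: float  # uM per % O2
    ph_coupling: PhCoupling
    lactate_glucose_ratio: float  # mol lactate per mol glucose
    glucose_km: float  # mM
    injury_gag_reduction: float  # fraction of NP GAG removed by the injury model
    injury_cellularity_reduction: float  # fraction of NP cells removed
    dose_reference_density: float  # cells/mm^3 the dose fraction is quoted against
    provenance: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.oxygen_solubility <= 0:
            raise ValidationError("oxygen_solubility must be positive")
        if self.lactate_glucose_ratio <= 0:
            raise ValidationError("lactate_glucose_ratio must be positive")
        if self.glucose_km <= 0:
            raise ValidationError("glucose_km must be positive")
        for name in ("injury_gag_reduction", "injury_cellularity_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


# --------------------------------------------------------------------------
# elementary operations


def half_life_to_decay_rate(tau: float) -> float:
    """First-order decay rate ln(2)/tau, same time unit as *tau* (canonical: h)."""
    if tau <= 0:
        raise ValidationError(f"half-life must be positive, got {tau}")
    return math.log(2.0) / tau


def convert_dw_to_volume(content_dw: float, dw_conversion: float) -> float:
    """ug/mg DW x mg DW/mm^3 -> ug/mm^3 (exact product)."""
    if content_dw < 0 or dw_conversion < 0:
        raise ValidationError("dry-weight conversion inputs must be non-negative")
    return content_dw * dw_conversion


def dose_fraction(n_cells: float, rho0: float, v_np: float) -> float:
    """Injected dose as percent of the reference NP cell population.

    ``rho0`` is the reference density (healthy for animals, pre-treatment
    grade for human) and ``v_np`` the analytic NP volume in mm^3.
    """
    if rho0 <= 0 or v_np <= 0:
        raise ValidationError("reference population must be positive")
    if n_cells < 0:
        raise ValidationError("cell count must be non-negative")
    return 100.0 * n_cells / (rho0 * v_np)


def oxygen_percent_to_concentration(pct: float, solubility: float) -> float:
    """% O2 -> uM via the configured Henry's-law solubility (uM per % O2)."""
    if pct < 0:
        raise ValidationError("oxygen percent must be non-negative")
    if solubility <= 0:
        raise ValidationError("solubility must be positive")
    return pct * solubility


def oxygen_concentration_to_percent(c_um: float, solubility: float) -> float:
    if c_um < 0:
        raise ValidationError("oxygen concentration must be non-negative")
    if solubility <= 0:
        raise ValidationError("solubility must be positive")
    return c_um / solubility


# --------------------------------------------------------------------------
# loading

_GEOMETRY_KEYS = ("np_semi_lateral", "np_semi_ap", "af_semi_lateral", "af_semi_ap", "height")
_METABOLITES = ("glucose", "oxygen", "lactate")
_DOMAINS = ("np", "af")


def builtin_config_path(species: str) -> Path:
    """Path of a shipped config (``rat``, ``goat``, ``human_grade3``)."""
    ref = resources.files("discregen") / "configs" / f"{species}.yaml"
    return Path(str(ref))


def _leaf(node: Any, key: str, expected_unit: str, prov: dict[str, str]) -> float:
    if not isinstance(node, Mapping) or set(node) - {"value", "units", "source"}:
        raise ValidationError(f"{key}: expected {{value, units, source}} mapping")
    for req in ("value", "units"):
        if req not in node:
            raise ValidationError(f"{key}: missing {req!r}")
    source = node.get("source", "derived")
    if source not in _SOURCES:
        raise ValidationError(f"{key}: unknown source {source!r}")
    prov[key] = source
    try:
        return to_canonical(float(node["value"]), node["units"], expected_unit, key)
    except UnitError as e:
        raise ValidationError(str(e)) from None


def _require(mapping: Mapping, key: str, context: str) -> Any:
    if key not in mapping:
        raise ValidationError(f"{context}: missing field {key!r}")
    return mapping[key]


def _reject_unknown(mapping: Mapping, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"{context}: unknown keys {sorted(unknown)}")


def load_species_parameters(config: str | Path | Mapping[str, Any]) -> SpeciesParameters:
    """Load and validate a species configuration.

    *config* may be a path to a YAML file, a YAML string, or an
    already-parsed mapping.  Returns parameters in canonical internal units.
    Raises :class:`ValidationError` naming the offending key on any missing
    field, unknown key, unit mismatch, or sign violation.
    """
    if isinstance(config, Mapping):
        doc = dict(config)
    else:
        path = Path(config)
        if path.suffix in {".yaml", ".yml"} or path.exists():
            text = path.read_text()
        else:
            text = str(config)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValidationError("config document must be a mapping")

    prov: dict[str, str] = {}
    allowed = {
        "species", "geometry", "diffusion", "metabolic_rates", "cell_densities",
        "gag", "boundaries", "oxygen_solubility", "ph_coupling",
        "lactate_glucose_ratio", "glucose_km", "injury",
    }
    _reject_unknown(doc, allowed, "config")
    species = str(_require(doc, "species", "config"))

    geo_doc = _require(doc, "geometry", "config")
    _reject_unknown(geo_doc, set(_GEOMETRY_KEYS), "geometry")
    geometry = {
        k: _leaf(_require(geo_doc, k, "geometry"), f"geometry.{k}", "mm", prov)
        for k in _GEOMETRY_KEYS
    }
    for k, v in geometry.items():
        if v <= 0:
            raise ValidationError(f"geometry.{k}: must be positive, got {v}")

    diff_doc = _require(doc, "diffusion", "config")
    _reject_unknown(diff_doc, set(_DOMAINS), "diffusion")
    diffusion: dict[str, dict[str, DiffusionTensor]] = {}
    for dom in _DOMAINS:
        dom_doc = _require(diff_doc, dom, "diffusion")
        _reject_unknown(dom_doc, set(_METABOLITES), f"diffusion.{dom}")
        diffusion[dom] = {}
        for met in _METABOLITES:
            node = _require(dom_doc, met, f"diffusion.{dom}")
            key = f"diffusion.{dom}.{met}"
            if not isinstance(node, Mapping):
                raise ValidationError(f"{key}: expected mapping")
            _reject_unknown(node, {"axial", "radial", "units", "source"}, key)
            source = node.get("source", "derived")
            if source not in _SOURCES:
                raise ValidationError(f"{key}: unknown source {source!r}")
            prov[key] = source
            units = _require(node, "units", key)
            ax = to_canonical(float(_require(node, "axial", key)), units, "mm^2/h", key)
            ra = to_canonical(float(_require(node, "radial", key)), units, "mm^2/h", key)
            if ax <= 0 or ra <= 0:
                raise ValidationError(f"{key}: diffusivity must be positive")
            diffusion[dom][met] = DiffusionTensor(axial=ax, radial=ra)

    met_doc = _require(doc, "metabolic_rates", "config")
    _reject_unknown(met_doc, set(_DOMAINS), "metabolic_rates")
    metabolic = {}
    for dom in _DOMAINS:
        dom_doc = _require(met_doc, dom, "metabolic_rates")
        _reject_unknown(dom_doc, {"vmax_o2", "lpr", "km_o2"}, f"metabolic_rates.{dom}")
        metabolic[dom] = MetabolicRates(
            vmax_o2=_leaf(_require(dom_doc, "vmax_o2", dom), f"metabolic_rates.{dom}.vmax_o2",
                          "nmol/10^6 cells/h", prov),
            lpr=_leaf(_require(dom_doc, "lpr", dom), f"metabolic_rates.{dom}.lpr",
                      "nmol/10^6 cells/h", prov),
            km_o2=_leaf(_require(dom_doc, "km_o2", dom), f"metabolic_rates.{dom}.km_o2",
                        "uM", prov),
        )

    dens_doc = _require(doc, "cell_densities", "config")
    _reject_unknown(dens_doc, {"np", "af", "dose_reference"}, "cell_densities")
    densities = CellDensities(
        np_density=_leaf(_require(dens_doc, "np", "cell_densities"),
                         "cell_densities.np", "cells/mm^3", prov),
        af_density=_leaf(_require(dens_doc, "af", "cell_densities"),
                         "cell_densities.af", "cells/mm^3", prov),
    )
    if "dose_reference" in dens_doc:
        dose_ref = _leaf(dens_doc["dose_reference"], "cell_densities.dose_reference",
                         "cells/mm^3", prov)
    else:
        dose_ref = densities.np_density
        prov["cell_densities.dose_reference"] = prov["cell_densities.np"]

    gag_doc = _require(doc, "gag", "config")
    _reject_unknown(gag_doc, {"native_content_dw", "degenerated_content_vol",
                              "synthesis_rate", "half_life", "dw_conversion",
                              "reference_content_vol"}, "gag")

    def _np_af(node: Any, key: str, unit: str) -> dict[str, float]:
        if not isinstance(node, Mapping):
            raise ValidationError(f"{key}: expected mapping")
        _reject_unknown(node, {"np", "af", "units", "source"}, key)
        source = node.get("source", "derived")
        if source not in _SOURCES:
            raise ValidationError(f"{key}: unknown source {source!r}")
        prov[key] = source
        units = _require(node, "units", key)
        out = {}
        for dom in _DOMAINS:
            v = to_canonical(float(_require(node, dom, key)), units, unit, key)
            if v < 0:
                raise ValidationError(f"{key}.{dom}: must be non-negative")
            out[dom] = v
        return out

    gag = GagParameters(
        native_content_dw=_np_af(_require(gag_doc, "native_content_dw", "gag"),
                                 "gag.native_content_dw", "ug/mg DW"),
        degenerated_content_vol=_np_af(_require(gag_doc, "degenerated_content_vol", "gag"),
                                       "gag.degenerated_content_vol", "ug/mm^3"),
        synthesis_rate=_leaf(_require(gag_doc, "synthesis_rate", "gag"),
                             "gag.synthesis_rate", "pg/cell/day", prov),
        half_life=_leaf(_require(gag_doc, "half_life", "gag"), "gag.half_life", "h", prov),
        dw_conversion=_leaf(_require(gag_doc, "dw_conversion", "gag"),
                            "gag.dw_conversion", "mg DW/mm^3", prov),
        reference_content_vol=_leaf(_require(gag_doc, "reference_content_vol", "gag"),
                                    "gag.reference_content_vol", "ug/mm^3", prov),
    )

    bnd_doc = _require(doc, "boundaries", "config")
    _reject_unknown(bnd_doc, {"periannular", "np_cep_interface"}, "boundaries")

    def _route(name: str) -> BoundaryValues:
        node = _require(bnd_doc, name, "boundaries")
        _reject_unknown(node, {"glucose", "oxygen", "ph"}, f"boundaries.{name}")
        return BoundaryValues(
            glucose=_leaf(_require(node, "glucose", name), f"boundaries.{name}.glucose",
                          "mM", prov),
            oxygen=_leaf(_require(node, "oxygen", name), f"boundaries.{name}.oxygen",
                         "uM", prov),
            ph=_leaf(_require(node, "ph", name), f"boundaries.{name}.ph", "pH", prov),
        )

    boundaries = BoundaryConditions(
        periannular=_route("periannular"),
        np_cep_interface=_route("np_cep_interface"),
    )

    solubility = _leaf(_require(doc, "oxygen_solubility", "config"),
                       "oxygen_solubility", "uM/%O2", prov)

    phc_doc = _require(doc, "ph_coupling", "config")
    _reject_unknown(phc_doc, {"reference_lactate", "reference_ph", "sensitivity"},
                    "ph_coupling")
    ph_coupling = PhCoupling(
        reference_lactate=_leaf(_require(phc_doc, "reference_lactate", "ph_coupling"),
                                "ph_coupling.reference_lactate", "mM", prov),
        reference_ph=_leaf(_require(phc_doc, "reference_ph", "ph_coupling"),
                           "ph_coupling.reference_ph", "pH", prov),
        sensitivity=_leaf(_require(phc_doc, "sensitivity", "ph_coupling"),
                          "ph_coupling.sensitivity", "pH/mM", prov),
    )

    ratio = _leaf(_require(doc, "lactate_glucose_ratio", "config"),
                  "lactate_glucose_ratio", "mol/mol", prov)
    glucose_km = _leaf(_require(doc, "glucose_km", "config"), "glucose_km", "mM", prov)

    inj_doc = _require(doc, "injury", "config")
    _reject_unknown(inj_doc, {"gag_reduction", "cellularity_reduction"}, "injury")
    gag_red = _leaf(_require(inj_doc, "gag_reduction", "injury"),
                    "injury.gag_reduction", "dimensionless", prov)
    cell_red = _leaf(_require(inj_doc, "cellularity_reduction", "injury"),
                     "injury.cellularity_reduction", "dimensionless", prov)

    if not (geometry["np_semi_lateral"] < geometry["af_semi_lateral"]
            and geometry["np_semi_ap"] < geometry["af_semi_ap"]):
        raise ValidationError("geometry: NP semi-axes must be strictly inside AF")

    return SpeciesParameters(
        species=species,
        geometry=geometry,
        diffusion=diffusion,
        metabolic_rates=metabolic,
        gag=gag,
        cell_densities=densities,
        boundaries=boundaries,
        oxygen_solubility=solubility,
        ph_coupling=ph_coupling,
        lactate_glucose_ratio=ratio,
        glucose_km=glucose_km,
        injury_gag_reduction=gag_red,
        injury_cellularity_reduction=cell_red,
        dose_reference_density=dose_ref,
        provenance=prov,
    )


def dump_species_parameters(params: SpeciesParameters) -> dict[str, Any]:
    """Serialize to a config mapping (canonical units) that reloads identically."""
    p = params.provenance

    def leaf(key: str, value: float, units: str) -> dict[str, Any]:
        return {"value": float(value), "units": units, "source": p.get(key, "derived")}

    doc: dict[str, Any] = {"species": params.species}
    doc["geometry"] = {k: leaf(f"geometry.{k}", v, "mm") for k, v in params.geometry.items()}
    doc["diffusion"] = {
        dom: {
            met: {"axial": d.axial, "radial": d.radial, "units": "mm^2/h",
                  "source": p.get(f"diffusion.{dom}.{met}", "derived")}
            for met, d in mets.items()
        }
        for dom, mets in params.diffusion.items()
    }
    doc["metabolic_rates"] = {
        dom: {
            "vmax_o2": leaf(f"metabolic_rates.{dom}.vmax_o2", r.vmax_o2, "nmol/10^6 cells/h"),
            "lpr": leaf(f"metabolic_rates.{dom}.lpr", r.lpr, "nmol/10^6 cells/h"),
            "km_o2": leaf(f"metabolic_rates.{dom}.km_o2", r.km_o2, "uM"),
        }
        for dom, r in params.metabolic_rates.items()
    }
    doc["cell_densities"] = {
        "np": leaf("cell_densities.np", params.cell_densities.np_density, "cells/mm^3"),
        "af": leaf("cell_densities.af", params.cell_densities.af_density, "cells/mm^3"),
        "dose_reference": leaf("cell_densities.dose_reference",
                               params.dose_reference_density, "cells/mm^3"),
    }
    g = params.gag
    doc["gag"] = {
        "native_content_dw": {**{d: g.native_content_dw[d] for d in _DOMAINS},
                              "units": "ug/mg DW",
                              "source": p.get("gag.native_content_dw", "derived")},
        "degenerated_content_vol": {**{d: g.degenerated_content_vol[d] for d in _DOMAINS},
                                    "units": "ug/mm^3",
                                    "source": p.get("gag.degenerated_content_vol", "derived")},
        "synthesis_rate": leaf("gag.synthesis_rate", g.synthesis_rate, "pg/cell/day"),
        "half_life": leaf("gag.half_life", g.half_life, "h"),
        "dw_conversion": leaf("gag.dw_conversion", g.dw_conversion, "mg DW/mm^3"),
        "reference_content_vol": leaf("gag.reference_content_vol",
                                      g.reference_content_vol, "ug/mm^3"),
    }
    doc["boundaries"] = {
        route: {
            "glucose": leaf(f"boundaries.{route}.glucose", bv.glucose, "mM"),
            "oxygen": leaf(f"boundaries.{route}.oxygen", bv.oxygen, "uM"),
            "ph": leaf(f"boundaries.{route}.ph", bv.ph, "pH"),
        }
        for route, bv in (("periannular", params.boundaries.periannular),
                          ("np_cep_interface", params.boundaries.np_cep_interface))
    }
    doc["oxygen_solubility"] = leaf("oxygen_solubility", params.oxygen_solubility, "uM/%O2")
    doc["ph_coupling"] = {
        "reference_lactate": leaf("ph_coupling.reference_lactate",
                                  params.ph_coupling.reference_lactate, "mM"),
        "reference_ph": leaf("ph_coupling.reference_ph",
                             params.ph_coupling.reference_ph, "pH"),
        "sensitivity": leaf("ph_coupling.sensitivity",
                            params.ph_coupling.sensitivity, "pH/mM"),
    }
    doc["lactate_glucose_ratio"] = leaf("lactate_glucose_ratio",
                                        params.lactate_glucose_ratio, "mol/mol")
    doc["glucose_km"] = leaf("glucose_km", params.glucose_km, "mM")
    doc["injury"] = {
        "gag_reduction": leaf("injury.gag_reduction", params.injury_gag_reduction,
                              "dimensionless"),
        "cellularity_reduction": leaf("injury.cellularity_reduction",
                                      params.injury_cellularity_reduction,
                                      "dimensionless"),
    }
    return doc
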