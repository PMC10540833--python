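"""Generators for every input the pipeline consumes.

No measurement data ship with the package; these generators emulate the
three experimental sources so each pipeline stage can be exercised and its
estimators validated by parameter recovery:

* flux-analyzer traces — chamber oxygen (mmHg) declining linearly after a
  curved ~10-min transient, and pH declining through an embedded standard
  curve; additive Gaussian instrument noise;
* spheroid GAG assays — cumulative GAG mass with multiplicative assay
  noise;
* intradiscal probe datasets — central oxygen/pH/glucose samples off a
  solved steady state with multiplicative (pH: additive) noise.

Every artifact is paired with a truth record embedding the generating
parameters and the seed, so recovery tests never re-derive truths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flux_estimation import (
    DEFAULT_CHAMBER_VOLUME_UL,
    DEFAULT_O2_UM_PER_MMHG,
    FluxTrace,
    SpheroidAssay,
    StandardCurve,
)
from .geometry import LabeledGrid
from .species_params import (
    SpeciesParameters,
    ValidationError,
    dump_species_parameters,
    load_species_parameters,
)
from .transport import SteadyStateFields, central_concentrations

__all__ = [
    "GeneratorSpec",
    "default_standard_curve",
    "generate_flux_trace",
    "generate_gag_assay",
    "generate_probe_dataset",
    "perturb_parameters",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Noise levels and replicate counts for the generators."""

    seed: int
    o2_mmhg_sd: float = 0.2  # instrument noise on chamber oxygen
    ph_sd: float = 0.002  # instrument noise on pH
    gag_cv: float = 0.10  # multiplicative CV of the GAG assay
    probe_cv: float = 0.05  # multiplicative CV of probe measurements
    n_discs: int = 3  # probed discs per dataset

    def __post_init__(self) -> None:
        if min(self.o2_mmhg_sd, self.ph_sd, self.gag_cv, self.probe_cv) < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_discs < 1:
            raise ValueError("need at least one probed disc")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_standard_curve() -> StandardCurve:
    """Affine pH vs lactate calibration for a weakly buffered assay medium,
    spanning 0-2 mM (the accumulation range of one measurement period)."""
    lac = np.linspace(0.0, 2.0, 6)
    return StandardCurve(lactate_mm=lac, ph_measured=7.6 - 0.6 * lac)


def generate_flux_trace(
    spec: GeneratorSpec,
    true_ocr: float,
    true_lpr: float,
    n_cells: float,
    chamber_volume_ul: float = DEFAULT_CHAMBER_VOLUME_UL,
    curve: StandardCurve | None = None,
    o2_um_per_mmhg: float = DEFAULT_O2_UM_PER_MMHG,
    duration_min: float = 30.0,
    n_samples: int = 16,
    transient_amplitude_mmhg: float = 5.0,
    transient_tau_min: float = 2.5,
    o2_baseline_mmhg: float = 152.0,
    lactate0_mm: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[FluxTrace, FluxTrace, dict]:
    """Emulate one well + blank for known per-cell rates.

    Oxygen declines linearly at the slope implied by ``true_ocr`` with an
    exponential pre-plateau transient (set ``transient_amplitude_mmhg=0``
    for an exactly linear trace); pH follows the lactate accumulation
    implied by ``true_lpr`` through the standard curve.  Returns
    ``(trace, blank, truth)``.
    """
    if true_ocr < 0 or true_lpr < 0 or n_cells <= 0 or chamber_volume_ul <= 0:
        raise ValueError("rates must be non-negative and counts/volume positive")
    curve = curve or default_standard_curve()
    rng = rng if rng is not None else spec.rng()
    t = np.linspace(0.0, duration_min, n_samples)

    # per-chamber slopes implied by the per-cell truths
    nmol_per_h_o2 = true_ocr * n_cells / 1.0e6
    slope_o2_mmhg_min = -nmol_per_h_o2 / (chamber_volume_ul * 1.0e-3) \
        / o2_um_per_mmhg / 60.0
    nmol_per_h_lac = true_lpr * n_cells / 1.0e6
    slope_lac_mm_min = nmol_per_h_lac / chamber_volume_ul / 60.0

    o2 = o2_baseline_mmhg + slope_o2_mmhg_min * t
    if transient_amplitude_mmhg:
        o2 = o2 + transient_amplitude_mmhg * np.exp(-t / transient_tau_min)
    lac = lactate0_mm + slope_lac_mm_min * t
    ph = curve.to_ph(lac)

    o2 = o2 + rng.normal(0.0, spec.o2_mmhg_sd, size=t.shape)
    ph = ph + rng.normal(0.0, spec.ph_sd, size=t.shape)
    trace = FluxTrace(time_min=t, o2_mmhg=o2, ph=ph, well="S1", is_blank=False)

    blank_o2 = np.full_like(t, o2_baseline_mmhg) \
        + rng.normal(0.0, spec.o2_mmhg_sd, size=t.shape)
    blank_ph = np.full_like(t, float(curve.to_ph(lactate0_mm))) \
        + rng.normal(0.0, spec.ph_sd, size=t.shape)
    blank = FluxTrace(time_min=t, o2_mmhg=blank_o2, ph=blank_ph,
                      well="B1", is_blank=True)

    truth = {
        "seed": spec.seed, "true_ocr": true_ocr, "true_lpr": true_lpr,
        "n_cells": n_cells, "chamber_volume_ul": chamber_volume_ul,
        "o2_um_per_mmhg": o2_um_per_mmhg,
        "transient_amplitude_mmhg": transient_amplitude_mmhg,
    }
    return trace, blank, truth


def generate_gag_assay(
    spec: GeneratorSpec,
    true_lambda1: float,
    n_cells_per_spheroid: float,
    days: float,
    pooled_n: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[SpheroidAssay, dict]:
    """Cumulative GAG readout for pooled spheroids at a known synthesis rate.

    total GAG (ug) = lambda1 * cells * days * (1 + cv * eps); pooling scales
    mass and cells together, so the per-cell rate is pooling-invariant.
    """
    if true_lambda1 < 0 or n_cells_per_spheroid <= 0 or days <= 0 or pooled_n < 1:
        raise ValueError("invalid assay generation inputs")
    rng = rng if rng is not None else spec.rng()
    cells = n_cells_per_spheroid * pooled_n
    clean_ug = true_lambda1 * cells * days / 1.0e6
    noisy_ug = clean_ug * max(0.0, 1.0 + spec.gag_cv * float(rng.standard_normal()))
    assay = SpheroidAssay(gag_ug=noisy_ug, cells=cells, days=days, pooled_n=pooled_n)
    truth = {"seed": spec.seed, "true_lambda1": true_lambda1,
             "n_cells_per_spheroid": n_cells_per_spheroid, "days": days,
             "pooled_n": pooled_n}
    return assay, truth


def generate_probe_dataset(
    fields: SteadyStateFields,
    grid: LabeledGrid,
    params: SpeciesParameters,
    spec: GeneratorSpec,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Intradiscal probe samples of the central microenvironment.

    One central measurement of glucose (mM), oxygen (%O2) and pH per disc,
    with multiplicative noise on glucose/oxygen and additive noise (scaled
    by the same CV) on pH.  Returns a long-format frame with columns
    ``disc_id, metabolite, value, location`` plus a truth record.
    """
    rng = rng if rng is not None else spec.rng()
    gluc, ph, o2 = central_concentrations(fields, grid, params.oxygen_solubility)
    rows = []
    for d in range(spec.n_discs):
        rows.append((f"disc{d + 1}", "glucose",
                     gluc * (1.0 + spec.probe_cv * rng.standard_normal()), "central"))
        rows.append((f"disc{d + 1}", "oxygen",
                     o2 * (1.0 + spec.probe_cv * rng.standard_normal()), "central"))
        rows.append((f"disc{d + 1}", "ph",
                     ph + spec.probe_cv * rng.standard_normal(), "central"))
    df = pd.DataFrame(rows, columns=["disc_id", "metabolite", "value", "location"])
    truth = {"seed": spec.seed, "central_glucose_mM": gluc, "central_ph": ph,
             "central_o2_pct": o2, "n_discs": spec.n_discs}
    return df, truth


# parameters addressable by perturb_parameters: dotted path -> (section walk)
_PERTURBABLE = {
    "cell_densities.np": ("cell_densities", "np"),
    "cell_densities.af": ("cell_densities", "af"),
    "metabolic_rates.np.vmax_o2": ("metabolic_rates", "np", "vmax_o2"),
    "metabolic_rates.np.lpr": ("metabolic_rates", "np", "lpr"),
    "metabolic_rates.af.vmax_o2": ("metabolic_rates", "af", "vmax_o2"),
    "metabolic_rates.af.lpr": ("metabolic_rates", "af", "lpr"),
    "gag.synthesis_rate": ("gag", "synthesis_rate"),
    "gag.dw_conversion": ("gag", "dw_conversion"),
}


def perturb_parameters(
    params: SpeciesParameters,
    spec: GeneratorSpec,
    sigma: float,
    which: tuple[str, ...] = ("metabolic_rates.np.vmax_o2", "metabolic_rates.np.lpr"),
    n: int = 10,
    max_resamples: int = 100,
) -> tuple[list[SpeciesParameters], int]:
    """Log-normal multiplicative ensemble around *params*.

    Each named parameter is multiplied by exp(sigma * z), z ~ N(0, 1), and
    the perturbed document is re-validated through the loader; members that
    fail validation are resampled (the resample count is returned).
    """
    unknown = set(which) - set(_PERTURBABLE)
    if unknown:
        raise ValueError(f"unperturbable parameters: {sorted(unknown)}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = spec.rng()
    ensemble: list[SpeciesParameters] = []
    resamples = 0
    while len(ensemble) < n:
        doc = dump_species_parameters(params)
        for name in which:
            path = _PERTURBABLE[name]
            node = doc
            for key in path[:-1]:
                node = node[key]
            leaf = node[path[-1]]
            leaf["value"] = float(leaf["value"]) * float(np.exp(sigma * rng.standard_normal()))
        try:
            ensemble.append(load_species_parameters(doc))
        except ValidationError:
            resamples += 1
            if resamples > max_resamples:
                raise
    return ensemble, resamples
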