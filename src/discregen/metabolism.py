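"""Pointwise metabolic kinetics and the lactate <-> pH coupling.

Oxygen consumption follows pH-modulated Michaelis-Menten kinetics,

    Q_O2 = Vmax * (pH - 4.95) * C_O2 / (Km * (pH - 4.59) + C_O2) * rho,

with *two distinct* printed offsets (4.95 in the numerator, 4.59 in the
denominator) kept as separate named constants.  The law is invalid at or
below pH 4.95.  Glucose consumption is plain Michaelis-Menten with maximal
rate LPR/2 (glycolytic 2:1 lactate:glucose stoichiometry), and lactate is
produced at exactly the stoichiometric multiple of the glucose sink.

Sign convention: all kinetics return **positive magnitudes**; the transport
assembler decides sink vs source.

Units: oxygen uM, glucose/lactate mM, rho cells/mm^3, Vmax/LPR nmol per
10^6 cells per h.  Volumetric rates come out in uM/h (oxygen) and mM/h
(glucose, lactate) because nmol/mm^3 = mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species_params import MetabolicRates, PhCoupling

__all__ = [
    "KineticsDomainError",
    "PH_NUMERATOR_OFFSET",
    "PH_DENOMINATOR_OFFSET",
    "LocalState",
    "oxygen_consumption",
    "glucose_consumption",
    "lactate_production",
    "lactate_to_ph",
    "ph_to_lactate",
]

PH_NUMERATOR_OFFSET = 4.95  # also the validity floor of the oxygen law
PH_DENOMINATOR_OFFSET = 4.59


class KineticsDomainError(ValueError):
    """State outside the validity domain of a rate law."""


@dataclass(frozen=True)
class LocalState:
    """Local tissue state at one point (canonical units)."""

    c_o2: float  # uM
    c_gluc: float  # mM
    c_lac: float  # mM
    ph: float
    rho: float  # cells/mm^3

    def __post_init__(self) -> None:
        if self.c_o2 < 0 or self.c_gluc < 0 or self.c_lac < 0 or self.rho < 0:
            raise KineticsDomainError("concentrations and density must be non-negative")
        if not self.ph < 9.0:
            raise KineticsDomainError(f"pH {self.ph} above validity window")


def oxygen_consumption(state: LocalState, rates: MetabolicRates) -> float:
    """Volumetric oxygen consumption magnitude (uM/h).

    Zero at C_O2 = 0 and at the pH floor; raises below the floor where the
    law is invalid.
    """
    if state.ph <= PH_NUMERATOR_OFFSET:
        raise KineticsDomainError(
            f"oxygen kinetics invalid at pH {state.ph} <= {PH_NUMERATOR_OFFSET}"
        )
    num = rates.vmax_o2 * (state.ph - PH_NUMERATOR_OFFSET) * state.c_o2
    den = rates.km_o2 * (state.ph - PH_DENOMINATOR_OFFSET) + state.c_o2
    # nmol/1e6 cells/h * cells/mm^3 -> 1e-6 nmol/mm^3/h = 1e-6 mM/h = 1e-3 uM/h
    return num / den * state.rho * 1.0e-3


def glucose_consumption(state: LocalState, rates: MetabolicRates,
                        km_gluc: float = 0.5) -> float:
    """Volumetric glucose consumption magnitude (mM/h).

    Michaelis-Menten in local glucose with Vmax_gluc = LPR/2; saturates to
    Vmax_gluc * rho as C_gluc -> infinity.
    """
    if km_gluc <= 0:
        raise KineticsDomainError("glucose Km must be positive")
    mm = state.c_gluc / (km_gluc + state.c_gluc) if state.c_gluc > 0 else 0.0
    return rates.vmax_gluc * mm * state.rho * 1.0e-6


def lactate_production(glucose_rate: float, ratio: float = 2.0) -> float:
    """Lactate production (mM/h) from a glucose consumption magnitude (mM/h)."""
    if glucose_rate < 0:
        raise KineticsDomainError("glucose rate magnitude must be non-negative")
    return ratio * glucose_rate


def lactate_to_ph(c_lac, coupling: PhCoupling, clamp_floor: float = PH_NUMERATOR_OFFSET + 0.05):
    """Map lactate (mM) to pH through the affine coupling; vectorized.

    Strictly decreasing; values that would fall at or below the oxygen-law
    floor are clamped to ``clamp_floor`` (the caller may warn).
    """
    c = np.asarray(c_lac, dtype=float)
    if np.any(c < 0):
        raise KineticsDomainError("lactate must be non-negative")
    ph = coupling.reference_ph - coupling.sensitivity * (c - coupling.reference_lactate)
    ph = np.maximum(ph, clamp_floor)
    return float(ph) if np.isscalar(c_lac) else ph


def ph_to_lactate(ph: float, coupling: PhCoupling) -> float:
    """Inverse of :func:`lactate_to_ph` on the unclamped domain."""
    c = coupling.reference_lactate + (coupling.reference_ph - ph) / coupling.sensitivity
    if c < 0:
        raise KineticsDomainError(
            f"pH {ph} maps to negative lactate under the configured coupling"
        )
    return c
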