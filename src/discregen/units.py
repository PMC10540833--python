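"""Canonical unit system and conversions.

Every quantity inside the package lives in one canonical system:

========================  =================
quantity                  canonical unit
========================  =================
length                    mm
time                      h
diffusivity               mm^2/h
oxygen concentration      uM
glucose / lactate         mM
GAG content               ug/mm^3
cell density              cells/mm^3
metabolic rate            nmol/1e6 cells/h
GAG synthesis rate        pg/cell/day
========================  =================

Config files must annotate every numeric leaf with a ``units:`` string; the
loader converts to canonical units through the table below.  The table is
deliberately small — only spellings the shipped configs and I/O formats use.
"""

from __future__ import annotations

HOURS_PER_DAY = 24.0
DAYS_PER_YEAR = 365.25  # documented constant; the half-life is quoted in years
HOURS_PER_YEAR = HOURS_PER_DAY * DAYS_PER_YEAR  # 8766.0

# unit string -> (canonical unit, multiplicative factor to canonical)
_CONVERSIONS: dict[str, tuple[str, float]] = {
    # length
    "mm": ("mm", 1.0),
    "cm": ("mm", 10.0),
    # volume
    "mm^3": ("mm^3", 1.0),
    # diffusivity
    "mm^2/h": ("mm^2/h", 1.0),
    "cm^2/s": ("mm^2/h", 100.0 * 3600.0),
    # concentrations
    "uM": ("uM", 1.0),
    "mM": ("mM", 1.0),
    "ug/mm^3": ("ug/mm^3", 1.0),
    "ug/mg DW": ("ug/mg DW", 1.0),
    "mg DW/mm^3": ("mg DW/mm^3", 1.0),
    # densities and counts
    "cells/mm^3": ("cells/mm^3", 1.0),
    "10^3 cells/mm^3": ("cells/mm^3", 1.0e3),
    "10^6 cells/mm^3": ("cells/mm^3", 1.0e6),
    "cells": ("cells", 1.0),
    # rates
    "nmol/10^6 cells/h": ("nmol/10^6 cells/h", 1.0),
    "pg/cell/day": ("pg/cell/day", 1.0),
    "1/h": ("1/h", 1.0),
    "1/year": ("1/h", 1.0 / HOURS_PER_YEAR),
    # durations
    "h": ("h", 1.0),
    "min": ("h", 1.0 / 60.0),
    "day": ("h", HOURS_PER_DAY),
    "days": ("h", HOURS_PER_DAY),
    "week": ("h", 7.0 * HOURS_PER_DAY),
    "year": ("h", HOURS_PER_YEAR),
    "years": ("h", HOURS_PER_YEAR),
    # misc
    "pH": ("pH", 1.0),
    "pH/mM": ("pH/mM", 1.0),
    "uM/%O2": ("uM/%O2", 1.0),
    "uM/mmHg": ("uM/mmHg", 1.0),
    "%O2": ("%O2", 1.0),
    "uL": ("uL", 1.0),
    "dimensionless": ("dimensionless", 1.0),
    "fraction": ("dimensionless", 1.0),
    "percent": ("dimensionless", 1.0e-2),
    "mol/mol": ("mol/mol", 1.0),
}


class UnitError(ValueError):
    """Raised when a unit annotation is missing, unknown, or incompatible."""


def to_canonical(value: float, units: str, expected: str, key: str = "?") -> float:
    """Convert *value* with annotation *units* to the *expected* canonical unit.

    Raises :class:`UnitError` naming *key* if the annotation is unknown or
    does not reduce to the expected canonical unit.
    """
    try:
        canonical, factor = _CONVERSIONS[units]
    except KeyError:
        raise UnitError(f"{key}: unknown units {units!r}") from None
    if canonical != expected:
        raise UnitError(
            f"{key}: units {units!r} are {canonical!r}, expected {expected!r}"
        )
    return value * factor


def hours_to_years(t_h: float) -> float:
    return t_h / HOURS_PER_YEAR


def years_to_hours(t_y: float) -> float:
    return t_y * HOURS_PER_YEAR
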