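"""Estimate per-cell metabolic parameters from flux-analyzer style data.

Raw inputs are oxygen (mmHg) and pH traces measured in a small chamber
around a single cell spheroid, plus cumulative GAG assay readouts from
spheroid cultures.  The estimators recover:

* OCR — oxygen consumption rate (nmol per 10^6 cells per h), from the
  blank-corrected linear decline of chamber oxygen after a 10-minute
  transient;
* LPR — lactate production rate (same units), from the pH trace mapped to
  lactate through a standard curve;
* lambda1 — GAG synthesis rate (pg/cell/day), from total accumulated GAG
  normalized by cell number and culture duration.

Replicate rate lists can be screened for outliers with a robust
location/scale test with FDR control (an approximation of the ROUT
procedure used by commercial software).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EstimationError",
    "FluxTrace",
    "StandardCurve",
    "SpheroidAssay",
    "OutlierResult",
    "estimate_ocr",
    "estimate_lpr",
    "estimate_gag_synthesis_rate",
    "remove_outliers",
    "OXYGEN_PLATEAU_CUTOFF_MIN",
    "DEFAULT_CHAMBER_VOLUME_UL",
    "DEFAULT_O2_UM_PER_MMHG",
]

OXYGEN_PLATEAU_CUTOFF_MIN = 10.0  # oxygen decline is linear only after ~10 min
DEFAULT_CHAMBER_VOLUME_UL = 2.3  # microchamber formed around a single spheroid
DEFAULT_O2_UM_PER_MMHG = 1.3  # O2 solubility in assay medium at 37 C


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class FluxTrace:
    """One well's raw trace: strictly increasing timestamps (min), oxygen
    (mmHg) and pH readings."""

    time_min: np.ndarray
    o2_mmhg: np.ndarray
    ph: np.ndarray
    well: str = "A1"
    is_blank: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "o2_mmhg", np.asarray(self.o2_mmhg, dtype=float))
        object.__setattr__(self, "ph", np.asarray(self.ph, dtype=float))
        if t.ndim != 1 or len(t) < 2:
            raise EstimationError("trace needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise EstimationError("timestamps must be strictly increasing")
        if self.o2_mmhg.shape != t.shape or self.ph.shape != t.shape:
            raise EstimationError("o2/pH arrays must match timestamps")


@dataclass(frozen=True)
class StandardCurve:
    """Monotone pH <-> lactate calibration fitted to known standards.

    The fitted form is affine, ``pH = intercept + slope * lactate`` with
    slope < 0, which is adequate over the small pH span of a measurement
    window; residuals are stored for inspection.
    """

    lactate_mm: np.ndarray
    ph_measured: np.ndarray
    slope: float = field(init=False)
    intercept: float = field(init=False)
    residuals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lac = np.asarray(self.lactate_mm, dtype=float)
        ph = np.asarray(self.ph_measured, dtype=float)
        if lac.size < 2:
            raise EstimationError("standard curve needs >= 2 calibration points")
        slope, intercept = np.polyfit(lac, ph, 1)
        if slope >= 0:
            raise EstimationError("standard curve must be strictly decreasing in lactate")
        object.__setattr__(self, "lactate_mm", lac)
        object.__setattr__(self, "ph_measured", ph)
        object.__setattr__(self, "slope", float(slope))
        object.__setattr__(self, "intercept", float(intercept))
        object.__setattr__(self, "residuals", ph - (intercept + slope * lac))

    def ph_range(self) -> tuple[float, float]:
        lo = self.intercept + self.slope * float(self.lactate_mm.max())
        hi = self.intercept + self.slope * float(self.lactate_mm.min())
        return lo, hi

    def to_lactate(self, ph, extrapolation_tol: float = 0.2):
        """Invert the curve; pH outside the calibrated range (+/- tol) errors."""
        ph_arr = np.asarray(ph, dtype=float)
        lo, hi = self.ph_range()
        if np.any(ph_arr < lo - extrapolation_tol) or np.any(ph_arr > hi + extrapolation_tol):
            raise EstimationError(
                f"pH outside calibrated standard-curve domain [{lo:.3f}, {hi:.3f}]"
            )
        return (ph_arr - self.intercept) / self.slope

    def to_ph(self, lactate_mm):
        return self.intercept + self.slope * np.asarray(lactate_mm, dtype=float)


@dataclass(frozen=True)
class SpheroidAssay:
    """Cumulative GAG readout for pooled spheroids over a culture window."""

    gag_ug: float  # total GAG, spheroids + retained media
    cells: float  # total cell count across the pooled spheroids
    days: float
    pooled_n: int = 1

    def __post_init__(self) -> None:
        if self.gag_ug < 0:
            raise EstimationError("GAG mass must be non-negative")
        if self.cells <= 0 or self.days <= 0 or self.pooled_n <= 0:
            raise EstimationError("cells, days and pooled_n must be positive")


def _blank_correct(trace: FluxTrace, blank: FluxTrace, values: str) -> np.ndarray:
    """Subtract the blank signal, interpolated onto the trace timestamps."""
    raw = getattr(trace, values)
    ref = np.interp(trace.time_min, blank.time_min, getattr(blank, values))
    return raw - ref


def _plateau_slope(t_min: np.ndarray, y: np.ndarray, cutoff_min: float) -> float:
    """Least-squares slope (per minute) on samples with t >= cutoff."""
    keep = t_min >= cutoff_min
    if np.count_nonzero(keep) < 2:
        raise EstimationError(
            f"fewer than 2 samples after the {cutoff_min}-min plateau cutoff"
        )
    slope = np.polyfit(t_min[keep], y[keep], 1)[0]
    return float(slope)


def estimate_ocr(
    trace: FluxTrace,
    blank: FluxTrace,
    n_cells: float,
    o2_um_per_mmhg: float = DEFAULT_O2_UM_PER_MMHG,
    chamber_volume_ul: float = DEFAULT_CHAMBER_VOLUME_UL,
) -> tuple[float, bool]:
    """Oxygen consumption rate (nmol per 10^6 cells per h).

    Fits the blank-corrected oxygen slope on t >= 10 min, converts mmHg to
    concentration, scales by chamber volume and normalizes per 10^6 cells.
    Returns ``(ocr, flagged)`` where *flagged* marks a non-physical positive
    oxygen slope (the magnitude is still reported, as 0 or negative OCR).
    """
    if n_cells <= 0:
        raise EstimationError("cell count must be positive")
    if trace.time_min[-1] <= OXYGEN_PLATEAU_CUTOFF_MIN:
        raise EstimationError("trace must span more than the 10-min transient")
    corrected = _blank_correct(trace, blank, "o2_mmhg")
    slope_mmhg_min = _plateau_slope(trace.time_min, corrected, OXYGEN_PLATEAU_CUTOFF_MIN)
    # uM/h in the chamber; uM * uL = pmol, so * volume / 1000 -> nmol/h
    slope_um_h = slope_mmhg_min * o2_um_per_mmhg * 60.0
    nmol_per_h = -slope_um_h * chamber_volume_ul * 1.0e-3
    ocr = nmol_per_h * 1.0e6 / n_cells
    flagged = ocr < 0
    return ocr, flagged


def _best_trailing_window(t_min: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean mask of the maximal trailing linear window.

    Leading points are trimmed one at a time while the candidate point sits
    more than 3 studentized residuals off the line fitted to the remaining
    tail (a curved transient), keeping at least half the trace.  Pure-noise
    linear data keeps the full window, so no precision is thrown away.
    """
    n = len(t_min)
    scale = max(1.0, float(np.max(np.abs(y))))
    start = 0
    while n - (start + 1) >= max(4, n // 2):
        tt, yy = t_min[start + 1:], y[start + 1:]
        coeffs = np.polyfit(tt, yy, 1)
        r0 = float(y[start] - np.polyval(coeffs, t_min[start]))
        if abs(r0) <= 1e-9 * scale:  # exactly linear data
            break
        s = max(float(np.std(yy - np.polyval(coeffs, tt))), 1e-12 * scale)
        if abs(r0) / s > 3.0:
            start += 1
        else:
            break
    mask = np.zeros(n, dtype=bool)
    mask[start:] = True
    return mask


def estimate_lpr(
    trace: FluxTrace,
    blank: FluxTrace,
    curve: StandardCurve,
    n_cells: float,
    chamber_volume_ul: float = DEFAULT_CHAMBER_VOLUME_UL,
) -> float:
    """Lactate production rate (nmol per 10^6 cells per h).

    The pH series is blank-drift corrected (relative to the trace's own
    start so absolute pH stays on the standard curve), mapped to lactate,
    and the slope fitted on the maximal trailing linear window.
    """
    if n_cells <= 0:
        raise EstimationError("cell count must be positive")
    drift = _blank_correct(trace, blank, "ph")
    # re-anchor so the corrected series starts at the trace's initial pH
    ph_corrected = trace.ph[0] + (drift - drift[0])
    lactate = curve.to_lactate(ph_corrected)
    window = _best_trailing_window(trace.time_min, lactate)
    slope_mm_min = float(np.polyfit(trace.time_min[window], lactate[window], 1)[0])
    # mM = nmol/uL, so mM/h * uL = nmol/h
    nmol_per_h = slope_mm_min * 60.0 * chamber_volume_ul
    return nmol_per_h * 1.0e6 / n_cells


def estimate_gag_synthesis_rate(assay: SpheroidAssay) -> float:
    """GAG synthesis rate lambda1 (pg/cell/day): mass / cells / days."""
    return assay.gag_ug * 1.0e6 / (assay.cells * assay.days)


@dataclass(frozen=True)
class OutlierResult:
    kept: np.ndarray
    flags: np.ndarray  # bool, aligned with the input order
    warned: bool = False


def remove_outliers(replicates, q: float = 0.01, min_n: int = 8) -> OutlierResult:
    """Flag replicate outliers by robust z-score with FDR control.

    Robust location/scale come from the median and the normalized MAD;
    two-sided normal p-values of the robust z-scores are screened with
    Benjamini-Hochberg at false-discovery setting *q* (default 1%).  With
    fewer than *min_n* replicates the input passes through with a warning.
    Output preserves input order.
    """
    values = np.asarray(replicates, dtype=float)
    if values.ndim != 1:
        raise EstimationError("replicates must be a 1-D list of rates")
    if len(values) < min_n:
        warnings.warn(
            f"only {len(values)} replicates (< {min_n}); outlier screen skipped",
            stacklevel=2,
        )
        return OutlierResult(kept=values.copy(),
                             flags=np.zeros(len(values), dtype=bool), warned=True)
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0:
        return OutlierResult(kept=values.copy(), flags=np.zeros(len(values), dtype=bool))
    z = (values - med) / mad
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    order = np.argsort(pvals)
    n = len(values)
    flags = np.zeros(n, dtype=bool)
    # BH step-up on the sorted p-values
    thresh = q * (np.arange(1, n + 1)) / n
    below = pvals[order] <= thresh
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        flags[order[: k + 1]] = True
    return OutlierResult(kept=values[~flags], flags=flags)
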