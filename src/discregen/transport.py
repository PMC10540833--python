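"""Steady-state coupled reaction-diffusion of oxygen, glucose and lactate.

Discretization: cell-centered finite volumes on the labeled voxel grid with
harmonic-mean interface diffusivities (conservative across the NP/AF
diffusivity jump).  AF diffusion may be anisotropic: the *axial* component
acts along the disc axis (z), the *radial* component in-plane (x, y).

Boundary routes (see :mod:`discregen.geometry`): Dirichlet on the
periannular surface and on the NP-CEP interface for all metabolites; the
AF endplate faces and the two symmetry planes are zero-flux.  Lactate
boundary values are not imposed directly but inferred from the boundary pH
through the inverse lactate->pH coupling.

The nonlinearity (Michaelis-Menten sinks, lactate->pH->oxygen coupling) is
resolved by a Picard fixed-point outer loop with lagged sink coefficients
and under-relaxation: per outer iteration, glucose is solved first, the
lactate source is set to the stoichiometric multiple of the realized
glucose sink, pH is mapped from lactate, then oxygen is solved with the
pH-modulated kinetics.  Each linearized system is an M-matrix, so fields
stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import cg, spsolve

from .geometry import AF_LABEL, EXTERIOR, NP_LABEL, LabeledGrid
from .metabolism import (
    PH_DENOMINATOR_OFFSET,
    PH_NUMERATOR_OFFSET,
    lactate_to_ph,
    ph_to_lactate,
)
from .species_params import (
    BoundaryConditions,
    BoundaryValues,
    SpeciesParameters,
    oxygen_concentration_to_percent,
)

__all__ = [
    "SolverError",
    "SolverSettings",
    "SteadyStateFields",
    "solve_steady_state",
    "central_concentrations",
    "extract_ap_profile",
    "calibrate_boundaries",
    "CalibrationResult",
]

_METABOLITES = ("glucose", "oxygen", "lactate")


class SolverError(RuntimeError):
    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


@dataclass(frozen=True)
class SolverSettings:
    """Outer-loop controls for the Picard iteration."""

    tolerance: float = 1.0e-10  # max relative field change between iterations
    max_outer: int = 80
    relaxation: float = 0.7  # under-relaxation factor in (0, 1]

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in (0, 1]")


@dataclass(frozen=True)
class SteadyStateFields:
    """Converged fields on the grid (NaN outside tissue) plus diagnostics."""

    oxygen: np.ndarray  # uM
    glucose: np.ndarray  # mM
    lactate: np.ndarray  # mM
    ph: np.ndarray
    iterations: int
    residual_history: tuple[float, ...]
    flux_balance: dict[str, float]  # per-metabolite |influx - consumption| / consumption
    total_consumption: dict[str, float]  # nmol/h equivalents (concentration*mm^3/h)
    ph_clamped: bool

    @property
    def converged(self) -> bool:
        return True  # non-converged solves raise SolverError instead


# --------------------------------------------------------------------------
# discrete operator


def _assemble_system(tissue, index, n, h, d_radial, d_axial, sink_k_flat,
                     source_flat, dirichlet_faces):
    """Shared finite-volume kernel: 7-point Laplacian with harmonic-mean
    interface diffusivities, half-cell ghost Dirichlet faces, linear sink and
    source.  ``dirichlet_faces`` is a list of (cell indices, face
    diffusivities, boundary value)."""
    inv_h2 = 1.0 / h ** 2
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n)
    b = np.zeros(n)

    def add_interior_faces(axis: int, d_vox: np.ndarray) -> None:
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        lo, hi = tuple(sl_lo), tuple(sl_hi)
        both = tissue[lo] & tissue[hi]
        d_lo, d_hi = d_vox[lo][both], d_vox[hi][both]
        t = 2.0 * d_lo * d_hi / (d_lo + d_hi) * inv_h2  # harmonic mean
        i_lo, i_hi = index[lo][both], index[hi][both]
        rows.extend([i_lo, i_hi])
        cols.extend([i_hi, i_lo])
        vals.extend([-t, -t])
        np.add.at(diag, i_lo, t)
        np.add.at(diag, i_hi, t)

    add_interior_faces(0, d_radial)
    add_interior_faces(1, d_radial)
    add_interior_faces(2, d_axial)

    for idx, d_face, value in dirichlet_faces:
        t = 2.0 * np.asarray(d_face, dtype=float) * inv_h2  # ghost at half spacing
        np.add.at(diag, idx, t)
        np.add.at(b, idx, t * value)

    diag += sink_k_flat
    b += source_flat
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    a = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return a, b


def solve_uniform_slab(n_cells: int, length: float, diffusivity: float,
                       consumption: float, c_boundary: float):
    """1-D slab solved through the same finite-volume kernel as the disc.

    A single voxel row of ``n_cells`` cells spanning ``length`` with
    zero-order volumetric consumption and both ends held at ``c_boundary``.
    Returns ``(centers, concentrations, flux_balance_rel)`` where the last
    is |boundary influx - total consumption| / total consumption.  The
    continuum solution is the parabola with midpoint deficit
    ``consumption * length^2 / (8 * diffusivity)``.
    """
    if n_cells < 2 or length <= 0 or diffusivity <= 0:
        raise ValueError("need >= 2 cells, positive length and diffusivity")
    h = length / n_cells
    shape = (1, 1, n_cells)
    tissue = np.ones(shape, dtype=bool)
    index = np.arange(n_cells).reshape(shape)
    d = np.full(shape, diffusivity)
    faces = [(np.array([0]), np.array([diffusivity]), c_boundary),
             (np.array([n_cells - 1]), np.array([diffusivity]), c_boundary)]
    a, b = _assemble_system(tissue, index, n_cells, h, d, d,
                            np.zeros(n_cells), np.full(n_cells, -consumption),
                            faces)
    c = spsolve(a, b)
    v = h ** 3
    influx = sum(float(np.sum(2.0 * df / h ** 2 * (val - c[idx]))) * v
                 for idx, df, val in faces)
    consumed = consumption * n_cells * v
    balance = abs(influx - consumed) / max(abs(consumed), 1e-300)
    centers = (np.arange(n_cells) + 0.5) * h
    return centers, c, balance


class _Discretization:
    """Index maps and per-face transmissibilities for one grid + parameters."""

    def __init__(self, grid: LabeledGrid, params: SpeciesParameters):
        self.grid = grid
        self.params = params
        labels = grid.labels
        self.tissue = labels != EXTERIOR
        self.index = -np.ones(labels.shape, dtype=np.int64)
        self.index[self.tissue] = np.arange(np.count_nonzero(self.tissue))
        self.n = int(np.count_nonzero(self.tissue))
        self.h = grid.spacing
        self.rho = np.where(labels == NP_LABEL,
                            params.cell_densities.np_density,
                            np.where(labels == AF_LABEL,
                                     params.cell_densities.af_density, 0.0))

    def voxel_diffusivity(self, metabolite: str) -> tuple[np.ndarray, np.ndarray]:
        """(radial, axial) diffusivity per voxel for one metabolite."""
        labels = self.grid.labels
        d_np = self.params.diffusion["np"][metabolite]
        d_af = self.params.diffusion["af"][metabolite]
        radial = np.where(labels == NP_LABEL, d_np.radial, d_af.radial)
        axial = np.where(labels == NP_LABEL, d_np.axial, d_af.axial)
        return radial, axial

    def assemble(self, metabolite: str, sink_k: np.ndarray, source: np.ndarray,
                 bc: BoundaryConditions, lactate_bc: tuple[float, float] | None = None):
        """Build A c = b for one metabolite with lagged linear sink.

        ``sink_k`` (1/h) and ``source`` (conc/h) are per-voxel 3-D arrays.
        ``lactate_bc`` overrides the Dirichlet values (periannular, np_cep)
        for the lactate field, whose boundary values come from the inverse
        pH coupling rather than the config directly.
        """
        grid, h, n = self.grid, self.h, self.n
        labels = grid.labels
        nz = labels.shape[2]
        radial, axial = self.voxel_diffusivity(metabolite)

        if metabolite == "lactate":
            peri_val, cep_val = lactate_bc  # type: ignore[misc]
        else:
            attr = {"glucose": "glucose", "oxygen": "oxygen"}[metabolite]
            peri_val = getattr(bc.periannular, attr)
            cep_val = getattr(bc.np_cep_interface, attr)

        dirichlet_faces: list[tuple[np.ndarray, np.ndarray, float]] = []

        # periannular Dirichlet: tissue faces adjoining exterior or the +x/+y box sides
        for axis, d_vox in ((0, radial), (1, radial)):
            shape = labels.shape
            # +side neighbor exterior or out of box
            pad_hi = np.ones(shape, dtype=bool)
            sl_this = [slice(None)] * 3
            sl_next = [slice(None)] * 3
            sl_this[axis] = slice(None, -1)
            sl_next[axis] = slice(1, None)
            pad_hi[tuple(sl_this)] = labels[tuple(sl_next)] == EXTERIOR
            faces_hi = self.tissue & pad_hi
            # -side neighbor exterior (never out of box: that's the symmetry plane)
            pad_lo = np.zeros(shape, dtype=bool)
            pad_lo[tuple(sl_next)] = labels[tuple(sl_this)] == EXTERIOR
            faces_lo = self.tissue & pad_lo
            for faces in (faces_hi, faces_lo):
                if faces.any():
                    dirichlet_faces.append(
                        (self.index[faces], d_vox[faces], peri_val))

        # NP-CEP Dirichlet on top/bottom faces over the NP footprint
        foot = grid.np_footprint()
        for k in (0, nz - 1):
            sel = self.tissue[:, :, k] & foot
            if sel.any():
                dirichlet_faces.append(
                    (self.index[:, :, k][sel], axial[:, :, k][sel], cep_val))

        a, b = _assemble_system(self.tissue, self.index, n, h, radial, axial,
                                sink_k[self.tissue], source[self.tissue],
                                dirichlet_faces)
        return a, b, dirichlet_faces

    # above this size a preconditioned conjugate gradient beats the fill-in
    # of a 3-D direct factorization; the systems are SPD M-matrices
    _DIRECT_LIMIT = 8000

    def solve_linear(self, metabolite, sink_k, source, bc, lactate_bc=None,
                     x0=None):
        a, b, dirichlet_faces = self.assemble(metabolite, sink_k, source, bc, lactate_bc)
        if self.n <= self._DIRECT_LIMIT:
            c = spsolve(a, b)
        else:
            precond = diags(1.0 / a.diagonal())
            c, info = cg(a, b, x0=x0, M=precond, rtol=1e-13, atol=0.0,
                         maxiter=20000)
            if info != 0:
                raise SolverError(f"CG failed for {metabolite} (info={info})")
        return c, dirichlet_faces

    def boundary_influx(self, c_flat: np.ndarray, dirichlet_faces) -> float:
        """Total Dirichlet influx in concentration * mm^3 / h."""
        v = self.h ** 3
        total = 0.0
        for idx, d_face, value in dirichlet_faces:
            total += float(np.sum(2.0 * d_face / self.h ** 2 * (value - c_flat[idx]))) * v
        return total

    def to_field(self, c_flat: np.ndarray) -> np.ndarray:
        out = np.full(self.grid.labels.shape, np.nan)
        out[self.tissue] = c_flat
        return out


# --------------------------------------------------------------------------
# nonlinear solve


def _metabolic_arrays(disc: _Discretization, extra_np_density: float = 0.0):
    """Per-voxel Vmax*rho prefactors (oxygen uM/h, glucose mM/h) and Km maps."""
    p = disc.params
    labels = disc.grid.labels
    rho = disc.rho.copy()
    if extra_np_density:
        rho = rho + np.where(labels == NP_LABEL, extra_np_density, 0.0)
    vmax_o2 = np.where(labels == NP_LABEL, p.metabolic_rates["np"].vmax_o2,
                       p.metabolic_rates["af"].vmax_o2)
    vmax_gl = np.where(labels == NP_LABEL, p.metabolic_rates["np"].vmax_gluc,
                       p.metabolic_rates["af"].vmax_gluc)
    km_o2 = np.where(labels == NP_LABEL, p.metabolic_rates["np"].km_o2,
                     p.metabolic_rates["af"].km_o2)
    o2_prefactor = vmax_o2 * rho * 1.0e-3  # uM/h at saturation
    gl_prefactor = vmax_gl * rho * 1.0e-6  # mM/h at saturation
    return o2_prefactor, gl_prefactor, km_o2


def solve_steady_state(
    grid: LabeledGrid,
    params: SpeciesParameters,
    settings: SolverSettings = SolverSettings(),
    boundaries: BoundaryConditions | None = None,
    extra_np_density: float = 0.0,
) -> SteadyStateFields:
    """Solve the coupled steady-state nutrient fields on *grid*.

    ``extra_np_density`` adds injected cells (cells/mm^3, uniform in NP) to
    the metabolically active density.  ``boundaries`` overrides the config
    boundary conditions (used by calibration).

    Raises :class:`SolverError` with the residual history on
    non-convergence.
    """
    disc = _Discretization(grid, params)
    if disc.n == 0:
        raise SolverError("grid contains no tissue voxels")
    bc = boundaries if boundaries is not None else params.boundaries
    coupling = params.ph_coupling
    lac_bc = (ph_to_lactate(bc.periannular.ph, coupling),
              ph_to_lactate(bc.np_cep_interface.ph, coupling))
    o2_pre, gl_pre, km_o2 = _metabolic_arrays(disc, extra_np_density)
    km_gl = params.glucose_km
    ratio = params.lactate_glucose_ratio
    zeros = np.zeros_like(disc.rho)

    # initial guesses: boundary-mixture constants
    c_gluc = np.full(disc.n, 0.5 * (bc.periannular.glucose + bc.np_cep_interface.glucose))
    c_o2 = np.full(disc.n, 0.5 * (bc.periannular.oxygen + bc.np_cep_interface.oxygen))
    c_lac = np.full(disc.n, 0.5 * (lac_bc[0] + lac_bc[1]))
    ph = lactate_to_ph(c_lac, coupling)

    tissue = disc.tissue
    omega = settings.relaxation
    history: list[float] = []
    ph_clamped = False
    result = None
    for it in range(1, settings.max_outer + 1):
        # glucose with lagged Michaelis-Menten sink
        k_gl = np.zeros_like(zeros)
        k_gl[tissue] = gl_pre[tissue] / (km_gl + c_gluc)
        gluc_new, gl_faces = disc.solve_linear("glucose", k_gl, zeros, bc, x0=c_gluc)

        # lactate: source = ratio x realized glucose sink
        gl_sink = k_gl[tissue] * gluc_new  # mM/h
        src_lac = np.zeros_like(zeros)
        src_lac[tissue] = ratio * gl_sink
        lac_new, lac_faces = disc.solve_linear("lactate", np.zeros_like(zeros),
                                               src_lac, bc, lactate_bc=lac_bc,
                                               x0=c_lac)

        ph_new = lactate_to_ph(lac_new, coupling)
        if np.any(ph_new <= PH_NUMERATOR_OFFSET + 0.051):
            ph_clamped = True

        # oxygen with lagged pH-modulated sink
        k_o2 = np.zeros_like(zeros)
        k_o2[tissue] = (o2_pre[tissue] * (ph_new - PH_NUMERATOR_OFFSET)
                        / (km_o2[tissue] * (ph_new - PH_DENOMINATOR_OFFSET) + c_o2))
        o2_new, o2_faces = disc.solve_linear("oxygen", k_o2, zeros, bc, x0=c_o2)

        def relchange(old, new):
            scale = max(float(np.max(np.abs(new))), 1e-300)
            return float(np.max(np.abs(new - old))) / scale

        res = max(relchange(c_gluc, gluc_new), relchange(c_lac, lac_new),
                  relchange(c_o2, o2_new))
        history.append(res)

        c_gluc = (1 - omega) * c_gluc + omega * gluc_new
        c_lac = (1 - omega) * c_lac + omega * lac_new
        c_o2 = (1 - omega) * c_o2 + omega * o2_new
        ph = lactate_to_ph(c_lac, coupling)

        if res < settings.tolerance:
            # one final un-relaxed pass so the reported fields satisfy their
            # linear systems exactly (machine-accurate flux balance)
            c_gluc, gl_faces = disc.solve_linear("glucose", k_gl, zeros, bc, x0=c_gluc)
            gl_sink = k_gl[tissue] * c_gluc
            src_lac[tissue] = ratio * gl_sink
            c_lac, lac_faces = disc.solve_linear("lactate", np.zeros_like(zeros),
                                                 src_lac, bc, lactate_bc=lac_bc,
                                                 x0=c_lac)
            ph = lactate_to_ph(c_lac, coupling)
            k_o2[tissue] = (o2_pre[tissue] * (ph - PH_NUMERATOR_OFFSET)
                            / (km_o2[tissue] * (ph - PH_DENOMINATOR_OFFSET) + c_o2))
            c_o2, o2_faces = disc.solve_linear("oxygen", k_o2, zeros, bc, x0=c_o2)
            result = (gl_faces, lac_faces, o2_faces, k_gl, k_o2, src_lac)
            break

    if result is None:
        raise SolverError(
            f"no convergence in {settings.max_outer} outer iterations "
            f"(last residual {history[-1]:.3e})", history)

    gl_faces, lac_faces, o2_faces, k_gl, k_o2, src_lac = result
    v = disc.h ** 3
    cons_gl = float(np.sum(k_gl[tissue] * c_gluc)) * v  # mM * mm^3 / h
    cons_o2 = float(np.sum(k_o2[tissue] * c_o2)) * v  # uM * mm^3 / h
    prod_lac = float(np.sum(src_lac[tissue])) * v

    def balance(influx: float, cons: float) -> float:
        denom = max(abs(cons), 1e-300)
        return abs(influx - cons) / denom

    flux_balance = {
        "glucose": balance(disc.boundary_influx(c_gluc, gl_faces), cons_gl),
        "oxygen": balance(disc.boundary_influx(c_o2, o2_faces), cons_o2),
        # lactate is produced, so boundary flux is an efflux of -production
        "lactate": balance(-disc.boundary_influx(c_lac, lac_faces), prod_lac),
    }
    return SteadyStateFields(
        oxygen=disc.to_field(c_o2),
        glucose=disc.to_field(c_gluc),
        lactate=disc.to_field(c_lac),
        ph=disc.to_field(ph),
        iterations=it,
        residual_history=tuple(history),
        flux_balance=flux_balance,
        total_consumption={"glucose": cons_gl, "oxygen": cons_o2, "lactate": prod_lac},
        ph_clamped=ph_clamped,
    )


# --------------------------------------------------------------------------
# post-processing


def _midheight_plane(field: np.ndarray, grid: LabeledGrid) -> np.ndarray:
    """Quadratic z-interpolation of a voxel field onto the exact mid-height
    plane (voxel layers rarely sit exactly at z = H/2, and the fields have
    strong axial curvature near the NP-CEP routes)."""
    nz = field.shape[2]
    if nz < 3:
        return field[:, :, nz // 2]
    z = grid.centers(2)
    zm = grid.geometry.height / 2.0
    k = int(np.clip(np.argmin(np.abs(z - zm)), 1, nz - 2))
    zs = z[k - 1: k + 2]
    w = np.array([
        (zm - zs[1]) * (zm - zs[2]) / ((zs[0] - zs[1]) * (zs[0] - zs[2])),
        (zm - zs[0]) * (zm - zs[2]) / ((zs[1] - zs[0]) * (zs[1] - zs[2])),
        (zm - zs[0]) * (zm - zs[1]) / ((zs[2] - zs[0]) * (zs[2] - zs[1])),
    ])
    return field[:, :, k - 1] * w[0] + field[:, :, k] * w[1] + field[:, :, k + 1] * w[2]


def central_concentrations(fields: SteadyStateFields, grid: LabeledGrid,
                           solubility: float) -> tuple[float, float, float]:
    """(glucose mM, pH, oxygen %O2) at the NP centroid (disc center at
    mid-height, i.e. the quadrant origin)."""
    if not np.any(grid.labels == NP_LABEL):
        raise SolverError("grid has no NP voxels")

    def center(field: np.ndarray) -> float:
        plane = _midheight_plane(field, grid)
        # voxel centers sit at h/2 off the symmetry planes; extrapolate to
        # the true center with the even (mirror-symmetric) quadratic
        # c(x) = a + b x^2 fitted along each in-plane axis
        c00, c10, c01 = plane[0, 0], plane[1, 0], plane[0, 1]
        return float(c00 - (c10 - c00) / 8.0 - (c01 - c00) / 8.0)

    gluc = center(fields.glucose)
    ph = center(fields.ph)
    o2 = center(fields.oxygen)
    return gluc, ph, oxygen_concentration_to_percent(o2, solubility)


def extract_ap_profile(fields: SteadyStateFields, grid: LabeledGrid,
                       params: SpeciesParameters,
                       boundaries: BoundaryConditions | None = None) -> pd.DataFrame:
    """Anterior-to-posterior mid-height profile through the disc center.

    Samples the x ~ 0 voxel column at mid-height along +y and mirrors it to
    the full anterior-posterior line; the two endpoints carry the imposed
    periannular boundary values at the tissue surface, and the center
    sample at position 0 is the :func:`central_concentrations` value.
    Columns: ``position_mm`` (0 at the disc center), ``domain``,
    ``glucose_mM``, ``ph``, ``o2_pct``.
    """
    bc = boundaries if boundaries is not None else params.boundaries
    col = grid.labels[0, :, grid.labels.shape[2] // 2]
    tissue_j = np.nonzero(col != EXTERIOR)[0]
    if tissue_j.size == 0:
        raise SolverError("empty anterior-posterior line")
    y = grid.centers(1)[tissue_j]
    dom = np.where(col[tissue_j] == NP_LABEL, "np", "af")
    gluc = _midheight_plane(fields.glucose, grid)[0, tissue_j]
    ph = _midheight_plane(fields.ph, grid)[0, tissue_j]
    o2 = _midheight_plane(fields.oxygen, grid)[0, tissue_j] / params.oxygen_solubility

    surface = y[-1] + grid.spacing / 2.0
    peri = bc.periannular
    pos = np.concatenate([[-surface], -y[::-1], [0.0], y, [surface]])
    dom_full = np.concatenate([["boundary"], dom[::-1], ["np"], dom, ["boundary"]])
    o2_b = oxygen_concentration_to_percent(peri.oxygen, params.oxygen_solubility)
    c_gluc, c_ph, c_o2 = central_concentrations(fields, grid, params.oxygen_solubility)

    def stack(values, bval, cval):
        return np.concatenate([[bval], values[::-1], [cval], values, [bval]])

    return pd.DataFrame({
        "position_mm": pos,
        "domain": dom_full,
        "glucose_mM": stack(gluc, peri.glucose, c_gluc),
        "ph": stack(ph, peri.ph, c_ph),
        "o2_pct": stack(o2, o2_b, c_o2),
    })


# --------------------------------------------------------------------------
# boundary calibration


@dataclass(frozen=True)
class CalibrationResult:
    boundaries: BoundaryConditions
    cost: float
    residuals: dict[str, float]
    n_solves: int
    at_bound: bool
    zero_iteration: bool
    message: str = ""


def _scaled_boundaries(initial: BoundaryConditions, x: np.ndarray,
                       metabolites: tuple[str, ...]) -> BoundaryConditions:
    """Apply per-metabolite adjustments to both routes.

    Glucose and oxygen scale multiplicatively; pH shifts additively (it is
    logarithmic already).
    """
    vals = {"periannular": {}, "np_cep_interface": {}}
    for route, bv in (("periannular", initial.periannular),
                      ("np_cep_interface", initial.np_cep_interface)):
        vals[route] = {"glucose": bv.glucose, "oxygen": bv.oxygen, "ph": bv.ph}
    for i, met in enumerate(metabolites):
        for route in vals:
            if met == "ph":
                vals[route]["ph"] = vals[route]["ph"] + x[i]
            else:
                vals[route][met] = vals[route][met] * x[i]
    return BoundaryConditions(
        periannular=BoundaryValues(**vals["periannular"]),
        np_cep_interface=BoundaryValues(**vals["np_cep_interface"]),
    )


def calibrate_boundaries(
    measured: pd.DataFrame,
    initial: BoundaryConditions,
    grid: LabeledGrid,
    params: SpeciesParameters,
    settings: SolverSettings | None = None,
    metabolites: tuple[str, ...] = ("glucose", "oxygen", "ph"),
    initial_tol: float = 1.0e-8,
    max_nfev: int = 40,
) -> CalibrationResult:
    """Adjust boundary values so predicted central values match probe data.

    *measured* is a long-format frame with columns ``metabolite`` (glucose /
    oxygen / ph) and ``value`` (glucose mM, oxygen %O2, pH), one row per
    probed disc; per-metabolite means are the fitting targets.  One
    adjustment factor per metabolite is applied to both boundary routes
    jointly (a single central measurement cannot separate the two routes):
    multiplicative for glucose and oxygen, additive for pH.  Bounds keep
    the search inside physiological ranges.
    """
    if settings is None:
        # full relaxation + moderate tolerance: the fixed point is contractive
        # at physiological parameters and each optimizer step re-solves anyway
        settings = SolverSettings(tolerance=1.0e-8, relaxation=1.0)
    targets = {}
    for met in metabolites:
        sel = measured.loc[measured["metabolite"] == met, "value"]
        if sel.empty:
            raise SolverError(f"no measurements for calibrated metabolite {met!r}")
        targets[met] = float(sel.mean())
    scales = {met: max(abs(t), 0.1) for met, t in targets.items()}
    n_solves = 0

    def predict(bc: BoundaryConditions) -> dict[str, float]:
        nonlocal n_solves
        n_solves += 1
        fields = solve_steady_state(grid, params, settings, boundaries=bc)
        gluc, ph, o2 = central_concentrations(fields, grid, params.oxygen_solubility)
        return {"glucose": gluc, "oxygen": o2, "ph": ph}

    def residual_vec(pred: dict[str, float]) -> np.ndarray:
        return np.array([(pred[m] - targets[m]) / scales[m] for m in metabolites])

    pred0 = predict(initial)
    r0 = residual_vec(pred0)
    if float(np.max(np.abs(r0))) < initial_tol:
        return CalibrationResult(
            boundaries=initial, cost=0.5 * float(r0 @ r0),
            residuals={m: pred0[m] - targets[m] for m in metabolites},
            n_solves=n_solves, at_bound=False, zero_iteration=True,
            message="initial boundaries already match the measurements")

    x0, lo, hi = [], [], []
    for met in metabolites:
        if met == "ph":
            x0.append(0.0)
            lo.append(-0.6)
            hi.append(0.6)
        else:
            x0.append(1.0)
            lo.append(0.2)
            hi.append(3.0)

    def fun(x: np.ndarray) -> np.ndarray:
        bc = _scaled_boundaries(initial, x, metabolites)
        return residual_vec(predict(bc))

    res = optimize.least_squares(fun, np.array(x0), bounds=(lo, hi),
                                 diff_step=1e-2, xtol=1e-8, ftol=1e-10,
                                 gtol=1e-10, max_nfev=max_nfev)
    bc = _scaled_boundaries(initial, res.x, metabolites)
    pred = predict(bc)
    at_bound = bool(np.any(np.isclose(res.x, lo, atol=1e-9))
                    or np.any(np.isclose(res.x, hi, atol=1e-9)))
    return CalibrationResult(
        boundaries=bc, cost=float(res.cost),
        residuals={m: pred[m] - targets[m] for m in metabolites},
        n_solves=n_solves, at_bound=at_bound, zero_iteration=False,
        message=res.message)
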