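"""Idealized disc geometries and labeled voxel grids.

The disc is modeled as an elliptic cylinder (flat endplates) containing an
elliptic-cylindrical nucleus pulposus (NP) core surrounded by the annulus
fibrosus (AF).  Exploiting the two in-plane mirror symmetries, only one
quadrant is rasterized: x >= 0 (lateral), y >= 0 (anterior-posterior), with
the disc center at the origin and z spanning the full height.

Boundary routes:

* ``periannular`` — the outer lateral surface (all metabolites Dirichlet);
* ``np_cep`` — the top/bottom faces over the NP footprint, standing in for
  transport across the cartilaginous endplate (Dirichlet);
* top/bottom faces over the AF footprint are zero-flux;
* the two symmetry planes are zero-flux by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "ResolutionError",
    "DiscGeometry",
    "LabeledGrid",
    "build_disc_geometry",
    "rasterize",
    "domain_volume",
]

EXTERIOR, NP_LABEL, AF_LABEL = 0, 1, 2
LABELS = {"exterior": EXTERIOR, "np": NP_LABEL, "af": AF_LABEL}

# boundary tag bits (per voxel: the voxel owns at least one face of the type)
TAG_PERIANNULAR = 1
TAG_NP_CEP = 2
TAG_SYMMETRY = 4


class GeometryError(ValueError):
    pass


class ResolutionError(ValueError):
    pass


@dataclass(frozen=True)
class DiscGeometry:
    """Validated idealized quadrant disc geometry (all lengths mm)."""

    species: str
    af_semi_lateral: float
    af_semi_ap: float
    np_semi_lateral: float
    np_semi_ap: float
    height: float

    def __post_init__(self) -> None:
        dims = (self.af_semi_lateral, self.af_semi_ap,
                self.np_semi_lateral, self.np_semi_ap, self.height)
        if any(d <= 0 for d in dims):
            raise GeometryError("all dimensions must be positive")
        if (self.np_semi_lateral >= self.af_semi_lateral
                or self.np_semi_ap >= self.af_semi_ap):
            raise GeometryError("NP semi-axes must lie strictly inside the AF")

    # analytic volumes of the FULL disc (not the quadrant)
    @property
    def np_volume(self) -> float:
        return math.pi * self.np_semi_lateral * self.np_semi_ap * self.height

    @property
    def disc_volume(self) -> float:
        return math.pi * self.af_semi_lateral * self.af_semi_ap * self.height

    @property
    def af_volume(self) -> float:
        return self.disc_volume - self.np_volume

    @property
    def quadrant_np_volume(self) -> float:
        return self.np_volume / 4.0

    @property
    def quadrant_disc_volume(self) -> float:
        return self.disc_volume / 4.0


def build_disc_geometry(spec: dict[str, float], species: str = "") -> DiscGeometry:
    """Build a geometry from the named-dimension block of a species config."""
    try:
        return DiscGeometry(
            species=species,
            af_semi_lateral=float(spec["af_semi_lateral"]),
            af_semi_ap=float(spec["af_semi_ap"]),
            np_semi_lateral=float(spec["np_semi_lateral"]),
            np_semi_ap=float(spec["np_semi_ap"]),
            height=float(spec["height"]),
        )
    except KeyError as e:
        raise GeometryError(f"geometry spec missing dimension {e.args[0]!r}") from None


@dataclass(frozen=True)
class LabeledGrid:
    """Uniform voxel grid over the quadrant bounding box.

    ``labels[i, j, k]`` with i along lateral x, j along A-P y, k along the
    disc axis z; voxel centers at ``(i + 1/2) h`` etc.  ``tags`` is a bitmask
    of boundary-face types per voxel (see TAG_* constants).
    """

    geometry: DiscGeometry
    spacing: float
    labels: np.ndarray  # int8, shape (nx, ny, nz)
    tags: np.ndarray  # uint8, same shape

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def centers(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return (np.arange(n) + 0.5) * self.spacing

    def np_footprint(self) -> np.ndarray:
        """(nx, ny) bool mask of columns whose center lies inside the NP ellipse."""
        g = self.geometry
        x = self.centers(0)[:, None]
        y = self.centers(1)[None, :]
        return (x / g.np_semi_lateral) ** 2 + (y / g.np_semi_ap) ** 2 <= 1.0


def rasterize(geometry: DiscGeometry, spacing: float) -> LabeledGrid:
    """Rasterize one quadrant by voxel-center membership.

    The requested spacing is snapped so that an integer number of voxel
    layers spans the disc height *exactly* (every z-layer is tissue, so an
    overshooting layer would thicken the modeled disc by a
    resolution-dependent amount and spoil mesh convergence).  In-plane the
    bounding box may overshoot harmlessly into exterior voxels.

    Requires at least 8 voxels across the smallest NP semi-axis; coarser
    spacing raises :class:`ResolutionError`.
    """
    if spacing <= 0:
        raise ResolutionError("spacing must be positive")
    nz = max(2, round(geometry.height / spacing))
    spacing = geometry.height / nz
    smallest = min(geometry.np_semi_lateral, geometry.np_semi_ap)
    if smallest / spacing < 8.0:
        raise ResolutionError(
            f"snapped spacing {spacing:.4g} too coarse: fewer than 8 voxels "
            f"across the smallest NP semi-axis ({smallest} mm)"
        )
    nx = int(math.ceil(geometry.af_semi_lateral / spacing))
    ny = int(math.ceil(geometry.af_semi_ap / spacing))

    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    r_af = (x[:, None] / geometry.af_semi_lateral) ** 2 + (y[None, :] / geometry.af_semi_ap) ** 2
    r_np = (x[:, None] / geometry.np_semi_lateral) ** 2 + (y[None, :] / geometry.np_semi_ap) ** 2

    plane = np.full((nx, ny), EXTERIOR, dtype=np.int8)
    plane[r_af <= 1.0] = AF_LABEL
    plane[r_np <= 1.0] = NP_LABEL
    labels = np.repeat(plane[:, :, None], nz, axis=2)

    tags = np.zeros_like(labels, dtype=np.uint8)
    tissue = labels != EXTERIOR
    # periannular: tissue voxel with an exterior in-plane neighbor; out-of-box
    # counts as exterior on the +x/+y sides only (the -x/-y sides are the
    # symmetry planes, interior to the full disc)
    ext = np.zeros((nx + 2, ny + 2), dtype=bool)
    ext[1:-1, 1:-1] = plane == EXTERIOR
    ext[-1, :] = True
    ext[:, -1] = True
    peri_plane = (plane != EXTERIOR) & (
        ext[:-2, 1:-1] | ext[2:, 1:-1] | ext[1:-1, :-2] | ext[1:-1, 2:]
    )
    tags[peri_plane, :] |= TAG_PERIANNULAR
    # NP-CEP: top and bottom voxel layers over the NP footprint
    np_foot = r_np <= 1.0
    tags[:, :, 0][np_foot] |= TAG_NP_CEP
    tags[:, :, -1][np_foot] |= TAG_NP_CEP
    # symmetry planes: faces at x=0 and y=0
    tags[0, :, :][tissue[0, :, :]] |= TAG_SYMMETRY
    tags[:, 0, :][tissue[:, 0, :]] |= TAG_SYMMETRY

    return LabeledGrid(geometry=geometry, spacing=spacing, labels=labels, tags=tags)


def domain_volume(grid: LabeledGrid, domain: str) -> float:
    """Voxelized volume (mm^3) of one domain label within the quadrant."""
    if domain not in LABELS:
        raise GeometryError(f"unknown domain label {domain!r}")
    return float(np.count_nonzero(grid.labels == LABELS[domain])) * grid.voxel_volume
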