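"""Zone projections and 1-D diffuse-intensity profiles from a reconstructed
reciprocal-space volume.

Given the orientation matrix of the average structure, a pathway such as
``10l`` (anchor (1,0,0), direction (0,0,1)) is sampled as the continuous
reciprocal position ``B (anchor + t * direction)``; the profile value at
each sample is the mean over an integration tube around the path, so rods
of diffuse intensity between the Bragg nodes show up directly against the
off-row background.  Samples falling outside the reconstructed wedge are
flagged rather than zero-filled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import CoverageError, GeometryError
from .model import UnitCell, VoxelVolume

__all__ = ["PathwaySpec", "project_zone", "extract_profile"]


@dataclass
class PathwaySpec:
    """A line through reciprocal space in lattice coordinates."""

    anchor_hkl: tuple[float, float, float]
    direction_hkl: tuple[int, int, int]
    t_range: tuple[float, float] = (-8.0, 8.0)
    samples_per_unit: int = 10
    line_thickness_A: Optional[float] = None  # default 1.5 voxels at run time
    zone_vector: Optional[tuple[int, int, int]] = None
    slab_thickness_A: Optional[float] = None

    def __post_init__(self) -> None:
        if not any(self.direction_hkl):
            raise GeometryError("pathway direction must be nonzero")
        if self.t_range[1] <= self.t_range[0]:
            raise GeometryError("t_max must exceed t_min")
        if self.samples_per_unit < 2:
            raise GeometryError("samples_per_unit must be >= 2")


def _in_zone_axes(cell: UnitCell, zone_vector) -> tuple[np.ndarray, np.ndarray]:
    """The two shortest non-collinear reciprocal lattice vectors hkl in the
    zone h*u + k*v + l*w = 0."""
    u = np.asarray(zone_vector, dtype=np.int64)
    cands = []
    for hkl in itertools.product(range(-4, 5), repeat=3):
        h = np.array(hkl, dtype=np.int64)
        if not h.any() or h @ u != 0:
            continue
        nz = h[h != 0]
        if nz[0] < 0:  # keep one representative of +-h, positive-leading
            continue
        cands.append(h)
    if not cands:
        raise GeometryError("no reciprocal lattice vectors found in the zone")
    cands.sort(key=lambda h: (np.linalg.norm(cell.B @ h), tuple(h)))
    e1 = cands[0]
    for h in cands[1:]:
        if np.linalg.norm(np.cross(e1, h)) > 0:
            return e1, h
    raise GeometryError("zone axes are collinear (degenerate zone vector)")


def project_zone(
    vol: VoxelVolume,
    cell: UnitCell,
    zone_vector,
    slab_thickness_A: float,
    mode: str = "max",
):
    """Project the slab about the zone plane through the origin.

    The zone axis is a direct-lattice direction; its lab-frame vector (via
    the cell's direct basis) is the plane normal.  Returns ``(image,
    (hkl_axis1, hkl_axis2))`` where the image pixel scale is the voxel
    edge and the two axes are the shortest reciprocal vectors in the zone.
    """
    zone = np.asarray(zone_vector, dtype=np.float64)
    if not zone.any():
        raise GeometryError("zone vector must be nonzero")
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    n = cell.direct_basis() @ zone
    n_hat = n / np.linalg.norm(n)
    e1_hkl, e2_hkl = _in_zone_axes(cell, zone_vector)
    ex = cell.B @ e1_hkl
    ex = ex / np.linalg.norm(ex)
    ey = np.cross(n_hat, ex)

    shape = vol.grid.shape
    half = int(max(shape))
    npix = 2 * half + 1
    img = np.zeros((npix, npix))
    iy, iz = np.mgrid[0 : shape[1], 0 : shape[2]]
    iy, iz = iy.ravel(), iz.ravel()
    hit = False
    for ix in range(shape[0]):
        coords = vol.origin + np.column_stack([np.full(iy.shape, ix), iy, iz]) * vol.voxel_A
        sel = np.abs(coords @ n_hat) <= slab_thickness_A / 2
        if not sel.any():
            continue
        hit = True
        p1 = coords[sel] @ ex
        p2 = coords[sel] @ ey
        vals = vol.grid[ix, iy[sel], iz[sel]]
        j1 = np.round(p1 / vol.voxel_A).astype(np.int64) + half
        j2 = np.round(p2 / vol.voxel_A).astype(np.int64) + half
        inb = (j1 >= 0) & (j1 < npix) & (j2 >= 0) & (j2 < npix)
        if mode == "sum":
            np.add.at(img, (j1[inb], j2[inb]), vals[inb])
        else:
            np.maximum.at(img, (j1[inb], j2[inb]), vals[inb])
    if not hit:
        raise GeometryError("slab does not intersect the volume")
    return img, (tuple(int(v) for v in e1_hkl), tuple(int(v) for v in e2_hkl))


def _tube_offsets(radius_vox: float, direction: np.ndarray) -> np.ndarray:
    """Stencil of offsets (voxel units) filling the disk of the integration
    tube perpendicular to the path direction: the centre plus two rings.
    Built in the plane normal to the path so the tube rotates with the
    lattice and profiles are rotation-covariant."""
    d = direction / np.linalg.norm(direction)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ d) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    offs = [np.zeros(3)]
    for r in (radius_vox / 2.0, radius_vox):
        for theta in np.arange(8) * (math.pi / 4.0):
            offs.append(r * (math.cos(theta) * e1 + math.sin(theta) * e2))
    return np.array(offs)


def extract_profile(
    vol: VoxelVolume,
    cell: UnitCell,
    path: PathwaySpec,
    interpolation: str = "linear",
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Sample intensity along the pathway.

    Returns a DataFrame with columns (t, h, k, l, intensity, n_voxels,
    in_volume).  ``intensity`` is the mean over a stencil of points within
    the tube radius, evaluated with trilinear interpolation (or at the
    nearest voxel centres with ``interpolation='nearest'``).  Raises
    :class:`CoverageError` when less than ``min_coverage`` of the samples
    lie inside the volume (the missing-wedge case), reporting the missing
    t-range.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    thickness = path.line_thickness_A if path.line_thickness_A is not None else 1.5 * vol.voxel_A
    radius_vox = thickness / vol.voxel_A

    t0, t1 = path.t_range
    n = int(round((t1 - t0) * path.samples_per_unit)) + 1
    ts = t0 + np.arange(n) / path.samples_per_unit
    anchor = np.asarray(path.anchor_hkl, dtype=np.float64)
    direction = np.asarray(path.direction_hkl, dtype=np.float64)
    frac = anchor[None, :] + ts[:, None] * direction[None, :]
    g = frac @ cell.B.T
    idx = vol.index_of(g)  # fractional voxel indices, (n, 3)
    offs = _tube_offsets(radius_vox, cell.B @ direction)

    shape = np.array(vol.grid.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    coverage = inside.mean() if n else 0.0
    if coverage < min_coverage:
        missing = ts[~inside]
        raise CoverageError(
            f"only {100*coverage:.1f}% of the path is inside the volume; "
            f"missing t in [{missing.min():.2f}, {missing.max():.2f}]"
        )

    intens = np.full(n, np.nan)
    nvox = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if not inside[i]:
            continue
        if interpolation == "nearest":
            pts = np.round(idx[i])[None, :] + offs
        else:
            pts = idx[i][None, :] + offs
        ok = np.all((pts >= 0) & (pts <= shape - 1), axis=1)
        pts = pts[ok]
        if not len(pts):
            continue
        vals = map_coordinates(vol.grid, pts.T, order=1 if interpolation == "linear" else 0,
                               mode="nearest")
        intens[i] = float(vals.mean())
        nvox[i] = len(pts)

    return pd.DataFrame(
        {
            "t": ts,
            "h": frac[:, 0],
            "k": frac[:, 1],
            "l": frac[:, 2],
            "intensity": intens,
            "n_voxels": nvox,
            "in_volume": inside,
        }
    )
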