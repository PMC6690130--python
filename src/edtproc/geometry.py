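"""Tilt-axis determination, Ewald-corrected back-projection and voxel
reconstruction.

A diffraction frame is not a plane section of reciprocal space but a cap of
the Ewald sphere of radius 1/lambda; back-projection therefore assigns each
detector position the out-of-plane component
``g_z = 1/lambda - sqrt(1/lambda^2 - r^2)`` (sphere tangent to the frame
plane at the pattern centre, g_z positive toward the electron source)
before rotating by the goniometer angle about the in-plane tilt axis
``(sin phi, cos phi, 0)`` (right-handed).

The tilt-axis azimuth phi is unknown a priori; it is found by demanding
that the back-projected peak cloud be as lattice-like as possible: pairwise
difference vectors are normalized onto the unit sphere, mapped by
stereographic projection to a plane, and histogrammed - at the correct phi
the directions collapse onto sharp lines and points, which a sum of squared
bin counts scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ResourceError
from .model import DiffractionFrame, Peak2D, Peak3D, TiltSeries, VoxelVolume

log = logging.getLogger(__name__)

__all__ = [
    "GeometrySolution",
    "ewald_backproject",
    "find_tilt_axis",
    "build_peaks3d",
    "merge_peaks3d",
    "reconstruct_volume",
    "slice_volume",
]


@dataclass
class GeometrySolution:
    """Result of the tilt-axis search."""

    phi_deg: float
    score: float
    score_curve: np.ndarray  # (n, 2) columns (phi, score)
    reliable: bool = True


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def _tilt_matrix(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Rodrigues rotation by theta about the axis (sin phi, cos phi, 0)."""
    p = math.radians(phi_deg)
    t = math.radians(theta_deg)
    ux, uy = math.sin(p), math.cos(p)
    c, s = math.cos(t), math.sin(t)
    C = 1 - c
    return np.array(
        [
            [c + ux * ux * C, ux * uy * C, uy * s],
            [ux * uy * C, c + uy * uy * C, -ux * s],
            [-uy * s, ux * s, c],
        ]
    )


def _ewald_vector(xy_px, center_px, px_cal: float, wavelength_A: float) -> np.ndarray:
    """Pre-rotation Ewald vectors for detector positions (vectorized)."""
    xy = np.atleast_2d(np.asarray(xy_px, dtype=np.float64))
    cx, cy = center_px
    gx = (xy[:, 0] - cx) * px_cal
    gy = (xy[:, 1] - cy) * px_cal
    r2 = gx * gx + gy * gy
    inv_lam = 1.0 / wavelength_A
    bad = r2 >= inv_lam * inv_lam
    if np.any(bad):
        raise GeometryError(
            f"{int(bad.sum())} position(s) beyond the Ewald sphere radius 1/lambda"
        )
    gz = inv_lam - np.sqrt(inv_lam * inv_lam - r2)
    return np.column_stack([gx, gy, gz])


def ewald_backproject(
    xy_px,
    center_px,
    px_cal: float,
    wavelength_A: float,
    tilt_deg: float,
    phi_deg: float,
) -> np.ndarray:
    """Back-project detector position(s) to 3-D reciprocal coordinates.

    Accepts one ``(x, y)`` pair or an (N, 2) array; returns a 3-vector or
    (N, 3) array in 1/Angstrom.
    """
    single = np.asarray(xy_px).ndim == 1
    e = _ewald_vector(xy_px, center_px, px_cal, wavelength_A)
    g = e @ _tilt_matrix(phi_deg, tilt_deg).T
    return g[0] if single else g


# ---------------------------------------------------------------------------
# tilt-axis search
# ---------------------------------------------------------------------------

_HIST_BINS = 512
_DIFF_CAP_A = 1.0
_DIFF_MAX_PAIRS = 200_000


def _collect_ewald(peaks: Sequence[Peak2D], series: TiltSeries):
    """Pre-rotation Ewald vectors and tilt of every peak (phi-independent)."""
    e_list, tilt_idx = [], []
    for p in peaks:
        frame = series.frames[p.frame_idx]
        if frame.center_px is None:
            raise GeometryError(f"frame {p.frame_idx} has no centre; run centring first")
        e_list.append(
            _ewald_vector([(p.x, p.y)], frame.center_px, frame.px_cal, series.wavelength_A)[0]
        )
        tilt_idx.append(p.frame_idx)
    return np.array(e_list), np.array(tilt_idx, dtype=np.int64)


def _rotate_all(e: np.ndarray, tilt_idx: np.ndarray, tilts: np.ndarray, phi: float) -> np.ndarray:
    mats = np.stack([_tilt_matrix(phi, t) for t in tilts])
    return np.einsum("nij,nj->ni", mats[tilt_idx], e)


def _sharpness(diffs: np.ndarray) -> float:
    """Sum of squared bin counts of the stereographic direction histogram."""
    norms = np.linalg.norm(diffs, axis=1)
    ok = norms > 1e-12
    v = diffs[ok] / norms[ok, None]
    flip = v[:, 2] < 0  # antipodal +-v fold onto the z >= 0 hemisphere
    v[flip] *= -1.0
    # stereographic projection from the south pole onto the equatorial plane
    denom = 1.0 + v[:, 2]
    X = v[:, 0] / denom
    Y = v[:, 1] / denom
    ix = np.clip(((X + 1.0) * 0.5 * _HIST_BINS).astype(np.int64), 0, _HIST_BINS - 1)
    iy = np.clip(((Y + 1.0) * 0.5 * _HIST_BINS).astype(np.int64), 0, _HIST_BINS - 1)
    counts = np.bincount(ix * _HIST_BINS + iy, minlength=_HIST_BINS * _HIST_BINS)
    return float((counts.astype(np.float64) ** 2).sum())


def find_tilt_axis(
    peaks: Sequence[Peak2D],
    series: TiltSeries,
    coarse_step_deg: float = 1.0,
    refine_tol_deg: float = 0.01,
) -> GeometrySolution:
    """Find the tilt-axis azimuth phi in [-90, 90) maximizing the
    stereographic sharpness of the difference-vector directions.

    Coarse 1-degree grid scan followed by golden-section refinement.  With
    fewer than 10 peaks or fewer than 5 frames (or a flat score curve) the
    solution is flagged unreliable.
    """
    e, tilt_idx = _collect_ewald(peaks, series)
    tilts = series.tilts_deg
    degenerate = len(peaks) < 10 or len(np.unique(tilt_idx)) < 5

    # pair selection at a reference phi; which pairs are "short" barely
    # depends on phi, the difference directions do
    g_ref = _rotate_all(e, tilt_idx, tilts, 0.0)
    tree = cKDTree(g_ref)
    pairs = tree.query_pairs(r=_DIFF_CAP_A * 1.25, output_type="ndarray")
    if len(pairs) > _DIFF_MAX_PAIRS:
        d = np.linalg.norm(g_ref[pairs[:, 0]] - g_ref[pairs[:, 1]], axis=1)
        pairs = pairs[np.argsort(d, kind="stable")[:_DIFF_MAX_PAIRS]]
    if len(pairs) == 0:
        raise GeometryError("no difference vectors within the magnitude cap")

    def score(phi: float) -> float:
        g = _rotate_all(e, tilt_idx, tilts, phi)
        d = g[pairs[:, 0]] - g[pairs[:, 1]]
        keep = np.linalg.norm(d, axis=1) <= _DIFF_CAP_A
        return _sharpness(d[keep])

    phis = np.arange(-90.0, 90.0, coarse_step_deg)
    scores = np.array([score(p) for p in phis])
    best_i = int(np.argmax(scores))

    # golden-section refinement inside the bracketing interval
    lo = phis[best_i] - coarse_step_deg
    hi = phis[best_i] + coarse_step_deg
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, f2 = score(c1), score(c2)
    while b - a > refine_tol_deg:
        if f1 > f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = score(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = score(c2)
    phi_best = (a + b) / 2
    if phi_best >= 90.0:
        phi_best -= 180.0
    score_best = score(phi_best)

    flat = scores.max() / max(np.median(scores), 1e-12) < 1.05
    reliable = not (flat or degenerate)
    if not reliable:
        log.warning("tilt-axis solution flagged unreliable (flat=%s, degenerate=%s)",
                    flat, degenerate)
    curve = np.column_stack([phis, scores])
    return GeometrySolution(phi_deg=float(phi_best), score=score_best,
                            score_curve=curve, reliable=reliable)


# ---------------------------------------------------------------------------
# 3-D peaks
# ---------------------------------------------------------------------------

def _default_merge_radius(peaks: Sequence[Peak2D], series: TiltSeries) -> float:
    """Merge-radius default bounded by two scales: it must stay below
    0.75 x the expected node spacing (estimated, before any cell is known,
    from the median nearest-neighbour 2-D peak distance) so distinct nodes
    never merge, and it need not exceed the distance a node travels between
    adjacent frames, ~ g_max * sin(tilt step), plus centroid noise."""
    px_cal = series.px_cal
    nn = []
    gmax = 0.0
    by_frame: dict[int, list[Peak2D]] = {}
    for p in peaks:
        by_frame.setdefault(p.frame_idx, []).append(p)
    for fi, plist in by_frame.items():
        frame = series.frames[fi]
        if frame.center_px is not None:
            cx, cy = frame.center_px
            r = max(math.hypot(p.x - cx, p.y - cy) for p in plist)
            gmax = max(gmax, r * px_cal)
        if len(plist) < 2:
            continue
        xy = np.array([[p.x, p.y] for p in plist])
        d, _ = cKDTree(xy).query(xy, k=2)
        nn.extend(d[:, 1])
    spacing_cap = 0.75 * float(np.median(nn)) * px_cal if nn else np.inf
    tilts = series.tilts_deg
    step = float(np.min(np.diff(tilts))) if len(tilts) > 1 else 1.0
    motion = 1.5 * gmax * math.sin(math.radians(step)) + 3.0 * px_cal
    return float(min(spacing_cap, motion)) if np.isfinite(spacing_cap) else float(motion)


def build_peaks3d(
    peaks: Sequence[Peak2D],
    series: TiltSeries,
    phi_deg: float,
    merge_radius_A: Optional[float] = None,
) -> list[Peak3D]:
    """Back-project every 2-D peak and merge adjacent-frame duplicates.

    Peaks on adjacent frames closer than the merge radius are the same
    reciprocal node sampled while it traversed the rocking width; they are
    merged into one Peak3D with intensity-weighted position and summed
    intensity, recording the contributing frames.
    """
    if not peaks:
        return []
    if merge_radius_A is None:
        merge_radius_A = _default_merge_radius(peaks, series)
        log.info("merge radius defaulted to %.4f 1/A", merge_radius_A)
    e, tilt_idx = _collect_ewald(peaks, series)
    g = _rotate_all(e, tilt_idx, series.tilts_deg, phi_deg)
    singles = [
        Peak3D(g=g[i], intensity=peaks[i].intensity, source_frames=(int(tilt_idx[i]),))
        for i in range(len(peaks))
    ]
    return merge_peaks3d(singles, merge_radius_A)


def merge_peaks3d(peaks3d: Sequence[Peak3D], merge_radius_A: float) -> list[Peak3D]:
    """Union-merge 3-D peaks closer than the radius on adjacent (or equal
    merged-range) frames.  Idempotent when components are separated."""
    if not peaks3d:
        return []
    g = np.array([p.g for p in peaks3d])
    fmin = np.array([min(p.source_frames) for p in peaks3d])
    fmax = np.array([max(p.source_frames) for p in peaks3d])
    tree = cKDTree(g)
    pairs = tree.query_pairs(r=merge_radius_A, output_type="ndarray")
    # adjacency only across consecutive frames (gap <= 1)
    if len(pairs):
        gap_ok = (
            np.minimum(
                np.abs(fmin[pairs[:, 0]] - fmax[pairs[:, 1]]),
                np.abs(fmin[pairs[:, 1]] - fmax[pairs[:, 0]]),
            )
            <= 1
        )
        pairs = pairs[gap_ok]
    # connected components via union-find
    parent = np.arange(len(peaks3d))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(peaks3d))])
    merged = []
    for root in np.unique(roots):
        members = np.where(roots == root)[0]
        w = np.array([peaks3d[i].intensity for i in members])
        pos = np.array([peaks3d[i].g for i in members])
        total = w.sum()
        centre = (pos * w[:, None]).sum(axis=0) / total if total > 0 else pos.mean(axis=0)
        frames = tuple(sorted({f for i in members for f in peaks3d[i].source_frames}))
        merged.append(Peak3D(g=centre, intensity=float(total), source_frames=frames))
    merged.sort(key=lambda p: -p.intensity)
    return merged


# ---------------------------------------------------------------------------
# voxel volume
# ---------------------------------------------------------------------------

def reconstruct_volume(
    series: TiltSeries,
    phi_deg: float,
    voxel_A: float,
    mode: str = "max",
    max_voxels: int = 320**3,
) -> VoxelVolume:
    """Deposit every detector pixel at its Ewald-corrected 3-D position by
    nearest-voxel assignment.

    ``mode='max'`` keeps the maximum of overlapping deposits (default),
    ``mode='sum'`` accumulates them so that the volume total equals the
    total in-bounds input intensity exactly.
    """
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    ny, nx = series.shape
    px_cal = series.px_cal
    r_corner = px_cal * math.hypot(nx, ny) / 2
    half = int(math.ceil(r_corner / voxel_A)) + 1
    n = 2 * half + 1
    if n**3 > max_voxels:
        suggested = voxel_A * (n**3 / max_voxels) ** (1 / 3)
        raise ResourceError(
            f"{n}^3 voxels exceed the cap; increase voxel_A to >= {suggested:.5f}"
        )
    grid = np.zeros((n, n, n))
    origin = -half * voxel_A * np.ones(3)

    yy, xx = np.mgrid[0:ny, 0:nx]
    xy = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    for frame in series.frames:
        if frame.center_px is None:
            raise GeometryError("all frames need centres before reconstruction")
        vals = frame.image.ravel()
        cx, cy = frame.center_px
        gx = (xy[:, 0] - cx) * px_cal
        gy = (xy[:, 1] - cy) * px_cal
        r2 = gx * gx + gy * gy
        inv_lam = 1.0 / series.wavelength_A
        ok = r2 < inv_lam * inv_lam
        gz = np.full_like(gx, np.nan)
        gz[ok] = inv_lam - np.sqrt(inv_lam * inv_lam - r2[ok])
        g = np.column_stack([gx, gy, gz]) @ _tilt_matrix(phi_deg, frame.tilt_deg).T
        idx = np.round((g - origin) / voxel_A).astype(np.int64)
        inb = ok & np.all((idx >= 0) & (idx < n), axis=1)
        ix, iy_, iz = idx[inb].T
        if mode == "sum":
            np.add.at(grid, (ix, iy_, iz), vals[inb])
        else:
            np.maximum.at(grid, (ix, iy_, iz), vals[inb])
    return VoxelVolume(grid=grid, voxel_A=voxel_A, origin=origin)


def slice_volume(
    vol: VoxelVolume,
    plane_normal,
    offset: float = 0.0,
    thickness: float = 0.01,
    mode: str = "max",
) -> np.ndarray:
    """Orthographic projection of the voxels within +-thickness/2 of the
    plane ``{g : g . n_hat = offset}`` onto that plane; pixel scale equals
    the voxel edge."""
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    nrm = np.asarray(plane_normal, dtype=np.float64)
    nlen = np.linalg.norm(nrm)
    if nlen == 0:
        raise GeometryError("plane normal must be nonzero")
    n_hat = nrm / nlen
    shape = np.array(vol.grid.shape)
    # deterministic in-plane frame
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ n_hat) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ n_hat) * n_hat
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_hat, e1)

    half = int(shape.max())  # generous plane extent
    npix = 2 * half + 1
    img = np.zeros((npix, npix))
    any_hit = False
    iy, iz = np.mgrid[0 : shape[1], 0 : shape[2]]
    iy, iz = iy.ravel(), iz.ravel()
    for ix in range(shape[0]):  # slice-wise to bound memory
        coords = vol.origin + np.column_stack([np.full(iy.shape, ix), iy, iz]) * vol.voxel_A
        dist = coords @ n_hat - offset
        sel = np.abs(dist) <= thickness / 2
        if not sel.any():
            continue
        any_hit = True
        p1 = coords[sel] @ e1
        p2 = coords[sel] @ e2
        vals = vol.grid[ix, iy[sel], iz[sel]]
        j1 = np.round(p1 / vol.voxel_A).astype(np.int64) + half
        j2 = np.round(p2 / vol.voxel_A).astype(np.int64) + half
        inb = (j1 >= 0) & (j1 < npix) & (j2 >= 0) & (j2 < npix)
        if mode == "sum":
            np.add.at(img, (j1[inb], j2[inb]), vals[inb])
        else:
            np.maximum.at(img, (j1[inb], j2[inb]), vals[inb])
    if not any_hit:
        raise GeometryError("slab does not intersect the volume")
    return img
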