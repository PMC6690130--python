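"""Geometric tilt-series simulator with known ground truth.

The generator renders exactly the geometry the reconstruction assumes: a
reciprocal lattice node is visible on a frame when a small additional tilt
(at most the rocking half-width, standing in for precession integration)
would bring it onto the Ewald sphere, and it is drawn as a Gaussian spot at
the detector position of that sphere crossing.  Intensities are kinematical
stand-ins, drawn log-uniformly per node; no structure factors.

The rotation convention is shared with the geometry module as a *contract*
(right-handed tilt about the in-plane axis ``(sin phi, cos phi, 0)``) but
not as code: this module uses :mod:`scipy.spatial.transform`, the solver
its own closed forms, so round-trip recovery tests stay meaningful.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .model import DiffractionFrame, TiltSeries, UnitCell

__all__ = ["GroundTruth", "DiffuseRodSpec", "simulate_series", "add_diffuse_rods"]


@dataclass
class GroundTruth:
    """Everything the simulator knows and downstream stages must recover."""

    cell: UnitCell
    phi_deg: float = 0.0
    #: effective excitation half-width (degrees); a node renders when the
    #: extra tilt needed to reach the sphere is below this
    rocking_deg: float = 1.0
    spot_sigma_px: float = 1.2
    noise: bool = True
    seed: int = 0
    central_beam: bool = True
    central_beam_counts: float = 2.0e5
    central_beam_sigma_px: float = 2.5
    #: log-uniform node intensity range (total counts per spot)
    intensity_range: tuple[float, float] = (300.0, 6000.0)
    #: pattern centre in px; defaults to the frame midpoint
    center_px: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (self.rocking_deg > 0):
            raise ConfigurationError("rocking_deg must be > 0")
        if self.spot_sigma_px < 0.5:
            raise ConfigurationError("spot_sigma_px must be >= 0.5")


@dataclass
class DiffuseRodSpec:
    """Continuous intensity rods along one lattice direction.

    ``affected_rows`` lists the integer anchor points (typically h,k,0
    rows) through which a rod parallel to ``rod_direction`` passes;
    ``rod_amplitude`` is the rendered line density in counts per detector
    pixel of rod length.
    """

    rod_direction: tuple[int, int, int]
    affected_rows: Sequence[tuple[int, int, int]] = field(default_factory=list)
    rod_amplitude: float = 100.0
    #: rod extent in units of rod_direction, symmetric about each anchor
    t_range: tuple[float, float] = (-8.0, 8.0)

    def __post_init__(self) -> None:
        if not any(self.rod_direction):
            raise ConfigurationError("rod_direction must be a nonzero lattice direction")


# ---------------------------------------------------------------------------
# geometry internals (generator side)
# ---------------------------------------------------------------------------

def _axis(phi_deg: float) -> np.ndarray:
    p = math.radians(phi_deg)
    return np.array([math.sin(p), math.cos(p), 0.0])


def _rot(phi_deg: float, theta_deg: float) -> np.ndarray:
    """Right-handed rotation by theta about the tilt axis at azimuth phi."""
    return Rotation.from_rotvec(np.radians(theta_deg) * _axis(phi_deg)).as_matrix()


def _sphere_crossing(v: np.ndarray, phi_deg: float, wavelength_A: float):
    """Additional tilt (degrees) bringing lab-frame points ``v`` onto the
    Ewald sphere, choosing the smaller |angle| of the two crossings.

    Solves ``A cos(t) + B sin(t) = C`` with A = v_z, B = (u x v)_z and
    C = lambda |v|^2 / 2; returns NaN where no crossing exists.
    """
    v = np.atleast_2d(v)
    u = _axis(phi_deg)
    A = v[:, 2]
    B = u[0] * v[:, 1] - u[1] * v[:, 0]
    C = 0.5 * wavelength_A * np.einsum("ij,ij->i", v, v)
    R = np.hypot(A, B)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(R > 0, C / R, np.inf)
        half = np.arccos(np.clip(ratio, -1.0, 1.0))
    delta = np.arctan2(B, A)
    t1 = delta + half
    t2 = delta - half
    wrap = lambda t: (t + np.pi) % (2 * np.pi) - np.pi
    t1, t2 = wrap(t1), wrap(t2)
    best = np.where(np.abs(t1) <= np.abs(t2), t1, t2)
    best = np.where(np.abs(ratio) <= 1.0, best, np.nan)
    return np.degrees(best)


def _enumerate_nodes(cell: UnitCell, gmax: float) -> np.ndarray:
    """All integer hkl (excluding 000) with |B hkl| <= gmax, sorted."""
    lens = (cell.a, cell.b, cell.c)
    bounds = [int(math.floor(l * gmax)) + 1 for l in lens]
    hkl = np.array(
        [t for t in itertools.product(*(range(-b, b + 1) for b in bounds)) if any(t)],
        dtype=np.int64,
    )
    g = hkl @ cell.B.T
    mask = np.linalg.norm(g, axis=1) <= gmax
    return hkl[mask]


def _stamp_gaussians(image: np.ndarray, xs, ys, amps, sigma: float) -> None:
    """Add normalized Gaussian spots (total counts = amp) in place."""
    ny, nx = image.shape
    w = max(2, int(math.ceil(4 * sigma)))
    norm = 1.0 / (2 * math.pi * sigma * sigma)
    for x0, y0, amp in zip(xs, ys, amps):
        ix, iy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(0, ix - w), min(nx, ix + w + 1)
        y_lo, y_hi = max(0, iy - w), min(ny, iy + w + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi) - x0
        gy = np.arange(y_lo, y_hi) - y0
        image[y_lo:y_hi, x_lo:x_hi] += (
            amp * norm * np.outer(np.exp(-gy * gy / (2 * sigma * sigma)),
                                  np.exp(-gx * gx / (2 * sigma * sigma)))
        )


def _node_intensities(hkl: np.ndarray, gt: GroundTruth) -> np.ndarray:
    """Log-uniform per-node amplitudes, Friedel-symmetric (I(h) = I(-h), as
    for kinematical intensities) and stable under node-set changes: each
    amplitude is drawn from a generator seeded by (seed, canonical hkl)."""
    lo, hi = gt.intensity_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    base = int(gt.seed) & 0x7FFFFFFF
    amps = np.empty(len(hkl))
    cache: dict[tuple[int, int, int], float] = {}
    for i, (h, k, l) in enumerate(hkl):
        key = (int(h), int(k), int(l))
        if key[0] < 0 or (key[0] == 0 and (key[1] < 0 or (key[1] == 0 and key[2] < 0))):
            key = (-key[0], -key[1], -key[2])
        if key not in cache:
            rng = np.random.default_rng(
                np.random.SeedSequence([base, key[0] + 1024, key[1] + 1024, key[2] + 1024])
            )
            cache[key] = math.exp(rng.uniform(log_lo, log_hi))
        amps[i] = cache[key]
    return amps


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_series(
    gt: GroundTruth,
    tilt_start_deg: float,
    tilt_end_deg: float,
    step_deg: float,
    frame_px: int = 256,
    px_cal: float = 0.006,
    wavelength_A: float = 0.0251,
    dmin_A: float = 1.2,
    render: bool = True,
) -> TiltSeries:
    """Simulate an ADT acquisition: sequential tilts over a wedge, spots at
    Ewald-sphere crossings of the ground-truth lattice.

    Frame count is ``round((end - start)/step) + 1``.  A ground-truth table
    (frame, hkl, detector position, rendered counts, crossing offset) is
    attached to the returned series as ``series.truth``.  With
    ``render=False`` only the truth table is computed and the frames stay
    empty (geometry-only studies).
    """
    if tilt_end_deg <= tilt_start_deg or step_deg <= 0:
        raise ConfigurationError("need tilt_end > tilt_start and step > 0")
    n_frames = int(round((tilt_end_deg - tilt_start_deg) / step_deg)) + 1
    tilts = tilt_start_deg + step_deg * np.arange(n_frames)

    gmax = 1.0 / dmin_A
    r_detector = px_cal * (frame_px / 2 - 4 * gt.spot_sigma_px - 1)
    if r_detector < gmax:
        raise ConfigurationError(
            f"detector radius {r_detector:.3f} 1/A cannot contain dmin={dmin_A} A "
            f"(needs {gmax:.3f} 1/A); increase frame_px or px_cal"
        )
    cx, cy = gt.center_px if gt.center_px is not None else ((frame_px - 1) / 2.0,) * 2

    hkl = _enumerate_nodes(gt.cell, gmax)
    g0 = hkl @ gt.cell.B.T
    amps = _node_intensities(hkl, gt)

    frames: list[DiffractionFrame] = []
    truth_rows = []
    for fi, eta in enumerate(tilts):
        v = g0 @ _rot(gt.phi_deg, -eta).T  # nodes in lab frame at this tilt
        dtheta = _sphere_crossing(v, gt.phi_deg, wavelength_A)
        sel = np.where(np.isfinite(dtheta) & (np.abs(dtheta) <= gt.rocking_deg))[0]
        image = np.zeros((frame_px, frame_px)) if render else None
        if len(sel):
            w = np.einsum("nij,nj->ni",
                          np.stack([_rot(gt.phi_deg, t) for t in dtheta[sel]]),
                          v[sel])
            xs = cx + w[:, 0] / px_cal
            ys = cy + w[:, 1] / px_cal
            falloff = 1.0 - np.abs(dtheta[sel]) / gt.rocking_deg
            counts = amps[sel] * falloff
            inside = (xs > 1) & (xs < frame_px - 2) & (ys > 1) & (ys < frame_px - 2)
            xs, ys, counts, node_idx = xs[inside], ys[inside], counts[inside], sel[inside]
            if render and len(xs):
                _stamp_gaussians(image, xs, ys, counts, gt.spot_sigma_px)
            for j, ni in enumerate(node_idx):
                truth_rows.append((fi, *hkl[ni], xs[j], ys[j], counts[j], float(dtheta[ni])))
        if render:
            if gt.central_beam:
                _stamp_gaussians(image, [cx], [cy], [gt.central_beam_counts],
                                 gt.central_beam_sigma_px)
            if gt.noise:
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(gt.seed) & 0x7FFFFFFF, 1, fi]))
                image = rng.poisson(image).astype(np.float64)
        else:
            image = np.zeros((16, 16))
        frames.append(DiffractionFrame(image=image, tilt_deg=float(eta), px_cal=px_cal))

    truth = pd.DataFrame(
        truth_rows, columns=["frame", "h", "k", "l", "x_px", "y_px", "counts", "dtheta_deg"]
    )
    series = TiltSeries(frames=frames, wavelength_A=wavelength_A)
    series.truth = truth
    return series


def add_diffuse_rods(series: TiltSeries, gt: GroundTruth, spec: DiffuseRodSpec) -> TiltSeries:
    """Overlay continuous diffuse rods on a simulated series.

    For every affected row the rod ``B (anchor + t * direction)`` is sampled
    finely in ``t``; each sample that a small extra tilt (within the rocking
    width) would bring onto the Ewald sphere is rendered, so each frame
    shows the short segment of rod it actually cuts.  Returns a new series;
    a table of rendered rod samples is attached as ``series.rod_truth``.
    """
    if spec.rod_amplitude == 0 or not spec.affected_rows:
        out = TiltSeries(
            frames=[DiffractionFrame(f.image.copy(), f.tilt_deg, f.px_cal,
                                     f.exposure_s, f.center_px) for f in series.frames],
            wavelength_A=series.wavelength_A,
            tilt_axis_phi_deg=series.tilt_axis_phi_deg,
        )
        out.truth = series.truth
        out.rod_truth = pd.DataFrame(columns=["frame", "anchor", "t", "x_px", "y_px", "counts"])
        return out

    B = gt.cell.B
    direction = np.asarray(spec.rod_direction, dtype=np.float64)
    g_dir = B @ direction
    px_cal = series.px_cal
    ny, nx = series.shape
    cx, cy = gt.center_px if gt.center_px is not None else ((nx - 1) / 2.0,) * 2
    # sample spacing: ~0.3 px of rod length per sample
    dt = 0.3 * px_cal / np.linalg.norm(g_dir)
    ts = np.arange(spec.t_range[0], spec.t_range[1] + dt / 2, dt)
    px_per_sample = dt * np.linalg.norm(g_dir) / px_cal

    new_frames = []
    rod_rows = []
    for fi, frame in enumerate(series.frames):
        image = frame.image.copy()
        Rback = _rot(gt.phi_deg, -frame.tilt_deg)
        for anchor in spec.affected_rows:
            ganchor = B @ np.asarray(anchor, dtype=np.float64)
            pts = ganchor[None, :] + ts[:, None] * g_dir[None, :]
            v = pts @ Rback.T
            dtheta = _sphere_crossing(v, gt.phi_deg, series.wavelength_A)
            sel = np.where(np.isfinite(dtheta) & (np.abs(dtheta) <= gt.rocking_deg))[0]
            if not len(sel):
                continue
            w = np.einsum("nij,nj->ni",
                          np.stack([_rot(gt.phi_deg, t) for t in dtheta[sel]]), v[sel])
            xs = cx + w[:, 0] / px_cal
            ys = cy + w[:, 1] / px_cal
            falloff = 1.0 - np.abs(dtheta[sel]) / gt.rocking_deg
            counts = spec.rod_amplitude * falloff * px_per_sample
            inside = (xs > 1) & (xs < nx - 2) & (ys > 1) & (ys < ny - 2)
            xs, ys, counts, tsel = xs[inside], ys[inside], counts[inside], ts[sel][inside]
            if len(xs):
                _stamp_gaussians(image, xs, ys, counts, gt.spot_sigma_px)
                for x, y, cts, t in zip(xs, ys, counts, tsel):
                    rod_rows.append((fi, tuple(anchor), t, x, y, cts))
        if gt.noise:
            rng = np.random.default_rng(
                np.random.SeedSequence([int(gt.seed) & 0x7FFFFFFF, 2, fi]))
            extra = image - frame.image
            image = frame.image + rng.poisson(np.clip(extra, 0, None)).astype(np.float64)
        new_frames.append(DiffractionFrame(image=image, tilt_deg=frame.tilt_deg,
                                           px_cal=frame.px_cal, exposure_s=frame.exposure_s,
                                           center_px=frame.center_px))
    out = TiltSeries(frames=new_frames, wavelength_A=series.wavelength_A,
                     tilt_axis_phi_deg=series.tilt_axis_phi_deg)
    out.truth = series.truth
    out.rod_truth = pd.DataFrame(rod_rows,
                                 columns=["frame", "anchor", "t", "x_px", "y_px", "counts"])
    return out
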