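"""Core in-memory types for electron diffraction tomography processing.

Conventions fixed once for the whole package:

* Pixel coordinates: origin at the centre of the top-left pixel, ``x``
  rightward (columns), ``y`` downward (rows), 0-based.  All sub-pixel
  positions are ``(x, y)`` pairs in this frame.
* Reciprocal coordinates are in 1/Angstrom.  The tilt axis lies in the
  detector plane at azimuth ``phi`` measured from the pattern y-axis, i.e.
  the unit axis vector is ``(sin phi, cos phi, 0)``; the goniometer tilt is
  a right-handed rotation about it.
* The Ewald out-of-plane component ``g_z`` is positive toward the electron
  source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import DataValidationError

__all__ = [
    "DiffractionFrame",
    "TiltSeries",
    "Peak2D",
    "Peak3D",
    "UnitCell",
    "ReflectionSet",
    "VoxelVolume",
    "MergeStats",
]


@dataclass
class DiffractionFrame:
    """One 2-D detector image with its goniometer angle and calibration.

    Parameters
    ----------
    image:
        2-D array of non-negative counts, at least 16x16.
    tilt_deg:
        Goniometer angle in degrees.
    px_cal:
        Reciprocal length per pixel (1/Angstrom per px), > 0.
    exposure_s:
        Exposure time in seconds.
    center_px:
        Optional pattern centre ``(x, y)`` in pixel units; ``None`` until a
        centring stage (or a manual sidecar override) sets it.
    """

    image: np.ndarray
    tilt_deg: float
    px_cal: float
    exposure_s: float = 1.0
    center_px: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2 or min(self.image.shape) < 16:
            raise DataValidationError(
                f"frame image must be 2-D and at least 16x16, got {self.image.shape}"
            )
        if not (self.px_cal > 0):
            raise DataValidationError("px_cal must be > 0")
        if not np.all(np.isfinite(self.image)) or self.image.min() < 0:
            raise DataValidationError("frame intensities must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # (rows, cols) = (ny, nx)


@dataclass
class TiltSeries:
    """An ordered tilt series sharing detector geometry and wavelength."""

    frames: list[DiffractionFrame]
    wavelength_A: float
    tilt_axis_phi_deg: Optional[float] = None
    #: optional per-node ground truth attached by the simulator (DataFrame)
    truth: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise DataValidationError("tilt series needs at least one frame")
        tilts = [f.tilt_deg for f in self.frames]
        if any(b <= a for a, b in zip(tilts, tilts[1:])):
            raise DataValidationError(
                "frames must be sorted by tilt angle, strictly monotonic"
            )
        shapes = {f.shape for f in self.frames}
        cals = {f.px_cal for f in self.frames}
        if len(shapes) != 1 or len(cals) != 1:
            raise DataValidationError("all frames must share shape and px_cal")
        if not (0.001 < self.wavelength_A < 0.1):
            raise DataValidationError(
                f"wavelength {self.wavelength_A} A outside the electron range (0.001, 0.1)"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def tilts_deg(self) -> np.ndarray:
        return np.array([f.tilt_deg for f in self.frames])

    @property
    def px_cal(self) -> float:
        return self.frames[0].px_cal

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass
class Peak2D:
    """A reflection found on one frame (connected pixel cluster)."""

    frame_idx: int
    x: float
    y: float
    intensity: float
    area_px: int
    density: float
    aspect: float

    @property
    def xy_px(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Peak3D:
    """A reflection in reciprocal space after Ewald back-projection."""

    g: np.ndarray  # 3-vector, 1/Angstrom
    intensity: float
    source_frames: tuple[int, ...]

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.float64).reshape(3)


def _cell_params_from_direct(A: np.ndarray) -> tuple[float, ...]:
    """Cell parameters (a, b, c, alpha, beta, gamma) from direct basis columns."""
    a, b, c = A[:, 0], A[:, 1], A[:, 2]
    la, lb, lc = np.linalg.norm(a), np.linalg.norm(b), np.linalg.norm(c)

    def ang(u, v):
        return float(np.degrees(np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))))

    return float(la), float(lb), float(lc), ang(b, c), ang(a, c), ang(a, b)


@dataclass
class UnitCell:
    """Unit cell plus the orientation matrix B mapping hkl to lab reciprocal
    coordinates (1/Angstrom).

    ``B`` columns are the reciprocal basis vectors a*, b*, c* in lab
    coordinates; the direct basis in lab coordinates is ``inv(B).T``.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    B: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.float64).reshape(3, 3)
        G = self.metric_tensor()
        try:
            np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            raise DataValidationError("cell metric tensor is not positive definite")
        derived = _cell_params_from_direct(self.direct_basis())
        stated = (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        for d, s in zip(derived, stated):
            if abs(d - s) > 1e-6 * max(abs(s), 1.0):
                raise DataValidationError(
                    f"orientation matrix inconsistent with cell parameters: {derived} vs {stated}"
                )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_parameters(
        cls,
        a: float,
        b: float,
        c: float,
        alpha: float,
        beta: float,
        gamma: float,
        orientation: Optional[np.ndarray] = None,
    ) -> "UnitCell":
        """Build from scalars, using the standard crystallographic frame
        (a along x, b in the xy plane); ``orientation`` is an optional lab
        rotation applied on top."""
        gc = gemmi.UnitCell(a, b, c, alpha, beta, gamma)
        A = np.array(gc.orth.mat.tolist())  # columns a, b, c
        B = np.linalg.inv(A).T
        if orientation is not None:
            U = np.asarray(orientation, dtype=np.float64).reshape(3, 3)
            if not np.allclose(U @ U.T, np.eye(3), atol=1e-8):
                raise DataValidationError("orientation must be a rotation matrix")
            B = U @ B
        return cls(a, b, c, alpha, beta, gamma, B)

    @classmethod
    def from_basis(cls, B: np.ndarray) -> "UnitCell":
        """Build from a reciprocal basis matrix, deriving the scalars."""
        B = np.asarray(B, dtype=np.float64).reshape(3, 3)
        A = np.linalg.inv(B).T
        return cls(*_cell_params_from_direct(A), B=B)

    # -- derived quantities ----------------------------------------------
    def direct_basis(self) -> np.ndarray:
        """Direct lattice basis in lab coordinates (columns a, b, c, Angstrom)."""
        return np.linalg.inv(self.B).T

    def metric_tensor(self) -> np.ndarray:
        A = _metric_from_params(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        return A

    @property
    def volume_A3(self) -> float:
        return float(abs(np.linalg.det(self.direct_basis())))

    def d_spacing(self, hkl: Sequence[float]) -> np.ndarray:
        """Resolution d (Angstrom) of one hkl or an (N, 3) array of them."""
        h = np.atleast_2d(np.asarray(hkl, dtype=np.float64))
        g = h @ self.B.T
        gl = np.linalg.norm(g, axis=1)
        with np.errstate(divide="ignore"):
            d = np.where(gl > 0, 1.0 / gl, np.inf)
        return d if np.asarray(hkl).ndim > 1 else d[0]

    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def _metric_from_params(a, b, c, alpha, beta, gamma) -> np.ndarray:
    ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


class ReflectionSet:
    """Indexed reflections: integer hkl, intensity, s.u. and resolution.

    Stored as parallel numpy arrays; ``peak_idx`` optionally links each
    record back to the Peak3D it came from, ``n_frames`` counts contributing
    frames.
    """

    def __init__(
        self,
        hkl: np.ndarray,
        I: np.ndarray,
        sigma: np.ndarray,
        d_A: np.ndarray,
        peak_idx: Optional[np.ndarray] = None,
        n_frames: Optional[np.ndarray] = None,
    ) -> None:
        self.hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
        n = len(self.hkl)
        self.I = np.asarray(I, dtype=np.float64).reshape(n)
        self.sigma = np.asarray(sigma, dtype=np.float64).reshape(n)
        self.d_A = np.asarray(d_A, dtype=np.float64).reshape(n)
        self.peak_idx = None if peak_idx is None else np.asarray(peak_idx, dtype=np.int64).reshape(n)
        self.n_frames = None if n_frames is None else np.asarray(n_frames, dtype=np.int64).reshape(n)
        if n:
            if np.any(self.d_A <= 0):
                raise DataValidationError("every reflection needs d > 0")
            if np.any(~self.hkl.any(axis=1)):
                raise DataValidationError("hkl (0,0,0) is not a reflection")

    def __len__(self) -> int:
        return len(self.hkl)

    @classmethod
    def empty(cls) -> "ReflectionSet":
        z = np.zeros((0, 3))
        return cls(z, np.zeros(0), np.zeros(0), np.zeros(0))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "I": self.I,
                "sigma": self.sigma,
                "d_A": self.d_A,
            }
        )
        if self.n_frames is not None:
            df["n_frames"] = self.n_frames
        return df


@dataclass
class VoxelVolume:
    """Reconstructed reciprocal-space intensity on a regular cubic grid."""

    grid: np.ndarray  # indexed [ix, iy, iz]
    voxel_A: float
    origin: np.ndarray  # reciprocal coordinate of grid corner voxel centre

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.grid.ndim != 3:
            raise DataValidationError("volume grid must be 3-D")
        if not (self.voxel_A > 0):
            raise DataValidationError("voxel_A must be > 0")

    def index_of(self, g: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of reciprocal position(s) g."""
        return (np.asarray(g, dtype=np.float64) - self.origin) / self.voxel_A

    def coord_of(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=np.float64) * self.voxel_A


@dataclass
class MergeStats:
    """Merging statistics of the kind reported for EDT data sets."""

    n_measured: int
    n_unique: int
    r_int: float
    completeness_pct: Optional[float] = None
    dmin_A: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_unique > self.n_measured:
            raise DataValidationError("n_unique cannot exceed n_measured")
        if self.r_int < 0:
            raise DataValidationError("r_int must be >= 0")
        if self.completeness_pct is not None and not (0 <= self.completeness_pct <= 100):
            raise DataValidationError("completeness must be within [0, 100] %")
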