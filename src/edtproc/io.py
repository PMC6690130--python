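"""Readers and writers for the formats the pipeline touches.

Tilt series come in as multi-page TIFF or MRC mode-2 stacks with a JSON (or
YAML) metadata sidecar listing one tilt angle per frame plus the detector
calibration and wavelength.  Outputs are SHELX HKLF-4 ``.hkl`` files, a
minimal cell CIF, TSV peak tables and MRC volumes.

The MRC code implements the fixed 1024-byte MRC-2014 header directly
(mode 2, float32) for both stacks and reconstructed volumes.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml
from gemmi import cif

from .errors import ConfigurationError, DataValidationError, FormatOverflowError
from .model import DiffractionFrame, Peak2D, ReflectionSet, TiltSeries, UnitCell, VoxelVolume

log = logging.getLogger(__name__)

__all__ = [
    "read_tilt_series",
    "write_tilt_series",
    "write_hkl",
    "read_hkl",
    "write_cell_cif",
    "read_cell_cif",
    "write_peaks_tsv",
    "read_peaks_tsv",
    "write_peaks3d_tsv",
    "write_volume_mrc",
    "read_volume_mrc",
]


# ---------------------------------------------------------------------------
# minimal MRC-2014 (mode 2) support
# ---------------------------------------------------------------------------

_MRC_HEADER_BYTES = 1024


def _write_mrc(path: Path, data: np.ndarray, cella: tuple[float, float, float]) -> None:
    """Write a float32 MRC-2014 file; ``data`` has shape (nz, ny, nx)."""
    data = np.ascontiguousarray(data, dtype=np.float32)
    nz, ny, nx = data.shape
    hdr = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)
    struct.pack_into("<i", hdr, 12, 2)  # mode 2 = float32
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", hdr, 40, *cella)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", hdr, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", hdr, 88, 0)  # ispg: image stack / volume
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", hdr, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(data.tobytes())


def _read_mrc(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    with open(path, "rb") as fh:
        hdr = fh.read(_MRC_HEADER_BYTES)
        if len(hdr) < _MRC_HEADER_BYTES:
            raise DataValidationError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", hdr, 0)
        mode = struct.unpack_from("<i", hdr, 12)[0]
        nsymbt = struct.unpack_from("<i", hdr, 92)[0]
        cella = struct.unpack_from("<3f", hdr, 40)
        if mode != 2:
            raise DataValidationError(f"{path}: only MRC mode 2 (float32) is supported, got mode {mode}")
        fh.seek(_MRC_HEADER_BYTES + nsymbt)
        data = np.frombuffer(fh.read(nx * ny * nz * 4), dtype="<f4")
    if data.size != nx * ny * nz:
        raise DataValidationError(f"{path}: truncated MRC data section")
    return data.reshape(nz, ny, nx).astype(np.float64), cella


# ---------------------------------------------------------------------------
# tilt series
# ---------------------------------------------------------------------------

def _load_sidecar(meta_path: Path) -> dict:
    text = Path(meta_path).read_text()
    if str(meta_path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _load_stack(image_path: Path) -> np.ndarray:
    suffix = Path(image_path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(image_path)
    elif suffix in (".mrc", ".map"):
        data, _ = _read_mrc(Path(image_path))
    else:
        raise ConfigurationError(f"unsupported stack format: {image_path}")
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    return data


def read_tilt_series(image_path, meta_path) -> TiltSeries:
    """Load a TIFF/MRC stack plus its metadata sidecar into a TiltSeries.

    The sidecar must provide ``tilts_deg`` (one per frame), ``px_cal`` and
    ``wavelength_A``; ``exposure_s`` (scalar or list), per-frame manual
    centre overrides ``centers_px`` and a known ``phi_deg`` are optional.
    """
    meta = _load_sidecar(Path(meta_path))
    for key in ("tilts_deg", "px_cal", "wavelength_A"):
        if key not in meta:
            raise ConfigurationError(f"metadata sidecar is missing required key '{key}'")
    stack = _load_stack(Path(image_path))
    tilts = list(meta["tilts_deg"])
    if len(tilts) != len(stack):
        raise DataValidationError(
            f"stack depth {len(stack)} does not match {len(tilts)} metadata tilt angles"
        )
    if "exposure_s" in meta:
        exposure = meta["exposure_s"]
        exposures = [float(exposure)] * len(stack) if np.isscalar(exposure) else [float(e) for e in exposure]
    else:
        log.warning("no exposure_s in sidecar; defaulting every frame to 1 s")
        exposures = [1.0] * len(stack)
    centers = meta.get("centers_px")
    if centers is None:
        centers = [None] * len(stack)
    if len(exposures) != len(stack) or len(centers) != len(stack):
        raise DataValidationError("per-frame metadata lists must match the stack depth")

    order = np.argsort(tilts, kind="stable")
    frames = [
        DiffractionFrame(
            image=stack[i],
            tilt_deg=float(tilts[i]),
            px_cal=float(meta["px_cal"]),
            exposure_s=exposures[i],
            center_px=None if centers[i] is None else tuple(float(v) for v in centers[i]),
        )
        for i in order
    ]
    return TiltSeries(
        frames=frames,
        wavelength_A=float(meta["wavelength_A"]),
        tilt_axis_phi_deg=meta.get("phi_deg"),
    )


def write_tilt_series(series: TiltSeries, image_path, meta_path) -> None:
    """Write a series as a float32 stack plus a JSON sidecar readable by
    :func:`read_tilt_series`."""
    stack = np.stack([f.image for f in series.frames]).astype(np.float32)
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(image_path, stack, photometric="minisblack")
    elif image_path.suffix.lower() == ".mrc":
        _write_mrc(image_path, stack, (stack.shape[2] * series.px_cal,
                                       stack.shape[1] * series.px_cal, float(len(stack))))
    else:
        raise ConfigurationError(f"unsupported stack format: {image_path}")
    meta = {
        "tilts_deg": [f.tilt_deg for f in series.frames],
        "px_cal": series.px_cal,
        "wavelength_A": series.wavelength_A,
        "exposure_s": [f.exposure_s for f in series.frames],
        "centers_px": [None if f.center_px is None else list(f.center_px) for f in series.frames],
    }
    if series.tilt_axis_phi_deg is not None:
        meta["phi_deg"] = series.tilt_axis_phi_deg
    Path(meta_path).write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# SHELX HKLF-4
# ---------------------------------------------------------------------------

def write_hkl(rs: ReflectionSet, path) -> None:
    """Write SHELX HKLF-4 fixed format (3I4, 2F8.2) with the terminating
    all-zero record."""
    if len(rs) and (np.any(np.abs(rs.hkl) >= 1000) or np.any(np.abs(rs.I) >= 1e6)
                    or np.any(np.abs(rs.sigma) >= 1e6)):
        raise FormatOverflowError("hkl index or intensity does not fit the HKLF-4 field width")
    if len(rs) and not (np.all(np.isfinite(rs.I)) and np.all(np.isfinite(rs.sigma))):
        raise DataValidationError("intensities and sigmas must be finite")
    with open(path, "w") as fh:
        for (h, k, l), I, sig in zip(rs.hkl, rs.I, rs.sigma):
            fh.write(f"{h:4d}{k:4d}{l:4d}{I:8.2f}{sig:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")


def read_hkl(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an HKLF-4 file; returns (hkl, I, sigma) arrays."""
    hkl, I, sig = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
        if (h, k, l) == (0, 0, 0):
            break
        hkl.append((h, k, l))
        I.append(float(line[12:20]))
        sig.append(float(line[20:28]))
    return (np.array(hkl, dtype=np.int64).reshape(-1, 3),
            np.array(I, dtype=np.float64), np.array(sig, dtype=np.float64))


# ---------------------------------------------------------------------------
# cell CIF
# ---------------------------------------------------------------------------

def write_cell_cif(cell: UnitCell, path) -> None:
    """Write a minimal CIF holding the six cell parameters."""
    doc = cif.Document()
    block = doc.add_new_block("cell")
    for tag, val, fmt in (
        ("_cell_length_a", cell.a, "%.4f"),
        ("_cell_length_b", cell.b, "%.4f"),
        ("_cell_length_c", cell.c, "%.4f"),
        ("_cell_angle_alpha", cell.alpha, "%.4f"),
        ("_cell_angle_beta", cell.beta, "%.4f"),
        ("_cell_angle_gamma", cell.gamma, "%.4f"),
    ):
        block.set_pair(tag, fmt % val)
    doc.write_file(str(path))


def read_cell_cif(path) -> UnitCell:
    doc = cif.read_file(str(path))
    block = doc.sole_block()
    vals = []
    for tag in ("_cell_length_a", "_cell_length_b", "_cell_length_c",
                "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma"):
        v = block.find_value(tag)
        if v is None:
            raise ConfigurationError(f"{path}: missing {tag}")
        vals.append(float(v))
    return UnitCell.from_parameters(*vals)


# ---------------------------------------------------------------------------
# TSV peak tables
# ---------------------------------------------------------------------------

_PEAK_COLS = ("frame", "x", "y", "I", "area", "density", "aspect")


def write_peaks_tsv(peaks: Sequence[Peak2D], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PEAK_COLS) + "\n")
        for p in peaks:
            fh.write(f"{p.frame_idx}\t{p.x:.4f}\t{p.y:.4f}\t{p.intensity:.4f}\t"
                     f"{p.area_px}\t{p.density:.6f}\t{p.aspect:.4f}\n")


def read_peaks_tsv(path) -> list[Peak2D]:
    peaks = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        f, x, y, I, area, dens, asp = line.split("\t")
        peaks.append(Peak2D(int(f), float(x), float(y), float(I), int(area),
                            float(dens), float(asp)))
    return peaks


def write_peaks3d_tsv(peaks, path) -> None:
    with open(path, "w") as fh:
        fh.write("gx\tgy\tgz\tI\tnframes\n")
        for p in peaks:
            fh.write(f"{p.g[0]:.6f}\t{p.g[1]:.6f}\t{p.g[2]:.6f}\t"
                     f"{p.intensity:.4f}\t{len(p.source_frames)}\n")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume_mrc(vol: VoxelVolume, path) -> None:
    """Write the volume as MRC mode 2; the voxel edge (1/Angstrom) is
    recorded in the header pixel-size (cella / m) fields."""
    nz, ny, nx = vol.grid.shape[2], vol.grid.shape[1], vol.grid.shape[0]
    # store as (nz, ny, nx) = grid transposed so axis order round-trips
    data = np.transpose(vol.grid, (2, 1, 0))
    _write_mrc(Path(path), data,
               (nx * vol.voxel_A, ny * vol.voxel_A, nz * vol.voxel_A))


def read_volume_mrc(path, origin: Optional[np.ndarray] = None) -> VoxelVolume:
    data, cella = _read_mrc(Path(path))
    grid = np.transpose(data, (2, 1, 0))
    voxel = cella[0] / grid.shape[0]
    if origin is None:
        # centred grid by convention when no sidecar origin is given
        origin = -voxel * (np.array(grid.shape) // 2)
    return VoxelVolume(grid=grid, voxel_A=float(voxel), origin=origin)
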