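"""End-to-end processing: centre -> peaks -> tilt axis -> 3-D peaks ->
cell -> index -> extract -> merge, with optional voxel reconstruction.

All stage parameters live in one :class:`RunConfig`; every run writes a
resolved-config snapshot next to its outputs so a result can be reproduced
from the snapshot alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import geometry, intensities, lattice, preprocess
from .errors import CenteringError, ConfigurationError
from .io import (
    read_tilt_series,
    write_cell_cif,
    write_hkl,
    write_peaks3d_tsv,
    write_peaks_tsv,
    write_tilt_series,
    write_volume_mrc,
)
from .model import TiltSeries, UnitCell
from .preprocess import PeakSearchParams
from .synthetic import GroundTruth, simulate_series

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "process_series"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    #: either an input block {"image": ..., "meta": ...} ...
    input: Optional[dict] = None
    #: ... or a simulate block (cell parameters, phi, wedge, detector)
    simulate: Optional[dict] = None
    seed: int = 0
    center_method: str = "auto"  # direct | friedel | auto
    peak_params: dict = field(default_factory=dict)
    max_peaks_for_cell: int = 400
    max_difference_vectors: int = 150_000
    cluster_min_points: int = 4
    cluster_max_intra_dist: float = 0.01
    cluster_max_origin_dist: float = 0.35
    index_tol: float = 0.25
    laue_group: str = "-1"
    dmin_A: Optional[float] = None
    reconstruct: bool = False
    voxel_A: float = 0.005
    outdir: str = "edtproc_run"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _simulate_from_config(cfg: RunConfig) -> TiltSeries:
    sim = dict(cfg.simulate)
    cell_params = sim.pop("cell")
    orientation = sim.pop("orientation_seed", None)
    if orientation is not None:
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(int(orientation) & 0x7FFFFFFF)
        U = Rotation.random(random_state=rng).as_matrix()
    else:
        U = None
    cell = UnitCell.from_parameters(*cell_params, orientation=U)
    gt = GroundTruth(
        cell=cell,
        phi_deg=sim.pop("phi_deg", 0.0),
        rocking_deg=sim.pop("rocking_deg", 1.0),
        spot_sigma_px=sim.pop("spot_sigma_px", 1.2),
        noise=sim.pop("noise", True),
        seed=sim.pop("seed", cfg.seed),
    )
    return simulate_series(
        gt,
        tilt_start_deg=sim.pop("tilt_start_deg", -44.0),
        tilt_end_deg=sim.pop("tilt_end_deg", 52.0),
        step_deg=sim.pop("step_deg", 1.0),
        frame_px=sim.pop("frame_px", 256),
        px_cal=sim.pop("px_cal", 0.006),
        wavelength_A=sim.pop("wavelength_A", 0.0251),
        dmin_A=sim.pop("dmin_A", 1.2),
    )


def _find_centers(series: TiltSeries, method: str, peak_params: PeakSearchParams) -> None:
    for i, frame in enumerate(series.frames):
        if frame.center_px is not None:
            continue  # manual sidecar override wins
        if method in ("direct", "auto"):
            try:
                frame.center_px = preprocess.find_center_direct(frame)
                continue
            except CenteringError:
                if method == "direct":
                    raise
        peaks = preprocess.peak_search_2d(frame, peak_params)
        (cx, cy), _ = preprocess.find_center_friedel(frame, peaks)
        frame.center_px = (cx, cy)


def process_series(series: TiltSeries, cfg: RunConfig, outdir: Optional[Path] = None) -> dict:
    """Run the processing chain on an in-memory series; returns the summary
    dict and optionally writes all intermediates below ``outdir``."""
    peak_params = PeakSearchParams(**cfg.peak_params)

    _find_centers(series, cfg.center_method, peak_params)

    peaks = []
    for i, frame in enumerate(series.frames):
        found = preprocess.peak_search_2d(frame, peak_params)
        for p in found:
            p.frame_idx = i
        peaks.extend(found)

    solution = geometry.find_tilt_axis(peaks, series)
    peaks3d = geometry.build_peaks3d(peaks, series, solution.phi_deg)

    strongest = peaks3d[: cfg.max_peaks_for_cell]
    vectors = lattice.difference_vectors(strongest, cfg.cluster_max_origin_dist)
    if len(vectors) > cfg.max_difference_vectors:
        stride = int(np.ceil(len(vectors) / cfg.max_difference_vectors))
        vectors = vectors[::stride]
    clusters = lattice.cluster_vectors(
        vectors,
        lattice.ClusterParams(
            min_points=cfg.cluster_min_points,
            max_intra_dist=cfg.cluster_max_intra_dist,
            max_origin_dist=cfg.cluster_max_origin_dist,
        ),
    )
    cell = lattice.find_basis(clusters, tol=cfg.index_tol)

    indexed, unindexed = lattice.index_peaks(peaks3d, cell, tol=cfg.index_tol)
    observations = intensities.integrate(peaks3d, indexed)
    unique, stats = intensities.merge(observations, cfg.laue_group)
    dmin = cfg.dmin_A if cfg.dmin_A is not None else (
        float(observations.d_A.min()) if len(observations) else 1.0
    )
    stats.completeness_pct = intensities.completeness(unique, cell, cfg.laue_group, dmin)
    stats.dmin_A = dmin

    summary = {
        "phi_deg": round(solution.phi_deg, 4),
        "phi_reliable": solution.reliable,
        "cell": {k: round(v, 4) for k, v in zip("a b c alpha beta gamma".split(),
                                                cell.parameters())},
        "n_peaks_2d": len(peaks),
        "n_peaks_3d": len(peaks3d),
        "n_clusters": len(clusters),
        "n_indexed": len(indexed),
        "n_unindexed": len(unindexed),
        "n_measured": stats.n_measured,
        "n_unique": stats.n_unique,
        "r_int": round(stats.r_int, 5),
        "completeness_pct": round(stats.completeness_pct, 2),
        "dmin_A": round(dmin, 4),
        "laue_group": cfg.laue_group,
    }

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_peaks_tsv(peaks, outdir / "peaks2d.tsv")
        write_peaks3d_tsv(peaks3d, outdir / "peaks3d.tsv")
        write_cell_cif(cell, outdir / "cell.cif")
        write_hkl(observations, outdir / "reflections.hkl")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        if cfg.reconstruct:
            vol = geometry.reconstruct_volume(series, solution.phi_deg, cfg.voxel_A)
            write_volume_mrc(vol, outdir / "volume.mrc")
    summary["_cell_object"] = cell
    summary["_solution"] = solution
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain per the config; emits all intermediate files
    plus ``summary.json`` and a resolved-config snapshot in the output
    directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.resolved.yaml")
    if cfg.input:
        for key in ("image", "meta"):
            if key not in cfg.input:
                raise ConfigurationError(f"input block needs '{key}'")
        series = read_tilt_series(cfg.input["image"], cfg.input["meta"])
    elif cfg.simulate:
        series = _simulate_from_config(cfg)
        write_tilt_series(series, outdir / "simulated.tiff", outdir / "simulated.json")
    else:
        raise ConfigurationError("config needs either an 'input' or a 'simulate' block")
    summary = process_series(series, cfg, outdir=outdir)
    summary.pop("_cell_object", None)
    summary.pop("_solution", None)
    return summary
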