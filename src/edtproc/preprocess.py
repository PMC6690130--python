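"""Pattern centring and 2-D reflection search on individual frames.

Two centring routes are provided: the direct beam (brightest, most
extended connected region) when the measurement was done without beam
blanking, and a Friedel-pair midpoint vote when the central beam is absent.
Reflection search is a thresholded 8-connected component analysis with
cluster-shape filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .errors import CenteringError
from .model import DiffractionFrame, Peak2D

log = logging.getLogger(__name__)

__all__ = [
    "PeakSearchParams",
    "find_center_direct",
    "find_center_friedel",
    "peak_search_2d",
    "auto_threshold",
]


@dataclass
class PeakSearchParams:
    """Parameters of the connected-component reflection search."""

    intensity_threshold: Union[float, str] = "auto"
    min_cluster_px: int = 4
    max_aspect: float = 5.0
    use_density_filter: bool = False
    min_density: float = 0.0
    #: radius (px) around a known centre excluded from the peak list
    center_exclude_px: float = 10.0
    #: k in the auto threshold median + k * (1.4826 * MAD)
    auto_k: float = 5.0

    def __post_init__(self) -> None:
        if self.min_cluster_px < 1:
            raise ValueError("min_cluster_px must be >= 1")
        if self.max_aspect < 1:
            raise ValueError("max_aspect must be >= 1")


def auto_threshold(image: np.ndarray, k: float = 5.0) -> float:
    """Deterministic robust threshold: median + k * 1.4826 * MAD."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med + k * 1.4826 * mad


def _weighted_centroid(image: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    w = image[rows, cols]
    s = w.sum()
    return float((cols * w).sum() / s), float((rows * w).sum() / s)


def find_center_direct(frame: DiffractionFrame) -> tuple[float, float]:
    """Locate the unblanked central beam: among the connected regions above
    the 99.9th-percentile threshold, pick the one maximizing
    (peak intensity x extent) and return its intensity-weighted centroid.

    Ties go to the larger extent, then lower y, then lower x.
    """
    image = frame.image
    thr = float(np.percentile(image, 99.9))
    mask = image > thr
    if not mask.any():
        raise CenteringError("no region above the direct-beam threshold")
    labels = measure.label(mask, connectivity=2)
    best = None
    for region in measure.regionprops(labels, intensity_image=image):
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        x, y = _weighted_centroid(image, rows, cols)
        score = float(region.intensity_max) * region.area
        key = (-score, -region.area, y, x)
        if best is None or key < best[0]:
            best = (key, (x, y))
    return best[1]


def find_center_friedel(
    frame: DiffractionFrame,
    peaks: Sequence[Peak2D],
    pair_tol_px: float = 2.0,
) -> tuple[tuple[float, float], int]:
    """Locate the pattern centre as the point about which the most peak
    pairs are symmetric (Friedel pairs hkl / -h-k-l share a midpoint).

    Every pair midpoint votes; the midpoint with the most neighbours within
    ``pair_tol_px`` wins and the centre is refined as the mean of the
    accepted midpoints.  Returns ``((x, y), n_pairs)``.
    """
    if len(peaks) < 3:
        raise CenteringError("Friedel centring needs at least 3 peaks")
    xy = np.array([[p.x, p.y] for p in peaks])
    n = len(xy)
    ii, jj = np.triu_indices(n, k=1)
    mids = 0.5 * (xy[ii] + xy[jj])
    tree = cKDTree(mids)
    counts = tree.query_ball_point(mids, r=pair_tol_px, return_length=True)
    best = int(np.argmax(counts))
    if counts[best] < 2:
        raise CenteringError("fewer than 2 consistent Friedel pairs found")
    members = tree.query_ball_point(mids[best], r=pair_tol_px)
    center = mids[members].mean(axis=0)
    # one refinement pass about the averaged centre
    members = tree.query_ball_point(center, r=pair_tol_px)
    center = mids[members].mean(axis=0)
    return (float(center[0]), float(center[1])), len(members)


def peak_search_2d(
    frame: DiffractionFrame,
    params: Optional[PeakSearchParams] = None,
    return_rejected: bool = False,
):
    """Threshold + 8-connected clustering reflection search.

    Pixels above the threshold are grouped with 8-connectivity; clusters
    smaller than ``min_cluster_px`` are dropped.  Each peak carries the
    intensity-weighted centroid, summed counts, the intensity density over
    the bounding rectangle and the rectangle aspect ratio.  Clusters failing
    the aspect (or optional density) filter are returned separately when
    ``return_rejected`` is set.  Peaks are sorted by intensity, descending.
    A region around a known frame centre is excluded.
    """
    params = params or PeakSearchParams()
    image = frame.image
    if params.intensity_threshold == "auto":
        thr = auto_threshold(image, params.auto_k)
    else:
        thr = float(params.intensity_threshold)
    mask = image > thr
    accepted: list[Peak2D] = []
    rejected: list[Peak2D] = []
    if mask.any():
        labels = measure.label(mask, connectivity=2)
        for fid, region in enumerate(measure.regionprops(labels, intensity_image=image)):
            if region.area < params.min_cluster_px:
                continue
            rows, cols = region.coords[:, 0], region.coords[:, 1]
            x, y = _weighted_centroid(image, rows, cols)
            intensity = float(image[rows, cols].sum())
            r0, c0, r1, c1 = region.bbox
            h, w = r1 - r0, c1 - c0
            density = intensity / (h * w)
            aspect = max(h, w) / min(h, w)
            peak = Peak2D(frame_idx=0, x=x, y=y, intensity=intensity,
                          area_px=int(region.area), density=density, aspect=aspect)
            if frame.center_px is not None:
                cx, cy = frame.center_px
                if (x - cx) ** 2 + (y - cy) ** 2 < params.center_exclude_px ** 2:
                    continue
            ok = aspect <= params.max_aspect
            if ok and params.use_density_filter:
                ok = density >= params.min_density
            (accepted if ok else rejected).append(peak)
    accepted.sort(key=lambda p: -p.intensity)
    rejected.sort(key=lambda p: -p.intensity)
    if return_rejected:
        return accepted, rejected
    return accepted
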