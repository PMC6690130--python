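"""Unit-cell determination from the 3-D peak cloud.

For a periodic lattice the pairwise difference vectors of the peak
positions reproduce the translation lattice, so clustering them yields
candidate lattice vectors; a basis is then chosen so that every significant
cluster centre is an integer combination of the three basis vectors, and
the winning basis is least-squares refined over its indexed clusters and
brought to the Niggli reduced form (Krivy-Gruber, via gemmi, with the
orientation matrix transformed consistently).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .errors import NoLatticeError
from .model import Peak3D, ReflectionSet, UnitCell, _cell_params_from_direct

log = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "ClusterSet",
    "difference_vectors",
    "cluster_vectors",
    "find_basis",
    "index_peaks",
    "niggli_reduce_cell",
]


@dataclass
class ClusterParams:
    """The three user-facing clustering parameters."""

    min_points: int = 4
    max_intra_dist: float = 0.01  # 1/Angstrom
    max_origin_dist: float = 0.6  # 1/Angstrom

    def __post_init__(self) -> None:
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if self.max_intra_dist <= 0 or self.max_origin_dist <= 0:
            raise ValueError("cluster distances must be > 0")


@dataclass
class ClusterSet:
    """Cluster centres of the difference-vector space, by |centre|."""

    centers: np.ndarray  # (n, 3), 1/Angstrom
    weights: np.ndarray  # member counts

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.int64).reshape(len(self.centers))

    def __len__(self) -> int:
        return len(self.centers)


def _canonical_hemisphere(vectors: np.ndarray) -> np.ndarray:
    """Sign-normalize each vector so its first nonzero component is positive."""
    v = vectors.copy()
    flip = (v[:, 0] < 0) | ((v[:, 0] == 0) & ((v[:, 1] < 0) | ((v[:, 1] == 0) & (v[:, 2] < 0))))
    v[flip] *= -1.0
    return v


def difference_vectors(peaks: Sequence[Peak3D], max_origin_dist: float) -> np.ndarray:
    """All pairwise position differences with magnitude <= the cap,
    sign-normalized to the canonical hemisphere."""
    if len(peaks) < 2:
        raise ValueError("difference vectors need at least 2 peaks")
    g = np.array([p.g for p in peaks])
    pairs = cKDTree(g).query_pairs(r=max_origin_dist, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 3))
    d = g[pairs[:, 0]] - g[pairs[:, 1]]
    return _canonical_hemisphere(d)


def cluster_vectors(vectors: np.ndarray, params: ClusterParams) -> ClusterSet:
    """Density-based grouping (eps = max_intra_dist, minPts = min_points) of
    the difference vectors; centres are plain means of cluster members,
    sorted by distance from the origin.  An empty result is valid."""
    vectors = np.asarray(vectors, dtype=np.float64).reshape(-1, 3)
    if len(vectors) == 0:
        raise ValueError("cluster_vectors needs a non-empty vector list")
    keep = np.linalg.norm(vectors, axis=1) <= params.max_origin_dist
    vectors = vectors[keep]
    if len(vectors) == 0:
        return ClusterSet(np.zeros((0, 3)), np.zeros(0, dtype=np.int64))
    labels = DBSCAN(eps=params.max_intra_dist, min_samples=params.min_points).fit_predict(vectors)
    centers, weights = [], []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = vectors[labels == lab]
        if len(members) < params.min_points:
            continue
        centre = members.mean(axis=0)
        if np.linalg.norm(centre) <= params.max_origin_dist:
            centers.append(centre)
            weights.append(len(members))
    if not centers:
        log.warning("no difference-vector cluster satisfied min_points=%d", params.min_points)
        return ClusterSet(np.zeros((0, 3)), np.zeros(0, dtype=np.int64))
    centers = np.array(centers)
    weights = np.array(weights, dtype=np.int64)
    order = np.argsort(np.linalg.norm(centers, axis=1), kind="stable")
    return ClusterSet(centers[order], weights[order])


# ---------------------------------------------------------------------------
# basis search
# ---------------------------------------------------------------------------

_MAX_CANDIDATE_CENTERS = 30


def _indexed_fraction(M: np.ndarray, centers: np.ndarray, weights: np.ndarray, tol: float):
    """Weighted fraction of cluster centres integer-indexable in basis M."""
    try:
        f = np.linalg.solve(M, centers.T).T
    except np.linalg.LinAlgError:
        return 0.0, np.zeros(len(centers), dtype=bool)
    res = np.abs(f - np.round(f)).max(axis=1)
    ok = res < tol
    return float(weights[ok].sum() / weights.sum()), ok


def find_basis(clusters: ClusterSet, tol: float = 0.25) -> UnitCell:
    """Choose the reciprocal basis from the shortest cluster centres.

    Candidate triples of linearly independent short centres are scored by
    the weighted fraction of all centres whose coordinates in that basis
    are within ``tol`` of integers; the winner (ties: smaller direct cell
    volume, then lexicographic parameters) is least-squares refined over
    its indexed centres and returned Niggli-reduced.
    """
    if len(clusters) < 6:
        raise NoLatticeError(f"basis search needs >= 6 clusters, got {len(clusters)}")
    centers, weights = clusters.centers, clusters.weights
    sv = np.linalg.svd(centers - centers.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-3 * sv[0]:
        raise NoLatticeError("cluster set does not span 3-D (planar or collinear)")

    cand = centers[: _MAX_CANDIDATE_CENTERS]
    best = None
    for i, j, k in itertools.combinations(range(len(cand)), 3):
        M = np.column_stack([cand[i], cand[j], cand[k]])
        det = np.linalg.det(M)
        norms = np.linalg.norm(M, axis=0).prod()
        if abs(det) < 1e-2 * norms:  # nearly coplanar triple
            continue
        frac, _ = _indexed_fraction(M, centers, weights, tol)
        vol_direct = 1.0 / abs(det)
        params = tuple(round(p, 6) for p in _cell_params_from_direct(np.linalg.inv(M).T))
        key = (-frac, round(vol_direct, 9), params)
        if best is None or key < best[0]:
            best = (key, M)
    if best is None or -best[0][0] < 0.5:
        raise NoLatticeError("no basis indexes at least half the cluster weight")
    M = best[1]

    # least-squares refinement over indexed clusters, iterated twice
    for _ in range(2):
        frac, ok = _indexed_fraction(M, centers, weights, tol)
        H = np.round(np.linalg.solve(M, centers[ok].T).T)
        w = weights[ok].astype(np.float64)
        lhs = (centers[ok] * w[:, None]).T @ H
        rhs = (H * w[:, None]).T @ H
        M = lhs @ np.linalg.inv(rhs)

    if np.linalg.det(M) < 0:
        M[:, 2] *= -1.0  # keep a right-handed reciprocal basis
    return niggli_reduce_cell(UnitCell.from_basis(M))


def niggli_reduce_cell(cell: UnitCell) -> UnitCell:
    """Niggli-reduce (Krivy-Gruber) keeping the orientation matrix in step.

    The reduced direct basis is A P with P the integer change-of-basis
    matrix, hence the reciprocal basis transforms as B inv(P)^T.
    """
    gv = gemmi.GruberVector(gemmi.UnitCell(*cell.parameters()), None,
                            track_change_of_basis=True)
    gv.niggli_reduce()
    op = gv.change_of_basis
    P = np.array(op.rot, dtype=np.float64) / op.DEN
    B_new = cell.B @ np.linalg.inv(P).T
    if np.linalg.det(B_new) < 0:
        B_new *= -1.0  # inversion leaves the lattice unchanged
    return UnitCell.from_basis(B_new)


def index_peaks(
    peaks: Sequence[Peak3D],
    cell: UnitCell,
    tol: float = 0.25,
) -> tuple[ReflectionSet, list[tuple[Peak3D, float]]]:
    """Assign integer hkl = round(B^-1 g) to every peak.

    A peak is accepted when the largest fractional residual is below
    ``tol`` (and hkl != 000); rejected peaks are returned with their
    residuals.  Intensities carry over, sigma = sqrt(I) floored at 1.
    """
    if not len(peaks):
        return ReflectionSet.empty(), []
    g = np.array([p.g for p in peaks])
    f = np.linalg.solve(cell.B, g.T).T
    hkl = np.round(f).astype(np.int64)
    res = np.abs(f - hkl).max(axis=1)
    ok = (res < tol) & hkl.any(axis=1)
    I = np.array([p.intensity for p in peaks])
    nfr = np.array([len(p.source_frames) for p in peaks])
    rs = ReflectionSet(
        hkl=hkl[ok],
        I=I[ok],
        sigma=np.maximum(1.0, np.sqrt(np.maximum(I[ok], 0.0))),
        d_A=cell.d_spacing(hkl[ok]),
        peak_idx=np.where(ok)[0],
        n_frames=nfr[ok],
    )
    rejected = [(peaks[i], float(res[i])) for i in np.where(~ok)[0]]
    return rs, rejected
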