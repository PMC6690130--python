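"""Reflection-intensity integration, symmetry merging and statistics.

Merging works in the 11 Laue classes.  Friedel pairs are always merged.
The internal residual is

    R_int = sum_hkl sum_i |I_i - <I>| / sum_hkl sum_i I_i

over symmetry-equivalent groups with at least two observations, and
completeness is the observed fraction of all symmetry-unique lattice
points inside the resolution sphere (enumerated by brute force).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .model import MergeStats, Peak3D, ReflectionSet, UnitCell

log = logging.getLogger(__name__)

__all__ = ["LAUE_GROUPS", "integrate", "merge", "completeness", "laue_equivalents"]


def _ops_from_generators(gens: list[np.ndarray]) -> list[np.ndarray]:
    """Close a set of integer hkl generators into the full rotation group."""
    ops = {tuple(np.eye(3, dtype=np.int64).ravel())}
    frontier = [np.eye(3, dtype=np.int64)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in gens:
                prod = g @ m
                key = tuple(prod.ravel())
                if key not in ops:
                    ops.add(key)
                    nxt.append(prod)
        frontier = nxt
    return [np.array(k, dtype=np.int64).reshape(3, 3) for k in sorted(ops)]


def _mat(rows) -> np.ndarray:
    return np.array(rows, dtype=np.int64)


# generators of the proper-rotation part of each Laue class, acting on hkl
# (standard settings: 2/m unique axis b; trigonal/hexagonal on hexagonal axes)
_GENERATORS = {
    "-1": [],
    "2/m": [_mat([[-1, 0, 0], [0, 1, 0], [0, 0, -1]])],
    "mmm": [_mat([[-1, 0, 0], [0, -1, 0], [0, 0, 1]]),
            _mat([[-1, 0, 0], [0, 1, 0], [0, 0, -1]])],
    "4/m": [_mat([[0, -1, 0], [1, 0, 0], [0, 0, 1]])],
    "4/mmm": [_mat([[0, -1, 0], [1, 0, 0], [0, 0, 1]]),
              _mat([[1, 0, 0], [0, -1, 0], [0, 0, -1]])],
    "-3": [_mat([[0, -1, 0], [1, -1, 0], [0, 0, 1]])],
    "-3m": [_mat([[0, -1, 0], [1, -1, 0], [0, 0, 1]]),
            _mat([[0, 1, 0], [1, 0, 0], [0, 0, -1]])],
    "6/m": [_mat([[1, -1, 0], [1, 0, 0], [0, 0, 1]])],
    "6/mmm": [_mat([[1, -1, 0], [1, 0, 0], [0, 0, 1]]),
              _mat([[0, 1, 0], [1, 0, 0], [0, 0, -1]])],
    "m-3": [_mat([[0, 0, 1], [1, 0, 0], [0, 1, 0]]),
            _mat([[-1, 0, 0], [0, -1, 0], [0, 0, 1]])],
    "m-3m": [_mat([[0, 0, 1], [1, 0, 0], [0, 1, 0]]),
             _mat([[0, -1, 0], [1, 0, 0], [0, 0, 1]])],
}

#: proper-rotation matrices per Laue class; inversion (Friedel) is applied
#: on top everywhere
LAUE_GROUPS = {name: _ops_from_generators(gens) for name, gens in _GENERATORS.items()}


def laue_equivalents(hkl: Sequence[int], laue_group: str) -> set[tuple[int, int, int]]:
    """The full orbit of hkl under the Laue group, Friedel mates included."""
    ops = _laue_ops(laue_group)
    h = np.asarray(hkl, dtype=np.int64)
    out = set()
    for m in ops:
        v = m @ h
        out.add(tuple(v))
        out.add(tuple(-v))
    return out


def _laue_ops(laue_group: str) -> list[np.ndarray]:
    if laue_group not in LAUE_GROUPS:
        raise ConfigurationError(
            f"unknown Laue group '{laue_group}'; choose from {sorted(LAUE_GROUPS)}"
        )
    return LAUE_GROUPS[laue_group]


def _canonical(hkl: np.ndarray, laue_group: str) -> np.ndarray:
    """Canonical representative (lexicographically greatest orbit member,
    Friedel mates included) for an (N, 3) array of indices."""
    ops = _laue_ops(laue_group)
    n = len(hkl)
    best = None
    for m in ops:
        for sign in (1, -1):
            cand = sign * (hkl @ m.T)
            if best is None:
                best = cand.copy()
            else:
                # lexicographic comparison on (h, k, l)
                gt = (
                    (cand[:, 0] > best[:, 0])
                    | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
                    | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] == best[:, 1])
                       & (cand[:, 2] > best[:, 2]))
                )
                best[gt] = cand[gt]
    return best


def integrate(peaks3d: Sequence[Peak3D], indexed: ReflectionSet) -> ReflectionSet:
    """Per-observation integrated intensities.

    Each indexed reflection keeps the intensity summed over the source-frame
    contributions that were merged into its Peak3D; sigma is a counting
    estimate sqrt(I) floored at 1.  Duplicate hkl observations remain
    separate records (the unmerged set).
    """
    if not len(indexed):
        return ReflectionSet.empty()
    I = indexed.I.copy()
    if indexed.peak_idx is not None:
        I = np.array([peaks3d[i].intensity for i in indexed.peak_idx])
    return ReflectionSet(
        hkl=indexed.hkl.copy(),
        I=I,
        sigma=np.maximum(1.0, np.sqrt(np.maximum(I, 0.0))),
        d_A=indexed.d_A.copy(),
        peak_idx=None if indexed.peak_idx is None else indexed.peak_idx.copy(),
        n_frames=None if indexed.n_frames is None else indexed.n_frames.copy(),
    )


def merge(rs: ReflectionSet, laue_group: str) -> tuple[ReflectionSet, MergeStats]:
    """Merge symmetry-equivalent observations and compute R_int.

    The unique set carries the group mean intensity and the propagated
    sigma sqrt(sum sigma_i^2)/n.
    """
    _laue_ops(laue_group)  # validate the symbol early
    if not len(rs):
        return ReflectionSet.empty(), MergeStats(0, 0, 0.0)
    canon = _canonical(rs.hkl, laue_group)
    # group rows by canonical representative
    order = np.lexsort((canon[:, 2], canon[:, 1], canon[:, 0]))
    canon_sorted = canon[order]
    boundaries = np.any(np.diff(canon_sorted, axis=0) != 0, axis=1)
    group_id = np.concatenate([[0], np.cumsum(boundaries)])
    n_groups = group_id[-1] + 1

    I_sorted = rs.I[order]
    sig_sorted = rs.sigma[order]
    d_sorted = rs.d_A[order]
    counts = np.bincount(group_id, minlength=n_groups)
    sums = np.bincount(group_id, weights=I_sorted, minlength=n_groups)
    means = sums / counts
    sig2 = np.bincount(group_id, weights=sig_sorted**2, minlength=n_groups)
    sig_merged = np.sqrt(sig2) / counts
    dev = np.bincount(group_id, weights=np.abs(I_sorted - means[group_id]), minlength=n_groups)

    multi = counts >= 2
    denom = sums[multi].sum()
    r_int = float(dev[multi].sum() / denom) if denom > 0 else 0.0

    first = np.concatenate([[0], 1 + np.where(boundaries)[0]])
    unique = ReflectionSet(
        hkl=canon_sorted[first],
        I=means,
        sigma=sig_merged,
        d_A=d_sorted[first],
    )
    stats = MergeStats(
        n_measured=len(rs),
        n_unique=int(n_groups),
        r_int=r_int,
        dmin_A=float(rs.d_A.min()),
    )
    return unique, stats


def completeness(
    unique: ReflectionSet,
    cell: UnitCell,
    laue_group: str,
    dmin_A: float,
) -> float:
    """Observed fraction (percent) of all symmetry-unique lattice points
    with d >= dmin, the denominator enumerated by brute force over the hkl
    box bounding the resolution sphere (000 excluded)."""
    _laue_ops(laue_group)
    if dmin_A <= 0:
        raise ConfigurationError("dmin must be positive")
    if len(unique) and dmin_A < unique.d_A.min():
        log.warning("requested dmin %.3f A is below the data limit %.3f A",
                    dmin_A, unique.d_A.min())
    bounds = [int(math.floor(length / dmin_A)) + 1 for length in (cell.a, cell.b, cell.c)]
    hkl = np.array(
        [t for t in itertools.product(*(range(-b, b + 1) for b in bounds)) if any(t)],
        dtype=np.int64,
    )
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= dmin_A]
    denom_set = {tuple(row) for row in _canonical(hkl, laue_group)}
    if not denom_set:
        return 100.0
    obs = unique.hkl[unique.d_A >= dmin_A - 1e-9]
    obs_set = {tuple(row) for row in _canonical(obs, laue_group)} if len(obs) else set()
    return 100.0 * len(obs_set & denom_set) / len(denom_set)
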