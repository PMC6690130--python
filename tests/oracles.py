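"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own implementations: plain-Python
pixel labelling, double loops over peak pairs, and root-finding on the
rotation angle instead of closed forms, so that agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation


def label_clusters_bruteforce(image: np.ndarray, threshold: float):
    """8-connected components of pixels strictly above the threshold via
    breadth-first search; returns a list of dicts with centroid, summed
    intensity, area, bounding box."""
    ny, nx = image.shape
    mask = image > threshold
    seen = np.zeros_like(mask, dtype=bool)
    clusters = []
    for r0 in range(ny):
        for c0 in range(nx):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            queue = [(r0, c0)]
            seen[r0, c0] = True
            members = []
            while queue:
                r, c = queue.pop()
                members.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            rows = np.array([m[0] for m in members])
            cols = np.array([m[1] for m in members])
            w = image[rows, cols]
            total = w.sum()
            bbox_h = rows.max() - rows.min() + 1
            bbox_w = cols.max() - cols.min() + 1
            clusters.append(
                {
                    "x": float((cols * w).sum() / total),
                    "y": float((rows * w).sum() / total),
                    "intensity": float(total),
                    "area": len(members),
                    "density": float(total) / (bbox_h * bbox_w),
                    "aspect": max(bbox_h, bbox_w) / min(bbox_h, bbox_w),
                }
            )
    return clusters


def difference_vectors_bruteforce(positions: np.ndarray, cap: float) -> np.ndarray:
    """All pairwise differences below the cap, canonical hemisphere, via an
    explicit double loop."""
    out = []
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            if np.linalg.norm(d) > cap:
                continue
            if d[0] < 0 or (d[0] == 0 and (d[1] < 0 or (d[1] == 0 and d[2] < 0))):
                d = -d
            out.append(d)
    return np.array(out).reshape(-1, 3)


def friedel_center_bruteforce(xy: np.ndarray, tol: float):
    """Exhaustive midpoint vote: for every pair midpoint count the pair
    midpoints within tol, return the best midpoint refined by averaging."""
    n = len(xy)
    mids = []
    for i in range(n):
        for j in range(i + 1, n):
            mids.append(0.5 * (xy[i] + xy[j]))
    mids = np.array(mids)
    best_count, best_mid = -1, None
    for m in mids:
        close = np.linalg.norm(mids - m, axis=1) <= tol
        if close.sum() > best_count:
            best_count = int(close.sum())
            best_mid = mids[close].mean(axis=0)
    return best_mid, best_count


def sphere_crossing_bruteforce(g0: np.ndarray, phi_deg: float, eta_deg: float,
                               wavelength_A: float, rocking_deg: float):
    """Detector-plane position of a node on a frame, by numeric
    root-finding on the rotation angle (no closed forms).

    Rotates the node by -eta about the axis (sin phi, cos phi, 0), then
    scans for the extra rotation theta bringing it onto the sphere
    |v - (0,0,1/lam)| = 1/lam; returns (x_rel, y_rel) in 1/Angstrom or
    None when no crossing lies within the rocking width.
    """
    axis = np.array([np.sin(np.radians(phi_deg)), np.cos(np.radians(phi_deg)), 0.0])
    rot = lambda t: Rotation.from_rotvec(np.radians(t) * axis)
    v = rot(-eta_deg).apply(g0)
    c = np.array([0.0, 0.0, 1.0 / wavelength_A])

    def f(theta):
        return np.linalg.norm(rot(theta).apply(v) - c) - 1.0 / wavelength_A

    # bracket roots on a fine scan over +-rocking
    thetas = np.linspace(-rocking_deg, rocking_deg, 4001)
    vals = np.array([f(t) for t in thetas])
    roots = []
    for i in range(len(thetas) - 1):
        if vals[i] == 0.0:
            roots.append(thetas[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, thetas[i], thetas[i + 1], xtol=1e-12))
    if not roots:
        return None
    theta = min(roots, key=abs)
    w = rot(theta).apply(v)
    return w[0], w[1], theta


def unique_cubic_m3m_count(a: float, dmin: float) -> int:
    """Number of symmetry-unique lattice points with d >= dmin for a cubic
    cell in Laue class m-3m: orbits are classified by sorted |h|,|k|,|l|."""
    hmax = int(np.floor(a / dmin)) + 1
    reps = set()
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-hmax, hmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if np.sqrt(h * h + k * k + l * l) / a > 1.0 / dmin:
                    continue
                reps.add(tuple(sorted((abs(h), abs(k), abs(l)))))
    return len(reps)
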