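"""Shared fixtures: small synthetic acquisitions with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from edtproc.model import UnitCell
from edtproc.synthetic import GroundTruth, simulate_series


def set_known_centers(series):
    ny, nx = series.shape
    for f in series.frames:
        f.center_px = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    return series


@pytest.fixture(scope="session")
def cubic_cell() -> UnitCell:
    return UnitCell.from_parameters(5.0, 5.0, 5.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def monoclinic_cell() -> UnitCell:
    """Carbamazepine-like monoclinic metric in a non-trivial orientation."""
    U = Rotation.random(random_state=np.random.default_rng(11)).as_matrix()
    return UnitCell.from_parameters(7.49, 11.28, 13.60, 90.2, 93.1, 90.5, orientation=U)


@pytest.fixture(scope="session")
def cubic_series(cubic_cell):
    """Noiseless cubic tilt series, centres known; reused read-only."""
    gt = GroundTruth(cell=cubic_cell, phi_deg=30.0, noise=False, seed=3)
    series = simulate_series(gt, -45, 45, 1.0, frame_px=256, px_cal=0.01, dmin_A=1.3)
    return set_known_centers(series), gt


@pytest.fixture(scope="session")
def cubic_peaks(cubic_series):
    from edtproc import preprocess

    series, gt = cubic_series
    params = preprocess.PeakSearchParams()
    peaks = []
    for i, frame in enumerate(series.frames):
        found = preprocess.peak_search_2d(frame, params)
        for p in found:
            p.frame_idx = i
        peaks.extend(found)
    return peaks
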