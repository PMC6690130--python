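"""Ewald back-projection, tilt-axis search, 3-D peak building and voxel
reconstruction."""

import numpy as np
import pytest

from edtproc import preprocess
from edtproc.errors import GeometryError, ResourceError
from edtproc.geometry import (
    build_peaks3d,
    ewald_backproject,
    find_tilt_axis,
    merge_peaks3d,
    reconstruct_volume,
    slice_volume,
)
from edtproc.model import DiffractionFrame, Peak2D, Peak3D, TiltSeries, VoxelVolume
from edtproc.synthetic import GroundTruth, simulate_series
from tests.conftest import set_known_centers


class TestEwaldBackprojection:
    def test_center_maps_to_origin_any_tilt(self):
        for tilt in (-40.0, 0.0, 33.0):
            g = ewald_backproject((100.0, 100.0), (100.0, 100.0), 0.01, 0.0251,
                                  tilt, 25.0)
            np.testing.assert_allclose(g, np.zeros(3), atol=1e-15)

    def test_curvature_closed_form_reference(self):
        # frozen from a 50-digit evaluation of 1/lam - sqrt(1/lam^2 - r^2)
        lam, r = 0.0251, 0.5
        g = ewald_backproject((100.0 + r / 0.01, 100.0), (100.0, 100.0), 0.01,
                              lam, 0.0, 0.0)
        assert g[0] == pytest.approx(0.5, rel=1e-12)
        assert g[2] == pytest.approx(3.137623550753405e-3, rel=1e-10)

    def test_small_r_approaches_planar_approximation(self):
        # exact factor 2/(1 + sqrt(1 - (lam r)^2)) reaches 1.0102 at
        # r = 0.2/lam, so the 1% bound is checked strictly inside that edge
        lam = 0.0251
        for r in (0.05, 0.5, 2.0, 0.195 / lam):
            g = ewald_backproject((100.0 + r / 0.01, 100.0), (100.0, 100.0), 0.01,
                                  lam, 0.0, 0.0)
            assert abs(g[2]) <= lam * r * r / 2 * 1.01

    def test_beyond_sphere_is_geometry_error(self):
        with pytest.raises(GeometryError):
            ewald_backproject((5000.0, 100.0), (100.0, 100.0), 0.01, 0.0251, 0.0, 0.0)

    def test_point_on_tilt_axis_invariant(self):
        """A detector point along the tilt-axis azimuth stays fixed under
        the tilt rotation (up to its tiny Ewald z-offset rotating)."""
        phi = 35.0
        ux, uy = np.sin(np.radians(phi)), np.cos(np.radians(phi))
        r_px = 30.0
        xy = (100.0 + ux * r_px, 100.0 + uy * r_px)
        g0 = ewald_backproject(xy, (100.0, 100.0), 0.01, 0.0251, 0.0, phi)
        g1 = ewald_backproject(xy, (100.0, 100.0), 0.01, 0.0251, 50.0, phi)
        # in-plane part lies on the axis and is exactly invariant
        np.testing.assert_allclose(g1[:2], g0[:2], atol=g0[2] + 1e-12)

    def test_backprojection_inverts_the_simulator(self, cubic_series):
        """Back-projecting the simulator's rendered spot positions at the
        true phi recovers the generating lattice nodes (cross-check that
        the independent forward and inverse geometry codes share one
        convention)."""
        series, gt = cubic_series
        truth = series.truth.head(200)
        c = (series.shape[1] - 1) / 2.0
        for row in truth.itertuples():
            g = ewald_backproject((row.x_px, row.y_px), (c, c), series.px_cal,
                                  series.wavelength_A,
                                  series.frames[row.frame].tilt_deg, gt.phi_deg)
            g_true = gt.cell.B @ np.array([row.h, row.k, row.l], dtype=float)
            # residual bounded by the rocking-width arc
            assert np.linalg.norm(g - g_true) < np.linalg.norm(g_true) * np.radians(
                gt.rocking_deg) + 1e-9


class TestTiltAxis:
    @pytest.mark.parametrize("phi_true", [-60.0, 0.0, 41.5])
    def test_recovery_within_half_degree(self, cubic_cell, phi_true):
        gt = GroundTruth(cell=cubic_cell, phi_deg=phi_true, noise=False, seed=3)
        series = set_known_centers(
            simulate_series(gt, -45, 45, 1.0, frame_px=256, px_cal=0.01, dmin_A=1.3))
        peaks = []
        for i, f in enumerate(series.frames):
            found = preprocess.peak_search_2d(f, preprocess.PeakSearchParams())
            for p in found:
                p.frame_idx = i
            peaks.extend(found)
        sol = find_tilt_axis(peaks, series)
        assert sol.reliable
        assert abs(sol.phi_deg - phi_true) < 0.5

    def test_inplane_rotation_equivariance(self, cubic_series, cubic_peaks):
        """Rotating every pattern by +psi about its centre moves the
        apparent tilt axis to phi - psi."""
        series, gt = cubic_series
        sol0 = find_tilt_axis(cubic_peaks, series)
        psi = np.radians(10.0)
        c = (series.shape[1] - 1) / 2.0
        rotated = []
        for p in cubic_peaks:
            dx, dy = p.x - c, p.y - c
            rotated.append(Peak2D(p.frame_idx,
                                  c + np.cos(psi) * dx - np.sin(psi) * dy,
                                  c + np.sin(psi) * dx + np.cos(psi) * dy,
                                  p.intensity, p.area_px, p.density, p.aspect))
        sol1 = find_tilt_axis(rotated, series)
        assert sol1.phi_deg - sol0.phi_deg == pytest.approx(-10.0, abs=0.2)

    def test_single_frame_flagged_unreliable(self, cubic_series, cubic_peaks):
        series, _ = cubic_series
        one_frame = [p for p in cubic_peaks if p.frame_idx == 40]
        if len(one_frame) < 2:
            one_frame = [p for p in cubic_peaks if p.frame_idx == 45]
        sol = find_tilt_axis(one_frame, series)
        assert not sol.reliable


class TestPeaks3D:
    def test_single_peak_at_closed_form_position(self):
        frame = DiffractionFrame(np.zeros((64, 64)), 0.0, 0.01,
                                 center_px=(31.5, 31.5))
        series = TiltSeries([frame], wavelength_A=0.0251)
        peak = Peak2D(0, 41.5, 31.5, 500.0, 5, 10.0, 1.0)
        out = build_peaks3d([peak], series, phi_deg=0.0, merge_radius_A=0.01)
        assert len(out) == 1
        expected = ewald_backproject((41.5, 31.5), (31.5, 31.5), 0.01, 0.0251, 0.0, 0.0)
        np.testing.assert_allclose(out[0].g, expected, atol=1e-12)

    def test_empty_input_empty_output(self, cubic_series):
        series, _ = cubic_series
        assert build_peaks3d([], series, 30.0) == []

    def test_rocking_samples_merge_into_single_node(self, cubic_cell):
        """A node whose rocking curve spans 3 consecutive frames becomes
        exactly one Peak3D with 3 source frames."""
        gt = GroundTruth(cell=cubic_cell, phi_deg=15.0, rocking_deg=1.6,
                         noise=False, central_beam=False, seed=6)
        series = set_known_centers(
            simulate_series(gt, -20, 20, 1.0, frame_px=256, px_cal=0.01, dmin_A=1.4))
        truth = series.truth
        counts = truth.groupby(["h", "k", "l"])["frame"].count()
        peaks = []
        for i, f in enumerate(series.frames):
            found = preprocess.peak_search_2d(f, preprocess.PeakSearchParams())
            for p in found:
                p.frame_idx = i
            peaks.extend(found)
        out = build_peaks3d(peaks, series, gt.phi_deg)
        by_node = {}
        for p in out:
            f = np.linalg.solve(cubic_cell.B, p.g)
            hkl = tuple(int(round(v)) for v in f)
            assert np.abs(f - np.round(f)).max() < 0.2
            by_node.setdefault(hkl, []).append(p)
        three_frame_nodes = [n for n, c in counts.items() if c == 3
                             and truth[(truth.h == n[0]) & (truth.k == n[1])
                                       & (truth.l == n[2])].counts.min() > 30]
        assert three_frame_nodes
        for node in three_frame_nodes:
            assert node in by_node
            assert len(by_node[node]) == 1
            assert len(by_node[node][0].source_frames) == 3

    def test_merge_idempotent(self, cubic_series, cubic_peaks):
        series, gt = cubic_series
        out = build_peaks3d(cubic_peaks, series, gt.phi_deg)
        again = merge_peaks3d(out, 0.015)
        assert len(again) == len(out)
        a = sorted((tuple(np.round(p.g, 9)), round(p.intensity, 6)) for p in out)
        b = sorted((tuple(np.round(p.g, 9)), round(p.intensity, 6)) for p in again)
        assert a == b


class TestReconstruction:
    def test_single_center_pixel_lands_at_origin(self):
        image = np.zeros((32, 32))
        image[15, 15] = 7.0  # at the declared centre
        frame = DiffractionFrame(image, 0.0, 0.01, center_px=(15.0, 15.0))
        series = TiltSeries([frame], wavelength_A=0.0251)
        vol = reconstruct_volume(series, 0.0, 0.01, mode="sum")
        nz = np.array(np.nonzero(vol.grid)).T
        assert len(nz) == 1
        np.testing.assert_allclose(vol.coord_of(nz[0]), np.zeros(3), atol=1e-12)
        assert vol.grid[tuple(nz[0])] == 7.0

    def test_sum_mode_conserves_total_intensity(self, cubic_series):
        series, gt = cubic_series
        vol = reconstruct_volume(series, gt.phi_deg, 0.012, mode="sum")
        total_in = sum(float(f.image.sum()) for f in series.frames)
        assert float(vol.grid.sum()) == pytest.approx(total_in, rel=1e-12)

    def test_volume_maxima_on_lattice_nodes(self, cubic_series):
        series, gt = cubic_series
        vol = reconstruct_volume(series, gt.phi_deg, 0.012, mode="max")
        truth = series.truth
        strong = truth[truth.counts > 1000].groupby(["h", "k", "l"]).size().index[:20]
        for hkl in strong:
            g = gt.cell.B @ np.array(hkl, dtype=float)
            idx = np.round(vol.index_of(g)).astype(int)
            lo = idx - 1
            window = vol.grid[lo[0]:lo[0] + 3, lo[1]:lo[1] + 3, lo[2]:lo[2] + 3]
            assert window.max() > 0
            # the local neighbourhood peaks within 1 voxel of the node
            far = vol.grid[lo[0] - 2:lo[0] + 5, lo[1] - 2:lo[1] + 5, lo[2] - 2:lo[2] + 5]
            assert window.max() == far.max()

    def test_memory_cap_raises_resource_error(self, cubic_series):
        series, gt = cubic_series
        with pytest.raises(ResourceError):
            reconstruct_volume(series, gt.phi_deg, 1e-4)


class TestSlicing:
    def test_full_slab_sum_equals_projection(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(0, 5, (11, 11, 11))
        vol = VoxelVolume(grid, 0.01, origin=-0.05 * np.ones(3))
        img = slice_volume(vol, (0, 0, 1), 0.0, thickness=1.0, mode="sum")
        assert img.sum() == pytest.approx(grid.sum(), rel=1e-12)

    def test_zero_volume_zero_image(self):
        vol = VoxelVolume(np.zeros((9, 9, 9)), 0.01, origin=-0.04 * np.ones(3))
        img = slice_volume(vol, (1, 0, 0), 0.0, thickness=0.05)
        assert img.sum() == 0

    def test_empty_slab_errors(self):
        vol = VoxelVolume(np.zeros((9, 9, 9)), 0.01, origin=-0.04 * np.ones(3))
        with pytest.raises(GeometryError):
            slice_volume(vol, (0, 0, 1), offset=5.0, thickness=0.001)
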