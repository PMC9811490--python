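"""Delay-and-sum reconstruction, stitching, projections, and resolution."""

import numpy as np
import pytest

from hemipact.core import GridSpec, Volume
from hemipact.forward import SignalFrame, impulse_response, simulate_signals
from hemipact.geometry import ElementSubset, SubsetMode, build_array, select_subset
from hemipact.reconstruction import (
    ReconGrid,
    das_reconstruct,
    depth_encode,
    map_projection,
    measure_fwhm,
    stitch_max,
)


def das_oracle(frame, geom, grid):
    """Independent delay-and-sum: per-element np.interp over voxel times."""
    g = grid.grid
    X, Y, Z = g.voxel_centers()
    vox = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    t = frame.t0_s + np.arange(frame.n_samples) / frame.sample_rate_hz
    out = np.zeros(len(vox))
    sos_mm = grid.speed_of_sound_m_s * 1e3
    for row, ch in zip(frame.samples, frame.subset.indices):
        p = geom.element_positions[ch - 1]
        tau = np.linalg.norm(vox - p, axis=1) / sos_mm
        out += np.interp(tau, t, row, left=0.0, right=0.0)
    return out.reshape(g.shape)


def random_frame(geom, rng, n_samples=160, n_rows=None):
    n = n_rows or geom.n_elements
    idx = np.sort(rng.choice(geom.n_elements, size=n, replace=False)) + 1
    subset = ElementSubset(SubsetMode.FULL, idx)
    samples = rng.normal(size=(n, n_samples))
    t0 = 50.0 / 1.5e6  # window bracketing the grid's times of flight
    return SignalFrame(samples, 8.33e6, t0, subset, 1500.0)


class TestDas:
    def test_matches_interp_oracle_on_random_instances(self, rng):
        geom = build_array(n_elements=64, element_area_mm2=100.0)
        for k in range(4):
            edge = int(rng.integers(8, 33))
            frame = random_frame(geom, rng, n_rows=int(rng.integers(4, 65)))
            grid = ReconGrid((edge,) * 3, 0.25)
            vol = das_reconstruct(frame, geom, grid)
            ref = das_oracle(frame, geom, grid)
            scale = np.abs(ref).max()
            np.testing.assert_allclose(vol.values, ref, atol=1e-6 * scale)

    def test_matches_pure_python_triple_loop(self, rng):
        geom = build_array(n_elements=4, element_area_mm2=100.0)
        frame = random_frame(geom, rng, n_samples=120)
        grid = ReconGrid((6, 6, 6), 0.3)
        vol = das_reconstruct(frame, geom, grid)
        g = grid.grid
        sos_mm = grid.speed_of_sound_m_s * 1e3
        ref = np.zeros(g.shape)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    x = np.array([g.axis_coords(0)[i], g.axis_coords(1)[j], g.axis_coords(2)[k]])
                    acc = 0.0
                    for row, ch in zip(frame.samples, frame.subset.indices):
                        r = np.linalg.norm(x - geom.element_positions[ch - 1])
                        p = (r / sos_mm - frame.t0_s) * frame.sample_rate_hz
                        jj = int(np.floor(p))
                        if 0 <= jj < frame.n_samples - 1:
                            f = p - jj
                            acc += row[jj] * (1 - f) + row[jj + 1] * f
                    ref[i, j, k] = acc
        np.testing.assert_allclose(vol.values, ref, atol=1e-9 * np.abs(ref).max())

    def test_zero_frame_reconstructs_to_zero(self, small_geom):
        frame = SignalFrame(
            np.zeros((64, 100)), 8.33e6, 3e-5, select_subset(small_geom, "full"), 1500.0
        )
        vol = das_reconstruct(frame, small_geom, ReconGrid((8, 8, 8), 0.1))
        assert not vol.values.any()

    def test_linearity(self, small_geom, rng):
        sub = select_subset(small_geom, "full")
        f1 = SignalFrame(rng.normal(size=(64, 120)), 8.33e6, 3e-5, sub, 1500.0)
        f2 = SignalFrame(rng.normal(size=(64, 120)), 8.33e6, 3e-5, sub, 1500.0)
        fs = SignalFrame(f1.samples + f2.samples, 8.33e6, 3e-5, sub, 1500.0)
        grid = ReconGrid((8, 8, 8), 0.2)
        v1 = das_reconstruct(f1, small_geom, grid)
        v2 = das_reconstruct(f2, small_geom, grid)
        vs = das_reconstruct(fs, small_geom, grid)
        np.testing.assert_allclose(vs.values, v1.values + v2.values, rtol=1e-12, atol=1e-12)

    def test_point_source_localized_within_one_voxel(self, small_geom):
        g = GridSpec((17, 17, 17), 0.1)
        values = np.zeros(g.shape)
        values[8, 8, 8] = 1.0
        vol_in = Volume(values, g.voxel_mm, g.origin_mm)
        frame = simulate_signals(vol_in, small_geom, select_subset(small_geom, "full"),
                                 impulse_response())
        recon = das_reconstruct(frame, small_geom, ReconGrid((17, 17, 17), 0.1))
        peak = np.unravel_index(np.argmax(np.abs(recon.values)), recon.shape)
        assert max(abs(p - 8) for p in peak) <= 1


class TestStitchMax:
    def test_single_volume_identity(self, rng):
        v = Volume(rng.random((6, 6, 6)), 0.1)
        out = stitch_max([v], [(0, 0, 0)])
        np.testing.assert_array_equal(out.values, v.values)

    def test_identical_overlap_unchanged(self, rng):
        v = Volume(rng.random((6, 6, 6)), 0.1)
        out = stitch_max([v, v], [(0, 0, 0), (0.3, 0, 0)])
        # overlapping region of the shifted copy: max(a, a_shifted)
        assert out.shape == (9, 6, 6)
        np.testing.assert_array_equal(out.values[:3, :, :], v.values[:3, :, :])

    def test_overlap_is_elementwise_max(self, rng):
        a = Volume(rng.random((8, 8, 8)), 0.1)
        b = Volume(rng.random((8, 8, 8)), 0.1)
        out = stitch_max([a, b], [(0, 0, 0), (0.4, 0, 0)])
        expected = np.maximum(a.values[4:, :, :], b.values[:4, :, :])
        np.testing.assert_array_equal(out.values[4:8, :, :], expected)

    def test_non_commensurate_offset_rejected(self, rng):
        v = Volume(rng.random((4, 4, 4)), 0.1)
        with pytest.raises(ValueError):
            stitch_max([v, v], [(0, 0, 0), (0.05, 0, 0)])


class TestProjections:
    def test_single_voxel_map(self):
        vals = np.zeros((5, 6, 7))
        vals[2, 3, 4] = 2.5
        m = map_projection(Volume(vals, 0.1), "z")
        assert m.data.shape == (5, 6)
        assert m.data[2, 3] == 2.5
        assert np.count_nonzero(m.data) == 1

    def test_homogeneity_and_loop_oracle(self, rng):
        vals = rng.normal(size=(16, 16, 16))
        v = Volume(vals, 0.1)
        m1 = map_projection(v, "y")
        m3 = map_projection(Volume(3.0 * vals, 0.1), "y")
        np.testing.assert_allclose(m3.data, 3.0 * m1.data)
        ref = np.empty((16, 16))
        for i in range(16):
            for k in range(16):
                ref[i, k] = max(abs(vals[i, j, k]) for j in range(16))
        np.testing.assert_allclose(m1.data, ref)

    def test_depth_encode_colors_by_depth(self):
        vals = np.zeros((4, 4, 10))
        vals[1, 1, 2] = 1.0
        vals[2, 2, 7] = 1.0
        img = depth_encode(Volume(vals, 0.1), "z", colormap="jet")
        assert img.depth_mm[1, 1] == pytest.approx(0.2)
        assert img.depth_mm[2, 2] == pytest.approx(0.7)
        assert not np.allclose(img.rgb[1, 1], img.rgb[2, 2])  # distinct hues
        from matplotlib import colormaps

        expected = np.asarray(colormaps["jet"](0.2 / 1.0))[:3]
        np.testing.assert_allclose(img.rgb[1, 1], expected, atol=1e-12)

    def test_depth_encode_black_where_empty(self):
        img = depth_encode(Volume(np.zeros((3, 3, 3)), 0.1), "z")
        assert not img.rgb.any()


class TestFwhm:
    def test_sampled_gaussian_closed_form(self):
        # FWHM of a Gaussian with sigma = 0.5 mm is 2 sqrt(2 ln 2) sigma
        g = GridSpec((64, 1, 1), 0.1)
        x = g.axis_coords(0)
        vals = np.exp(-(x**2) / (2 * 0.5**2)).reshape(-1, 1, 1)
        width = measure_fwhm(Volume(vals, 0.1), "x", (np.argmax(vals), 0, 0))
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.5, rel=0.01)

    def test_single_voxel_is_one_voxel_wide(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 1.0
        assert measure_fwhm(Volume(vals, 0.1), "x", (4, 4, 4)) == pytest.approx(0.1)

    def test_profile_that_never_drops_raises(self):
        vals = np.ones((9, 9, 9))
        with pytest.raises(ValueError):
            measure_fwhm(Volume(vals, 0.1), "z", (4, 4, 4))
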