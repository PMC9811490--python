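"""Band-limited transducer response and the acoustic forward model."""

import numpy as np
import pytest

from hemipact.core import GridSpec, Volume
from hemipact.forward import add_noise, impulse_response, simulate_signals
from hemipact.geometry import select_subset


class TestImpulseResponse:
    def test_minus6db_band_edges(self):
        ir = impulse_response(2.02e6, 0.54, 8.33e6, 255)
        nfft = 1 << 16
        spec = np.abs(np.fft.rfft(ir.kernel, nfft))
        freqs = np.fft.rfftfreq(nfft, 1.0 / ir.sample_rate_hz)
        half = spec.max() / 2.0
        above = freqs[spec >= half]
        lo, hi = above.min(), above.max()
        assert lo == pytest.approx(2.02e6 * (1 - 0.27), rel=0.02)
        assert hi == pytest.approx(2.02e6 * (1 + 0.27), rel=0.02)

    def test_zero_mean_and_unit_peak(self):
        ir = impulse_response()
        assert abs(ir.kernel.sum()) < 1e-6 * np.abs(ir.kernel).max()
        assert np.abs(ir.kernel).max() == pytest.approx(1.0)

    def test_narrowband_limit_peaks_at_fc(self):
        ir = impulse_response(2.0e6, 0.02, 8.33e6, 2047)
        nfft = 1 << 16
        spec = np.abs(np.fft.rfft(ir.kernel, nfft))
        freqs = np.fft.rfftfreq(nfft, 1.0 / ir.sample_rate_hz)
        assert freqs[np.argmax(spec)] == pytest.approx(2.0e6, rel=1e-3)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            impulse_response(5e6, 0.5, 8.33e6)


@pytest.fixture(scope="module")
def center_source():
    g = GridSpec((9, 9, 9), 0.1)
    values = np.zeros(g.shape)
    values[4, 4, 4] = 1.0
    return Volume(values, g.voxel_mm, g.origin_mm)


class TestSimulateSignals:
    def test_center_source_arrival_time(self, small_geom, center_source):
        ir = impulse_response()
        frame = simulate_signals(
            center_source, small_geom, select_subset(small_geom, "full"), ir, 1500.0
        )
        expected_t = 0.060 / 1500.0
        for row in frame.samples:
            t_peak = frame.t0_s + np.argmax(np.abs(row)) / frame.sample_rate_hz
            assert t_peak == pytest.approx(expected_t, abs=1.5 / frame.sample_rate_hz)

    def test_empty_volume_gives_silence(self, small_geom):
        g = GridSpec((8, 8, 8), 0.1)
        vol = Volume(np.zeros(g.shape), g.voxel_mm, g.origin_mm)
        frame = simulate_signals(vol, small_geom, select_subset(small_geom, "full"),
                                 impulse_response())
        assert not frame.samples.any()

    def test_linearity(self, small_geom, rng):
        g = GridSpec((8, 8, 8), 0.2)
        v1 = Volume(rng.random(g.shape), g.voxel_mm, g.origin_mm)
        v2 = Volume(rng.random(g.shape), g.voxel_mm, g.origin_mm)
        ir = impulse_response(n_taps=63)
        sub = select_subset(small_geom, "cluster")
        combo = Volume(2.0 * v1.values + 3.0 * v2.values, g.voxel_mm, g.origin_mm)
        f_combo = simulate_signals(combo, small_geom, sub, ir)
        f1 = simulate_signals(v1, small_geom, sub, ir)
        f2 = simulate_signals(v2, small_geom, sub, ir)
        np.testing.assert_allclose(
            f_combo.samples, 2.0 * f1.samples + 3.0 * f2.samples, rtol=1e-9, atol=1e-12
        )

    def test_amplitude_falls_as_one_over_r(self, small_geom):
        # same source amplitude at two depths: received peak scales as 1/r
        ir = impulse_response(n_taps=63)
        sub = select_subset(small_geom, "full")
        g = GridSpec((9, 9, 9), 0.1)
        peaks = []
        dists = []
        pole = small_geom.element_positions[0]
        for z in (0.0, 2.0):
            values = np.zeros(g.shape)
            values[4, 4, 4] = 1.0
            vol = Volume(values, g.voxel_mm, (g.origin_mm[0], g.origin_mm[1], g.origin_mm[2] + z))
            frame = simulate_signals(vol, small_geom, sub, ir)
            # received pulse energy is sub-sample-phase independent, the
            # discrete peak sample is not
            peaks.append(np.sqrt(np.sum(frame.samples[0] ** 2)))
            dists.append(np.linalg.norm(pole - [0, 0, z]))
        assert peaks[0] / peaks[1] == pytest.approx(dists[1] / dists[0], rel=1e-3)

    def test_cluster_rows_equal_full_frame_rows(self, small_geom, center_source):
        # extracting the cluster from full raw data is exact, as in the
        # published preprocessing
        ir = impulse_response()
        full = simulate_signals(center_source, small_geom,
                                select_subset(small_geom, "full"), ir)
        cluster = simulate_signals(center_source, small_geom,
                                   select_subset(small_geom, "cluster"), ir)
        rows = cluster.subset.indices - 1
        assert cluster.t0_s == full.t0_s
        np.testing.assert_array_equal(cluster.samples, full.samples[rows])

    def test_determinism(self, small_geom, center_source):
        ir = impulse_response()
        sub = select_subset(small_geom, "sparse")
        a = simulate_signals(center_source, small_geom, sub, ir)
        b = simulate_signals(center_source, small_geom, sub, ir)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_source_outside_hemisphere_warned_and_dropped(self, small_geom):
        g = GridSpec((5, 5, 5), 0.1, origin_mm=(70.0, 0.0, 0.0))
        vol = Volume(np.ones(g.shape), g.voxel_mm, g.origin_mm)
        with pytest.warns(UserWarning):
            frame = simulate_signals(vol, small_geom, select_subset(small_geom, "full"),
                                     impulse_response())
        assert not frame.samples.any()

    def test_empty_subset_rejected(self, small_geom, center_source):
        from hemipact.geometry import ElementSubset, SubsetMode

        empty = ElementSubset(SubsetMode.FULL, np.array([], dtype=int))
        with pytest.raises(ValueError):
            simulate_signals(center_source, small_geom, empty, impulse_response())


class TestAddNoise:
    def _frame(self, small_geom, center_source):
        return simulate_signals(center_source, small_geom,
                                select_subset(small_geom, "full"), impulse_response())

    def test_infinite_snr_is_identity(self, small_geom, center_source):
        frame = self._frame(small_geom, center_source)
        noisy = add_noise(frame, np.inf, seed=3)
        np.testing.assert_array_equal(noisy.samples, frame.samples)

    def test_empirical_snr_matches_request(self, small_geom, center_source):
        frame = self._frame(small_geom, center_source)
        snr_db = 10.0
        noisy = add_noise(frame, snr_db, seed=5)
        noise = noisy.samples - frame.samples
        measured = 10.0 * np.log10(np.mean(frame.samples**2) / np.mean(noise**2))
        assert measured == pytest.approx(snr_db, abs=0.5)

    def test_seeded_noise_reproducible(self, small_geom, center_source):
        frame = self._frame(small_geom, center_source)
        a = add_noise(frame, 20.0, seed=9)
        b = add_noise(frame, 20.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_power_frame_rejected(self, small_geom):
        g = GridSpec((4, 4, 4), 0.1)
        vol = Volume(np.zeros(g.shape), g.voxel_mm, g.origin_mm)
        frame = simulate_signals(vol, small_geom, select_subset(small_geom, "full"),
                                 impulse_response())
        with pytest.raises(ValueError):
            add_noise(frame, 10.0, seed=0)
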