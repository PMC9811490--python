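"""Spectral unmixing, sO2 mapping, preprocessing, and HbT masking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemipact.core import GridSpec, Volume
from hemipact.phantom import OxygenChallengeProtocol, make_oxygen_challenge
from hemipact.unmixing import (
    ExtinctionTable,
    compute_so2,
    default_extinction_table,
    functional_maps,
    hbt_mask,
    preprocess_functional,
    unmix_two_wavelength,
)


class TestPreprocess:
    def test_positive_constant_unchanged(self):
        v = Volume(np.full((6, 6, 6), 0.4))
        np.testing.assert_array_equal(preprocess_functional(v).values, v.values)

    def test_negative_voxel_clipped_then_smoothed(self):
        vals = np.ones((7, 7, 7))
        vals[3, 3, 3] = -5.0
        out = preprocess_functional(Volume(vals))
        assert out.values.min() >= 0.0
        assert out.values[3, 3, 3] == 1.0  # 26 of 27 neighbors are 1

    def test_interior_matches_sorted_median_oracle(self, rng):
        vals = rng.normal(size=(5, 5, 5))
        out = preprocess_functional(Volume(vals)).values
        clipped = np.clip(vals, 0, None)
        for i in range(1, 4):
            for j in range(1, 4):
                for k in range(1, 4):
                    window = clipped[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2]
                    assert out[i, j, k] == sorted(window.ravel())[13]


def table_from_matrix(E):
    return ExtinctionTable(
        table=((750.0, E[0, 0], E[0, 1]), (850.0, E[1, 0], E[1, 1]))
    )


class TestUnmixing:
    def test_identity_matrix_passthrough(self, rng):
        pa1 = Volume(rng.random((5, 5, 5)))
        pa2 = Volume(rng.random((5, 5, 5)))
        c_hbo, c_hbr = unmix_two_wavelength(pa1, pa2, table_from_matrix(np.eye(2)))
        np.testing.assert_allclose(c_hbo.values, pa1.values, atol=1e-12)
        np.testing.assert_allclose(c_hbr.values, pa2.values, atol=1e-12)

    def test_compose_then_unmix_is_exact(self, rng):
        table = default_extinction_table()
        E = table.matrix((750.0, 850.0))
        c_true = rng.random((2, 6, 6, 6))
        pa = np.einsum("wc,cxyz->wxyz", E, c_true)
        c_hbo, c_hbr = unmix_two_wavelength(
            Volume(pa[0]), Volume(pa[1]), table, mode="lsq"
        )
        np.testing.assert_allclose(c_hbo.values, c_true[0], atol=1e-12)
        np.testing.assert_allclose(c_hbr.values, c_true[1], atol=1e-12)

    def test_first_column_signal_has_no_hbr(self, rng):
        table = default_extinction_table()
        E = table.matrix((750.0, 850.0))
        a = rng.random((4, 4, 4))
        c_hbo, c_hbr = unmix_two_wavelength(
            Volume(E[0, 0] * a), Volume(E[1, 0] * a), table
        )
        np.testing.assert_allclose(c_hbr.values, 0.0, atol=1e-10)
        np.testing.assert_allclose(c_hbo.values, a, atol=1e-10)

    def test_singular_table_rejected(self, rng):
        v = Volume(rng.random((3, 3, 3)))
        with pytest.raises(ValueError):
            unmix_two_wavelength(v, v, table_from_matrix(np.ones((2, 2))))

    def test_nnls_mode_clips_active_constraints(self):
        table = table_from_matrix(np.array([[1.0, 0.2], [0.2, 1.0]]))
        pa750 = Volume(np.full((2, 2, 2), 0.1))
        pa850 = Volume(np.full((2, 2, 2), 1.0))  # forces negative C_HbO
        c_hbo, c_hbr = unmix_two_wavelength(pa750, pa850, table, mode="nnls")
        assert (c_hbo.values >= 0).all() and (c_hbr.values >= 0).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_unmixing_inverts_composition_for_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.uniform(0.1, 2.0, (2, 2))
        if np.linalg.cond(E) > 1e6:
            return
        c_true = rng.random((2, 3, 3, 3))
        pa = np.einsum("wc,cxyz->wxyz", E, c_true)
        c_hbo, c_hbr = unmix_two_wavelength(
            Volume(pa[0]), Volume(pa[1]), table_from_matrix(E), mode="lsq"
        )
        scale = max(np.abs(c_true).max(), 1.0)
        np.testing.assert_allclose(c_hbo.values, c_true[0], atol=1e-9 * scale * np.linalg.cond(E))
        np.testing.assert_allclose(c_hbr.values, c_true[1], atol=1e-9 * scale * np.linalg.cond(E))


class TestSo2:
    def test_trivial_values(self):
        ones = Volume(np.ones((3, 3, 3)))
        zeros = Volume(np.zeros((3, 3, 3)))
        np.testing.assert_allclose(compute_so2(ones, zeros).values, 1.0)
        np.testing.assert_allclose(compute_so2(ones, ones).values, 0.5)

    def test_scale_invariance(self, rng):
        c1 = Volume(rng.random((4, 4, 4)) + 0.1)
        c2 = Volume(rng.random((4, 4, 4)) + 0.1)
        a = compute_so2(c1, c2).values
        b = compute_so2(c1.with_values(7.0 * c1.values), c2.with_values(7.0 * c2.values)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_undefined_outside_support(self):
        c = Volume(np.zeros((3, 3, 3)))
        assert np.isnan(compute_so2(c, c).values).all()


class TestHbtMask:
    def test_threshold_extremes(self, rng):
        c1 = Volume(rng.random((5, 5, 5)))
        c2 = Volume(rng.random((5, 5, 5)))
        hbt = c1.values + c2.values
        m0 = hbt_mask(c1, c2, 0.0).values
        np.testing.assert_array_equal(m0, hbt > 0)
        m1 = hbt_mask(c1, c2, 1.0).values
        assert m1.sum() >= 1
        assert m1[np.unravel_index(np.argmax(hbt), hbt.shape)]

    def test_count_matches_loop_oracle(self, rng):
        c1 = Volume(rng.random((5, 5, 5)))
        c2 = Volume(rng.random((5, 5, 5)))
        mask = hbt_mask(c1, c2, 0.3).values
        hbt = c1.values + c2.values
        expected = sum(
            1
            for i in range(5) for j in range(5) for k in range(5)
            if hbt[i, j, k] >= 0.3 * hbt.max()
        )
        assert mask.sum() == expected

    def test_all_zero_gives_empty_mask(self):
        z = Volume(np.zeros((3, 3, 3)))
        assert not hbt_mask(z, z, 0.1).values.any()


class TestOxygenChallengeRoundTrip:
    def test_composition_unmixing_recovers_schedule_exactly(self):
        # noise-free composition through the extinction model inverts to
        # the piecewise sO2 schedule at every frame
        g = GridSpec((10, 10, 10), 0.5)
        labels = np.zeros(g.shape, dtype=int)
        labels[3:7, 3:7, 3:7] = 1
        protocol = OxygenChallengeProtocol(
            segments=((10.0, 0.95), (10.0, 0.70), (10.0, 0.95))
        )
        table = default_extinction_table()
        res = make_oxygen_challenge(Volume(labels, 0.5), protocol, table, frame_rate_hz=0.5)
        for frame_i in range(len(res.seq_750)):
            c_hbo, c_hbr = unmix_two_wavelength(
                res.seq_750[frame_i], res.seq_850[frame_i], table, mode="lsq"
            )
            so2 = compute_so2(c_hbo, c_hbr).values
            inside = labels > 0
            np.testing.assert_allclose(so2[inside], res.so2_true[frame_i], atol=1e-9)
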