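import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhicast.core_io import ValidationError, Variable
from vhicast.indices import (
    DroughtClass,
    NormalizationStats,
    classify_drought,
    compute_ndvi,
    compute_tci,
    compute_vci,
    compute_vhi,
    normalization_stats,
)
from vhicast.synthetic import inject_range_outliers
from tests.conftest import make_cube


class TestComputeNdvi:
    @pytest.mark.parametrize(
        "red,nir,expected",
        [(0.4, 0.4, 0.0), (0.0, 0.6, 1.0), (0.3, 0.5, 0.25)],
    )
    def test_point_values(self, red, nir, expected):
        out = compute_ndvi(np.array([[red]]), np.array([[nir]]))
        assert out[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_zero_denominator_masked(self):
        out = compute_ndvi(np.array([[0.0, 0.2]]), np.array([[0.0, 0.2]]))
        assert out.mask[0, 0] and not out.mask[0, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_ndvi(np.zeros((2, 2)), np.zeros((3, 3)))


class TestNormalizationStats:
    def test_constant_cube_both_scopes(self):
        cube = make_cube(np.full((3, 2, 2), 7.0))
        for scope in ("image", "global", "global_scalar"):
            s = normalization_stats(cube, scope)
            assert np.all(s.minimum == 7.0) and np.all(s.maximum == 7.0)

    def test_two_frame_single_pixel_global(self):
        cube = make_cube(np.array([3.0, 9.0]).reshape(2, 1, 1))
        s = normalization_stats(cube, "global")
        assert s.minimum[0, 0] == 3.0 and s.maximum[0, 0] == 9.0

    def test_matches_brute_force_loops(self, rng):
        cube = make_cube(rng.uniform(-1, 1, (5, 4, 4)).astype(np.float32))
        img = normalization_stats(cube, "image")
        for t in range(5):
            assert img.minimum[t] == cube.values[t].min()
            assert img.maximum[t] == cube.values[t].max()
        glo = normalization_stats(cube, "global")
        for r in range(4):
            for c in range(4):
                assert glo.minimum[r, c] == cube.values[:, r, c].min()
                assert glo.maximum[r, c] == cube.values[:, r, c].max()

    def test_masked_cells_rejected(self, rng):
        mask = np.zeros((3, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        cube = make_cube(rng.uniform(0, 1, (3, 2, 2)), mask=mask)
        with pytest.raises(ValidationError):
            normalization_stats(cube, "image")


class TestConditionIndices:
    def test_vci_anchors_and_midpoint(self):
        cube = make_cube(np.array([0.2, 0.5, 0.8]).reshape(3, 1, 1))
        stats = NormalizationStats("global", Variable.NDVI,
                                   np.full((1, 1), 0.2), np.full((1, 1), 0.8))
        vci = compute_vci(cube, stats)
        np.testing.assert_allclose(vci.values[:, 0, 0], [0.0, 0.5, 1.0], atol=1e-6)

    def test_tci_anchors_and_midpoint(self):
        cube = make_cube(np.array([290.0, 300.0, 310.0]).reshape(3, 1, 1),
                         variable=Variable.LST)
        stats = NormalizationStats("global", Variable.LST,
                                   np.full((1, 1), 290.0), np.full((1, 1), 310.0))
        tci = compute_tci(cube, stats)
        np.testing.assert_allclose(tci.values[:, 0, 0], [1.0, 0.5, 0.0], atol=1e-6)

    def test_degenerate_range_maps_to_half(self):
        cube = make_cube(np.full((2, 2, 2), 0.3))
        vci = compute_vci(cube, normalization_stats(cube, "image"))
        np.testing.assert_array_equal(vci.values, 0.5)

    def test_vci_monotone_in_ndvi_tci_antitone_in_lst(self, rng):
        stats_n = NormalizationStats("global_scalar", Variable.NDVI,
                                     np.float32(-0.2), np.float32(0.9))
        stats_l = NormalizationStats("global_scalar", Variable.LST,
                                     np.float32(280.0), np.float32(320.0))
        n1 = make_cube(rng.uniform(0, 0.5, (3, 3, 3)))
        n2 = make_cube(n1.values + 0.2)
        assert np.all(compute_vci(n2, stats_n).values >= compute_vci(n1, stats_n).values)
        l1 = make_cube(rng.uniform(285, 300, (3, 3, 3)), variable=Variable.LST)
        l2 = make_cube(l1.values + 5.0, variable=Variable.LST)
        assert np.all(compute_tci(l2, stats_l).values <= compute_tci(l1, stats_l).values)

    def test_image_scope_vci_attains_full_range_per_frame(self, rng):
        cube = make_cube(rng.uniform(0, 1, (4, 6, 6)))
        vci = compute_vci(cube, normalization_stats(cube, "image"))
        for t in range(4):
            assert vci.values[t].min() == 0.0 and vci.values[t].max() == 1.0

    def test_global_scope_round_trip_reconstructs_ndvi(self, rng):
        cube = make_cube(rng.uniform(-0.2, 0.9, (6, 5, 5)).astype(np.float32))
        stats = normalization_stats(cube, "global")
        vci = compute_vci(cube, stats)
        recon = vci.values * (stats.maximum - stats.minimum)[None] + stats.minimum[None]
        np.testing.assert_allclose(recon, cube.values, atol=1e-5)


class TestComputeVhi:
    def test_weighted_mean(self):
        vci = make_cube(np.full((1, 1, 1), 0.6), variable=Variable.VCI)
        tci = make_cube(np.full((1, 1, 1), 0.4), variable=Variable.TCI)
        assert compute_vhi(vci, tci, 0.5).values[0, 0, 0] == pytest.approx(0.5)

    def test_degenerate_weights_bitwise(self, rng):
        vci = make_cube(rng.uniform(0, 1, (3, 2, 2)), variable=Variable.VCI)
        tci = make_cube(rng.uniform(0, 1, (3, 2, 2)), variable=Variable.TCI)
        np.testing.assert_array_equal(compute_vhi(vci, tci, 1.0).values, vci.values)
        np.testing.assert_array_equal(compute_vhi(vci, tci, 0.0).values, tci.values)

    def test_half_alpha_is_arithmetic_mean(self, rng):
        vci = make_cube(rng.uniform(0, 1, (3, 4, 4)).astype(np.float32), variable=Variable.VCI)
        tci = make_cube(rng.uniform(0, 1, (3, 4, 4)).astype(np.float32), variable=Variable.TCI)
        np.testing.assert_allclose(
            compute_vhi(vci, tci, 0.5).values, (vci.values + tci.values) / 2, atol=1e-6
        )

    def test_misaligned_axes_rejected(self, rng):
        import datetime as dt

        vci = make_cube(rng.uniform(0, 1, (3, 2, 2)), variable=Variable.VCI)
        tci = make_cube(rng.uniform(0, 1, (3, 2, 2)), variable=Variable.TCI,
                        start=dt.date(2013, 1, 1))
        with pytest.raises(ValidationError):
            compute_vhi(vci, tci, 0.5)


class TestClassifyDrought:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.75, DroughtClass.none),
            (0.51, DroughtClass.none),
            (0.50, DroughtClass.mild),  # upper-inclusive below 0.5
            (0.40, DroughtClass.mild),
            (0.35, DroughtClass.moderate),
            (0.25, DroughtClass.moderate),
            (0.20, DroughtClass.severe),
            (0.15, DroughtClass.severe),
            (0.10, DroughtClass.extreme),
            (0.05, DroughtClass.extreme),
            (0.0, DroughtClass.extreme),
            (1.0, DroughtClass.none),
        ],
    )
    def test_class_boundaries(self, value, expected):
        assert classify_drought(value) is expected

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_every_vhi_value_gets_exactly_one_class(self, v):
        assert classify_drought(v) in DroughtClass

    def test_out_of_range_rejected(self):
        for v in (-0.1, 1.1):
            with pytest.raises(ValidationError):
                classify_drought(v)


class TestDistributionShift:
    def test_global_scope_preserves_frame_mean_dynamics(self, rng):
        # seasonal cube whose per-frame extremes are jittered by contamination:
        # image scope re-anchors each frame, flattening frame-mean dynamics
        t = np.arange(92)
        seasonal = 0.4 + 0.25 * np.sin(2 * np.pi * t / 46)
        vals = seasonal[:, None, None] + rng.normal(0, 0.02, (92, 10, 10))
        cube = make_cube(np.clip(vals, -1, 1).astype(np.float32))
        cube = inject_range_outliers(cube, pixel_fraction=0.03, sign=-1, seed=2)
        means = {}
        for scope in ("image", "global"):
            vci = compute_vci(cube, normalization_stats(cube, scope))
            means[scope] = vci.values.mean(axis=(1, 2))
        assert means["global"].var() > means["image"].var()
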