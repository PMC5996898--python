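import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phyllo import (
    Contour,
    DensityField,
    PHParams,
    RasterMask,
    annulus_weight,
    gaussian_density,
    localized_density,
    make_annuli,
    normalize_contour,
    ph_descriptor,
    rasterize_contour,
    superlevel_ec_curve,
)
from phyllo.errors import ConfigurationError
from phyllo.ph_descriptor import (
    GAUSS_MAX,
    AnnulusSpec,
    euler_characteristic,
    euler_characteristic_bitquad,
)

from conftest import rotate


def single_pixel_mask() -> RasterMask:
    """3x3 grid whose center pixel is foreground with center at the origin."""
    grid = np.zeros((3, 3), dtype=bool)
    grid[1, 1] = True
    return RasterMask(grid=grid, origin=(-1.5, -1.5), pixel_size=1.0)


def field_from_grid(values: np.ndarray) -> DensityField:
    rows, cols = np.nonzero(values > 0)
    mask = RasterMask(
        grid=values > 0, origin=(0.0, 0.0), pixel_size=1.0
    )
    return DensityField(
        rows=rows, cols=cols, values=values[rows, cols], mask=mask, h=1.0
    )


class TestGaussianDensity:
    def test_kernel_peak_at_data_point(self):
        f = gaussian_density(single_pixel_mask(), np.array([[0.0, 0.0]]), h=0.5)
        assert f.values[0] == pytest.approx(GAUSS_MAX, abs=1e-12)
        assert GAUSS_MAX == pytest.approx(0.3989422804, abs=1e-9)

    def test_kernel_at_one_bandwidth(self):
        h = 0.02
        f = gaussian_density(single_pixel_mask(), np.array([[h, 0.0]]), h=h)
        assert f.values[0] == pytest.approx(np.exp(-0.5) * GAUSS_MAX, abs=1e-9)
        assert np.exp(-0.5) * GAUSS_MAX == pytest.approx(0.2419707245, abs=1e-9)

    def test_duplicate_points_average_to_same_value(self):
        f1 = gaussian_density(single_pixel_mask(), np.array([[0.0, 0.0]]), h=0.1)
        f2 = gaussian_density(
            single_pixel_mask(), np.array([[0.0, 0.0], [0.0, 0.0]]), h=0.1
        )
        assert f2.values[0] == pytest.approx(f1.values[0], abs=1e-15)

    def test_bounded_above_everywhere(self, circle_factory, small_params):
        norm = normalize_contour(circle_factory(n=100), n_resample=400)
        mask = rasterize_contour(norm, resolution=128)
        f = gaussian_density(mask, norm.points, h=0.03)
        assert np.all(f.values > 0)
        assert np.all(f.values <= GAUSS_MAX + 1e-15)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ConfigurationError):
            gaussian_density(single_pixel_mask(), np.array([[0.0, 0.0]]), h=0.0)


class TestAnnuli:
    def test_default_schedule(self):
        annuli = make_annuli(16)
        np.testing.assert_allclose(
            [a.radius for a in annuli], np.arange(1, 17) / 16.0
        )
        assert all(a.width == pytest.approx(1.0 / 32.0) for a in annuli)
        assert sorted(a.index for a in annuli) == list(range(1, 17))

    def test_single_annulus_at_unit_radius(self):
        (a,) = make_annuli(1)
        assert a.radius == 1.0
        assert a.center == (0.0, 0.0)

    @pytest.mark.parametrize(
        "offset, expected",
        [(0.0, 1.0), (1.0, np.exp(-0.5)), (10.0, None)],
    )
    def test_weight_values(self, offset, expected):
        a = AnnulusSpec(center=(0.0, 0.0), radius=0.5, width=0.04, index=1)
        d = a.radius + offset * a.width
        w = annulus_weight(a, np.array([[d, 0.0]]))[0]
        if expected is None:
            assert w < 1e-21
        else:
            assert w == pytest.approx(expected, abs=1e-12)

    def test_localized_identity_in_wide_kernel_limit(self, circle_factory):
        norm = normalize_contour(circle_factory(n=100), n_resample=300)
        mask = rasterize_contour(norm, resolution=64)
        f = gaussian_density(mask, norm.points, h=0.05)
        wide = AnnulusSpec(center=(0.0, 0.0), radius=1.0, width=1e6, index=1)
        local = localized_density(f, wide)
        np.testing.assert_allclose(local.values, f.values, atol=1e-9)

    def test_far_annulus_has_empty_support(self, circle_factory):
        norm = normalize_contour(circle_factory(n=100), n_resample=300)
        mask = rasterize_contour(norm, resolution=64)
        f = gaussian_density(mask, norm.points, h=0.05)
        # outline sits at radius ~1; the innermost of 16 rings never reaches it
        inner = make_annuli(16)[0]
        assert localized_density(f, inner).n_pixels == 0


class TestEulerCharacteristic:
    @pytest.mark.parametrize(
        "grid, expected",
        [
            (np.ones((3, 3), dtype=bool), 1),
            (
                np.kron(np.array([[1, 0, 1]]), np.ones((3, 3))).astype(bool),
                2,
            ),
            (np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool), 0),
            (np.zeros((4, 4), dtype=bool), 0),
            (np.array([[1, 0], [0, 1]], dtype=bool), 1),  # diagonal connects
        ],
    )
    def test_known_masks(self, grid, expected):
        assert euler_characteristic(grid) == expected
        assert euler_characteristic_bitquad(grid) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(arrays(bool, (16, 16), elements=st.booleans()))
    def test_bitquad_matches_floodfill(self, grid):
        assert euler_characteristic_bitquad(grid) == euler_characteristic(grid)


class TestSuperlevelECCurve:
    def test_two_bumps_birth_order(self):
        values = np.zeros((5, 9))
        values[2, 1:4] = [0.6, 1.0, 0.6]  # bump peaking at 1.0
        values[2, 5:8] = [0.3, 0.5, 0.3]  # bump peaking at 0.5
        curve = superlevel_ec_curve(field_from_grid(values), n_levels=50)
        assert curve.values[0] == 1
        assert curve.values[-1] == 2  # disjoint supports stay disjoint
        crossing = curve.thresholds <= 0.5
        assert np.all(curve.values[crossing] == 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_level_floodfill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = np.where(rng.random((25, 25)) < 0.5, rng.random((25, 25)), 0.0)
        if not values.any():
            pytest.skip("empty draw")
        f = field_from_grid(values)
        curve = superlevel_ec_curve(f, n_levels=40)
        for t, v in zip(curve.thresholds, curve.values):
            level_set = np.zeros_like(values, dtype=bool)
            level_set[f.rows[f.values >= t], f.cols[f.values >= t]] = True
            assert euler_characteristic(level_set) == v

    @pytest.mark.parametrize("seed", range(4))
    def test_superlevel_sets_are_nested(self, seed):
        rng = np.random.default_rng(100 + seed)
        values = np.where(rng.random((20, 20)) < 0.6, rng.random((20, 20)), 0.0)
        f = field_from_grid(values)
        curve = superlevel_ec_curve(f, n_levels=25)
        previous = None
        for t in curve.thresholds:
            current = f.values >= t
            if previous is not None:
                assert np.all(current[previous])  # supersets as threshold drops
            previous = current

    def test_constant_field_repeats_full_support_ec(self):
        values = np.zeros((4, 4))
        values[1:3, 1:3] = 0.7
        curve = superlevel_ec_curve(field_from_grid(values), n_levels=10)
        assert np.all(curve.values == 1)

    def test_empty_field_is_all_zero(self):
        mask = RasterMask(grid=np.ones((3, 3), bool), origin=(0, 0), pixel_size=1.0)
        empty = DensityField(
            rows=np.array([], int),
            cols=np.array([], int),
            values=np.array([]),
            mask=mask,
            h=1.0,
        )
        curve = superlevel_ec_curve(empty, n_levels=12)
        assert np.all(curve.values == 0)

    def test_single_level_rejected(self):
        values = np.ones((2, 2))
        with pytest.raises(ConfigurationError):
            superlevel_ec_curve(field_from_grid(values), n_levels=1)


class TestPHDescriptor:
    def test_descriptor_layout(self, circle_factory, small_params):
        d = ph_descriptor(circle_factory(n=200), small_params)
        assert d.vector.shape == (small_params.n_annuli * small_params.n_levels,)

    def test_inner_annuli_of_circle_are_zero_blocks(self, circle_factory, small_params):
        d = ph_descriptor(circle_factory(n=200), small_params)
        n = small_params.n_levels
        blocks = d.vector.reshape(small_params.n_annuli, n)
        # a unit circle's outline lives at radius 1: only outer rings see it
        assert np.all(blocks[0] == 0)
        assert np.any(blocks[-1] != 0)

    def test_translation_invariance(self, small_params):
        from phyllo import LeafParams, generate_blade

        # asymmetric leaf: no symmetry-induced density ties at the curve ends
        leaf = generate_blade(LeafParams(lobe_count=3, lobe_depth=0.3, noise_sd=0.002))
        moved = Contour(points=leaf.points + np.array([13.0, -7.0]))
        d0 = ph_descriptor(leaf, small_params)
        d1 = ph_descriptor(moved, small_params)
        norm0 = normalize_contour(leaf, small_params.n_resample)
        norm1 = normalize_contour(moved, small_params.n_resample)
        np.testing.assert_allclose(norm1.points, norm0.points, atol=1e-12)
        np.testing.assert_array_equal(d0.vector, d1.vector)

    def test_quarter_turn_invariance(self, small_params):
        from phyllo import LeafParams, generate_blade

        leaf = generate_blade(LeafParams(lobe_count=5, lobe_depth=0.4))
        d0 = ph_descriptor(leaf, small_params).vector
        d90 = ph_descriptor(
            Contour(points=rotate(leaf.points, 90.0)), small_params
        ).vector
        rel = np.linalg.norm(d90 - d0) / np.linalg.norm(d0)
        assert rel <= 0.05

    def test_field_domain_matches_floodfill_at_curve_ends(self, circle_factory):
        from phyllo.ph_descriptor import grid_density

        params = PHParams(
            h=0.05, resolution=64, n_resample=200, n_annuli=4, n_levels=20,
            filtration_domain="field",
        )
        c = circle_factory(n=100)
        d = ph_descriptor(c, params)
        assert d.vector.shape == (80,)
        # final entry of each annulus block equals the EC of that localized
        # support computed by the flood-fill oracle
        norm = normalize_contour(c, n_resample=params.n_resample)
        mask = rasterize_contour(norm, resolution=params.resolution)
        field = grid_density(mask, norm.points, params.h)
        blocks = d.vector.reshape(params.n_annuli, params.n_levels)
        for i, annulus in enumerate(make_annuli(params.n_annuli)):
            local = localized_density(field, annulus)
            support = np.zeros(mask.grid.shape, dtype=bool)
            support[local.rows, local.cols] = True
            assert blocks[i, -1] == euler_characteristic(support)
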