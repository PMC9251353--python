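"""Stereogram synthesis: masks, disparity encoding, stimulus items."""

import numpy as np
import pytest

from rdstereo import blockmatch as bm
from rdstereo import rds
from rdstereo.geometry import extent_to_visual_angle, quantize_disparity


def _angular_for_px(px, geom):
    """Angular size whose rasterized extent is the given pixel count."""
    return extent_to_visual_angle(px * geom.pixel_pitch_mm, geom.viewing_distance_mm)


class TestShapeMasks:
    def test_circle_area_matches_analytic(self, small_geometry):
        spec = rds.ShapeSpec("circle", angular_size_deg=1.5)
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        r_px = (
            rds.visual_angle_to_extent(1.5, small_geometry.viewing_distance_mm)
            / small_geometry.pixel_pitch_mm
            / 2
        )
        assert mask.sum() == pytest.approx(np.pi * r_px**2, rel=0.02)

    def test_square_pixel_count_exact(self, small_geometry):
        spec = rds.ShapeSpec("square", angular_size_deg=_angular_for_px(100, small_geometry))
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        assert mask.sum() == 100 * 100

    def test_empty_mask_raises(self, small_geometry):
        spec = rds.ShapeSpec("circle", angular_size_deg=1e-5)
        with pytest.raises(rds.EmptyMaskError):
            rds.make_shape_mask(spec, small_geometry, (960, 540))

    def test_unknown_shape_rejected(self):
        with pytest.raises(rds.CatalogueError):
            rds.ShapeSpec("hexagon")

    @pytest.mark.parametrize("shape_id", rds.GEOMETRIC_SHAPES + ("A", "K", "Q", "4", "8"))
    def test_catalogue_shapes_rasterize_nonempty(self, shape_id, small_geometry):
        spec = rds.ShapeSpec(shape_id, angular_size_deg=1.0)
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        assert mask.any()
        # roughly centred
        ys, xs = np.nonzero(mask)
        assert abs(xs.mean() - 480) < 30 and abs(ys.mean() - 270) < 30

    def test_oversized_shape_rejected(self, small_geometry):
        spec = rds.ShapeSpec("square", angular_size_deg=4.0)
        with pytest.raises(rds.GeometryError):
            rds.make_shape_mask(spec, small_geometry, (960, 540))


@pytest.fixture()
def circle_pair(small_geometry, small_params):
    spec = rds.ShapeSpec("circle", angular_size_deg=1.5)
    mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
    disp = quantize_disparity(800.0, small_geometry)
    return rds.generate_rds(mask, disp, small_params, shape=spec), mask, disp


class TestGenerateRDS:
    def test_zero_disparity_identity(self, small_geometry, small_params):
        spec = rds.ShapeSpec("square", angular_size_deg=1.0)
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        disp = quantize_disparity(0.0, small_geometry)
        pair = rds.generate_rds(mask, disp, small_params)
        assert np.array_equal(pair.left, pair.right)

    def test_seed_determinism(self, circle_pair, small_geometry, small_params):
        pair, mask, disp = circle_pair
        again = rds.generate_rds(mask, disp, small_params, shape=pair.shapes[0])
        assert np.array_equal(pair.left, again.left)
        assert np.array_equal(pair.right, again.right)

    def test_block_matching_recovers_shift(self, circle_pair):
        pair, _, disp = circle_pair
        recovered = bm.verify_pair(pair, n_blocks=10, seed=3, tol_px=1)
        assert set(recovered) == {0.0, float(disp.shift_px_applied)}

    def test_density_conserved(self, circle_pair, small_params):
        pair, _, _ = circle_pair
        for img in (pair.left, pair.right):
            density = (img == small_params.foreground).mean()
            assert density == pytest.approx(small_params.dot_density, abs=0.01)

    def test_no_monocular_density_cue(self, small_geometry, small_params):
        """Mask vs background dot density in one eye stays within binomial noise.

        The independence unit is the dot cell (dot_size^2 pixels), so the
        binomial sigma uses cell counts; the pooled standardized difference
        over the seeds should behave like a standard normal mean.
        """
        spec = rds.ShapeSpec("circle", angular_size_deg=1.5)
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        disp = quantize_disparity(800.0, small_geometry)
        rho, ds = small_params.dot_density, small_params.dot_size
        n_in = mask.sum() / ds**2
        n_out = (~mask).sum() / ds**2
        sigma = np.sqrt(rho * (1 - rho) * (1 / n_in + 1 / n_out))
        zs = []
        for seed in range(20):
            p = rds.generate_rds(
                mask, disp, rds.RDSParams(canvas_px=(960, 540), seed=seed)
            )
            for img in (p.left, p.right):
                bright = img == small_params.foreground
                zs.append((bright[mask].mean() - bright[~mask].mean()) / sigma)
        zs = np.array(zs)
        assert abs(zs.mean()) < 3 / np.sqrt(len(zs))
        assert np.abs(zs).max() < 4.5

    def test_shift_off_canvas_rejected(self, small_geometry, small_params):
        spec = rds.ShapeSpec("square", angular_size_deg=0.5, center=(0.08, 0.5))
        mask = rds.make_shape_mask(spec, small_geometry, (960, 540))
        disp = quantize_disparity(2400.0, small_geometry)
        with pytest.raises(rds.GeometryError):
            rds.generate_rds(mask, disp, small_params)


class TestScreeningItem:
    def test_metadata_lists_three_requested_levels(self, small_geometry, small_params):
        pair = rds.generate_screening_item(small_geometry, small_params)
        assert [d.disparity_arcsec for d in pair.disparities] == [800.0, 1600.0, 2400.0]
        assert [s.shape_id for s in pair.shapes] == ["circle", "square", "pentagon"]

    def test_three_distinct_recovered_zones(self, small_geometry, small_params):
        pair = rds.generate_screening_item(small_geometry, small_params)
        recovered = bm.verify_pair(pair, n_blocks=6, seed=4, tol_px=1)
        shifts = sorted(v for v in recovered if v > 0)
        assert len(shifts) == 3
        assert shifts == sorted(float(d.shift_px_applied) for d in pair.disparities)

    def test_zero_levels_give_identical_images(self, small_geometry, small_params):
        pair = rds.generate_screening_item(
            small_geometry, small_params, levels_arcsec=(0.0, 1.0, 2.0)
        )
        # the three shifts all quantize to zero pixels on this grid
        assert all(d.shift_px_applied == 0 for d in pair.disparities)
        assert np.array_equal(pair.left, pair.right)

    def test_non_nested_sizes_rejected(self, small_geometry, small_params):
        with pytest.raises(rds.LayoutError):
            rds.generate_screening_item(
                small_geometry, small_params, sizes_deg=(1.0, 1.9, 2.8)
            )


class TestTeachingItem:
    def test_circle_diameters_match_physical_size(self, small_geometry, small_params):
        pair = rds.generate_teaching_item(small_geometry, small_params)
        d_px = round(150.0 / small_geometry.pixel_pitch_mm)
        for shape in pair.shapes:
            extent = rds.visual_angle_to_extent(
                shape.angular_size_deg, small_geometry.viewing_distance_mm
            )
            assert round(extent / small_geometry.pixel_pitch_mm) == d_px

    def test_contour_half_identical_across_eyes(self, small_geometry, small_params):
        pair = rds.generate_teaching_item(small_geometry, small_params)
        width = pair.left.shape[1]
        assert np.array_equal(pair.left[:, width // 2 :], pair.right[:, width // 2 :])

    def test_rds_circle_recovers_at_applied_shift(self, small_geometry, small_params):
        pair = rds.generate_teaching_item(small_geometry, small_params)
        recovered = bm.verify_pair(pair, n_blocks=8, seed=5, tol_px=1)
        assert float(pair.disparities[0].shift_px_applied) in recovered

    def test_canvas_too_small_rejected(self, small_geometry, small_params):
        from dataclasses import replace

        params = replace(small_params, canvas_px=(400, 200))
        with pytest.raises(rds.GeometryError):
            rds.generate_teaching_item(small_geometry, params)


class TestLevelBank:
    def test_ten_distinct_shapes_at_level(self, small_geometry, small_params):
        bank = rds.build_level_bank(400.0, small_geometry, small_params, seed=9)
        assert len(bank) == 10
        ids = [p.shapes[0].shape_id for p in bank]
        assert len(set(ids)) == 10
        assert all(p.disparities[0].disparity_arcsec == 400.0 for p in bank)

    def test_seed_changes_order_not_set(self, small_geometry, small_params):
        bank_a = rds.build_level_bank(800.0, small_geometry, small_params, seed=1)
        bank_b = rds.build_level_bank(800.0, small_geometry, small_params, seed=2)
        ids_a = [p.shapes[0].shape_id for p in bank_a]
        ids_b = [p.shapes[0].shape_id for p in bank_b]
        assert set(ids_a) == set(ids_b)
        assert ids_a != ids_b

    def test_bank_deterministic_under_seed(self, small_geometry, small_params):
        bank_a = rds.build_level_bank(800.0, small_geometry, small_params, seed=1)
        bank_b = rds.build_level_bank(800.0, small_geometry, small_params, seed=1)
        assert [p.shapes[0].shape_id for p in bank_a] == [p.shapes[0].shape_id for p in bank_b]
        assert np.array_equal(bank_a[0].left, bank_b[0].left)

    def test_short_catalogue_rejected(self, small_geometry, small_params):
        with pytest.raises(rds.CatalogueError):
            rds.build_level_bank(
                800.0, small_geometry, small_params, seed=1, bank_shapes=("circle", "A")
            )

    def test_metadata_regenerates_pair(self, small_geometry, small_params):
        bank = rds.build_level_bank(800.0, small_geometry, small_params, seed=3)
        pair = bank[4]
        meta = pair.metadata()
        from dataclasses import replace

        params = replace(small_params, seed=meta["seed"])
        mask = rds.make_shape_mask(pair.shapes[0], small_geometry, (960, 540))
        disp = quantize_disparity(
            meta["disparities"][0]["requested_arcsec"], small_geometry
        )
        again = rds.generate_rds(mask, disp, params)
        assert np.array_equal(pair.left, again.left)
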