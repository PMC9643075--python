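"""Image-trait extraction: volume, lightness, wing geometry, residuals."""

import numpy as np
import pytest

import phylorisk as pr
from oracles import ols_residuals_normal_equations, proximal_by_sorting


@pytest.mark.parametrize("dpi,expected", [
    (1200, 2.54 / 1200),
    (2.54, 1.0),
    (300, 2.54 / 300),
])
def test_pixel_edge_cm(dpi, expected):
    assert pr.pixel_edge_cm(dpi) == pytest.approx(expected, abs=1e-15)


def test_pixel_edge_rejects_nonpositive_dpi():
    with pytest.raises(ValueError):
        pr.pixel_edge_cm(0)


class TestBodyVolume:
    def test_rectangle_closed_form(self):
        # 10 px wide, 100 rows, s = 0.01 cm: V = 100·π·0.05²·0.01
        mask = np.zeros((100, 20), dtype=bool)
        mask[:, 5:15] = True
        v = pr.body_volume(mask, dpi=2.54 / 0.01)
        assert v == pytest.approx(np.pi * 2.5e-3, rel=1e-12)

    def test_single_pixel(self):
        mask = np.ones((1, 1), dtype=bool)
        assert pr.body_volume(mask, dpi=2.54) == pytest.approx(np.pi / 4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            pr.body_volume(np.zeros((5, 5), dtype=bool), 300)

    def test_scaling_with_pixel_size(self):
        # exact 2× downsampling of a rectangle: area <2%, volume <4% off
        mask = np.zeros((200, 60), dtype=bool)
        mask[:, 10:50] = True
        small = mask[::2, ::2]
        a1 = pr.wing_area(mask, 1200)
        a2 = pr.wing_area(small, 600)
        v1 = pr.body_volume(mask, 1200)
        v2 = pr.body_volume(small, 600)
        assert abs(a2 - a1) / a1 < 0.02
        assert abs(v2 - v1) / v1 < 0.04


class TestColorLightness:
    @pytest.mark.parametrize("gray,expected", [(0, 0.0), (255, 255.0)])
    def test_constant_images(self, gray, expected):
        px = np.full((10, 10, 3), gray, dtype=np.uint8)
        mask = np.ones((10, 10), dtype=bool)
        assert pr.color_lightness(px, mask, include_wings=False) == expected

    def test_half_black_half_white_is_exactly_midgray(self):
        px = np.zeros((10, 10, 3), dtype=np.uint8)
        px[5:] = 255
        mask = np.ones((10, 10), dtype=bool)
        assert pr.color_lightness(px, mask, include_wings=False) == 127.5

    def test_invariant_to_pixel_permutation(self, rng):
        px = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        mask = np.ones((8, 8), dtype=bool)
        val = pr.color_lightness(px, mask, include_wings=False)
        perm = rng.permutation(64)
        shuffled = px.reshape(64, 3)[perm].reshape(8, 8, 3)
        assert pr.color_lightness(shuffled, mask,
                                  include_wings=False) == val

    def test_empty_selection_rejected(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            pr.color_lightness(px, np.zeros((4, 4), dtype=bool),
                               include_wings=False)


class TestProximalWingRegion:
    def test_fraction_one_is_identity(self):
        wing = np.zeros((10, 40), dtype=bool)
        wing[:, 10:] = True
        body = np.zeros((10, 40), dtype=bool)
        body[:, :5] = True
        out = pr.proximal_wing_region(wing, body, 1.0)
        assert (out == wing).all()

    def test_horizontal_strip_keeps_nearest_columns(self):
        # a 30-column strip abutting the body: 1/3 keeps the 10 nearest
        body = np.zeros((5, 40), dtype=bool)
        body[:, :10] = True
        wing = np.zeros((5, 40), dtype=bool)
        wing[:, 10:40] = True
        out = pr.proximal_wing_region(wing, body, 1.0 / 3.0)
        expected = np.zeros_like(wing)
        expected[:, 10:20] = True
        assert (out == expected).all()

    def test_symmetric_wings_get_equal_counts(self):
        body = np.zeros((9, 21), dtype=bool)
        body[:, 9:12] = True
        wing = np.zeros((9, 21), dtype=bool)
        wing[2:7, 0:7] = True
        wing[2:7, 14:21] = True
        out = pr.proximal_wing_region(wing, body, 1.0 / 3.0)
        left = out[:, :10].sum()
        right = out[:, 11:].sum()
        assert abs(int(left) - int(right)) <= 1

    def test_matches_bruteforce_distance_sort(self, rng):
        body = np.zeros((20, 20), dtype=bool)
        body[8:12, 8:12] = True
        wing = rng.random((20, 20)) < 0.35
        wing &= ~body
        out = pr.proximal_wing_region(wing, body, 0.4)
        expected = proximal_by_sorting(wing, body, 0.4)
        assert (out == expected).all()

    def test_empty_wing_mask_gives_empty_region(self):
        body = np.ones((3, 3), dtype=bool)
        out = pr.proximal_wing_region(np.zeros((3, 3), dtype=bool),
                                      body, 0.5)
        assert not out.any()


class TestWingArea:
    def test_pixel_count_times_pixel_area(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[:100, :100] = True
        assert pr.wing_area(mask, 2.54 / 0.01) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self):
        assert pr.wing_area(np.zeros((5, 5), dtype=bool), 300) == 0.0

    def test_rendered_polygon_matches_shoelace_within_one_percent(self):
        poly = [(0.05, 0.05), (1.3, 0.2), (1.1, 1.4), (0.2, 1.0)]
        spec = pr.SpecimenSpec(body_length_cm=0.1, body_width_cm=0.02,
                               wing_polygons=[poly], dpi=300)
        img, truth = pr.render_specimen_image(spec)
        assert img.wing_mask.sum() >= 10_000
        est = pr.wing_area(img.wing_mask, img.dpi)
        assert abs(est - truth["wing_area_cm2"]) \
            < 0.01 * truth["wing_area_cm2"]


class TestResidualWingArea:
    def test_power_law_gives_zero_residuals(self, rng):
        v = rng.uniform(0.5, 2.0, size=30)
        a = 3.0 * v ** 0.63
        res = pr.residual_wing_area(a, v)
        assert np.max(np.abs(res)) < 1e-10

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            pr.residual_wing_area([1.0, 2.0], [1.0, 2.0])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pr.residual_wing_area([1.0, -1.0, 2.0], [1.0, 2.0, 3.0])

    def test_constant_volume_rejected_as_singular(self):
        with pytest.raises(ValueError):
            pr.residual_wing_area([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])

    def test_matches_normal_equations_oracle(self, rng):
        v = rng.uniform(0.2, 3.0, size=100)
        a = np.exp(0.4 + 0.7 * np.log(v) + rng.normal(0, 0.2, size=100))
        res = pr.residual_wing_area(a, v)
        expected = ols_residuals_normal_equations(np.log(v), np.log(a))
        assert np.max(np.abs(res - expected)) < 1e-8
        assert abs(res.sum()) < 1e-10

    def test_invariant_to_volume_rescaling(self, rng):
        v = rng.uniform(0.2, 3.0, size=50)
        a = np.exp(0.3 * np.log(v) + rng.normal(0, 0.1, size=50))
        r1 = pr.residual_wing_area(a, v)
        r2 = pr.residual_wing_area(a, 100.0 * v)
        assert np.allclose(r1, r2, atol=1e-10)


def test_morphometric_table_on_synthetic_specimens():
    imgs, truth = pr.simulate_specimens([f"s{i}" for i in range(5)],
                                        seed=9, dpi=300)
    table = pr.morphometric_table(imgs)
    assert list(table.columns) == ["body_volume_cm3", "color_lightness",
                                   "wing_area_cm2", "residual_wing_area"]
    rel = np.abs(table["body_volume_cm3"] - truth["body_volume_cm3"]) \
        / truth["body_volume_cm3"]
    # at 300 dpi the narrowest bodies are ~9 px wide, so rounding the
    # width to whole pixels can move the squared diameter by ~(1±1/18)²
    assert rel.max() < 0.12
    assert abs(table["residual_wing_area"].sum()) < 1e-10
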