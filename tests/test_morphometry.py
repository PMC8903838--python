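"""Shoelace areas, brightness, spine density and mask topology."""

import numpy as np
import pytest
from skimage.draw import polygon as raster_polygon
from skimage.measure import euler_number

from synmorph.data_model import DendriteRecord, ValidationError
from synmorph.morphometry import (
    GeometryError,
    MorphClass,
    NanopatternMask,
    PolygonROI,
    classify_nanopattern,
    polygon_area,
    roi_brightness,
    spine_density,
    tabulate_morphometry,
)
from synmorph.synthetic import generate_nanopattern_mask


def square(side, x0=0.0, y0=0.0):
    return ((x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side))


class TestPolygonArea:
    def test_square_at_30nm(self):
        # 100 px² × (0.03 µm)² = 0.09 µm²
        roi = PolygonROI(square(10), pixel_size_nm=30)
        assert polygon_area(roi) == pytest.approx(0.09)

    def test_right_triangle(self):
        roi = PolygonROI(((0, 0), (4, 0), (0, 3)), pixel_size_nm=30)
        assert polygon_area(roi) == pytest.approx(6 * 0.0009)

    def test_orientation_and_rigid_motion_invariance(self):
        verts = ((0, 0), (7, 1), (9, 6), (4, 9), (-1, 5))
        base = polygon_area(PolygonROI(verts))
        assert polygon_area(PolygonROI(tuple(reversed(verts)))) == pytest.approx(base)
        shifted = tuple((x + 11.5, y - 3.25) for x, y in verts)
        assert polygon_area(PolygonROI(shifted)) == pytest.approx(base)
        rotated = tuple((-y, x) for x, y in verts)  # 90 degrees
        assert polygon_area(PolygonROI(rotated)) == pytest.approx(base)

    def test_matches_rasterization_within_perimeter_bound(self):
        verts = ((0, 0), (20, 3), (25, 18), (12, 27), (2, 15))
        roi = PolygonROI(verts, pixel_size_nm=1000)  # 1 µm/px: area in px²
        shoelace_px2 = polygon_area(roi)
        rr, cc = raster_polygon([v[1] for v in verts], [v[0] for v in verts])
        raster_px2 = len(rr)
        perimeter = sum(
            np.hypot(x2 - x1, y2 - y1)
            for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1])
        )
        assert abs(shoelace_px2 - raster_px2) <= perimeter

    def test_too_few_vertices(self):
        with pytest.raises(GeometryError):
            PolygonROI(((0, 0), (1, 1)))

    def test_self_intersection(self):
        with pytest.raises(GeometryError):
            PolygonROI(((0, 0), (2, 2), (2, 0), (0, 2)))  # bow-tie


class TestBrightness:
    def test_small_grid_sum(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = NanopatternMask(np.ones((2, 2), dtype=bool))
        assert roi_brightness(img, mask) == 10.0

    def test_zero_image(self):
        mask = NanopatternMask(np.ones((3, 3), dtype=bool))
        assert roi_brightness(np.zeros((3, 3)), mask) == 0.0

    def test_matches_loop_sum_oracle(self, rng):
        img = rng.uniform(0, 100, size=(16, 16))
        grid = np.zeros((16, 16), dtype=bool)
        grid[:8, :] = True
        mask = NanopatternMask(grid)
        oracle = sum(
            img[i, j] for i in range(16) for j in range(16) if grid[i, j]
        )
        assert roi_brightness(img, mask) == pytest.approx(oracle, rel=1e-15)

    def test_shape_mismatch(self):
        mask = NanopatternMask(np.ones((2, 2), dtype=bool))
        with pytest.raises(ValidationError):
            roi_brightness(np.zeros((3, 3)), mask)


class TestSpineDensity:
    def test_five_spines_over_8um(self):
        d = DendriteRecord("d", (0.0, 2.0, 4.0, 6.0, 8.0))
        assert spine_density(d) == pytest.approx(0.5)

    def test_two_spines_1um_apart(self):
        assert spine_density(DendriteRecord("d", (3.0, 4.0))) == pytest.approx(1.0)

    def test_single_spine_undefined(self):
        with pytest.raises(ValidationError):
            spine_density(DendriteRecord("d", (1.0,)))

    def test_zero_span_degenerate(self):
        with pytest.raises(GeometryError):
            spine_density(DendriteRecord("d", (2.0, 2.0)))


def disc_mask(r=10, pad=4):
    n = 2 * (r + pad) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = r + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


class TestClassification:
    def test_filled_disc_is_macular(self):
        res = classify_nanopattern(NanopatternMask(disc_mask()))
        assert (res.category, res.n_components, res.n_holes) == ("macular", 1, 0)

    def test_annulus_is_perforated(self):
        grid = disc_mask(10) & ~disc_mask(4, pad=10)
        res = classify_nanopattern(NanopatternMask(grid))
        assert (res.category, res.n_components, res.n_holes) == ("perforated", 1, 1)

    def test_three_discs_are_clustered(self):
        small = disc_mask(3, pad=1)
        n = small.shape[0]
        grid = np.zeros((n, 3 * n + 4), dtype=bool)
        for k in range(3):
            grid[:, k * (n + 2) : k * (n + 2) + n] |= small
        res = classify_nanopattern(NanopatternMask(grid))
        assert (res.category, res.n_components) == ("clustered", 3)

    def test_diagonal_ring_keeps_its_hole(self):
        # foreground touching only diagonally must stay one component and
        # must not leak the enclosed hole (8/4 duality)
        grid = np.array(
            [
                [0, 1, 0],
                [1, 0, 1],
                [0, 1, 0],
            ],
            dtype=bool,
        )
        res = classify_nanopattern(NanopatternMask(grid))
        assert res.n_components == 1 and res.n_holes == 1

    def test_translation_and_rotation_invariance(self):
        grid = disc_mask(6) & ~disc_mask(2, pad=8)
        base = classify_nanopattern(NanopatternMask(grid))
        padded = np.zeros((grid.shape[0] + 10, grid.shape[1] + 6), dtype=bool)
        padded[7 : 7 + grid.shape[0], 2 : 2 + grid.shape[1]] = grid
        moved = classify_nanopattern(NanopatternMask(padded))
        rotated = classify_nanopattern(NanopatternMask(np.rot90(grid)))
        for other in (moved, rotated):
            assert (other.category, other.n_components, other.n_holes) == (
                base.category, base.n_components, base.n_holes,
            )

    def test_euler_consistency_on_random_masks(self, rng):
        # components − holes must match the integral-geometry Euler number
        for _ in range(60):
            grid = rng.random((12, 12)) < 0.45
            if not grid.any():
                continue
            res = classify_nanopattern(NanopatternMask(grid))
            assert res.n_components - res.n_holes == euler_number(
                grid, connectivity=2
            )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            NanopatternMask(np.zeros((4, 4), dtype=bool))

    def test_concavity_rescue_promotes_horseshoe(self):
        grid = disc_mask(10) & ~disc_mask(5, pad=9)
        grid[14:, 12:18] = False  # open the ring into a horseshoe
        strict = classify_nanopattern(NanopatternMask(grid))
        rescued = classify_nanopattern(NanopatternMask(grid), concavity_rescue=True)
        assert strict.category == "macular"
        assert rescued.category == "perforated" and rescued.concavity_rescued


class TestTabulation:
    def test_simple_frequencies(self):
        classes = [
            MorphClass("perforated", 1, 1),
            MorphClass("perforated", 1, 2),
            MorphClass("clustered", 2, 0),
        ]
        table = tabulate_morphometry(classes).set_index("category")
        assert table.loc["perforated", "frequency"] == pytest.approx(2 / 3)
        assert table.loc["clustered-2", "frequency"] == pytest.approx(1 / 3)

    def test_empty_input_gives_empty_table(self):
        assert tabulate_morphometry([]).empty

    def test_known_mixture_recovered(self):
        # 60/25/15 macular/perforated/clustered, n = 400: binomial SE < 0.025
        classes = []
        for i in range(240):
            classes.append(classify_nanopattern(
                generate_nanopattern_mask("macular", seed=i)))
        for i in range(100):
            classes.append(classify_nanopattern(
                generate_nanopattern_mask("perforated", seed=1000 + i)))
        for i in range(60):
            classes.append(classify_nanopattern(
                generate_nanopattern_mask("clustered", n_clusters=2, seed=2000 + i)))
        table = tabulate_morphometry(classes).set_index("category")
        assert table.loc["macular", "frequency"] == pytest.approx(0.6, abs=0.03)
        assert table.loc["perforated", "frequency"] == pytest.approx(0.25, abs=0.03)
        assert table["frequency"].sum() == pytest.approx(1.0)
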