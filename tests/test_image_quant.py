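"""Calibrated image measurements against pixel-counting and flood-fill oracles."""

from collections import deque

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from organoidqc.image_quant import (
    BinaryMask,
    SectionImage,
    cell_density,
    cellless_fraction,
    count_puncta,
    gfap_fraction,
    positive_control_ratio,
    positive_surface,
    puncta_density,
    quantify_section,
    section_mask,
    threshold_mask,
)


def flood_fill_components(mask):
    """Brute-force 8-connected component count (independent labeling oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    count = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        count += 1
        queue = deque([(sy, sx)])
        seen[sy, sx] = True
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                            and mask[ny, nx] and not seen[ny, nx]):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
    return count


class TestThresholding:
    def test_two_level_image_otsu_recovers_bright_fraction(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((200, 200)) < 0.4, 200.0, 10.0)
        mask = threshold_mask(img, pixel_size=1.0, method="otsu")
        assert positive_surface(mask)[1] == pytest.approx((img == 200).mean())
        assert mask.provenance.startswith("otsu=")

    def test_fixed_threshold_extremes(self):
        img = np.zeros((10, 10))
        assert threshold_mask(img, 1.0, method=1.0).n_pixels == 0
        assert threshold_mask(img, 1.0, method=0.0).n_pixels == 100

    def test_constant_image_auto_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="fixed threshold"):
            threshold_mask(np.full((10, 10), 7.0), 1.0, method="otsu")


class TestAreas:
    def test_positive_surface_calibration(self):
        data = np.zeros((100, 100), bool)
        data[:50, :50] = True  # 2500 in-pixels
        area1, frac1 = positive_surface(BinaryMask(data, pixel_size=1.0))
        assert (area1, frac1) == (2500.0, 0.25)
        area_half, frac_half = positive_surface(BinaryMask(data, pixel_size=0.5))
        assert area_half == pytest.approx(area1 * 0.25)
        assert frac_half == frac1

    def test_cell_density_identities(self):
        # A fully DAPI-positive square millimetre holds 10^6/80 nuclei.
        density, count = cell_density(1.0e6, 1.0)
        assert density == pytest.approx(12_500.0)
        assert count == pytest.approx(12_500.0)
        assert cell_density(0.0, 1.0)[0] == 0.0
        # 40% coverage of a 2 mm^2 section: 0.4e6/80 per mm^2.
        density, count = cell_density(0.4 * 2.0e6, 2.0)
        assert density == pytest.approx(5_000.0)
        assert count == pytest.approx(10_000.0)

    def test_cell_density_is_linear_in_dapi_area(self):
        base = cell_density(1.0e5, 1.0)[0]
        assert cell_density(3.0e5, 1.0)[0] == pytest.approx(3 * base)
        assert base <= 1.0e6 / 80.0

    def test_density_rejects_mask_larger_than_section(self):
        with pytest.raises(ValueError, match="exceeds"):
            cell_density(2.0e6, 1.0)


def _disk_mask(shape, center, radius):
    m = np.zeros(shape, bool)
    rr, cc = draw_disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


class TestCelllessRegions:
    def test_solid_disk_has_no_holes(self):
        tissue = BinaryMask(_disk_mask((256, 256), (128, 128), 100), 1.0)
        assert cellless_fraction(tissue) == 0.0

    def test_single_hole_fraction_matches_pixel_counts(self):
        shape = (256, 256)
        outer = _disk_mask(shape, (128, 128), 100)
        hole = _disk_mask(shape, (128, 128), 20)
        tissue = BinaryMask(outer & ~hole, 1.0)
        expected = 100.0 * (outer & hole).sum() / outer.sum()  # exact oracle
        measured = cellless_fraction(tissue)
        assert measured == pytest.approx(expected)
        assert measured == pytest.approx(4.0, abs=0.1)  # (20/100)^2 analytic

    def test_two_holes_sum(self):
        shape = (256, 256)
        outer = _disk_mask(shape, (128, 128), 100)
        holes = (_disk_mask(shape, (90, 90), 14) | _disk_mask(shape, (170, 160), 14))
        tissue = BinaryMask(outer & ~holes, 1.0)
        expected = 100.0 * holes.sum() / outer.sum()
        assert cellless_fraction(tissue) == pytest.approx(expected)
        assert expected == pytest.approx(2 * (14 / 100) ** 2 * 100, abs=0.2)

    def test_hole_and_tissue_fractions_partition_the_outline(self):
        shape = (256, 256)
        outer = _disk_mask(shape, (128, 128), 90)
        holes = _disk_mask(shape, (110, 130), 25)
        tissue = BinaryMask(outer & ~holes, 1.0)
        tissue_frac = 100.0 * tissue.n_pixels / outer.sum()
        assert tissue_frac + cellless_fraction(tissue) == pytest.approx(100.0)

    def test_empty_tissue_mask_is_an_error(self):
        with pytest.raises(ValueError):
            cellless_fraction(BinaryMask(np.zeros((10, 10), bool), 1.0))


class TestGfap:
    def test_zero_and_full_coverage(self):
        ref = BinaryMask(_disk_mask((128, 128), (64, 64), 40), 1.0)
        empty = BinaryMask(np.zeros((128, 128), bool), 1.0)
        assert gfap_fraction(empty, ref) == 0.0
        assert gfap_fraction(ref, ref) == pytest.approx(100.0)

    def test_zero_reference_is_an_error(self):
        empty = BinaryMask(np.zeros((8, 8), bool), 1.0)
        with pytest.raises(ValueError, match="reference"):
            gfap_fraction(empty, empty)

    def test_calibration_mismatch_rejected(self):
        a = BinaryMask(np.ones((8, 8), bool), 1.0)
        b = BinaryMask(np.ones((8, 8), bool), 0.5)
        with pytest.raises(ValueError, match="calibration"):
            gfap_fraction(a, b)


class TestPuncta:
    def _render(self, mask):
        return np.where(mask, 200.0, 10.0)

    def test_blank_image_has_no_puncta(self):
        img = np.full((64, 64), 10.0)
        assert count_puncta(img, 1.0, threshold=100.0).count == 0

    def test_well_separated_disks_counted_exactly(self):
        # 20 disks of radius 3 um (area ~28.3 um^2 >= 15) on a sparse grid.
        shape = (256, 256)
        mask = np.zeros(shape, bool)
        centers = [(20 + 40 * i, 25 + 45 * j) for i in range(5) for j in range(4)]
        for c in centers:
            mask |= _disk_mask(shape, c, 3)
        puncta = count_puncta(self._render(mask), 1.0, threshold=100.0)
        assert puncta.count == 20
        assert all(p.area_um2 >= 15.0 for p in puncta.puncta)
        assert all(0.0 <= p.circularity <= 1.0 for p in puncta.puncta)

    def test_size_filter_removes_small_objects(self):
        # Radius-2 um disks (~12.6 um^2) all fall below the 15 um^2 cutoff.
        shape = (256, 256)
        mask = np.zeros(shape, bool)
        for i in range(3):
            for j in range(5):
                mask |= _disk_mask(shape, (30 + 50 * i, 20 + 45 * j), 2)
        assert count_puncta(self._render(mask), 1.0, threshold=100.0).count == 0

    def test_physical_area_filter_depends_on_pixel_size(self):
        # The same raster disk passes at 2 um/px and fails at 0.5 um/px.
        mask = _disk_mask((64, 64), (32, 32), 3)
        img = self._render(mask)
        assert count_puncta(img, 2.0, threshold=100.0).count == 1
        assert count_puncta(img, 0.5, threshold=100.0).count == 0

    def test_circularity_filter_rejects_lines(self):
        mask = np.zeros((64, 64), bool)
        mask[32, 5:60] = True  # 1-px line: circularity far below a disk's
        img = self._render(mask)
        assert count_puncta(img, 1.0, min_area_um2=10.0, threshold=100.0,
                            circ_range=(0.5, 1.0)).count == 0
        assert count_puncta(img, 1.0, min_area_um2=10.0, threshold=100.0).count == 1

    def test_missing_pixel_size_is_an_error(self):
        with pytest.raises(ValueError, match="pixel_size"):
            count_puncta(np.zeros((8, 8)), None)

    def test_labeling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            mask = rng.random((96, 96)) < 0.25
            puncta = count_puncta(np.where(mask, 200.0, 10.0), 1.0,
                                  min_area_um2=0.0, threshold=100.0)
            assert puncta.count == flood_fill_components(mask)

    def test_puncta_density_arithmetic(self):
        per_um2, per_mm2 = puncta_density(50, 0.5e6)  # 50 foci over 0.5 mm^2
        assert per_mm2 == pytest.approx(100.0)
        assert per_um2 == pytest.approx(1.0e-4)
        assert puncta_density(50, 1.0e6)[1] == pytest.approx(per_mm2 / 2)
        assert puncta_density(0, 1.0)[0] == 0.0
        with pytest.raises(ValueError):
            puncta_density(1, 0.0)


class TestPositiveControlRatio:
    def test_hand_computed_example(self):
        # Controls {8, 12}: mean 10, sample sd 2sqrt(2); value 4 sits 2.12 sd below.
        assert positive_control_ratio(4.0, [8.0, 12.0]) == pytest.approx(2.1213, abs=1e-4)

    def test_value_at_control_mean_is_zero(self):
        assert positive_control_ratio(10.0, [8.0, 12.0]) == 0.0

    def test_value_above_controls_is_negative(self):
        assert positive_control_ratio(13.0, [8.0, 12.0]) < 0.0

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError):
            positive_control_ratio(1.0, [5.0])
        with pytest.raises(ValueError):
            positive_control_ratio(1.0, [5.0, 5.0])


class TestQuantifySection:
    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            SectionImage({"dapi": np.zeros((8, 8)), "gfap": np.zeros((4, 4))}, 1.0)

    def test_full_pipeline_on_a_painted_section(self):
        shape = (256, 256)
        outer = _disk_mask(shape, (128, 128), 100)
        nuclei = _disk_mask(shape, (100, 100), 30) | _disk_mask(shape, (150, 140), 30)
        dapi = np.where(nuclei, 200.0, np.where(outer, 60.0, 10.0))
        image = SectionImage({"dapi": dapi}, pixel_size=1.0, organoid_id="o1")
        results = {r.metric: r.value for r in
                   quantify_section(image, dapi_threshold=100.0, tissue_threshold=40.0)}
        assert results["section_area"] == pytest.approx(outer.sum())
        assert results["dapi_area"] == pytest.approx(nuclei.sum())
        assert results["cell_density"] == pytest.approx(
            (nuclei.sum() / 80.0) / (outer.sum() / 1e6))
        assert results["cellless_fraction"] == 0.0
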