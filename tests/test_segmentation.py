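"""Segmentation tests: region finding, geometry, newborn filter, intensity route."""

import numpy as np
import pytest

from halocount.segmentation import (
    CellRegion,
    filter_newborn,
    mean_intensity_per_area,
    region_properties,
    segment_by_intensity,
    segment_cells,
)
from halocount.simgen import (
    OpticsConfig,
    Spherocylinder,
    footprint_mask,
    render_autofluorescence,
    sample_cell_geometries,
)
from conftest import match_region_to_cell

PX = 0.16


def _fake_region(length_um, cell_id=0):
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    return CellRegion(cell_id=cell_id, mask=mask, centroid=(2.0, 2.0), area=1,
                      perimeter=0.0, length_um=length_um, width_um=0.5)


class TestSegmentCells:
    def test_blank_noise_yields_no_regions(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 5.0, size=(128, 128))
        assert segment_cells(img, PX) == []

    def test_constant_image_yields_no_regions(self):
        assert segment_cells(np.full((64, 64), 7.0), PX) == []

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            segment_cells(np.zeros((4, 4, 4)), PX)

    def test_five_cells_recovered_with_accurate_centroids(self, five_cell_field):
        cells, _, _, autofluo = five_cell_field
        regions = segment_cells(autofluo, PX)
        assert len(regions) == 5
        for r in regions:
            c = cells[match_region_to_cell(r, cells, PX)]
            expected = (c.center[1] / PX, c.center[0] / PX)
            assert np.hypot(r.centroid[0] - expected[0],
                            r.centroid[1] - expected[1]) <= 2.0

    def test_regions_disjoint_and_above_min_area(self, five_cell_field):
        _, _, _, autofluo = five_cell_field
        regions = segment_cells(autofluo, PX, min_area=50)
        total = np.zeros_like(regions[0].mask, dtype=int)
        for r in regions:
            assert r.area >= 50
            total += r.mask
        assert total.max() <= 1

    def test_border_touching_cell_removed(self):
        opt = OpticsConfig()
        inner = Spherocylinder(2.0, 0.5, (8.0, 8.0), 0.5)
        clipped = Spherocylinder(2.0, 0.5, (1.2, 8.0), 0.0)  # pole beyond x=0
        img = render_autofluorescence([inner, clipped], opt, 0, field_size=(16.0, 16.0))
        regions, dropped = segment_cells(img, PX, return_dropped=True)
        assert len(regions) == 1
        assert any(d["reason"] == "border" for d in dropped)

    def test_perfect_recall_and_precision_on_sparse_fields(self):
        """High-contrast, well-gapped fields: every cell found, nothing else."""
        opt = OpticsConfig()
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            cells = sample_cell_geometries(
                4, field_size=(24.0, 24.0), rng_seed=rng, min_gap=1.6
            )
            img = render_autofluorescence(cells, opt, rng, field_size=(24.0, 24.0))
            regions = segment_cells(img, PX)
            assert len(regions) == len(cells)
            matched = {match_region_to_cell(r, cells, PX) for r in regions}
            assert matched == set(range(len(cells)))

    def test_exclusion_list_drops_named_label(self, five_cell_field):
        _, _, _, autofluo = five_cell_field
        baseline = segment_cells(autofluo, PX)
        excl = segment_cells(autofluo, PX, exclusions=[1])
        assert len(excl) == len(baseline) - 1


class TestRegionProperties:
    def test_solid_square(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        r = region_properties(mask, pixel_size=0.1)
        assert r.area == 100
        assert r.length_um == pytest.approx(1.0)
        assert r.width_um == pytest.approx(1.0)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        r = region_properties(mask, pixel_size=0.1)
        assert r.area == 1
        assert r.length_um == pytest.approx(0.1)
        assert r.width_um == pytest.approx(0.1)
        assert r.perimeter == 0.0  # scikit-image convention for one pixel

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_properties(np.zeros((4, 4), bool), 0.1)

    def test_spherocylinder_mask_length(self):
        cell = Spherocylinder(2.0, 0.5, (5.0, 5.0), 0.6)  # total length 3.0
        mask = footprint_mask([cell], (63, 63), PX)
        r = region_properties(mask, PX)
        assert abs(r.length_um - 3.0) / 3.0 < 0.10
        assert abs(r.width_um - 1.0) / 1.0 < 0.15

    def test_rotation_and_translation_invariance(self):
        cell = Spherocylinder(1.6, 0.4, (4.0, 3.0), 0.3)
        mask = footprint_mask([cell], (50, 50), PX)
        r = region_properties(mask, PX)
        rot = region_properties(np.rot90(mask), PX)
        assert rot.length_um == pytest.approx(r.length_um, abs=1e-9)
        assert rot.width_um == pytest.approx(r.width_um, abs=1e-9)
        shifted = np.roll(mask, (3, 4), axis=(0, 1))
        tr = region_properties(shifted, PX)
        assert tr.length_um == pytest.approx(r.length_um)
        assert tr.width_um == pytest.approx(r.width_um)


class TestNewbornFilter:
    def test_threshold_is_strict(self):
        regions = [_fake_region(3.4), _fake_region(3.5, 1), _fake_region(3.6, 2)]
        kept = filter_newborn(regions)
        assert [r.length_um for r in kept] == [3.4]

    def test_empty_input(self):
        assert filter_newborn([]) == []

    def test_subset_and_idempotent(self):
        regions = [_fake_region(l, i) for i, l in enumerate([1.0, 3.0, 4.0])]
        once = filter_newborn(regions)
        assert all(r in regions for r in once)
        assert filter_newborn(once) == once


class TestSegmentByIntensity:
    def test_flat_image_no_regions(self):
        assert segment_by_intensity(np.full((80, 80), 5.0)) == []

    def test_sparse_bright_cells_recovered(self):
        rng = np.random.default_rng(1)
        cells = [
            Spherocylinder(2.0, 0.5, (5.0, 5.0), 0.2),
            Spherocylinder(1.8, 0.5, (14.0, 6.0), 1.2),
            Spherocylinder(2.2, 0.5, (8.0, 14.0), 2.0),
        ]
        mask = footprint_mask(cells, (125, 125), PX)
        img = rng.normal(100.0, 3.0, size=mask.shape) + mask * 80.0
        regions = segment_by_intensity(img, opening_radius=10, gaussian_sigma=1.5)
        assert len(regions) == 3

    def test_low_fraction_trimming_is_monotone(self):
        rng = np.random.default_rng(2)
        cells = [Spherocylinder(2.0, 0.5, (5.0, 5.0), 0.4)]
        mask = footprint_mask(cells, (63, 63), PX)
        img = rng.normal(100.0, 3.0, size=mask.shape) + mask * 80.0
        full = segment_by_intensity(img, opening_radius=10, low_fraction=0.0)
        trimmed = segment_by_intensity(img, opening_radius=10, low_fraction=0.2)
        union_full = np.any([r.mask for r in full], axis=0)
        union_trim = np.any([r.mask for r in trimmed], axis=0)
        assert (union_trim <= union_full).all()


class TestMeanIntensity:
    def test_constant_image(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        region = region_properties(mask, 0.1)
        assert mean_intensity_per_area(np.full((6, 6), 7.0), region) == 7.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 100, size=(20, 20))
        mask = rng.random((20, 20)) > 0.6
        region = region_properties(mask, 0.1)
        acc, n = 0.0, 0
        for i in range(20):
            for j in range(20):
                if mask[i, j]:
                    acc += img[i, j]
                    n += 1
        assert mean_intensity_per_area(img, region) == pytest.approx(acc / n)

    def test_two_level_image(self):
        img = np.full((10, 10), 10.0)
        img[:, 5:] = 20.0
        m1 = np.zeros((10, 10), bool); m1[2:5, 1:4] = True
        m2 = np.zeros((10, 10), bool); m2[2:5, 6:9] = True
        r1 = region_properties(m1, 0.1)
        r2 = region_properties(m2, 0.1)
        assert mean_intensity_per_area(img, r1) == 10.0
        assert mean_intensity_per_area(img, r2) == 20.0

    def test_shape_mismatch_rejected(self):
        mask = np.ones((5, 5), bool)
        region = region_properties(mask, 0.1)
        with pytest.raises(ValueError):
            mean_intensity_per_area(np.zeros((9, 9)), region)
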