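"""Stacked richness, range-size rarity, correlations, areas, quintiles,
mask overlap."""

import numpy as np
import pytest

from marsflora.grids import GridSpec, Raster
from marsflora.richness import (area_above, mask_overlap_stats, quintile_classes,
                                rarity_weighted, richness_correlation,
                                stack_richness)
from marsflora.thresholds import RangeMap


def _range_map(sp, values, method="sd_band"):
    values = np.asarray(values, dtype=float)
    spec = GridSpec(0, values.shape[0] * 1.0, 1.0, *values.shape)
    return RangeMap(sp, method, Raster(spec, values), 0.5)


class TestStackRichness:
    def test_two_overlapping_maps(self):
        a = _range_map("A", [[1, 1], [0, 0]])
        b = _range_map("B", [[1, 0], [1, 0]])
        out = stack_richness([a, b])
        np.testing.assert_array_equal(out.values, [[2, 1], [1, 0]])

    def test_empty_filter_all_zero(self):
        a = _range_map("A", [[1, 1], [0, 0]])
        out = stack_richness([a], species_filter=[])
        np.testing.assert_array_equal(out.values, 0.0)

    def test_matches_cellwise_sum_oracle(self):
        rng = np.random.default_rng(113)
        maps = [_range_map(f"s{i}", (rng.uniform(size=(9, 9)) < 0.4).astype(float))
                for i in range(50)]
        out = stack_richness(maps)
        expected = np.zeros((9, 9))
        for m in maps:
            expected += m.presence.values
        np.testing.assert_array_equal(out.values, expected)
        assert out.values.max() <= 50

    def test_mismatched_grids_rejected(self):
        a = _range_map("A", np.zeros((3, 3)))
        b = _range_map("B", np.zeros((4, 4)))
        with pytest.raises(ValueError, match="shared grid"):
            stack_richness([a, b])


class TestRarity:
    def test_shared_cell_weight(self):
        a = _range_map("A", [[1, 1], [0, 0]])           # range 2 cells
        b = _range_map("B", [[1, 1], [1, 1]])           # range 4 cells
        out = rarity_weighted([a, b])
        assert out.values[0, 0] == pytest.approx(0.5 + 0.25)

    def test_single_species_total_one(self):
        a = _range_map("A", [[1, 0, 1], [0, 1, 0]])
        out = rarity_weighted([a])
        np.testing.assert_allclose(out.values[a.presence.values == 1], 1 / 3)
        assert np.nansum(out.values) == pytest.approx(1.0, abs=1e-12)

    def test_conservation_identity(self):
        rng = np.random.default_rng(127)
        maps = [_range_map(f"s{i}", (rng.uniform(size=(12, 12)) < 0.3).astype(float))
                for i in range(25)]
        maps = [m for m in maps if m.range_cells > 0]
        out = rarity_weighted(maps)
        assert np.nansum(out.values) == pytest.approx(len(maps), abs=1e-9)

    def test_empty_range_skipped_with_warning(self):
        a = _range_map("A", [[1, 0], [0, 0]])
        b = _range_map("B", [[0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="empty range"):
            out = rarity_weighted([a, b])
        assert np.nansum(out.values) == pytest.approx(1.0)


class TestCorrelation:
    def _random_map(self, seed):
        rng = np.random.default_rng(seed)
        spec = GridSpec(0, 10, 1.0, 10, 10)
        return Raster(spec, rng.poisson(5, (10, 10)).astype(float))

    def test_self_correlation_one(self):
        m = self._random_map(131)
        assert richness_correlation(m, m) == pytest.approx(1.0)

    def test_affine_negation_minus_one(self):
        m = self._random_map(137)
        neg = Raster(m.spec, m.values.max() - m.values)
        assert richness_correlation(m, neg) == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self):
        from scipy.stats import pearsonr
        a, b = self._random_map(139), self._random_map(149)
        r = richness_correlation(a, b)
        assert r == pytest.approx(pearsonr(a.values.ravel(), b.values.ravel())[0],
                                  rel=1e-12)

    def test_constant_map_flagged_nan(self):
        a = self._random_map(151)
        const = Raster(a.spec, np.full(a.spec.shape, 2.0))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(richness_correlation(a, const))


class TestAreaAbove:
    def test_counting_example(self):
        m = Raster(GridSpec(0, 1, 1.0, 1, 5),
                   np.array([[10.0, 60.0, 60.0, 110.0, 0.0]]))
        assert area_above(m, 50, 0.1) == pytest.approx(0.3)
        assert area_above(m, 1000, 0.1) == 0.0

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(157)
        m = Raster(GridSpec(0, 8, 1.0, 8, 8), rng.poisson(30, (8, 8)).astype(float))
        areas = [area_above(m, t, 0.1) for t in range(0, 60, 5)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestQuintiles:
    def test_ten_distinct_values_two_per_class(self):
        vals = np.zeros((4, 5))
        vals.ravel()[:10] = np.arange(1, 11)
        m = Raster(GridSpec(0, 4, 1.0, 4, 5), vals)
        out = quintile_classes(m)
        classes, counts = np.unique(out.values[vals != 0], return_counts=True)
        np.testing.assert_array_equal(classes, [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(counts, 2)
        assert (out.values[vals == 0] == 0).all()

    def test_all_equal_degenerate_warns(self):
        vals = np.zeros((3, 3))
        vals.ravel()[:6] = 7.0
        m = Raster(GridSpec(0, 3, 1.0, 3, 3), vals)
        with pytest.warns(UserWarning, match="degenerate"):
            quintile_classes(m)

    def test_too_few_nonzero_rejected(self):
        m = Raster(GridSpec(0, 2, 1.0, 2, 2), np.eye(2))
        with pytest.raises(ValueError, match="at least 5"):
            quintile_classes(m)

    def test_matches_sort_split_oracle(self):
        rng = np.random.default_rng(163)
        vals = rng.uniform(1, 9, (10, 10))  # all non-zero, distinct
        m = Raster(GridSpec(0, 10, 1.0, 10, 10), vals)
        out = quintile_classes(m)
        order = np.argsort(vals.ravel(), kind="stable")
        expected = np.zeros(100)
        bounds = np.linspace(0, 100, 6).round().astype(int)
        for k in range(5):
            expected[order[bounds[k]:bounds[k + 1]]] = k + 1
        np.testing.assert_array_equal(out.values.ravel(), expected)
        _, counts = np.unique(out.values, return_counts=True)
        assert counts.max() - counts.min() <= 1


class TestMaskOverlap:
    def test_mask_on_top_quintile_only(self):
        rng = np.random.default_rng(167)
        vals = rng.uniform(1, 9, (10, 10))
        m = Raster(GridSpec(0, 10, 1.0, 10, 10), vals)
        classed = quintile_classes(m)
        mask = Raster(m.spec, (classed.values == 5).astype(float))
        assert mask_overlap_stats(m, mask, top_classes=1) == pytest.approx(1.0)

    def test_mask_on_zero_cells(self):
        vals = np.zeros((3, 4))
        vals.ravel()[:6] = np.arange(1, 7)
        m = Raster(GridSpec(0, 3, 1.0, 3, 4), vals)
        mask = Raster(m.spec, (vals == 0).astype(float))
        assert mask_overlap_stats(m, mask, top_classes=2) == 0.0

    def test_empty_mask_rejected(self):
        rng = np.random.default_rng(173)
        m = Raster(GridSpec(0, 5, 1.0, 5, 5), rng.uniform(1, 2, (5, 5)))
        mask = Raster(m.spec, np.zeros((5, 5)))
        with pytest.raises(ValueError, match="mask"):
            mask_overlap_stats(m, mask)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(179)
        vals = rng.uniform(1, 9, (10, 10))
        m = Raster(GridSpec(0, 10, 1.0, 10, 10), vals)
        mask_arr = (rng.uniform(size=(10, 10)) < 0.5).astype(float)
        mask = Raster(m.spec, mask_arr)
        got = mask_overlap_stats(m, mask, top_classes=2)
        classed = quintile_classes(m).values
        sel = mask_arr > 0
        expected = np.mean(classed[sel] >= 4)
        assert got == pytest.approx(expected)
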