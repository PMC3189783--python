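"""stdev*coeff map construction, contour level sets and region reports."""

import numpy as np
import pytest

from gridqsar import contours, pls
from gridqsar.fields import FieldBlock, GridSpec, ProbeSpec
from gridqsar.contours import ContourMap


def block_and_model(matrix, y, n_components=1, kind="comsia_S", min_sd=0.0):
    matrix = np.asarray(matrix, float)
    grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(matrix.shape[1], 1, 1))
    block = FieldBlock(kind, matrix, grid, list(range(1, matrix.shape[0] + 1)), ProbeSpec())
    fb = pls.filter_columns(block, min_sd)
    desc = pls.combine_blocks([fb])
    model = pls.fit(
        desc.X,
        y,
        n_components,
        column_scales=desc.column_scales,
        column_field_kinds=desc.column_field_kinds,
        column_grid_indices=desc.column_grid_indices,
    )
    return block, model


class TestStdevCoeffMap:
    def test_filtered_constant_column_maps_to_zero(self):
        rng = np.random.default_rng(0)
        mat = np.column_stack([np.full(10, 3.0), rng.normal(size=10)])
        y = mat[:, 1] * 2.0
        block, model = block_and_model(mat, y, min_sd=0.1)
        cmap = contours.stdev_coeff_map(model, block)
        assert cmap.values[0] == 0.0
        assert cmap.values[1] != 0.0

    def test_single_column_product(self):
        # one informative column: coefficient (original units) x column sd
        rng = np.random.default_rng(1)
        col = rng.normal(0, 0.5, 30)
        y = 2.0 * col + 5.0
        block, model = block_and_model(col[:, None], y)
        cmap = contours.stdev_coeff_map(model, block)
        expected = model.coef_raw[0] * col.std()
        assert cmap.values[0] == pytest.approx(expected, rel=1e-9)
        assert model.coef_raw[0] == pytest.approx(2.0, rel=1e-6)

    def test_elementwise_product_oracle(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(12, 7))
        y = rng.normal(size=12)
        block, model = block_and_model(mat, y, n_components=3)
        cmap = contours.stdev_coeff_map(model, block)
        expected = model.coef_raw * mat.std(axis=0, ddof=0)
        np.testing.assert_allclose(cmap.values, expected, atol=1e-12)

    def test_provenance_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(8, 4))
        block, model = block_and_model(mat, rng.normal(size=8))
        other = FieldBlock(
            "comsia_H",
            mat,
            block.grid,
            list(range(1, 9)),
            ProbeSpec(),
        )
        with pytest.raises(ValueError, match="comsia_H"):
            contours.stdev_coeff_map(model, other)


def flat_map(values, dims=None):
    values = np.asarray(values, float)
    dims = dims or (values.size, 1, 1)
    grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=dims)
    return ContourMap(field_kind="comsia_S", grid=grid, values=values)


class TestContourLevels:
    def test_percentiles_on_four_values(self):
        cmap = contours.contour_levels(flat_map([-2.0, -1.0, 1.0, 2.0]), 80, 20)
        assert 3 in cmap.favored_points  # the +2 point
        assert 0 in cmap.disfavored_points  # the -2 point
        assert not set(cmap.favored_points) & set(cmap.disfavored_points)

    def test_median_split_partitions_nonzero_points(self):
        vals = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        cmap = contours.contour_levels(flat_map(vals), 50, 50)
        covered = set(cmap.favored_points) | set(cmap.disfavored_points)
        nonzero = set(np.flatnonzero(vals))
        assert covered == nonzero

    def test_positive_rescaling_leaves_index_sets_unchanged(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=40)
        a = contours.contour_levels(flat_map(vals.copy()), 80, 20)
        b = contours.contour_levels(flat_map(vals * 7.5), 80, 20)
        np.testing.assert_array_equal(a.favored_points, b.favored_points)
        np.testing.assert_array_equal(a.disfavored_points, b.disfavored_points)

    def test_all_zero_map_warns_and_empties(self):
        with pytest.warns(UserWarning, match="all-zero"):
            cmap = contours.contour_levels(flat_map(np.zeros(5)))
        assert cmap.favored_points.size == 0
        assert cmap.disfavored_points.size == 0


class TestRegions:
    def test_six_neighbourhood_components(self):
        vals = np.zeros(27)
        vals[[0, 1, 26]] = 5.0  # (0,0,0)+(0,0,1) touch; (2,2,2) isolated
        cmap = flat_map(vals, dims=(3, 3, 3))
        cmap.favored_points = np.flatnonzero(vals > 0)
        cmap.disfavored_points = np.array([], dtype=int)
        regs = contours.connected_regions(cmap)
        assert len(regs) == 2
        assert sorted(r.point_indices.size for r in regs) == [1, 2]

    def test_empty_sets_give_empty_report(self, toy_molecule):
        cmap = flat_map(np.zeros(8), dims=(2, 2, 2))
        regions, text = contours.substituent_report(cmap, toy_molecule([[0, 0, 0]]))
        assert regions == []
        assert "no contour regions" in text

    def test_point_at_substituent_named_with_zero_distance(self, toy_molecule):
        ref = toy_molecule([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        ref.anchors = {"N1-R1": 0, "4'": 1}
        vals = np.zeros(3 * 1 * 1)
        vals[2] = 4.0  # lattice point at x=2 == the 4' anchor atom
        cmap = flat_map(vals, dims=(3, 1, 1))
        contours.contour_levels(cmap, 50, 50)
        regions, text = contours.substituent_report(cmap, ref)
        fav = [r for r in regions if r.kind == "favored"]
        assert fav and fav[0].nearest_label == "4'"
        assert fav[0].nearest_distance == pytest.approx(0.0, abs=1e-12)
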