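"""Coordinate transforms: variance scaling, explicit axes, parallel
coordinates, trajectories, biplots, axis flips."""

import numpy as np
import pytest
from scipy.optimize import linprog

from ordviz import (
    ValidationError,
    biplot_coords,
    flip_axes,
    make_explicit_axis,
    make_trajectories,
    parallel_coordinates,
    scale_axes_by_variance,
)
from ordviz.io_formats import MISSING, TaxaTable

from conftest import make_meta, make_ord


class TestScaleAxesByVariance:
    def test_forced_ratios(self):
        coords = np.array([[1.0, 2.0, 4.0], [-2.0, 6.0, -8.0]])
        ord_res = make_ord(coords, eigvals=[4.0, 2.0, 1.0], pct=[40.0, 20.0, 10.0])
        scaled = scale_axes_by_variance(ord_res)
        np.testing.assert_array_equal(scaled[:, 1], coords[:, 1] * 0.5)
        np.testing.assert_array_equal(scaled[:, 2], coords[:, 2] * 0.25)

    def test_first_column_bit_exact(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(7, 3))
        ord_res = make_ord(coords, pct=[37.7, 21.1, 9.3], eigvals=[3, 2, 1])
        assert np.array_equal(scale_axes_by_variance(ord_res)[:, 0], coords[:, 0])

    def test_equal_percentages_are_identity(self):
        coords = np.array([[1.0, 2.0], [3.0, 4.0]])
        ord_res = make_ord(coords, pct=[30.0, 30.0], eigvals=[1.0, 1.0])
        np.testing.assert_array_equal(scale_axes_by_variance(ord_res), coords)

    def test_single_axis_unchanged(self):
        ord_res = make_ord([[1.0], [2.0]], pct=[80.0], eigvals=[2.0])
        np.testing.assert_array_equal(
            scale_axes_by_variance(ord_res), [[1.0], [2.0]]
        )

    def test_zero_first_axis_rejected(self):
        ord_res = make_ord([[1.0, 2.0]], pct=[0.0, 0.0], eigvals=[0.0, 0.0])
        with pytest.raises(ValidationError):
            scale_axes_by_variance(ord_res)


class TestExplicitAxis:
    def test_min_max_scaled_to_pc1_range(self):
        # PC1 spans [-1, 3] -> range 4; ages 1..3 -> axis values 0, 2, 4
        ord_res = make_ord([[-1.0, 0.0], [1.0, 1.0], [3.0, 2.0]])
        meta = make_meta(ord_res.sample_ids, Age=["1", "2", "3"])
        out = make_explicit_axis(ord_res, meta, "Age")
        np.testing.assert_allclose(out.coords[:, 0], [0.0, 2.0, 4.0])

    def test_augmentation_only(self):
        ord_res = make_ord([[-1.0, 0.0], [1.0, 1.0], [3.0, 2.0]])
        meta = make_meta(ord_res.sample_ids, Age=["1", "2", "3"])
        out = make_explicit_axis(ord_res, meta, "Age")
        np.testing.assert_array_equal(out.coords[:, 1:], ord_res.coords)
        assert out.pct_explained[0] == 0.0 and out.eigvals[0] == 0.0
        assert out.sample_ids == ord_res.sample_ids

    def test_missing_value_lists_offender(self):
        ord_res = make_ord([[-1.0, 0.0], [1.0, 1.0]])
        meta = make_meta(ord_res.sample_ids, Age=["1", MISSING])
        with pytest.raises(ValidationError, match="s1"):
            make_explicit_axis(ord_res, meta, "Age")

    def test_zero_range_rejected(self):
        ord_res = make_ord([[-1.0, 0.0], [1.0, 1.0]])
        meta = make_meta(ord_res.sample_ids, Age=["2", "2"])
        with pytest.raises(ValidationError, match="zero range"):
            make_explicit_axis(ord_res, meta, "Age")

    def test_non_numeric_column_rejected(self):
        ord_res = make_ord([[-1.0, 0.0], [1.0, 1.0]])
        meta = make_meta(ord_res.sample_ids, Age=["young", "old"])
        with pytest.raises(ValidationError, match="Age"):
            make_explicit_axis(ord_res, meta, "Age")


class TestParallelCoordinates:
    def test_extreme_sample_hits_one_everywhere(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [0.5, 1.0, 1.5]])
        out = parallel_coordinates(make_ord(coords), 3)
        np.testing.assert_array_equal(out[1], [1.0, 1.0, 1.0])
        np.testing.assert_array_equal(out[0], [0.0, 0.0, 0.0])

    def test_symmetric_samples_sum_to_one(self):
        coords = np.array([[1.0, -2.0], [-1.0, 2.0]])
        out = parallel_coordinates(make_ord(coords), 2)
        np.testing.assert_allclose(out.sum(axis=0), [1.0, 1.0])

    def test_constant_axis_maps_to_half(self):
        coords = np.array([[1.0, 5.0], [2.0, 5.0]])
        out = parallel_coordinates(make_ord(coords), 2)
        np.testing.assert_array_equal(out[:, 1], [0.5, 0.5])

    def test_output_in_unit_interval(self, rng):
        coords = rng.normal(scale=7.0, size=(40, 5))
        out = parallel_coordinates(make_ord(coords), 4)
        assert out.shape == (40, 4)
        assert out.min() >= 0.0 and out.max() <= 1.0

    @pytest.mark.parametrize("n_axes", [1, 4])
    def test_axis_count_out_of_range(self, n_axes):
        with pytest.raises(ValidationError):
            parallel_coordinates(make_ord(np.zeros((3, 3))), n_axes)


class TestTrajectories:
    def _inputs(self):
        ord_res = make_ord(np.arange(12.0).reshape(6, 2),
                           ids=["a1", "a2", "a3", "b1", "b2", "c1"])
        meta = make_meta(
            ord_res.sample_ids,
            Subject=["A", "A", "A", "B", "B", "C"],
            Day=["14", "2", "7", "5", "5", "1"],
        )
        return ord_res, meta

    def test_ordered_by_gradient(self):
        ord_res, meta = self._inputs()
        trajs = {t.label: t for t in make_trajectories(ord_res, meta, "Subject", "Day")}
        assert trajs["A"].ordered_sample_ids == ["a2", "a3", "a1"]  # days 2,7,14
        assert list(trajs["A"].gradient_values) == [2.0, 7.0, 14.0]

    def test_ties_broken_lexicographically(self):
        ord_res, meta = self._inputs()
        trajs = {t.label: t for t in make_trajectories(ord_res, meta, "Subject", "Day")}
        assert trajs["B"].ordered_sample_ids == ["b1", "b2"]

    def test_partition_of_samples(self):
        ord_res, meta = self._inputs()
        trajs = make_trajectories(ord_res, meta, "Subject", "Day")
        assert len(trajs) == 3
        all_ids = [s for t in trajs for s in t.ordered_sample_ids]
        assert sorted(all_ids) == sorted(ord_res.sample_ids)
        singleton = [t for t in trajs if t.label == "C"][0]
        assert singleton.polyline.shape == (1, 2)

    def test_polyline_matches_sample_coords(self):
        ord_res, meta = self._inputs()
        trajs = {t.label: t for t in make_trajectories(ord_res, meta, "Subject", "Day")}
        idx = {s: i for i, s in enumerate(ord_res.sample_ids)}
        for t in trajs.values():
            for sid, pt in zip(t.ordered_sample_ids, t.polyline):
                np.testing.assert_array_equal(pt, ord_res.coords[idx[sid]])

    def test_non_numeric_gradient_lists_samples(self):
        ord_res, meta = self._inputs()
        bad = make_meta(
            ord_res.sample_ids,
            Subject=["A"] * 6,
            Day=["1", "2", "x", "4", "y", "6"],
        )
        with pytest.raises(ValidationError, match="a3"):
            make_trajectories(ord_res, bad, "Subject", "Day")


def _taxa(ids, rows, taxa_ids=None):
    taxa_ids = taxa_ids or [f"t{i}" for i in range(len(rows))]
    return TaxaTable(taxa_ids, list(ids), np.asarray(rows, dtype=float))


class TestBiplot:
    def test_exclusive_taxon_sits_on_its_sample(self):
        ord_res = make_ord([[1.0, 2.0], [5.0, -3.0]])
        taxa = _taxa(ord_res.sample_ids, [[4.0, 0.0], [0.0, 4.0]])
        points = {p.taxon_id: p for p in biplot_coords(ord_res, taxa, 2)}
        np.testing.assert_array_equal(points["t0"].position, [1.0, 2.0])

    def test_uniform_taxon_hits_centroid(self):
        coords = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 8.0], [4.0, 8.0]])
        ord_res = make_ord(coords)
        # equal relative abundance in every sample: equal column totals
        taxa = _taxa(ord_res.sample_ids, [[1.0] * 4, [3.0] * 4])
        points = {p.taxon_id: p for p in biplot_coords(ord_res, taxa, 2)}
        np.testing.assert_array_equal(points["t0"].position, coords.mean(axis=0))

    def test_weighted_average_ratio(self):
        # equal column totals keep relative abundances proportional to counts
        ord_res = make_ord([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        taxa = _taxa(ord_res.sample_ids, [[1.0, 3.0], [3.0, 1.0]])
        points = {p.taxon_id: p for p in biplot_coords(ord_res, taxa, 2)}
        np.testing.assert_array_equal(points["t0"].position, [1.5, 0.0, 0.0])

    def test_weights_sum_to_at_most_one_and_rank_by_mass(self):
        ord_res = make_ord(np.arange(6.0).reshape(3, 2))
        taxa = _taxa(ord_res.sample_ids, [[5, 5, 5], [1, 1, 1], [0, 0, 0]])
        points = biplot_coords(ord_res, taxa, 2)
        assert [p.taxon_id for p in points] == ["t0", "t1"]
        assert sum(p.weight for p in points) <= 1.0 + 1e-12

    def test_zero_total_taxa_never_kept(self):
        ord_res = make_ord(np.arange(4.0).reshape(2, 2))
        taxa = _taxa(ord_res.sample_ids, [[0.0, 0.0], [1.0, 1.0]])
        points = biplot_coords(ord_res, taxa, 5)
        assert [p.taxon_id for p in points] == ["t1"]

    def test_empty_taxa_table_rejected(self):
        ord_res = make_ord(np.arange(4.0).reshape(2, 2))
        taxa = _taxa(ord_res.sample_ids, [[0.0, 0.0]])
        with pytest.raises(ValidationError):
            biplot_coords(ord_res, taxa, 1)

    def test_positions_inside_convex_hull(self, rng):
        """LP feasibility: each biplot point is a convex combination of
        sample coordinates."""
        coords = rng.normal(size=(12, 3))
        ord_res = make_ord(coords)
        taxa = _taxa(ord_res.sample_ids, rng.integers(0, 20, size=(6, 12)))
        for p in biplot_coords(ord_res, taxa, 6):
            a_eq = np.vstack([coords.T, np.ones(12)])
            b_eq = np.concatenate([p.position, [1.0]])
            res = linprog(np.zeros(12), A_eq=a_eq, b_eq=b_eq,
                          bounds=[(0, 1)] * 12, method="highs")
            assert res.success


class TestFlipAxes:
    def test_flip_twice_is_identity(self):
        ord_res = make_ord(np.arange(6.0).reshape(3, 2))
        out = flip_axes(flip_axes(ord_res, [2]), [2])
        np.testing.assert_array_equal(out.coords, ord_res.coords)

    def test_flip_nothing_is_identity(self):
        ord_res = make_ord(np.arange(6.0).reshape(3, 2))
        np.testing.assert_array_equal(flip_axes(ord_res, []).coords, ord_res.coords)

    def test_flip_is_isometric(self, rng):
        from scipy.spatial.distance import pdist

        coords = rng.normal(size=(10, 4))
        ord_res = make_ord(coords)
        out = flip_axes(ord_res, [1, 3])
        np.testing.assert_allclose(pdist(out.coords), pdist(coords), atol=1e-12)
        np.testing.assert_array_equal(out.eigvals, ord_res.eigvals)

    def test_out_of_range_axis_rejected(self):
        with pytest.raises(ValidationError, match="axis 3"):
            flip_axes(make_ord(np.zeros((2, 2))), [3])
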