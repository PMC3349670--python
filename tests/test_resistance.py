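"""Resistance surfaces and circuit-theory solver against closed forms."""

import numpy as np
import pytest

from streamscape import resistance as rs
from streamscape.datasets import LandscapeStack


def dense_resistance_oracle(surface, sites):
    """Effective resistance via the deflated dense pseudo-inverse.

    For a connected graph, L^+ = inv(L + J/n) - J/n exactly.
    """
    L, idx = rs._lattice_laplacian(surface)
    Ld = L.toarray()
    n = Ld.shape[0]
    J = np.full((n, n), 1.0 / n)
    Lp = np.linalg.inv(Ld + J) - J
    f = idx[sites.rows, sites.cols]
    return np.array([[Lp[i, i] + Lp[j, j] - 2 * Lp[i, j] for j in f]
                     for i in f])


class TestConversions:
    def test_continuous_endpoints_and_interpolation(self):
        layer = np.array([[0.0, 5.0, 10.0], [0.0, 5.0, 10.0]])
        plus = rs.continuous_to_resistance(layer, "+")
        assert np.allclose(plus.values[0], [1.0, 5.5, 10.0])
        minus = rs.continuous_to_resistance(layer, "-")
        assert np.allclose(minus.values[0], [10.0, 5.5, 1.0])

    def test_constant_layer_warns_and_maps_to_rmin(self):
        with pytest.warns(UserWarning, match="constant"):
            out = rs.continuous_to_resistance(np.full((3, 3), 7.0), "+")
        assert (out.values == 1.0).all()

    def test_categorical_cost_ratios(self):
        layer = np.array([[1, 2], [3, 1]])
        out = rs.categorical_to_resistance(layer, {1: 1, 2: 50, 3: 100})
        assert np.array_equal(out.values, [[1, 50], [100, 1]])

    def test_uniform_forest_is_uniform_least_cost(self):
        out = rs.categorical_to_resistance(np.ones((4, 4), int),
                                           {1: 1, 2: 5, 3: 10})
        assert (out.values == 1.0).all()

    def test_unmapped_code_named_in_error(self):
        with pytest.raises(ValueError, match="4"):
            rs.categorical_to_resistance(np.array([[1, 4]]), {1: 1})

    def test_ibr_surface_flat_with_provenance(self):
        surf = rs.ibr_surface((5, 7))
        assert (surf.values == 1.0).all()
        assert surf.provenance["variable"] == "IBR"


class TestClipBuffer:
    def test_expansion_is_ceil_buffer_over_cellsize(self):
        surf = rs.ibr_surface((100, 100), 30.0)
        sites = rs.FocalSites(["a", "b"], [40, 60], [40, 60])
        clipped, ns = rs.clip_buffer(surf, sites, 500.0)
        # span 21 cells + 17 per side
        assert clipped.shape == (55, 55)
        assert ns.rows.min() == 17

    def test_clamps_at_grid_edges(self):
        surf = rs.ibr_surface((20, 20), 30.0)
        sites = rs.FocalSites(["a"], [1], [1])
        clipped, ns = rs.clip_buffer(surf, sites, 500.0)
        assert clipped.shape == (19, 19)  # clamped top-left
        assert (ns.rows[0], ns.cols[0]) == (1, 1)

    def test_full_span_sites_leave_grid_unchanged(self):
        stack = LandscapeStack(10, 10, 30.0,
                               {"elevation": np.zeros((10, 10))})
        sites = rs.FocalSites(["a", "b"], [0, 9], [0, 9])
        clipped, _ = rs.clip_buffer(stack, sites, 500.0)
        assert (clipped.n_rows, clipped.n_cols) == (10, 10)


class TestEffectiveResistance:
    def test_single_resistor_average_of_cells(self):
        surf = rs.ResistanceSurface(np.array([[2.0, 4.0]]), 30.0)
        m = rs.effective_resistance(
            surf, rs.FocalSites(["a", "b"], [0, 0], [0, 1])
        )
        assert m.values[0, 1] == pytest.approx(3.0, abs=1e-12)

    def test_series_law_on_path(self):
        surf = rs.ResistanceSurface(np.ones((1, 5)), 30.0)
        m = rs.effective_resistance(
            surf, rs.FocalSites(["a", "b"], [0, 0], [0, 4])
        )
        assert m.values[0, 1] == pytest.approx(4.0, abs=1e-12)

    def test_parallel_law_on_2x2(self):
        # two corner-to-corner routes of 2 unit resistors in parallel -> 1
        surf = rs.ResistanceSurface(np.ones((2, 2)), 30.0)
        m = rs.effective_resistance(
            surf, rs.FocalSites(["a", "b"], [0, 1], [0, 1])
        )
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        surf = rs.ResistanceSurface(rng.uniform(1, 10, (15, 15)), 30.0)
        sites = rs.FocalSites(
            [f"s{i}" for i in range(5)], [1, 3, 7, 12, 14], [2, 9, 4, 13, 0]
        )
        m = rs.effective_resistance(surf, sites)
        oracle = dense_resistance_oracle(surf, sites)
        assert np.abs(m.values - oracle).max() < 1e-9

    def test_resistance_increases_with_separation_on_flat_row(self):
        surf = rs.ResistanceSurface(np.ones((1, 12)), 30.0,
                                    provenance={"variable": "IBR"})
        sites = rs.FocalSites([f"s{i}" for i in range(6)],
                              [0] * 6, [0, 2, 4, 6, 8, 11])
        m = rs.effective_resistance(surf, sites)
        row = m.values[0]
        assert (np.diff(row[1:]) > 0).all()

    def test_global_scaling_scales_resistances(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 5, (8, 8))
        sites = rs.FocalSites(["a", "b", "c"], [0, 4, 7], [0, 5, 7])
        m1 = rs.effective_resistance(rs.ResistanceSurface(vals, 30.0), sites)
        m3 = rs.effective_resistance(
            rs.ResistanceSurface(3 * vals, 30.0), sites
        )
        assert np.allclose(m3.values, 3 * m1.values, atol=1e-10)

    def test_site_order_equivariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 10, (9, 9))
        ids = ["a", "b", "c", "d"]
        rows, cols = [0, 2, 5, 8], [1, 7, 3, 8]
        m = rs.effective_resistance(
            rs.ResistanceSurface(vals, 30.0),
            rs.FocalSites(ids, rows, cols),
        )
        perm = [2, 0, 3, 1]
        m2 = rs.effective_resistance(
            rs.ResistanceSurface(vals, 30.0),
            rs.FocalSites([ids[i] for i in perm],
                          [rows[i] for i in perm],
                          [cols[i] for i in perm]),
        )
        assert np.allclose(m2.reorder(ids).values, m.values, atol=1e-10)

    def test_disconnected_components_are_named(self):
        vals = np.ones((3, 3))
        mask = np.zeros((3, 3), bool)
        mask[:, 1] = True  # vertical nodata wall
        surf = rs.ResistanceSurface(vals, 30.0, mask)
        sites = rs.FocalSites(["west", "east"], [1, 1], [0, 2])
        with pytest.raises(ValueError, match="disconnected"):
            rs.effective_resistance(surf, sites)

    def test_shared_cell_rejected(self):
        with pytest.raises(ValueError, match="same raster cell"):
            rs.FocalSites(["a", "b"], [1, 1], [1, 1])


class TestStandardizeAndSum:
    def test_single_surface_is_its_rescaling(self):
        surf = rs.ResistanceSurface(np.array([[0.0, 10.0], [5.0, 5.0]])
                                    + 1.0, 30.0)
        out = rs.standardize_and_sum([surf])
        assert np.allclose(out.values, [[1.0, 10.0], [5.5, 5.5]])

    def test_two_identical_surfaces_double(self):
        surf = rs.ResistanceSurface(np.array([[1.0, 2.0], [3.0, 4.0]]), 30.0)
        out = rs.standardize_and_sum([surf, surf])
        assert out.values.min() == pytest.approx(2.0)
        assert out.values.max() == pytest.approx(20.0)

    def test_hand_2x2_example(self):
        a = rs.ResistanceSurface(np.array([[0.0, 10.0], [5.0, 5.0]]) + 1,
                                 30.0)
        b = rs.ResistanceSurface(np.array([[1.0, 1.0], [1.0, 3.0]]), 30.0)
        out = rs.standardize_and_sum([a, b])
        assert np.allclose(out.values, [[2.0, 11.0], [6.5, 15.5]])

    def test_dimension_mismatch_rejected(self):
        a = rs.ibr_surface((3, 3))
        b = rs.ibr_surface((4, 4))
        with pytest.raises(ValueError, match="co-registered"):
            rs.standardize_and_sum([a, b])
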