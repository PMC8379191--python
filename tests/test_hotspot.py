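"""Grid discretisation and the Getis-Ord statistic against permutation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mamspat import hotspot as hs
from mamspat import synthetic as syn


def _pts(coords):
    return pd.DataFrame({"x_px": [c[0] for c in coords],
                         "y_px": [c[1] for c in coords]})


class TestGridDiscretise:
    def test_empty_table_all_zero(self):
        with pytest.warns(UserWarning):
            grid = hs.grid_discretise(_pts([]), (100, 100), 10)
        assert grid.counts.sum() == 0

    def test_half_open_convention(self):
        grid = hs.grid_discretise(_pts([(10.0, 10.0)]), (100, 100), 10)
        assert grid.counts[1, 1] == 1
        assert grid.counts[0, 0] == 0

    def test_conservation(self, rng):
        pts = _pts(rng.uniform(0, 97, size=(1000, 2)))
        grid = hs.grid_discretise(pts, (97, 97), 10)
        assert grid.counts.sum() == 1000
        # ragged final row/column kept
        assert grid.counts.shape == (10, 10)

    def test_ragged_cell_centres_adjusted(self):
        grid = hs.GridCounts(
            np.zeros((2, 2), int), cell_size_px=10, field_shape_px=(15, 15)
        )
        centres = grid.cell_centres_px()
        assert centres[0].tolist() == [5.0, 5.0]
        assert centres[-1].tolist() == [12.5, 12.5]


class TestGetisOrd:
    def test_three_cell_worked_example_exact(self):
        """x=(2,1,0) on a line, d spanning adjacent cells only: the first cell
        has G=1, E=1/2, Var=1/4, Z=1, identical to exhaustive conditional
        permutation of the remaining values."""
        grid = hs.GridCounts(np.array([[2, 1, 0]]), cell_size_px=10.0)
        res = hs.getis_ord(grid, d_px=15.0)
        assert res.g[0, 0] == 1.0
        assert res.expected[0, 0] == 0.5
        assert res.variance[0, 0] == 0.25
        assert res.z[0, 0] == 1.0
        weights = hs.distance_band_weights(grid, 15.0)
        null = hs.permutation_null(grid, weights, exhaustive=True)
        assert null["mean"][0, 0] == 0.5
        assert null["var"][0, 0] == 0.25

    def test_constant_grid_all_z_zero(self):
        grid = hs.GridCounts(np.full((5, 5), 3), cell_size_px=1.0)
        res = hs.getis_ord(grid, d_px=2.0)
        assert np.allclose(res.z, 0.0)

    def test_expected_is_W_over_n_minus_1(self, rng):
        counts = rng.poisson(2, size=(8, 8))
        counts[0, 0] += 1  # ensure positive total
        grid = hs.GridCounts(counts, cell_size_px=1.0)
        weights = hs.distance_band_weights(grid, 2.5)
        res = hs.getis_ord(grid, 2.5, weights=weights)
        assert np.allclose(res.expected.ravel(), weights.W / (grid.n_cells - 1))

    def test_empty_grid_errors(self):
        grid = hs.GridCounts(np.zeros((4, 4), int), cell_size_px=1.0)
        with pytest.raises(ValueError):
            hs.getis_ord(grid, 2.0)

    def test_moment_z_matches_permutation_z(self, rng):
        """Closed-form randomisation moments against the Monte-Carlo
        conditional permutation null on random Poisson grids."""
        deltas = []
        for seed in range(3):
            counts = np.random.default_rng(seed).poisson(3, size=(12, 12))
            grid = hs.GridCounts(counts, cell_size_px=1.0)
            res = hs.getis_ord(grid, 3.0)
            weights = hs.distance_band_weights(grid, 3.0)
            null = hs.permutation_null(grid, weights, n_perm=4999, seed=seed)
            deltas.append(np.nanmean(np.abs(res.z - null["z"])))
        assert np.mean(deltas) <= 0.05

    def test_permutation_mean_converges_to_expected(self):
        counts = np.random.default_rng(5).poisson(4, size=(6, 6))
        grid = hs.GridCounts(counts, cell_size_px=1.0)
        weights = hs.distance_band_weights(grid, 2.0)
        null = hs.permutation_null(grid, weights, n_perm=10000, seed=0)
        res = hs.getis_ord(grid, 2.0, weights=weights)
        mc_se = np.sqrt(null["var"] / 10000)
        ok = np.abs(null["mean"] - res.expected) <= 3 * mc_se + 1e-12
        assert ok.all()

    def test_zero_permutations_errors(self):
        grid = hs.GridCounts(np.array([[1, 2, 3]]), cell_size_px=1.0)
        weights = hs.distance_band_weights(grid, 1.5)
        with pytest.raises(ValueError):
            hs.permutation_null(grid, weights, n_perm=0)

    def test_translation_invariance(self, rng):
        """Shifting all centroids by whole cells shifts Z identically, for
        cells far enough from the border that their neighbourhood is not
        truncated (edge cells keep truncated W by design)."""
        pts = rng.uniform(10, 90, size=(300, 2))
        a = hs.grid_discretise(_pts(pts), (200, 200), 10)
        b = hs.grid_discretise(_pts(pts + 20.0), (200, 200), 10)
        za = hs.getis_ord(a, 25.0).z
        zb = hs.getis_ord(b, 25.0).z
        assert np.allclose(za[3:-5, 3:-5], zb[5:-3, 5:-3], equal_nan=True)

    def test_injection_into_own_cell_never_decreases_z(self, rng):
        counts = rng.poisson(3, size=(6, 6)) + 1
        grid = hs.GridCounts(counts, cell_size_px=1.0)
        z0 = hs.getis_ord(grid, 2.0).z
        bumped = counts.copy()
        bumped[2, 2] += 5
        z1 = hs.getis_ord(hs.GridCounts(bumped, cell_size_px=1.0), 2.0).z
        assert z1[2, 2] >= z0[2, 2] - 1e-12

    def test_convolution_path_matches_dense_weights(self, rng):
        """The large-grid convolution shortcut reproduces the exact pairwise
        computation on an evenly dividing grid."""
        counts = rng.poisson(2, size=(30, 30))
        grid = hs.GridCounts(counts, cell_size_px=10.0,
                             field_shape_px=(300, 300))
        exact = hs.getis_ord(grid, 25.0)
        old = hs._MAX_DENSE_CELLS
        try:
            hs._MAX_DENSE_CELLS = 10
            conv = hs.getis_ord(grid, 25.0)
        finally:
            hs._MAX_DENSE_CELLS = old
        assert np.allclose(exact.z, conv.z, equal_nan=True)


class TestHotspots:
    def test_all_zero_z_empty_mask(self):
        grid = hs.GridCounts(np.full((4, 4), 2), cell_size_px=1.0)
        res = hs.getis_ord(grid, 1.5)
        assert not hs.hotspot_mask(res).any()

    def test_threshold_minus_inf_flags_all_defined(self, rng):
        counts = rng.poisson(3, size=(5, 5))
        counts[0, 0] += 1
        res = hs.getis_ord(hs.GridCounts(counts, cell_size_px=1.0), 1.5)
        mask = hs.hotspot_mask(res, z_threshold=-np.inf)
        assert mask.sum() == np.isfinite(res.z).sum()

    def test_polarised_hotspots_index_one(self):
        hot = np.array([[False, True], [False, True]])
        u = np.array([[0.2, 0.9], [0.3, 0.8]])
        assert hs.polarisation_index(hot, u) == 1.0

    def test_uniform_hotspots_index_half(self, rng):
        hot = rng.random((40, 40)) < 0.3
        u = rng.random((40, 40))
        idx = hs.polarisation_index(hot, u)
        n = hot.sum()
        assert abs(idx - 0.5) < 2.576 * np.sqrt(0.25 / n)

    def test_empty_hotspot_set_errors(self):
        with pytest.raises(ValueError):
            hs.polarisation_index(np.zeros((3, 3), bool), np.full((3, 3), 0.5))

    def test_planted_gradient_recovered(self, young_gt):
        """ki67_slope=4 drives hotspots to the leading half of the lobules."""
        cells = young_gt.cells
        pos = cells[
            cells.ki67 & cells.cell_class.isin(["luminal", "basal"])
        ].assign(phenotype="ki67_pos")
        grid = hs.grid_discretise(pos, young_gt.field_shape, 12.5, "ki67_pos")
        res = hs.getis_ord(grid, 62.5)
        hot = hs.hotspot_mask(res, 1.96)
        u = hs.grid_axis_coordinates(grid, young_gt.lobules)
        sel = hot.ravel() & np.isfinite(u.ravel())
        k = int((u.ravel()[sel] > 0.5).sum())
        p = sps.binomtest(k, int(sel.sum()), 0.5, alternative="greater").pvalue
        assert p < 0.01
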