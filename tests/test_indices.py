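import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import specphos as sp
from specphos.dataset import SpectraError

finite_refl = st.floats(min_value=1e-6, max_value=1.0, allow_nan=False)
refl_vectors = st.lists(st.tuples(finite_refl, finite_refl), min_size=2, max_size=12)


def brute_force_scan(matrix, lpc, kind):
    """Nested-loop oracle: every ordered pair, plain corrcoef correlation."""
    n, b = matrix.shape
    best = (None, -np.inf)
    grid = np.full((b, b), np.nan)
    for m in range(b):
        for j in range(b):
            if m == j:
                continue
            vals = sp.compute_index(matrix[:, m], matrix[:, j], kind)
            if np.isnan(vals).any() or np.std(vals) == 0:
                continue
            r2 = min(np.corrcoef(vals, lpc)[0, 1] ** 2, 1.0)
            grid[m, j] = r2
            if r2 > best[1]:
                best = ((m, j), r2)
    return grid, best


class TestComputeIndex:
    def test_equal_bands(self):
        r = np.array([0.5, 0.5])
        assert sp.compute_index(r, r, "NDSI").tolist() == [0.0, 0.0]
        assert sp.compute_index(r, r, "DSI").tolist() == [0.0, 0.0]
        assert sp.compute_index(r, r, "RSI").tolist() == [1.0, 1.0]

    def test_direct_arithmetic(self):
        rm, rn = np.array([0.6]), np.array([0.2])
        assert sp.compute_index(rm, rn, "NDSI")[0] == pytest.approx(0.5)
        assert sp.compute_index(rm, rn, "DSI")[0] == pytest.approx(0.4)
        assert sp.compute_index(rm, rn, "RSI")[0] == pytest.approx(3.0)

    def test_zero_denominator_yields_nan_not_exception(self):
        rm, rn = np.array([0.6, 0.3]), np.array([0.0, 0.3])
        rsi = sp.compute_index(rm, rn, "RSI")
        assert np.isnan(rsi[0]) and rsi[1] == pytest.approx(1.0)
        ndsi = sp.compute_index(rm, rn, "NDSI")
        assert np.isfinite(ndsi).all()  # Rm + Rn nonzero here

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpectraError):
            sp.compute_index(np.ones(3), np.ones(4), "DSI")


class TestIndexAlgebra:
    @settings(deadline=None, max_examples=200)
    @given(refl_vectors)
    def test_ndsi_bounded_on_nonnegative_inputs(self, pairs):
        rm = np.array([p[0] for p in pairs])
        rn = np.array([p[1] for p in pairs])
        vals = sp.compute_index(rm, rn, "NDSI")
        ok = ~np.isnan(vals)
        assert np.all(vals[ok] >= -1.0) and np.all(vals[ok] <= 1.0)

    @settings(deadline=None, max_examples=200)
    @given(refl_vectors)
    def test_swap_antisymmetry_and_reciprocity(self, pairs):
        rm = np.array([p[0] for p in pairs])
        rn = np.array([p[1] for p in pairs])
        np.testing.assert_allclose(
            sp.compute_index(rm, rn, "NDSI"), -sp.compute_index(rn, rm, "NDSI"),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            sp.compute_index(rm, rn, "DSI"), -sp.compute_index(rn, rm, "DSI"),
            atol=1e-15,
        )
        np.testing.assert_allclose(
            sp.compute_index(rm, rn, "RSI"),
            1.0 / sp.compute_index(rn, rm, "RSI"),
            rtol=1e-12,
        )


class TestScanPairs:
    @pytest.mark.parametrize("kind", sp.indices.KINDS)
    def test_matches_brute_force_oracle(self, kind):
        rng = np.random.default_rng(8)
        matrix = 0.1 + 0.8 * rng.random((12, 10))
        lpc = rng.uniform(0.06, 0.12, 12)
        wl = np.arange(400.0, 410.0)
        res = sp.scan_pairs(matrix, lpc, kind, wl)
        grid, ((bm, bn), br2) = brute_force_scan(matrix, lpc, kind)
        np.testing.assert_allclose(res.r2_grid, grid, atol=1e-12)
        assert res.best_r2 == pytest.approx(br2, abs=1e-12)
        assert res.best_r2 == pytest.approx(np.nanmax(res.r2_grid), abs=0)

    def test_ndsi_grid_symmetric(self, tiny_set):
        res = sp.scan_pairs(tiny_set.reflectance, tiny_set.lpc, "NDSI",
                            tiny_set.wavelengths)
        g = res.r2_grid
        np.testing.assert_array_equal(
            np.where(np.isnan(g), -1, g), np.where(np.isnan(g.T), -1, g.T)
        )

    def test_r2_invariant_under_affine_lpc(self, tiny_set):
        a = sp.scan_pairs(tiny_set.reflectance, tiny_set.lpc, "DSI",
                          tiny_set.wavelengths)
        b = sp.scan_pairs(tiny_set.reflectance, 3.0 * tiny_set.lpc + 0.4, "DSI",
                          tiny_set.wavelengths)
        np.testing.assert_allclose(a.r2_grid, b.r2_grid, atol=1e-10)
        assert (a.best.lambda_m, a.best.lambda_n) == (b.best.lambda_m, b.best.lambda_n)

    def test_constant_lpc_rejected(self, tiny_set):
        with pytest.raises(SpectraError):
            sp.scan_pairs(tiny_set.reflectance, np.full(5, 0.09), "DSI",
                          tiny_set.wavelengths)

    def test_planted_dsi_recovered(self, planted_set):
        res = sp.scan_pairs(planted_set.reflectance, planted_set.lpc, "DSI",
                            planted_set.wavelengths)
        assert (res.best.lambda_m, res.best.lambda_n) == (850.0, 950.0)


class TestScanAll:
    def test_cardinality_and_report(self, tiny_set):
        frs = sp.fod_sweep(tiny_set, sp.FODConfig(orders=(0.0, 1.0, 1.6, 2.0)))
        results = sp.scan_all(frs, tiny_set.lpc)
        assert len(results) == 12
        table = sp.best_pairs_table(results)
        assert set(table["kind"]) == {"NDSI", "DSI", "RSI"}
        assert set(table["order"]) == {0.0, 1.0, 1.6, 2.0}
        assert ((table["best_r2"] >= 0) & (table["best_r2"] <= 1)).all()

    def test_full_grid_scan_consistent_with_band_subset(self, planted_set):
        """Entries of the 751-band scan agree with a direct small scan."""
        full = sp.scan_pairs(planted_set.reflectance, planted_set.lpc, "DSI",
                             planted_set.wavelengths)
        pick_nm = [460.0, 680.0, 850.0, 950.0, 1000.0]
        cols = [planted_set.band_index(nm) for nm in pick_nm]
        sub = sp.scan_pairs(planted_set.reflectance[:, cols], planted_set.lpc,
                            "DSI", np.array(pick_nm))
        # spacing differs but pairwise r^2 depends only on the two columns
        for i, ci in enumerate(cols):
            for j, cj in enumerate(cols):
                if i != j:
                    assert full.r2_grid[ci, cj] == pytest.approx(
                        sub.r2_grid[i, j], abs=1e-12
                    )
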