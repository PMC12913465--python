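"""Correlation spectra, top-k picks, and SPA selection/optimisation."""

import numpy as np
import pytest
from sklearn.model_selection import KFold

from heatspec import band_selection as bsel
from heatspec.errors import DegenerateMatrixError, ValidationError


def naive_spa(X, k0, N):
    """Literal per-candidate residualisation loop (independent oracle)."""
    sd = X.std(0)
    Xs = (X - X.mean(0)) / np.where(sd > 0, sd, 1.0)
    cols = {j: Xs[:, j].copy() for j in range(X.shape[1])}
    sel = [k0]
    for n in range(1, N):
        xk = cols[sel[n - 1]]
        for j in cols:
            if j not in sel:
                cols[j] = cols[j] - (cols[j] @ xk) / (xk @ xk) * xk
        candidates = [j for j in cols if j not in sel]
        norms = [np.linalg.norm(cols[j]) for j in candidates]
        sel.append(candidates[int(np.argmax(norms))])
    return sel


class TestCorrelationSpectrum:
    def test_self_correlation_is_one(self, rng):
        X = rng.uniform(0.1, 0.9, (20, 5))
        corr = bsel.correlation_spectrum(X, np.arange(5.0) + 700, X[:, 0])
        assert corr.r[0] == pytest.approx(1.0)

    def test_hand_evaluated_pearson(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        corr = bsel.correlation_spectrum(X, [700.0], y)
        assert corr.r[0] == pytest.approx(0.8)

    def test_independent_noise_has_small_max_correlation(self, rng):
        X = rng.normal(size=(500, 50))
        y = rng.normal(size=500)
        corr = bsel.correlation_spectrum(X, np.arange(50.0), y)
        assert np.max(np.abs(corr.r)) < 0.3

    def test_zero_variance_band_flagged(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 0.5
        corr = bsel.correlation_spectrum(X, np.arange(3.0), rng.normal(size=10))
        assert corr.r[1] == 0.0 and corr.zero_variance[1]

    def test_constant_indicator_rejected(self, rng):
        with pytest.raises(ValidationError):
            bsel.correlation_spectrum(rng.normal(size=(5, 3)),
                                      np.arange(3.0), np.ones(5))

    def test_affine_rescaling_of_y_preserves_magnitude(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        a = bsel.correlation_spectrum(X, np.arange(4.0), y).r
        b = bsel.correlation_spectrum(X, np.arange(4.0), -3.0 * y + 2.0).r
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-12)
        np.testing.assert_allclose(b, -a, atol=1e-12)


class TestTopK:
    def test_k1_is_argmax(self, rng):
        r = np.array([0.1, -0.9, 0.5])
        corr = bsel.CorrelationSpectrum(np.array([700.0, 701.0, 702.0]), r, n=10)
        assert bsel.top_k_bands(corr, 1).tolist() == [701.0]

    def test_all_equal_gives_shortest_wavelengths(self):
        wl = np.array([700.0, 701.0, 702.0, 703.0])
        corr = bsel.CorrelationSpectrum(wl, np.full(4, 0.5), n=10)
        assert bsel.top_k_bands(corr, 2).tolist() == [700.0, 701.0]

    def test_matches_full_sort_oracle(self, rng):
        wl = np.arange(50.0) + 400
        r = rng.uniform(-1, 1, 50)
        corr = bsel.CorrelationSpectrum(wl, r, n=10)
        picks = bsel.top_k_bands(corr, 10)
        oracle = [w for _, w in sorted(zip(-np.abs(r), wl))][:10]
        assert picks.tolist() == oracle

    def test_k_exceeding_bands_rejected(self):
        corr = bsel.CorrelationSpectrum(np.array([700.0]), np.array([0.5]), n=5)
        with pytest.raises(ValidationError):
            bsel.top_k_bands(corr, 2)


class TestSpaSelect:
    def test_orthogonal_columns_picked_by_norm(self):
        # orthogonal columns of norms 3 > 2 > 1; projection leaves the
        # others untouched, so picks follow the norm ordering
        X = np.diag([3.0, 2.0, 1.0])
        sel = bsel.spa_select(X, k0=0, n_select=3, standardize=False)
        assert sel == [0, 1, 2]

    def test_duplicate_column_eliminated(self, rng):
        X = rng.normal(size=(10, 5))
        X[:, 3] = X[:, 0]  # exact duplicate of the start band
        sel = bsel.spa_select(X, k0=0, n_select=4)
        assert 3 not in sel

    def test_matches_naive_gram_schmidt(self, rng):
        for _ in range(20):
            n, B = int(rng.integers(6, 12)), int(rng.integers(5, 15))
            X = rng.normal(size=(n, B))
            k0 = int(rng.integers(B))
            N = int(rng.integers(2, min(n - 1, B) + 1))
            assert bsel.spa_select(X, k0, N) == naive_spa(X, k0, N)

    def test_residual_norms_non_increasing(self, rng):
        X = rng.normal(size=(12, 10))
        _, norms = bsel.spa_select(X, 0, 8, return_norms=True)
        assert np.all(np.diff(norms) <= 1e-9)

    def test_selected_columns_linearly_independent(self, rng):
        X = rng.normal(size=(12, 10))
        sel = bsel.spa_select(X, 2, 6)
        sub = X[:, sel] - X[:, sel].mean(0)
        assert np.linalg.matrix_rank(sub) == len(sel)

    def test_band_permutation_equivariance(self, rng):
        X = rng.normal(size=(10, 8))
        perm = rng.permutation(8)
        sel = bsel.spa_select(X, 3, 5)
        sel_p = bsel.spa_select(X[:, perm], int(np.flatnonzero(perm == 3)[0]), 5)
        assert [perm[j] for j in sel_p] == sel

    def test_zero_norm_column_raises_with_iteration(self):
        X = np.zeros((5, 3))
        X[:, 0] = np.arange(5.0)
        with pytest.raises(DegenerateMatrixError) as err:
            bsel.spa_select(X, 1, 2, standardize=False)
        assert err.value.iteration == 1


class TestSpaOptimize:
    def test_nmax_one_degenerates_to_best_single_band(self, rng):
        X = rng.normal(size=(20, 6))
        y = X[:, 4] + rng.normal(0, 0.01, 20)
        res = bsel.spa_optimize(X, y, n_max=1, seed=0)
        assert res.n_selected == 1 and res.selected == (4,)

    def test_matches_exhaustive_rerun_on_toy_grid(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        res = bsel.spa_optimize(X, y, n_max=4, cv_folds=3, seed=9)
        # independent exhaustive sweep with the same CV protocol
        best = None
        for k0 in range(8):
            path = naive_spa(X, k0, 4)
            for N in (2, 3, 4):
                sel = path[:N]
                cols = sorted(sel)
                kf = KFold(n_splits=3, shuffle=True, random_state=9)
                errs = np.empty(15)
                for tr, te in kf.split(X):
                    A = np.column_stack([np.ones(tr.size), X[tr][:, cols]])
                    At = np.column_stack([np.ones(te.size), X[te][:, cols]])
                    coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                    errs[te] = (y[te] - At @ coef) ** 2
                rmsecv = float(np.sqrt(errs.mean()))
                key = (rmsecv, N, k0)
                if best is None or key < best[:3]:
                    best = (rmsecv, N, k0, tuple(sel))
        assert res.rmsecv == pytest.approx(best[0], abs=1e-12)
        assert (res.n_selected, res.k0, res.selected) == (best[1], best[2], best[3])

    def test_planted_two_band_target_recovered(self, rng):
        X = rng.normal(size=(30, 12))
        y = 1.5 * X[:, 2] - 0.7 * X[:, 9] + 3.0
        res = bsel.spa_optimize(X, y, n_max=6, seed=1)
        assert {2, 9} <= set(res.selected)
        assert res.rmsecv < 1e-8
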