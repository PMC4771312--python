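"""Ordination layer: Bray-Curtis, PCA, envfit, dispersion, correlations, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metaltrait.ordination import (
    ZeroVarianceError,
    benjamini_hochberg,
    bray_curtis,
    chi_squared,
    dispersion_test,
    envfit,
    pca,
    spearman_screen,
)


class TestBrayCurtis:
    def test_arithmetic_examples(self):
        D = bray_curtis(np.array([[2.0, 2.0], [1.0, 1.0], [2.0, 2.0], [1.0, 0.0]]))
        assert D.iloc[0, 1] == pytest.approx(1 / 3)
        assert D.iloc[0, 2] == 0.0
        D2 = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert D2.iloc[0, 1] == pytest.approx(1.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ZeroVarianceError):
            bray_curtis(np.array([[1.0, 2.0], [0.0, 0.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(
            np.float64,
            (6, 4),
            elements=st.floats(0, 100, allow_nan=False),
        ).filter(lambda X: (X.sum(axis=1) > 0).all())
    )
    def test_metric_properties(self, X):
        D = bray_curtis(X).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()


class TestPCA:
    def test_rank_one_collinear_data(self):
        x = np.arange(10.0)
        M = pca(np.column_stack([x, 2 * x]))
        assert M.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)

    def test_eigenvalue_sum_is_total_variance(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 6))
        M = pca(X)
        assert M.eigenvalues.sum() == pytest.approx(
            np.var(X, axis=0, ddof=1).sum(), rel=1e-10
        )

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 6))
        M = pca(X)
        Xc = X - X.mean(axis=0)
        rec = M.scores.to_numpy() @ M.loadings.to_numpy().T
        assert np.abs(rec - Xc).max() < 1e-8

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.random((15, 5))
        L = pca(X).loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] > 0

    def test_scale_with_constant_feature_rejected(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ZeroVarianceError):
            pca(X, scale=True)


class TestEnvfit:
    def test_self_fit_r2_one_minimal_p(self):
        rng = np.random.default_rng(4)
        S = rng.random((30, 2))
        r = envfit(S, S[:, 0], n_permutations=999, seed=0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.p_perm == pytest.approx(1 / 1000)

    def test_orthogonal_variable_r2_zero(self):
        n = 16
        S = np.column_stack([np.sin(np.arange(n)), np.cos(np.arange(n))])
        S -= S.mean(axis=0)
        v = np.ones(n)
        v[: n // 2] = -1
        v -= v.mean()
        # project out the (centered) axis span explicitly
        beta, *_ = np.linalg.lstsq(S, v, rcond=None)
        v = v - S @ beta
        r = envfit(S, v, n_permutations=99, seed=0)
        assert r.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_factor_mode_separated_groups(self):
        S = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 5])
        g = np.array(["a"] * 10 + ["b"] * 10)
        r = envfit(S, g, kind="factor", n_permutations=199, seed=1)
        assert r.r_squared > 0.95 and r.p_perm < 0.05

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        S = rng.random((25, 2))
        ps = [
            envfit(S, rng.random(25), n_permutations=99, seed=s).p_perm
            for s in range(200)
        ]
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_variable_rejected(self):
        with pytest.raises(ZeroVarianceError):
            envfit(np.random.default_rng(0).random((10, 2)), np.ones(10))


class TestDispersion:
    def test_translated_clouds_equal_dispersion(self):
        rng = np.random.default_rng(6)
        cloud = rng.random((15, 2))
        S = np.vstack([cloud, cloud + 10.0])
        g = np.array(["a"] * 15 + ["b"] * 15)
        res = dispersion_test(S, g, n_permutations=499, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p_perm > 0.5

    def test_power_at_5_to_1_ratio(self):
        rejections = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            S = np.vstack(
                [rng.normal(0, 5.0, (20, 2)), rng.normal(0, 1.0, (20, 2))]
            )
            g = np.array(["a"] * 20 + ["b"] * 20)
            res = dispersion_test(S, g, n_permutations=199, seed=s)
            rejections += res.p_perm < 0.05
        assert rejections >= 40

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            dispersion_test(np.random.default_rng(0).random((4, 2)), ["a", "b", "b", "b"])


class TestSpearmanChiBH:
    def test_monotone_pairs(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 2, "z": -np.arange(10.0)})
        out = spearman_screen(df, [("x", "y"), ("x", "z")])
        assert out["rho"].tolist() == pytest.approx([1.0, -1.0])

    def test_tied_data_matches_rank_formula(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 4, 10).astype(float)
        y = rng.integers(0, 4, 10).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        out = spearman_screen(df, [("x", "y")])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        want = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"][0] == pytest.approx(want, rel=1e-10)

    def test_constant_flagged_excluded_from_bh(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.ones(10), "z": np.arange(10.0)})
        out = spearman_screen(df, [("x", "y"), ("x", "z")])
        assert out.loc[0, "constant"] and np.isnan(out.loc[0, "q"])
        assert not np.isnan(out.loc[1, "q"])

    def test_chi2_uniform_table(self):
        stat, df, p = chi_squared([[10, 10], [10, 10]])
        assert stat == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_chi2_matches_longhand(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            T = rng.integers(1, 30, (3, 4)).astype(float)
            stat, df, _ = chi_squared(T)
            E = np.outer(T.sum(1), T.sum(0)) / T.sum()
            assert stat == pytest.approx(((T - E) ** 2 / E).sum(), rel=1e-12)
            assert df == 6

    def test_chi2_zero_marginal(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [1, 2]])

    def test_bh_step_up_by_hand(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_bh_order_preserving(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bh_invalid_input(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_bh_empirical_fdr_control(self):
        rng = np.random.default_rng(10)
        fdrs = []
        for _ in range(100):
            null_p = rng.random(80)
            alt_p = rng.beta(0.5, 30, 20)
            p = np.concatenate([null_p, alt_p])
            q = benjamini_hochberg(p)
            sel = q < 0.05
            if sel.sum():
                fdrs.append(sel[:80].sum() / sel.sum())
            else:
                fdrs.append(0.0)
        assert np.mean(fdrs) <= 0.05 + 3 * np.std(fdrs) / np.sqrt(len(fdrs))
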