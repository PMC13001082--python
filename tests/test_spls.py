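"""Sparse PLS: preprocessing, fitting, Q2 selection, sparsity tuning."""

import numpy as np
import pandas as pd
import pytest

from dompaint.spls import (
    CvSpec,
    axis_feature_sets,
    fit_spls,
    predict,
    preprocess_xy,
    q2_total,
    select_ncomponents,
    tune_sparsity,
)


def planted_xy(seed, n=30, pX=40, pY=12, kx=5, ky=3, noise=0.3):
    """Rank-1 latent model with sparse supports; returns blocks + truth."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(n)
    a = np.zeros(pX)
    sup_a = rng.choice(pX, kx, replace=False)
    a[sup_a] = rng.choice([-1.0, 1.0], kx)
    b = np.zeros(pY)
    sup_b = rng.choice(pY, ky, replace=False)
    b[sup_b] = rng.choice([-1.0, 1.0], ky)
    X = np.outer(t, a) + rng.normal(0, noise, (n, pX))
    Y = np.outer(t, b) + rng.normal(0, noise, (n, pY))
    idx = [f"s{i}" for i in range(n)]
    return (
        pd.DataFrame(X, index=idx, columns=[f"x{j}" for j in range(pX)]),
        pd.DataFrame(Y, index=idx, columns=[f"y{j}" for j in range(pY)]),
        {f"x{j}" for j in sup_a},
        {f"y{j}" for j in sup_b},
    )


def dense_pls_oracle(X, Y):
    """First dense PLS component = leading singular pair of Xc'Yc."""
    xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
    u, _, vt = np.linalg.svd(xc.T @ yc, full_matrices=False)
    u0, v0 = u[:, 0], vt[0]
    if u0[np.argmax(np.abs(u0))] < 0:
        u0, v0 = -u0, -v0
    return u0, v0


class TestPreprocess:
    def make(self, seed=0, n=10, pX=6, pY=4):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        x = pd.DataFrame(rng.random((n, pX)) + 0.1, index=idx,
                         columns=[f"x{j}" for j in range(pX)])
        y = pd.DataFrame(rng.normal(size=(n, pY)), index=idx,
                         columns=[f"y{j}" for j in range(pY)])
        return x, y

    def test_constant_peak_column_dropped(self):
        x, y = self.make()
        # make x0 a fixed fraction of each row total: constant after TIC
        others = x.drop(columns="x0").sum(axis=1)
        x["x0"] = others * 0.25
        with pytest.warns(UserWarning, match="constant"):
            X, _ = preprocess_xy(x, y, row_zscore=False)
        assert "x0" not in X.columns

    def test_unit_variance_columns(self):
        x, y = self.make()
        X, _ = preprocess_xy(x, y, row_zscore=False)
        assert np.allclose(X.std(axis=0, ddof=1), 1.0)

    def test_row_zscore_of_merged_blocks(self):
        x, y = self.make()
        X, Y = preprocess_xy(x, y, row_zscore=True)
        merged = pd.concat([X, Y], axis=1)
        assert np.allclose(merged.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(merged.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_mismatched_samples_rejected(self):
        x, y = self.make()
        with pytest.raises(ValueError, match="only one block"):
            preprocess_xy(x.iloc[:-1], y)


class TestFitSpls:
    def test_rank1_support_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        n, pX, pY = 30, 20, 8
        t = rng.standard_normal(n)
        a = np.zeros(pX); a[[2, 5, 9]] = [1.0, -1.0, 0.5]
        b = np.zeros(pY); b[[1, 4]] = [1.0, -1.0]
        X = pd.DataFrame(np.outer(t, a), columns=[f"x{j}" for j in range(pX)])
        Y = pd.DataFrame(np.outer(t, b), columns=[f"y{j}" for j in range(pY)])
        m = fit_spls(X, Y, ncomp=1, keepX=3, keepY=2)
        assert set(m.selected_x()) == {"x2", "x5", "x9"}
        assert set(m.selected_y()) == {"y1", "y4"}

    def test_dense_limit_equals_pls_oracle(self):
        X, Y, _, _ = planted_xy(1)
        m = fit_spls(X, Y, ncomp=1)
        u0, v0 = dense_pls_oracle(X, Y)
        assert np.abs(m.u[:, 0] - u0).max() < 1e-6
        assert np.abs(m.v[:, 0] - v0).max() < 1e-6

    def test_zero_y_rejected(self):
        X, Y, _, _ = planted_xy(2)
        with pytest.raises(ValueError):
            fit_spls(X, Y * 0.0, ncomp=1)

    def test_loading_norms_and_sparsity(self):
        X, Y, _, _ = planted_xy(3)
        m = fit_spls(X, Y, ncomp=2, keepX=7, keepY=4)
        for h in range(2):
            assert np.linalg.norm(m.u[:, h]) == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(m.v[:, h]) == pytest.approx(1.0, abs=1e-9)
            assert (m.u[:, h] != 0).sum() <= 7
            assert (m.v[:, h] != 0).sum() <= 4

    def test_x_scores_orthogonal(self):
        X, Y, _, _ = planted_xy(4)
        m = fit_spls(X, Y, ncomp=3, keepX=10, keepY=5)
        g = m.xi.T @ m.xi
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-6

    def test_sign_convention_deterministic(self):
        X, Y, _, _ = planted_xy(5)
        m1 = fit_spls(X, Y, ncomp=1, keepX=8, keepY=4)
        m2 = fit_spls(-X, -Y, ncomp=1, keepX=8, keepY=4)
        u = m1.u[:, 0]
        assert u[np.argmax(np.abs(u))] > 0
        u2 = m2.u[:, 0]
        assert u2[np.argmax(np.abs(u2))] > 0

    def test_keep_bounds_validated(self):
        X, Y, _, _ = planted_xy(6)
        with pytest.raises(ValueError):
            fit_spls(X, Y, keepX=0)
        with pytest.raises(ValueError):
            fit_spls(X, Y, keepY=Y.shape[1] + 1)


class TestQ2:
    def test_noise_free_latent_gives_high_q2(self):
        X, Y, _, _ = planted_xy(7, noise=0.01)
        q2 = q2_total(X, Y, ncomp=1, keepX=5, keepY=3, cv=CvSpec(folds=5, repeats=2, seed=0))
        assert q2[0] > 0.9

    def test_null_gives_low_q2(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(30)]
        X = pd.DataFrame(rng.standard_normal((30, 20)), index=idx)
        Y = pd.DataFrame(rng.standard_normal((30, 6)), index=idx)
        q2 = q2_total(X, Y, ncomp=1, keepX=5, keepY=3, cv=CvSpec(folds=5, repeats=2, seed=0))
        assert q2[0] < 0.0975

    def test_fold_count_limits(self):
        X, Y, _, _ = planted_xy(9, n=8)
        with pytest.raises(ValueError):
            q2_total(X, Y, ncomp=1, cv=CvSpec(folds=10, repeats=1))

    def test_press_uses_out_of_fold_rows_only(self):
        """A held-out outlier must not leak into training centering."""
        X, Y, _, _ = planted_xy(10, n=20)
        cv = CvSpec(folds=5, repeats=1, seed=1)
        q2_base = q2_total(X, Y, ncomp=1, keepX=5, keepY=3, cv=cv)
        # corrupting one row changes PRESS only through its own fold's
        # held-out error, not through other folds' training means
        folds = cv.fold_assignments(20)[0]
        target = int(np.flatnonzero(folds == 0)[0])
        X2 = X.copy()
        X2.iloc[target] += 100.0
        q2_shift = q2_total(X2, Y, ncomp=1, keepX=5, keepY=3, cv=cv)
        assert not np.allclose(q2_base, q2_shift)


class TestSelection:
    def test_paper_style_first_component_only(self):
        assert select_ncomponents(np.array([0.13, 0.01, -0.2])) == 1

    def test_leading_run(self):
        assert select_ncomponents(np.array([0.5, 0.2, 0.05])) == 2

    def test_none_retained_warns(self):
        with pytest.warns(UserWarning):
            assert select_ncomponents(np.array([0.01])) == 0

    def test_stops_at_first_failure(self):
        # a later excursion above threshold is not counted
        assert select_ncomponents(np.array([0.5, 0.01, 0.4])) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_ncomponents(np.array([]))


class TestTuneSparsity:
    def test_selects_informative_sparsity(self):
        rng = np.random.default_rng(11)
        n, pX = 40, 30
        t = rng.standard_normal(n)
        X = rng.normal(0, 1.0, (n, pX))
        X[:, 3] = t  # single informative X feature
        Y = np.outer(t, [1.0, -1.0, 0.5]) + rng.normal(0, 0.2, (n, 3))
        Xd = pd.DataFrame(X, columns=[f"x{j}" for j in range(pX)])
        Yd = pd.DataFrame(Y)
        best = tune_sparsity(Xd, Yd, grid=[(1, 3), (pX, 3)],
                             cv=CvSpec(folds=5, repeats=2, seed=0))
        assert best == (1, 3)

    def test_single_point_grid(self):
        X, Y, _, _ = planted_xy(12)
        assert tune_sparsity(X, Y, grid=[(4, 2)], cv=CvSpec(folds=5, repeats=1)) == (4, 2)

    def test_empty_grid_rejected(self):
        X, Y, _, _ = planted_xy(13)
        with pytest.raises(ValueError):
            tune_sparsity(X, Y, grid=[])

    def test_all_noise_no_crash(self):
        rng = np.random.default_rng(14)
        idx = [f"s{i}" for i in range(25)]
        X = pd.DataFrame(rng.standard_normal((25, 10)), index=idx)
        Y = pd.DataFrame(rng.standard_normal((25, 4)), index=idx)
        best = tune_sparsity(X, Y, grid=[(2, 2), (5, 4)], cv=CvSpec(folds=5, repeats=1))
        assert best in [(2, 2), (5, 4)]


class TestAxisFeatureSets:
    def test_split_by_sign_and_disjoint_union(self):
        X, Y, _, _ = planted_xy(15)
        m = fit_spls(X, Y, ncomp=1, keepX=8, keepY=4)
        axes = axis_feature_sets(m)
        neg, pos = set(axes["negative"]), set(axes["positive"])
        assert not neg & pos
        assert neg | pos == set(m.selected_x())
        for f in neg:
            assert m.u[m.x_names.index(f), 0] < 0
        for f in pos:
            assert m.u[m.x_names.index(f), 0] > 0

    def test_out_of_range_component(self):
        X, Y, _, _ = planted_xy(16)
        m = fit_spls(X, Y, ncomp=1)
        with pytest.raises(ValueError):
            axis_feature_sets(m, component=2)


class TestPredict:
    def test_training_fit_quality_noise_free(self):
        X, Y, _, _ = planted_xy(17, noise=0.0)
        m = fit_spls(X, Y, ncomp=1, keepX=5, keepY=3)
        pred = predict(m, X)
        resid = Y.to_numpy() - pred
        ss = (resid**2).sum() / (Y.to_numpy()**2).sum()
        assert ss < 1e-6

    def test_zero_components_predicts_mean(self):
        X, Y, _, _ = planted_xy(18)
        m = fit_spls(X, Y, ncomp=1)
        pred = predict(m, X, ncomp=0)
        assert np.allclose(pred, Y.to_numpy().mean(axis=0))
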