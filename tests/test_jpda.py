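"""Joint-probability MMD construction, eigensolve and the full driver."""

import numpy as np
import pytest
import scipy.linalg

from haradapt.jpda import (
    JPDAConfig,
    build_F,
    build_R,
    ipl_jpda_fit_predict,
    jpda_step,
    one_hot,
)


class TestOneHot:
    def test_basic(self):
        np.testing.assert_array_equal(one_hot([1, 2], 2), [[1, 0], [0, 1]])

    def test_single_class_column(self):
        Y = one_hot([1, 1, 1], 3)
        assert np.all(Y[:, 0] == 1) and np.all(Y[:, 1:] == 0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        Y = one_hot(rng.integers(1, 8, 30), 7)
        np.testing.assert_array_equal(Y.sum(axis=1), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            one_hot([0, 1], 2)


class TestBuildF:
    def test_c2_source_expansion(self):
        """For C=2 each class column is repeated once: Fs is Ys itself."""
        Ys = one_hot([1, 2], 2)
        Fs, _ = build_F(Ys, Ys)
        np.testing.assert_array_equal(Fs, [[1, 0], [0, 1]])

    def test_c2_target_takes_complement_columns(self):
        """Block c of Ft holds the non-c columns: a class-2 row becomes [1, 0]."""
        Yt = one_hot([2], 2)
        _, Ft = build_F(one_hot([1], 2), Yt)
        np.testing.assert_array_equal(Ft, [[1, 0]])

    def test_c7_width_42(self):
        Ys = one_hot(np.arange(1, 8), 7)
        Fs, Ft = build_F(Ys, Ys)
        assert Fs.shape == (7, 42) and Ft.shape == (7, 42)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="C >= 2"):
            build_F(one_hot([1], 1), one_hot([1], 1))

    def test_matches_blockwise_loop(self):
        rng = np.random.default_rng(1)
        C = 4
        Ys = one_hot(rng.integers(1, C + 1, 6), C)
        Yt = one_hot(rng.integers(1, C + 1, 5), C)
        Fs, Ft = build_F(Ys, Yt)
        for c in range(C):
            block = slice(c * (C - 1), (c + 1) * (C - 1))
            np.testing.assert_array_equal(Fs[:, block], np.tile(Ys[:, [c]], (1, C - 1)))
            others = [j for j in range(C) if j != c]
            np.testing.assert_array_equal(Ft[:, block], Yt[:, others])


class TestBuildR:
    def test_psd_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            C = int(rng.integers(2, 6))
            Ys = one_hot(rng.integers(1, C + 1, int(rng.integers(C, 12))), C)
            Yt = one_hot(rng.integers(1, C + 1, int(rng.integers(C, 12))), C)
            Rmin, Rmax = build_R(Ys, Yt)
            for R in (Rmin, Rmax):
                assert np.abs(R - R.T).max() < 1e-12
                assert np.linalg.eigvalsh(R).min() >= -1e-10

    def test_copied_domain_joint_mmd_vanishes(self):
        """Identical domains and labels zero out the same-class MMD kernel."""
        rng = np.random.default_rng(3)
        X0 = rng.normal(size=(5, 8))
        Ys = one_hot(rng.integers(1, 3, 8), 2)
        Rmin, _ = build_R(Ys, Ys)
        X = np.hstack([X0, X0])
        M = X @ Rmin @ X.T
        assert np.abs(M).max() < 1e-9
        A = rng.normal(size=(5, 3))
        assert abs(np.trace(A.T @ M @ A)) < 1e-9

    def test_shape_is_n_by_n(self):
        Rmin, Rmax = build_R(one_hot([1, 2, 1], 2), one_hot([2, 2], 2))
        assert Rmin.shape == Rmax.shape == (5, 5)


class TestJPDAStep:
    def _instance(self, rng, d=6, ns=6, nt=4, C=2):
        X = rng.normal(size=(d, ns + nt))
        Ys = one_hot(rng.integers(1, C + 1, ns), C)
        Yt = one_hot(rng.integers(1, C + 1, nt), C)
        return X, Ys, Yt

    def test_matches_dense_generalized_eig_oracle(self):
        """Trailing eigenvectors equal a dense two-sided solve, 10 instances."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            X, Ys, Yt = self._instance(rng)
            d, n = X.shape
            p = 3
            A, eigs = jpda_step(X, Ys, Yt, mu=0.1, lam=0.1, p=p)
            Rmin, Rmax = build_R(Ys, Yt)
            lhs = X @ (Rmin - 0.1 * Rmax) @ X.T + 0.1 * np.eye(d)
            H = np.eye(n) - np.full((n, n), 1.0 / n)
            rhs = X @ H @ X.T
            lhs = (lhs + lhs.T) / 2
            rhs = (rhs + rhs.T) / 2 + 1e-8 * np.eye(d)
            w, V = scipy.linalg.eig(lhs, rhs)
            order = np.argsort(w.real)[:p]
            np.testing.assert_allclose(np.sort(eigs), np.sort(w.real[order]), atol=1e-8)
            for i, j in enumerate(order):
                v = V[:, j].real
                v /= np.linalg.norm(v)
                v *= np.sign(v[np.abs(v).argmax()])
                a = A[:, i] / np.linalg.norm(A[:, i])
                np.testing.assert_allclose(a, v, atol=1e-8)

    def test_eigenpair_residual_small(self):
        rng = np.random.default_rng(5)
        X, Ys, Yt = self._instance(rng, d=10, ns=15, nt=12, C=3)
        A, eigs = jpda_step(X, Ys, Yt, p=6)
        d, n = X.shape
        Rmin, Rmax = build_R(Ys, Yt)
        lhs = X @ (Rmin - 0.1 * Rmax) @ X.T + 0.1 * np.eye(d)
        H = np.eye(n) - np.full((n, n), 1.0 / n)
        rhs = X @ H @ X.T
        lhs = (lhs + lhs.T) / 2
        rhs = (rhs + rhs.T) / 2 + 1e-8 * np.eye(d)
        for i in range(A.shape[1]):
            a = A[:, i]
            res = np.linalg.norm(lhs @ a - eigs[i] * rhs @ a) / np.linalg.norm(a)
            assert res <= 1e-6

    def test_zero_mu_identical_domains_objective_zero(self):
        """With no shift and mu=0 the optimal alignment objective vanishes."""
        rng = np.random.default_rng(6)
        X0 = rng.normal(size=(6, 8))
        Ys = one_hot(rng.integers(1, 3, 8), 2)
        X = np.hstack([X0, X0])
        A, _ = jpda_step(X, Ys, Ys, mu=1e-12, lam=0.1, p=3)
        Rmin, _ = build_R(Ys, Ys)
        assert abs(np.trace(A.T @ X @ Rmin @ X.T @ A)) < 1e-9

    def test_contract(self):
        rng = np.random.default_rng(7)
        X, Ys, Yt = self._instance(rng)
        A, _ = jpda_step(X, Ys, Yt, p=4)
        assert A.shape == (6, 4)
        assert np.all(np.isfinite(A))


class TestDriver:
    def test_copied_domain_is_fixed_point_at_full_accuracy(self, two_domain):
        Xs, ys, _, _ = two_domain
        cfg = JPDAConfig(T=4)
        res = ipl_jpda_fit_predict(Xs, ys, Xs.copy(), cfg, y_true=ys)
        assert np.array_equal(res.labels, ys)
        assert res.accuracy_history[-1] == 1.0
        assert len(res.history) == 4
        # once converged the labels stop moving
        assert np.array_equal(res.history[-1], res.history[-2])

    def test_t1_returns_improved_pseudo_labels_only(self, two_domain):
        Xs, ys, Xt, _ = two_domain
        res = ipl_jpda_fit_predict(Xs, ys, Xt, JPDAConfig(T=1))
        assert res.A is None
        assert len(res.history) == 1

    def test_source_permutation_invariance(self, two_domain):
        """A global permutation of source columns leaves predictions alone."""
        Xs, ys, Xt, _ = two_domain
        cfg = JPDAConfig(T=3)
        base = ipl_jpda_fit_predict(Xs, ys, Xt, cfg)
        rng = np.random.default_rng(8)
        perm = rng.permutation(Xs.shape[1])
        permuted = ipl_jpda_fit_predict(Xs[:, perm], ys[perm], Xt, cfg)
        assert np.mean(permuted.labels == base.labels) >= 0.99

    def test_beats_raw_nearest_neighbour_on_shifted_cohort(self, two_domain):
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        Xs, ys, Xt, yt = two_domain
        clf = make_pipeline(StandardScaler(), KNeighborsClassifier(1))
        clf.fit(Xs.T, ys)
        base_acc = np.mean(clf.predict(Xt.T) == yt)
        res = ipl_jpda_fit_predict(Xs, ys, Xt, y_true=yt)
        assert np.mean(res.labels == yt) >= base_acc - 1e-12

    def test_mmd_diagnostic_recorded(self, two_domain):
        Xs, ys, Xt, _ = two_domain
        res = ipl_jpda_fit_predict(Xs, ys, Xt, JPDAConfig(T=3))
        assert len(res.mmd) == 3
        assert np.isnan(res.mmd[0]) and all(np.isfinite(res.mmd[1:]))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [dict(mu=0.0), dict(lam=-0.1), dict(T=0)])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            JPDAConfig(**kwargs)
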