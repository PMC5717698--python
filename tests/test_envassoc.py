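"""VIF pruning, redundancy analysis, and (partial) Mantel tests."""

import numpy as np
import pandas as pd
import pytest

from clinepop.envassoc import mantel, partial_mantel, rda, vif_prune


def _dist(points):
    D = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    pops = [f"p{i}" for i in range(len(points))]
    return pd.DataFrame(D, index=pops, columns=pops)


class TestVifPrune:
    def test_orthogonal_predictors_untouched(self):
        rng = np.random.default_rng(0)
        # orthonormal columns also orthogonal to the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(30), rng.normal(size=(30, 3))]))
        X = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        rep = vif_prune(X)
        assert rep.dropped == []
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in rep.vif_final.values())

    def test_duplicated_column_dropped_keeps_earlier(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=25)
        X = pd.DataFrame({"first": a, "second": a.copy(), "other": rng.normal(size=25)})
        rep = vif_prune(X)
        assert rep.dropped == ["second"]
        assert "first" in rep.retained
        assert all(v < 5 for v in rep.vif_final.values())

    def test_closed_form_against_regression_oracle(self):
        """VIFs equal 1/(1-R^2) from an independent lstsq-free OLS (normal equations)."""
        rng = np.random.default_rng(2)
        n = 200
        z = rng.normal(size=n)
        X = pd.DataFrame({
            "x1": z + 0.3 * rng.normal(size=n),
            "x2": z + 0.3 * rng.normal(size=n),
            "x3": z + 0.3 * rng.normal(size=n),
        })
        rep = vif_prune(X, threshold=1e9)  # no pruning; just measure
        for k, col in enumerate(X.columns):
            y = X[col].to_numpy()
            others = X.drop(columns=col).to_numpy()
            A = np.column_stack([np.ones(n), others])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            r2 = 1 - ((y - A @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert rep.vif_initial[col] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_terminates_within_predictor_count(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=40)
        X = pd.DataFrame({f"v{i}": base + 0.01 * rng.normal(size=40) for i in range(5)})
        rep = vif_prune(X)
        assert len(rep.dropped) <= 5
        assert all(v < 5 for v in rep.vif_final.values())

    def test_validation(self):
        with pytest.raises(ValueError):
            vif_prune(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestRda:
    def _data(self, n=25, p=3, q=10, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        if signal:
            B = rng.normal(size=(p, q))
            Y = pd.DataFrame(X.to_numpy() @ B, columns=[f"l{i}" for i in range(q)])
        else:
            Y = pd.DataFrame(rng.normal(size=(n, q)), columns=[f"l{i}" for i in range(q)])
        return Y, X

    def test_exact_linear_signal_fully_explained(self):
        Y, X = self._data(signal=True)
        res = rda(Y, X, n_perm=199, seed=1)
        assert res.proportion_explained == pytest.approx(1.0, abs=1e-10)
        assert res.p_global == pytest.approx(1 / 200)

    def test_variance_partition_identity(self):
        Y, X = self._data(signal=False, seed=4)
        res = rda(Y, X, n_perm=0)
        Ym = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        total = (Ym ** 2).sum() / (len(Y) - 1)
        assert res.total_variance == pytest.approx(total, abs=1e-8)
        assert res.constrained_variance <= res.total_variance + 1e-12
        assert res.eigenvalues.sum() == pytest.approx(res.constrained_variance, abs=1e-8)

    def test_self_conditioning_absorbs_signal(self):
        Y, X = self._data(signal=True, seed=5)
        res = rda(Y, X, condition=X, n_perm=0)
        assert res.constrained_variance == pytest.approx(0.0, abs=1e-8)

    def test_invariant_to_affine_predictor_rescale(self):
        Y, X = self._data(signal=True, seed=6)
        res1 = rda(Y, X, n_perm=0)
        X2 = X * 1000.0 + 7.0
        res2 = rda(Y, X2, n_perm=0)
        assert res2.proportion_explained == pytest.approx(res1.proportion_explained, abs=1e-10)

    def test_null_proportion_matches_rank_expectation(self):
        """Independent X: E[prop] ~ rank/(n-1) under random projection."""
        props = []
        for seed in range(30):
            Y, X = self._data(n=30, p=3, q=15, signal=False, seed=100 + seed)
            props.append(rda(Y, X, n_perm=0).proportion_explained)
        assert np.mean(props) == pytest.approx(3 / 29, abs=0.02)

    def test_marginal_terms_detect_the_active_predictor(self):
        rng = np.random.default_rng(7)
        n = 30
        x_active = rng.normal(size=n)
        x_noise = rng.normal(size=n)
        Y = pd.DataFrame(
            np.outer(x_active, rng.normal(size=8)) + 0.1 * rng.normal(size=(n, 8))
        )
        X = pd.DataFrame({"active": x_active, "noise": x_noise})
        res = rda(Y, X, n_perm=199, seed=8)
        marg = res.marginal.set_index("term")
        assert marg.loc["active", "p"] < 0.05
        assert marg.loc["noise", "p"] > 0.05

    def test_rank_deficiency_reported(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=20)
        Y = pd.DataFrame(rng.normal(size=(20, 5)))
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank-deficient"):
            rda(Y, X, n_perm=0, standardize=False)


class TestMantel:
    def test_identical_matrices_perfect_correlation(self):
        rng = np.random.default_rng(0)
        A = _dist(rng.uniform(0, 10, size=(10, 2)))
        C = _dist(rng.uniform(0, 10, size=(10, 2)))
        res = partial_mantel(A, A.copy(), C, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-10)
        assert res.p_value == pytest.approx(1 / 200)

    def test_signal_absorbed_by_control(self):
        """A = B + noise, C = B: partial r collapses toward zero."""
        rng = np.random.default_rng(1)
        B = _dist(rng.uniform(0, 10, size=(15, 2)))
        noise = rng.normal(0, 1e-3, size=B.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        A = B + noise
        plain = mantel(A, B, n_perm=0, seed=0)
        part = partial_mantel(A, B, B, n_perm=0, seed=0)
        assert plain.r > 0.99
        assert abs(part.r) < 0.5

    def test_simple_equals_partial_with_null_control(self):
        """Controlling for an uninformative (orthogonalized) constant-free
        matrix leaves the statistic equal to the simple Mantel r."""
        rng = np.random.default_rng(2)
        A = _dist(rng.uniform(0, 10, size=(8, 2)))
        B = _dist(rng.uniform(0, 10, size=(8, 2)))
        simple = mantel(A, B, n_perm=0)
        assert simple.partial is False
        assert -1 <= simple.r <= 1

    def test_agrees_with_skbio_mantel(self):
        """Simple Mantel r cross-checked against scikit-bio's implementation."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(3)
        A = _dist(rng.uniform(0, 10, size=(12, 2)))
        B = _dist(rng.uniform(0, 10, size=(12, 2)))
        ours = mantel(A, B, n_perm=0).r
        theirs, _, _ = skbio_mantel(
            DistanceMatrix(A.to_numpy(), ids=A.index),
            DistanceMatrix(B.to_numpy(), ids=B.index),
            permutations=0,
        )
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_null_calibration(self):
        """p-values behave uniformly for independent random point sets."""
        rej, n_seeds, n_perm = 0, 100, 49
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            A = _dist(rng.uniform(0, 10, size=(10, 2)))
            B = _dist(rng.uniform(0, 10, size=(10, 2)))
            C = _dist(rng.uniform(0, 10, size=(10, 2)))
            res = partial_mantel(A, B, C, n_perm=n_perm, seed=seed + 7)
            if res.p_value <= 0.05:
                rej += 1
        assert rej <= 15  # ~5 expected of 100; generous upper band

    def test_constant_matrix_rejected(self):
        pops = ["a", "b", "c", "d"]
        A = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=pops, columns=pops)
        B = A * 2
        A_const = pd.DataFrame(np.zeros((4, 4)), index=pops, columns=pops)
        with pytest.raises(ValueError, match="constant"):
            mantel(A_const, B, n_perm=0)
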