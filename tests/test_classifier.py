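"""Shrinkage covariance and regularized LDA."""

import numpy as np
import pytest

from erpspell.classifier import (RLDAModel, analytic_shrinkage_covariance,
                                 rlda_score, train_rlda)

# frozen oracle values: independent loop evaluation of the shrinkage
# formulas on fixed integer matrices (see the fixture matrices below)
FIXTURE_SMALL = np.array([[1, 2, 0], [0, 1, 1], [2, 0, 1], [1, 1, 0]],
                         dtype=float)
SMALL_GAMMA = 1.0                      # numerator exceeds denominator
SMALL_NU = 0.5555555555555555

FIXTURE_LARGE = np.array([
    [-2, 1, -3, -2], [-1, -1, 3, 2], [3, 3, -3, -3], [3, -3, -2, -2],
    [3, -1, -2, -2], [0, 1, 2, 1], [3, -3, 0, 0], [1, -3, -2, 0],
    [-3, 3, 1, 2], [0, 1, -1, -1], [-3, -2, 2, 0], [2, -2, 2, 3],
    [2, -2, -1, -2], [2, 2, 0, -2], [-3, -2, -2, -3], [2, 0, 3, -2],
    [-1, 3, 1, -1], [-1, 2, -1, 0], [0, 0, 0, 3], [-2, 3, -2, -3]],
    dtype=float)
LARGE_GAMMA = 0.75923224151619628
LARGE_NU = 4.2934210526315786


def shrinkage_oracle(X):
    """Independent loop implementation of the analytic-shrinkage
    formulas (column-centered data, divide-by-(n-1) covariance)."""
    X = np.asarray(X, float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            S[i, j] = sum(Xc[k, i] * Xc[k, j] for k in range(n)) / (n - 1)
    nu = np.trace(S) / p
    num = 0.0
    for i in range(p):
        for j in range(p):
            w = [Xc[k, i] * Xc[k, j] for k in range(n)]
            wbar = float(np.mean(w))
            num += n / (n - 1) ** 3 * sum((wk - wbar) ** 2 for wk in w)
    den = sum((S[i, j] - (nu if i == j else 0.0)) ** 2
              for i in range(p) for j in range(p))
    gamma = 1.0 if den == 0 else min(1.0, max(0.0, num / den))
    return gamma, nu, (1 - gamma) * S + gamma * nu * np.eye(p)


class TestAnalyticShrinkage:
    @pytest.mark.parametrize("X,gamma,nu", [
        (FIXTURE_SMALL, SMALL_GAMMA, SMALL_NU),
        (FIXTURE_LARGE, LARGE_GAMMA, LARGE_NU),
    ])
    def test_frozen_fixture_regression(self, X, gamma, nu):
        cov = analytic_shrinkage_covariance(X)
        assert cov.gamma == pytest.approx(gamma, abs=1e-12)
        assert cov.nu == pytest.approx(nu, abs=1e-12)
        _, _, sigma = shrinkage_oracle(X)
        assert np.allclose(cov.sigma_hat, sigma, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle_on_random_input(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((int(rng.integers(5, 25)),
                                 int(rng.integers(2, 6))))
        cov = analytic_shrinkage_covariance(X)
        gamma, nu, sigma = shrinkage_oracle(X)
        assert cov.gamma == pytest.approx(gamma, abs=1e-10)
        assert np.allclose(cov.sigma_hat, sigma, atol=1e-10)

    def test_trace_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 10))
        cov = analytic_shrinkage_covariance(X)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / (X.shape[0] - 1)
        assert np.trace(cov.sigma_hat) == pytest.approx(np.trace(S),
                                                        abs=1e-8)

    def test_spherical_input_gives_gamma_one(self):
        # centered data with S exactly nu*I -> denominator 0 -> gamma 1
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        cov = analytic_shrinkage_covariance(X)
        assert cov.gamma == 1.0
        assert np.allclose(cov.sigma_hat, cov.nu * np.eye(2))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            analytic_shrinkage_covariance(np.ones((1, 3)))

    def test_gamma_shrinks_with_more_data(self):
        """More samples -> less shrinkage needed, on average."""
        rng = np.random.default_rng(7)
        p = 50
        A = rng.standard_normal((p, p))
        cov_true = A @ A.T / p
        L = np.linalg.cholesky(cov_true)
        means = []
        for n in (20, 200, 2000):
            gs = [analytic_shrinkage_covariance(
                rng.standard_normal((n, p)) @ L.T).gamma
                for _ in range(3)]
            means.append(np.mean(gs))
        assert means[0] > means[1] > means[2]


class TestTrainRlda:
    def test_separable_single_feature(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.repeat([1, 0], n // 2)
        X = 0.01 * rng.standard_normal((n, 3))
        X[:, 0] += np.where(y == 1, 1.0, -1.0)
        model = train_rlda(X, y)
        assert np.all((model.score(X) > 0) == (y == 1))
        assert abs(model.w[0]) > 5 * np.abs(model.w[1:]).max()

    def test_identical_class_means_give_zero_weights(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [1.0, 2.0], [3.0, 4.0]])
        model = train_rlda(X, [1, 1, 0, 0])
        assert np.allclose(model.w, 0.0)
        assert np.allclose(model.score(X), 0.0)

    def test_weights_match_direct_solve_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 3))
        y = np.array([1, 0, 1, 0, 0, 1, 0, 0])
        model = train_rlda(X, y)
        mu_t, mu_nt = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
        Xw = X.copy()
        Xw[y == 1] -= mu_t
        Xw[y == 0] -= mu_nt
        # direct evaluation on the already-centered pooled data
        n, p = Xw.shape
        S = Xw.T @ Xw / (n - 1)
        nu = np.trace(S) / p
        num = 0.0
        for i in range(p):
            for j in range(p):
                w = Xw[:, i] * Xw[:, j]
                num += n / (n - 1) ** 3 * np.sum((w - w.mean()) ** 2)
        den = np.sum((S - nu * np.eye(p)) ** 2)
        gamma = min(1.0, max(0.0, num / den))
        sigma = (1 - gamma) * S + gamma * nu * np.eye(p)
        w_oracle = np.linalg.solve(sigma, mu_t - mu_nt)
        assert np.allclose(model.w, w_oracle, atol=1e-8)
        assert model.b == pytest.approx(
            -0.5 * w_oracle @ (mu_t + mu_nt), abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_rlda(np.ones((4, 2)), [1, 1, 1, 1])

    def test_class_imbalance_one_to_five(self):
        """The speller's natural 2:10 target:non-target ratio."""
        rng = np.random.default_rng(9)
        n = 240
        y = (np.arange(n) % 12 < 2).astype(int)
        X = rng.standard_normal((n, 6))
        X[y == 1, 0] += 4.0
        model = train_rlda(X, y)
        scores = model.score(X)
        assert scores[y == 1].mean() > 0 > scores[y == 0].mean()
        acc = np.mean((scores > 0) == (y == 1))
        assert acc > 0.9

    def test_scale_equivariance_of_decisions(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((60, 4))
        y = (np.arange(60) % 3 == 0).astype(int)
        X[y == 1] += 0.5
        m1 = train_rlda(X, y)
        m2 = train_rlda(10.0 * X, y)
        s1, s2 = m1.score(X), m2.score(10.0 * X)
        assert np.array_equal(np.sign(s1), np.sign(s2))
        ratio = s2[np.abs(s1) > 1e-9] / s1[np.abs(s1) > 1e-9]
        assert np.all(ratio > 0)


class TestScoring:
    @pytest.fixture
    def model(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 5))
        y = (np.arange(50) % 5 == 0).astype(int)
        X[y == 1] += 1.0
        return train_rlda(X, y)

    def test_class_mean_scores_are_symmetric(self, model):
        st = model.score(model.mu_target[None, :])[0]
        snt = model.score(model.mu_nontarget[None, :])[0]
        assert st == pytest.approx(-snt, abs=1e-10)
        half = 0.5 * model.w @ (model.mu_target - model.mu_nontarget)
        assert st == pytest.approx(half, abs=1e-10)

    def test_midpoint_scores_zero(self, model):
        mid = 0.5 * (model.mu_target + model.mu_nontarget)
        assert model.score(mid[None, :])[0] == pytest.approx(0.0, abs=1e-10)

    def test_batch_equals_per_row(self, model):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((7, 5))
        batch = rlda_score(model, X)
        rows = np.array([rlda_score(model, X[i:i + 1])[0]
                         for i in range(7)])
        assert np.allclose(batch, rows)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="features"):
            model.score(np.ones((3, 4)))

    def test_json_roundtrip(self, model, tmp_path):
        p = tmp_path / "model.json"
        model.to_json(p)
        back = RLDAModel.from_json(p)
        assert np.allclose(back.w, model.w)
        assert back.b == pytest.approx(model.b)
        assert back.gamma == pytest.approx(model.gamma)
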