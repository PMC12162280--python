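import numpy as np
import pytest

from mksvrb.easymkl import (
    decision_scores,
    fit_mkmodel,
    kernel_weights,
    risk,
    solve_gamma,
)
from mksvrb.kernels import KernelSpec, gram


def random_psd(n: int, rng: np.random.Generator) -> np.ndarray:
    B = rng.standard_normal((n, n))
    return B @ B.T


def quadratic_objective(K, labels, phi, gamma):
    y = np.asarray(labels, dtype=float)
    A = (1 - phi) * (y[:, None] * K * y[None, :]) + phi * np.eye(len(y))
    return float(gamma @ A @ gamma)


def grid_minimum_n4(K, labels, phi, step=1e-3):
    """Brute-force oracle for n=4, 2 per class: minimize over (a, b) in [0,1]^2
    with gamma = (a, 1-a) on the positive pair and (b, 1-b) on the negative."""
    y = np.asarray(labels, dtype=float)
    A = (1 - phi) * (y[:, None] * K * y[None, :]) + phi * np.eye(4)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == -1)
    c = np.zeros(4)
    c[pos[1]] = 1.0
    c[neg[1]] = 1.0
    u = np.zeros(4)
    u[pos[0]], u[pos[1]] = 1.0, -1.0
    v = np.zeros(4)
    v[neg[0]], v[neg[1]] = 1.0, -1.0
    a = np.arange(0.0, 1.0 + step / 2, step)
    A_, B_ = np.meshgrid(a, a, indexing="ij")
    obj = (
        c @ A @ c
        + 2 * A_ * (u @ A @ c)
        + 2 * B_ * (v @ A @ c)
        + A_**2 * (u @ A @ u)
        + B_**2 * (v @ A @ v)
        + 2 * A_ * B_ * (u @ A @ v)
    )
    return float(obj.min())


class TestSolveGamma:
    @pytest.mark.parametrize("n_pos, n_neg", [(2, 1), (3, 5), (1, 7), (10, 10)])
    def test_phi_one_closed_form_uniform_per_class(self, n_pos, n_neg):
        rng = np.random.default_rng(n_pos * 10 + n_neg)
        n = n_pos + n_neg
        labels = np.array([1] * n_pos + [-1] * n_neg)
        res = solve_gamma(random_psd(n, rng), labels, phi=1.0)
        expected = np.where(labels == 1, 1.0 / n_pos, 1.0 / n_neg)
        np.testing.assert_allclose(res.gamma, expected, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_feasibility_per_class_simplices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 200))
        labels = np.where(rng.random(n) < 0.4, 1, -1)
        if abs(labels.sum()) == n:
            labels[0] = -labels[0]
        res = solve_gamma(random_psd(n, rng), labels, phi=float(rng.random()))
        g = res.gamma
        assert (g >= -1e-12).all()
        assert g[labels == 1].sum() == pytest.approx(1.0, abs=1e-6)
        assert g[labels == -1].sum() == pytest.approx(1.0, abs=1e-6)
        assert np.abs(g).sum() == pytest.approx(2.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_grid_oracle_n4(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1, 1, -1, -1])
        K = random_psd(4, rng)
        res = solve_gamma(K, labels, phi=0.5)
        oracle = grid_minimum_n4(K, labels, 0.5)
        assert res.objective <= oracle + 1e-3

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(11)
        labels = np.array([1] * 8 + [-1] * 12)
        res = solve_gamma(random_psd(20, rng), labels, phi=0.3)
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-10).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            solve_gamma(np.eye(3), np.array([1, 1, 1]))

    def test_non_finite_kernel_rejected(self):
        K = np.eye(3)
        K[0, 1] = np.nan
        with pytest.raises(ValueError):
            solve_gamma(K, np.array([1, 1, -1]))


class TestKernelWeights:
    def test_identical_grams_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        K = random_psd(6, rng)
        labels = np.array([1, 1, 1, -1, -1, -1])
        gamma = solve_gamma(K, labels).gamma
        eta = kernel_weights(gamma, labels, [K, K, K, K])
        np.testing.assert_allclose(eta, 0.25, atol=1e-12)

    def test_single_gram_weight_one(self):
        labels = np.array([1, -1])
        eta = kernel_weights(np.array([1.0, 1.0]), labels, [np.eye(2)])
        np.testing.assert_allclose(eta, [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * 5 + [-1] * 5)
        gamma = np.concatenate([np.full(5, 0.2), np.full(5, 0.2)])
        grams = [random_psd(10, rng) for _ in range(3)]
        eta = kernel_weights(gamma, labels, grams)
        assert eta.sum() == pytest.approx(1.0, abs=1e-8)
        assert (eta >= 0).all()


class TestMkModel:
    def test_separable_toy_scores_match_label_signs(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        scores = decision_scores(model, X)
        assert np.all(np.sign(scores) == y)

    def test_single_kernel_subset_gives_unit_weight(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("gaussian",))
        np.testing.assert_allclose(model.eta, [1.0])

    def test_label_mirroring_negates_scores(self, separable_xy):
        X, y = separable_xy
        m1 = fit_mkmodel(X, y, ("linear", "gaussian"))
        m2 = fit_mkmodel(X, -y, ("linear", "gaussian"))
        Xnew = np.linspace(-2, 2, 9)[:, None]
        np.testing.assert_allclose(
            decision_scores(m1, Xnew), -decision_scores(m2, Xnew), atol=1e-8
        )

    def test_duplicated_test_row_scores_identically(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear", "polynomial"))
        row = np.array([[0.3]])
        s = decision_scores(model, np.vstack([row, row]))
        assert s[0] == s[1]

    def test_gamma_weighted_class_mean_margin_nonnegative(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        s = decision_scores(model, X) + model.bias  # unbiased scores
        pos_mean = float(model.gamma[y == 1] @ s[y == 1])
        neg_mean = float(model.gamma[y == -1] @ s[y == -1])
        assert pos_mean - neg_mean >= -1e-10

    def test_dimension_mismatch_rejected(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        with pytest.raises(ValueError, match="dimension"):
            decision_scores(model, np.ones((3, 2)))

    def test_two_stage_weights_track_informative_kernel(self):
        """With one informative and one pure-noise feature block, the kernel
        restricted to the informative block should carry more weight."""
        rng = np.random.default_rng(3)
        signal = np.concatenate([1 + 0.3 * rng.standard_normal(15),
                                 -1 + 0.3 * rng.standard_normal(15)])
        y = np.array([1] * 15 + [-1] * 15)
        X = signal[:, None]
        grams = [
            gram(KernelSpec("linear"), X, X),
            gram(KernelSpec("gaussian", sigma=100.0), X, X),  # ~identity: uninformative
        ]
        gamma = solve_gamma(sum(grams) / 2, y).gamma
        eta = kernel_weights(gamma, y, grams)
        assert eta[0] > eta[1]


class TestRisk:
    def test_risks_in_unit_interval_and_monotone_in_score(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        wide = np.linspace(-5, 5, 21)[:, None]
        r_wide = risk(model, wide)
        assert ((r_wide > 0) & (r_wide < 1)).all()
        # strict monotonicity over the unsaturated training score range
        r = risk(model, X)
        s = decision_scores(model, X)
        order = np.argsort(s)
        assert (np.diff(r[order]) > 0).all()

    def test_half_risk_score_closed_form(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        s_half = -model.platt_b / model.platt_a
        # invert the score map approximately via a fine grid
        grid = np.linspace(-5, 5, 20001)[:, None]
        s = decision_scores(model, grid)
        j = int(np.argmin(np.abs(s - s_half)))
        assert risk(model, grid[j : j + 1])[0] == pytest.approx(0.5, abs=0.01)

    def test_positive_class_has_higher_mean_risk(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        r = risk(model, X)
        assert r[y == 1].mean() > r[y == -1].mean()

    def test_uncalibrated_model_rejected(self, separable_xy):
        X, y = separable_xy
        model = fit_mkmodel(X, y, ("linear",))
        model.platt_a = None
        with pytest.raises(ValueError):
            risk(model, X)
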