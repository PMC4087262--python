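"""SVM geometry and QP oracle, ELM least-squares optimality, CSP recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

import tfpbci as t
from tfpbci.classify import (
    ClassifierSpec,
    CspModel,
    csp_classify,
    csp_features,
    csp_fit,
    elm_fit,
    elm_predict,
    svm_fit,
    svm_objective,
    svm_predict,
)
from tfpbci.errors import ClassifierError


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


def dual_qp_svm(X, y, C):
    """Independent oracle: solve the SVM dual QP with SLSQP.

    maximize sum(a) - 1/2 sum_ij a_i a_j y_i y_j <x_i, x_j>
    s.t. 0 <= a_i <= C, sum(a_i y_i) = 0; returns (w, b, primal objective).
    """
    y = np.where(y == np.unique(y)[1], 1.0, -1.0)
    K = (X * y[:, None]) @ (X * y[:, None]).T
    n = len(y)

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    res = minimize(
        neg_dual,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=lambda a: K @ a - 1.0,
        bounds=[(0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y},
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    w = ((a * y)[:, None] * X).sum(axis=0)
    on_margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if on_margin.any():
        b = float(np.mean(y[on_margin] - X[on_margin] @ w))
    else:
        b = 0.0
    xi = np.maximum(0, 1 - y * (X @ w + b))
    return w, b, 0.5 * w @ w + C * xi.sum()


class TestSvm:
    def test_separable_toy_geometry(self):
        """Classes at x1 = 0 and x1 = 2: boundary x1 = 1, w along (1, 0)."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array([-1, -1, 1, 1])
        model = svm_fit(X, y, C=1e6)
        w = model.weights
        assert abs(w[1]) < 1e-6 * abs(w[0])
        # margin 1 on each side: w = (1, 0), b = -1
        assert w[0] == pytest.approx(1.0, rel=1e-3)
        assert model.bias == pytest.approx(-1.0, rel=1e-3)
        assert np.array_equal(svm_predict(model, X), y)

    def test_separable_training_accuracy_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 1, (20, 4)), rng.normal(3, 1, (20, 4))])
        y = np.repeat([0, 1], 20)
        model = svm_fit(X, y, C=1e6)
        assert np.mean(svm_predict(model, X) == y) == 1.0

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_objective_matches_qp_oracle(self, C):
        """Primal objective agrees with an independent dual-QP solve."""
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(-1, 1, (8, 3)), rng.normal(1, 1, (8, 3))])
        y = np.repeat([0, 1], 8)
        model = svm_fit(X, y, C=C)
        obj = svm_objective(model, X, y)
        _, _, obj_oracle = dual_qp_svm(X, y, C)
        assert obj == pytest.approx(obj_oracle, abs=1e-3)

    def test_decision_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 6))
        y = (X[:, 0] + 0.2 * rng.standard_normal(30) > 0).astype(int)
        model = svm_fit(X, y)
        perm = rng.permutation(6)
        model_p = svm_fit(X[:, perm], y)
        assert np.allclose(model_p.weights, model.weights[perm], atol=1e-6)
        assert np.array_equal(svm_predict(model_p, X[:, perm]),
                              svm_predict(model, X))

    def test_single_class_rejected(self):
        with pytest.raises(ClassifierError):
            svm_fit(np.zeros((4, 2)), np.zeros(4))


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------


class TestElm:
    def test_interpolates_when_hidden_equals_samples(self):
        """Square full-rank H: zero training error."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        model = elm_fit(X, y, n_hidden=20, rng_seed=1)
        assert np.mean(elm_predict(model, X) == y) == 1.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = (X[:, 0] > 0).astype(int)
        Xt = rng.standard_normal((10, 4))
        a = elm_predict(elm_fit(X, y, n_hidden=15, rng_seed=7), Xt)
        b = elm_predict(elm_fit(X, y, n_hidden=15, rng_seed=7), Xt)
        assert np.array_equal(a, b)

    def test_output_weights_are_least_squares_optimum(self):
        """No random perturbation of beta reduces the residual ||H beta - T||."""
        from tfpbci.classify import _elm_hidden

        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        model = elm_fit(X, y, n_hidden=10, rng_seed=3)
        H = _elm_hidden(model.input_weights, model.biases, X, model.activation)
        T = np.where(y[:, None] == model.classes[None, :], 1.0, -1.0)
        base = np.linalg.norm(H @ model.output_weights - T)
        for _ in range(100):
            delta = rng.standard_normal(model.output_weights.shape)
            delta *= 1e-2 / np.linalg.norm(delta)
            perturbed = np.linalg.norm(H @ (model.output_weights + delta) - T)
            assert perturbed >= base - 1e-12

    def test_residual_nonincreasing_in_hidden_count(self):
        """Least-squares residual over nested hidden-node subsets of one
        fitted layer never increases as nodes are added."""
        from tfpbci.classify import _elm_hidden

        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 5))
        y = (X @ rng.standard_normal(5) > 0).astype(int)
        model = elm_fit(X, y, n_hidden=30, rng_seed=4)
        H = _elm_hidden(model.input_weights, model.biases, X, model.activation)
        T = np.where(y[:, None] == model.classes[None, :], 1.0, -1.0)
        prev = np.inf
        for k in (1, 5, 10, 20, 30):
            beta, *_ = np.linalg.lstsq(H[:, :k], T, rcond=None)
            resid = np.linalg.norm(H[:, :k] @ beta - T)
            assert resid <= prev + 1e-9
            prev = resid

    def test_invalid_hidden_count_rejected(self):
        with pytest.raises(ClassifierError):
            elm_fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]), n_hidden=0)


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------


def _planted_trials(seed, n_trials=100, n_time=200, cov_a=(4.0, 1.0),
                    cov_b=(1.0, 4.0)):
    rng = np.random.default_rng(seed)
    trials, labels = [], []
    for covd, lab in ((cov_a, 0), (cov_b, 1)):
        sd = np.sqrt(np.asarray(covd))
        for _ in range(n_trials):
            trials.append(sd[:, None] * rng.standard_normal((2, n_time)))
            labels.append(lab)
    return trials, np.array(labels)


class TestCsp:
    def test_recovers_planted_axes(self):
        """diag(4,1) vs diag(1,4): filters align with the coordinate axes."""
        trials, labels = _planted_trials(0)
        model = csp_fit(trials, labels, n_components=2)
        axes = np.eye(2)
        for k in range(2):
            f = model.filters[:, k] / np.linalg.norm(model.filters[:, k])
            cosines = [abs(f @ ax) for ax in axes]
            assert max(cosines) >= 0.95

    def test_eigvals_in_unit_interval_and_pair(self):
        trials, labels = _planted_trials(1)
        m1 = csp_fit(trials, labels, n_components=2)
        m2 = csp_fit(trials, 1 - labels, n_components=2)
        assert np.all((m1.eigvals >= 0) & (m1.eigvals <= 1))
        # swapping classes maps each extreme eigenvalue to 1 - eigenvalue
        assert np.allclose(sorted(m1.eigvals), sorted(1 - m2.eigvals), atol=1e-9)

    def test_label_swap_reverses_filter_order(self):
        trials, labels = _planted_trials(2)
        m1 = csp_fit(trials, labels, n_components=2)
        m2 = csp_fit(trials, 1 - labels, n_components=2)
        for a, b in ((m1.filters[:, 0], m2.filters[:, 1]),
                     (m1.filters[:, 1], m2.filters[:, 0])):
            ca = a / np.linalg.norm(a)
            cb = b / np.linalg.norm(b)
            assert abs(ca @ cb) >= 0.99

    def test_two_components_give_two_features(self):
        # no Laplacian: the spatial filter would rank-deficiate the
        # composite covariance, which csp_fit rejects by design
        from conftest import power_effects, session_epochs

        eps = session_epochs(power_effects(), seed=13, n_trials=20,
                             laplacian=False)
        model = csp_fit(eps, n_components=2)
        feats = csp_features(model, eps[0])
        assert feats.shape == (2,)
        assert model.filters.shape == (21, 2)

    def test_rank_deficient_composite_rejected(self):
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(8):
            row = rng.standard_normal(100)
            trials.append(np.vstack([row, row]))  # perfectly dependent
        with pytest.raises(ClassifierError, match="Laplacian"):
            csp_fit(trials, np.repeat([0, 1], 4))

    def test_strong_separation_classified_correctly(self):
        train_x, train_y = _planted_trials(4, n_trials=40)
        test_x, test_y = _planted_trials(5, n_trials=20)
        model = csp_fit(train_x, train_y, n_components=2)
        Xtr = np.array([csp_features(model, tr) for tr in train_x])
        Xte = np.array([csp_features(model, tr) for tr in test_x])
        clf = svm_fit(Xtr, train_y)
        assert np.mean(svm_predict(clf, Xte) == test_y) >= 0.95

    def test_label_shuffle_near_chance(self):
        rng = np.random.default_rng(6)
        trials, labels = _planted_trials(6, n_trials=40)
        shuffled = rng.permutation(labels)
        half = len(trials) // 2
        model = csp_fit(trials[:half], shuffled[:half], n_components=2)
        Xte = np.array([csp_features(model, tr) for tr in trials[half:]])
        Xtr = np.array([csp_features(model, tr) for tr in trials[:half]])
        clf = svm_fit(Xtr, shuffled[:half])
        acc = np.mean(svm_predict(clf, Xte) == shuffled[half:])
        sd = 0.5 / np.sqrt(len(Xte))
        assert abs(acc - 0.5) <= 3 * sd


def test_make_classifier_round_trip():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(-2, 1, (15, 3)), rng.normal(2, 1, (15, 3))])
    y = np.repeat([0, 1], 15)
    for kind in ("svm", "elm"):
        clf = t.classify.make_classifier(ClassifierSpec(kind=kind, rng_seed=1))
        clf.fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95
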