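"""Classifiers: soft-margin linear SVM, extreme learning machine, CSP baseline.

* The SVM is the standard soft-margin problem
  ``min 1/2 w'w + C sum(xi_i)`` with a linear kernel; scikit-learn's SVC
  provides the solver and this module exposes the fitted hyperplane (w, b),
  support indices and the primal objective value.
* The ELM is a single-hidden-layer network whose input weights and biases
  are drawn uniformly from [-1, 1] (reproducible from a seed) and whose
  output weights are the least-squares solution ``beta = pinv(H) T`` with
  H the hidden-layer activation matrix.  Targets are one-hot in {-1, +1};
  prediction is the argmax output.
* CSP finds spatial filters maximizing the variance ratio between two
  classes via the generalized eigendecomposition of the class-average
  normalized covariances; per-trial features are the log of the normalized
  variance of each projected component.  The conventional baseline uses the
  8-30 Hz band with no Laplacian (the Laplacian can make the composite
  covariance rank-deficient).
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field
from typing import Sequence

from scipy import linalg

from .errors import ClassifierError
from .preprocess import TrialEpoch

__all__ = [
    "ClassifierSpec",
    "make_classifier",
    "SvmModel",
    "svm_fit",
    "svm_predict",
    "svm_objective",
    "ElmModel",
    "elm_fit",
    "elm_predict",
    "CspModel",
    "csp_fit",
    "csp_features",
    "csp_classify",
]


# ---------------------------------------------------------------------------
# uniform classifier handle used by selection.choose_k and evaluate.run_grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build, with its hyperparameters."""

    kind: str = "svm"  # "svm" or "elm"
    C: float = 1.0
    n_hidden: int = 100
    activation: str = "sigmoid"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "elm"):
            raise ClassifierError(f"unknown classifier kind {self.kind!r}")


class _ElmEstimator:
    """sklearn-style fit/predict facade over the functional ELM API."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.model: ElmModel | None = None

    def fit(self, X, y):
        self.model = elm_fit(
            X, y, n_hidden=self.spec.n_hidden, rng_seed=self.spec.rng_seed,
            activation=self.spec.activation,
        )
        return self

    def predict(self, X):
        return elm_predict(self.model, X)


class _SvmEstimator:
    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.model: SvmModel | None = None

    def fit(self, X, y):
        self.model = svm_fit(X, y, C=self.spec.C)
        return self

    def predict(self, X):
        return svm_predict(self.model, X)


def make_classifier(spec: ClassifierSpec):
    """Instantiate a fit/predict estimator from a :class:`ClassifierSpec`."""
    return _SvmEstimator(spec) if spec.kind == "svm" else _ElmEstimator(spec)


# ---------------------------------------------------------------------------
# linear SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    """Fitted soft-margin linear SVM: decision sign(w . x + b)."""

    weights: np.ndarray
    bias: float
    C: float
    support: np.ndarray
    classes: np.ndarray
    _estimator: object = field(repr=False, default=None)


def _check_training(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ClassifierError("X must be 2-D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ClassifierError("training data contain NaN or Inf")
    if np.unique(y).size < 2:
        raise ClassifierError("training set contains a single class")
    return X, y


def svm_fit(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SvmModel:
    """Fit the linear-kernel soft-margin SVM ``min 1/2 w'w + C sum(xi)``."""
    from sklearn.svm import SVC

    X, y = _check_training(X, y)
    if C <= 0:
        raise ClassifierError("C must be positive")
    est = SVC(kernel="linear", C=C, tol=1e-6)
    est.fit(X, y)
    return SvmModel(
        weights=est.coef_.ravel().copy(),
        bias=float(est.intercept_[0]),
        C=C,
        support=est.support_.copy(),
        classes=est.classes_.copy(),
        _estimator=est,
    )


def svm_predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """Predict labels by the sign of the decision function w . x + b."""
    X = np.asarray(X, dtype=np.float64)
    scores = X @ model.weights + model.bias
    return np.where(scores >= 0, model.classes[1], model.classes[0])


def svm_objective(model: SvmModel, X: np.ndarray, y: np.ndarray) -> float:
    """Primal objective 1/2 ||w||^2 + C sum(hinge) of a fitted model."""
    X = np.asarray(X, dtype=np.float64)
    t = np.where(np.asarray(y) == model.classes[1], 1.0, -1.0)
    margins = t * (X @ model.weights + model.bias)
    xi = np.maximum(0.0, 1.0 - margins)
    return 0.5 * float(model.weights @ model.weights) + model.C * float(xi.sum())


# ---------------------------------------------------------------------------
# extreme learning machine
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


@dataclass
class ElmModel:
    """Fitted single-hidden-layer network with random input weights.

    ``input_weights`` is hidden x features and ``biases`` hidden; both are
    reproducible from ``rng_seed``.  ``output_weights`` (hidden x outputs)
    is the pseudoinverse least-squares solution.
    """

    input_weights: np.ndarray
    biases: np.ndarray
    output_weights: np.ndarray
    classes: np.ndarray
    activation: str
    rng_seed: int

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]


def _elm_hidden(model_w: np.ndarray, b: np.ndarray, X: np.ndarray,
                activation: str) -> np.ndarray:
    g = _ACTIVATIONS[activation]
    return g(X @ model_w.T + b)


def elm_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 100,
    rng_seed: int = 0,
    activation: str = "sigmoid",
) -> ElmModel:
    """Fit an ELM: random input layer, least-squares output layer.

    Targets are one-hot in {-1, +1} (one output per class); the output
    weights are ``pinv(H) @ T``, the minimum-norm least-squares solution,
    which attains zero training error whenever H has full row rank (e.g.
    ``n_hidden`` equal to the number of training samples, generically).
    """
    X, y = _check_training(X, y)
    if n_hidden < 1:
        raise ClassifierError("n_hidden must be >= 1")
    if activation not in _ACTIVATIONS:
        raise ClassifierError(f"unknown activation {activation!r}")
    classes = np.unique(y)
    T = np.where(y[:, None] == classes[None, :], 1.0, -1.0)
    rng = np.random.default_rng(rng_seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = _elm_hidden(W, b, X, activation)
    beta = np.linalg.pinv(H) @ T
    return ElmModel(W, b, beta, classes, activation, rng_seed)


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Predict the class whose output node is largest."""
    X = np.asarray(X, dtype=np.float64)
    H = _elm_hidden(model.input_weights, model.biases, X, model.activation)
    return model.classes[np.argmax(H @ model.output_weights, axis=1)]


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------


@dataclass
class CspModel:
    """CSP spatial filters (channels x components) and their eigenvalues.

    Filters correspond to the extreme eigenvalues of the whitened problem,
    alternating largest / smallest, so two components capture the most
    class-discriminative variance axes.  ``eigvals`` are the corresponding
    generalized eigenvalues in [0, 1].
    """

    filters: np.ndarray
    eigvals: np.ndarray
    classes: np.ndarray
    band_hz: tuple[float, float] = (8.0, 30.0)
    log_variance: bool = True


def _trial_cov(x: np.ndarray) -> np.ndarray:
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ClassifierError("trial with zero variance")
    return c / tr


def csp_fit(
    epochs: Sequence[TrialEpoch] | Sequence[np.ndarray],
    labels: Sequence | None = None,
    n_components: int = 2,
    *,
    log_variance: bool = True,
    band_hz: tuple[float, float] = (8.0, 30.0),
) -> CspModel:
    """Fit CSP filters from band-passed trials of two classes.

    ``epochs`` may be :class:`TrialEpoch` objects (labels taken from them)
    or bare channels x time arrays with explicit ``labels``.  Filters solve
    the generalized eigenproblem ``Sigma_1 v = lambda (Sigma_1 + Sigma_2) v``
    on trace-normalized class-average covariances and the ``n_components``
    filters are taken from the extreme eigenvalues, alternating ends.
    """
    arrays, labs = _epochs_to_arrays(epochs, labels)
    classes = np.unique(labs)
    if classes.size != 2:
        raise ClassifierError("CSP requires exactly two classes")
    covs = {}
    for cls in classes:
        members = [arrays[i] for i in range(len(arrays)) if labs[i] == cls]
        if len(members) < 2:
            raise ClassifierError("CSP needs at least 2 trials per class")
        covs[cls] = np.mean([_trial_cov(a) for a in members], axis=0)
    s1, s2 = covs[classes[0]], covs[classes[1]]
    composite = s1 + s2
    # reject rank-deficient composite covariance (e.g. Laplacian-filtered or
    # linearly dependent channels) before the generalized eigendecomposition
    eigs = np.linalg.eigvalsh(composite)
    if eigs.min() < 1e-10 * eigs.max():
        raise ClassifierError(
            "composite covariance is rank-deficient; CSP needs full-rank data "
            "(use recordings without the surface Laplacian)"
        )
    vals, vecs = linalg.eigh(s1, composite)
    n_ch = vals.size
    if not 1 <= n_components <= n_ch:
        raise ClassifierError("n_components must be in [1, n_channels]")
    order = np.argsort(vals)  # ascending in [0, 1]
    picks = []
    lo_i, hi_i = 0, n_ch - 1
    for i in range(n_components):  # alternate: largest, smallest, ...
        if i % 2 == 0:
            picks.append(order[hi_i])
            hi_i -= 1
        else:
            picks.append(order[lo_i])
            lo_i += 1
    filters = vecs[:, picks]
    return CspModel(filters, vals[picks], classes, band_hz, log_variance)


def _epochs_to_arrays(epochs, labels):
    arrays = []
    labs = []
    for i, ep in enumerate(epochs):
        if isinstance(ep, TrialEpoch):
            arrays.append(np.asarray(ep.samples, dtype=np.float64))
            labs.append(ep.label if labels is None else labels[i])
        else:
            if labels is None:
                raise ClassifierError("bare arrays require explicit labels")
            arrays.append(np.asarray(ep, dtype=np.float64))
            labs.append(labels[i])
    if not arrays:
        raise ClassifierError("no trials given")
    return arrays, np.asarray(labs)


def csp_features(model: CspModel, epoch: TrialEpoch | np.ndarray) -> np.ndarray:
    """Per-trial CSP features: (log-)normalized variance of each component."""
    x = epoch.samples if isinstance(epoch, TrialEpoch) else np.asarray(epoch)
    proj = model.filters.T @ x
    var = proj.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ClassifierError("projected trial has zero variance")
    norm = var / total
    return np.log(norm) if model.log_variance else norm


def csp_classify(
    train_epochs: Sequence[TrialEpoch],
    test_epochs: Sequence[TrialEpoch],
    classifier_spec: ClassifierSpec | None = None,
    n_components: int = 2,
) -> np.ndarray:
    """Fit CSP + classifier on training epochs and predict the test epochs.

    Epochs must already be band-passed (conventionally 8-30 Hz, without the
    surface Laplacian).
    """
    model = csp_fit(train_epochs, n_components=n_components)
    Xtr = np.array([csp_features(model, ep) for ep in train_epochs])
    ytr = np.array([ep.label for ep in train_epochs])
    Xte = np.array([csp_features(model, ep) for ep in test_epochs])
    clf = make_classifier(classifier_spec or ClassifierSpec())
    clf.fit(Xtr, ytr)
    return clf.predict(Xte)
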