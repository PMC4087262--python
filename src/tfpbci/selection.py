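"""Mutual-information feature selection: MIFS and mRMR.

Both criteria greedily grow a feature set S, at each step adding the
feature X_k maximizing

* MIFS:  J(X_k) = I(X_k; Y) - beta * sum_{X_j in S} I(X_k; X_j)
* mRMR:  J(X_k) = I(X_k; Y) - (1/|S|) * sum_{X_j in S} I(X_k; X_j)

i.e. relevance to the class label penalized by redundancy with the features
already selected; mRMR fixes MIFS's beta at 1/|S| so the penalty stays on
the relevance scale as S grows.  Mutual information is the plug-in estimate
on a discretized joint histogram, in bits; continuous features are binned
into eight equal-frequency bins by default.  Ties in the argmax break toward
the lowest column index so rankings are reproducible.

``choose_k`` picks the subset size by inner cross-validation over nested
prefixes of the ranking, returning the smallest size attaining the best
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError
from .features import FeatureMatrix

__all__ = [
    "MIEstimatorConfig",
    "SelectionResult",
    "mutual_info",
    "rank_mifs",
    "rank_mrmr",
    "choose_k",
]


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Plug-in MI estimator settings (histogram bins for continuous data)."""

    n_bins: int = 8
    binning: str = "equal_frequency"
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise SelectionError("n_bins must be >= 2")
        if self.binning not in ("equal_frequency", "equal_width"):
            raise SelectionError("binning must be equal_frequency or equal_width")
        if self.log_base <= 1:
            raise SelectionError("log_base must exceed 1")


@dataclass
class SelectionResult:
    """Greedy ranking produced by MIFS or mRMR.

    ``order`` holds the selected column indices in selection order and
    ``scores`` the criterion value J at the moment each was picked.
    ``chosen_k`` is filled in by :func:`choose_k`.
    """

    criterion: str
    order: np.ndarray
    scores: np.ndarray
    beta: float | None = None
    chosen_k: int | None = None

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.order)) != len(self.order):
            raise SelectionError("ranking contains duplicate feature indices")
        if self.chosen_k is not None and self.chosen_k > len(self.order):
            raise SelectionError("chosen_k exceeds ranking length")


# ---------------------------------------------------------------------------
# discretization and plug-in MI
# ---------------------------------------------------------------------------


def _discretize_column(x: np.ndarray, cfg: MIEstimatorConfig) -> np.ndarray:
    """Integer codes in [0, n_bins): quantile or equal-width bins.

    Columns with at most ``n_bins`` distinct values are treated as already
    discrete and passed through as rank codes.
    """
    uniq = np.unique(x)
    if uniq.size <= cfg.n_bins:
        return np.searchsorted(uniq, x)
    if cfg.binning == "equal_frequency":
        edges = np.quantile(x, np.linspace(0, 1, cfg.n_bins + 1)[1:-1])
    else:
        edges = np.linspace(x.min(), x.max(), cfg.n_bins + 1)[1:-1]
    return np.searchsorted(edges, x, side="right")


def _codes(values: np.ndarray, cfg: MIEstimatorConfig) -> np.ndarray:
    """Discretize every column of a trials x features matrix."""
    return np.column_stack(
        [_discretize_column(values[:, j], cfg) for j in range(values.shape[1])]
    ).astype(np.int64)


def _mi_from_counts(counts: np.ndarray, log_base: float) -> np.ndarray:
    """Plug-in MI for a stack of contingency tables (..., a, b)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    term = np.where(p > 0, term, 0.0)
    return term.sum(axis=(-2, -1)) / np.log(log_base)


def _mi_many(codes: np.ndarray, levels: int, ref: np.ndarray, ref_levels: int,
             log_base: float) -> np.ndarray:
    """MI between every column of ``codes`` and the single vector ``ref``."""
    n, p = codes.shape
    cell = codes * ref_levels + ref[:, None]
    flat = (np.arange(p) * (levels * ref_levels))[None, :] + cell
    counts = np.bincount(
        flat.ravel(), minlength=p * levels * ref_levels
    ).reshape(p, levels, ref_levels)
    return _mi_from_counts(counts.astype(np.float64), log_base)


def mutual_info(
    x: np.ndarray, y: np.ndarray, cfg: MIEstimatorConfig = MIEstimatorConfig()
) -> float:
    """Plug-in mutual information between two vectors, in bits.

    Continuous input is discretized per ``cfg``; inputs with at most
    ``n_bins`` distinct values (e.g. class labels) are used as-is.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise SelectionError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 4:
        raise SelectionError("need at least 4 samples")
    cx = _discretize_column(x, cfg)
    cy = _discretize_column(y, cfg)
    levels = int(cx.max()) + 1
    return float(_mi_many(cx[:, None], levels, cy, int(cy.max()) + 1, cfg.log_base)[0])


# ---------------------------------------------------------------------------
# greedy rankings
# ---------------------------------------------------------------------------


def _greedy_rank(
    fm: FeatureMatrix,
    cfg: MIEstimatorConfig,
    max_k: int,
    beta_of: "callable",
    criterion: str,
    beta_field: float | None,
) -> SelectionResult:
    if fm.n_features == 0 or fm.n_trials == 0:
        raise SelectionError("empty feature matrix")
    max_k = int(min(max_k, fm.n_features))
    if max_k < 1:
        raise SelectionError("max_k must be >= 1")
    codes = _codes(fm.values, cfg)
    levels = cfg.n_bins
    y = _discretize_column(np.asarray(fm.labels), cfg)
    y_levels = int(y.max()) + 1

    relevance = _mi_many(codes, levels, y, y_levels, cfg.log_base)
    penalty = np.zeros(fm.n_features)
    available = np.ones(fm.n_features, dtype=bool)
    order: list[int] = []
    scores: list[float] = []
    for step in range(max_k):
        beta = beta_of(len(order))
        j_vals = relevance - beta * penalty
        j_vals[~available] = -np.inf
        pick = int(np.argmax(j_vals))  # ties -> lowest index
        order.append(pick)
        scores.append(float(j_vals[pick]))
        available[pick] = False
        if step + 1 < max_k:
            penalty += _mi_many(codes, levels, codes[:, pick], levels, cfg.log_base)
    return SelectionResult(criterion, np.array(order), np.array(scores), beta_field)


def rank_mifs(
    fm: FeatureMatrix,
    beta: float = 0.5,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    max_k: int = 500,
) -> SelectionResult:
    """Greedy MIFS ranking with a fixed redundancy weight ``beta``."""
    if beta < 0:
        raise SelectionError("beta must be non-negative")
    return _greedy_rank(fm, cfg, max_k, lambda size: beta, "MIFS", beta)


def rank_mrmr(
    fm: FeatureMatrix,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    max_k: int = 500,
) -> SelectionResult:
    """Greedy mRMR ranking (redundancy averaged over the selected set)."""
    return _greedy_rank(
        fm, cfg, max_k, lambda size: 1.0 / size if size else 0.0, "mRMR", None
    )


# ---------------------------------------------------------------------------
# subset-size choice by inner cross-validation
# ---------------------------------------------------------------------------


def choose_k(
    sel: SelectionResult,
    fm: FeatureMatrix,
    classifier_spec=None,
    inner_folds: int = 5,
    *,
    k_step: int = 1,
    rng_seed: int = 0,
    return_accuracies: bool = False,
):
    """Pick the subset size by inner CV over nested prefixes of the ranking.

    Evaluates prefixes k = 1, 1+k_step, ... of ``sel.order`` with stratified
    ``inner_folds``-fold CV on ``fm`` (which should contain training trials
    only) and returns the smallest k attaining the maximum mean accuracy.
    """
    from sklearn.model_selection import StratifiedKFold

    from .classify import ClassifierSpec, make_classifier

    if inner_folds < 2:
        raise SelectionError("inner_folds must be >= 2")
    labels = np.asarray(fm.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2 or counts.min() < inner_folds:
        raise SelectionError(
            "each class needs at least inner_folds trials for inner CV"
        )
    spec = classifier_spec or ClassifierSpec()
    ks = list(range(1, len(sel.order) + 1, max(1, k_step)))
    if ks[-1] != len(sel.order):
        ks.append(len(sel.order))
    acc = np.zeros(len(ks))
    skf = StratifiedKFold(inner_folds, shuffle=True, random_state=rng_seed)
    for tr, te in skf.split(fm.values, labels):
        for i, k in enumerate(ks):
            cols = sel.order[:k]
            clf = make_classifier(spec)
            clf.fit(fm.values[np.ix_(tr, cols)], labels[tr])
            acc[i] += np.mean(clf.predict(fm.values[np.ix_(te, cols)]) == labels[te])
    acc /= inner_folds
    best = ks[int(np.flatnonzero(np.isclose(acc, acc.max()))[0])]
    sel.chosen_k = best
    if return_accuracies:
        return best, dict(zip(ks, acc))
    return best
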