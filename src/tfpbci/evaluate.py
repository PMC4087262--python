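"""Cross-validated evaluation grid and statistical comparisons.

``run_grid`` evaluates every combination of

* feature-processing regime: ``noscale_MIFS`` (raw features, MIFS ranking),
  ``scale_MIFS`` (min-max scaled, MIFS), ``scale_mRMR`` (scaled, mRMR);
* feature set: the four single types and four combinations;
* classifier: linear SVM or ELM,

with stratified k-fold cross-validation (default 5 folds).  Every cell is
scored on identical fold splits.  Inside each fold, scaling statistics,
feature rankings and the subset size (inner CV) are fitted on the training
rows only, so no information leaks from the test fold.

``compare`` runs paired t-tests between cells on their per-fold accuracy
vectors and reports an indicator that condition A scores below condition B
at the chosen significance level.  Exact ties (identical vectors) give
indicator 0 with a warning; a constant nonzero difference is treated as a
certain ordering (indicator by the means).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifierSpec, make_classifier
from .errors import ClassifierError, ConfigError, FeatureError
from .features import (
    FEATURE_SETS,
    FeatureMatrix,
    WindowSpec,
    analytic_signal,
    assemble,
    scale,
    window_average,
)
from .preprocess import DEFAULT_BANDS, TrialEpoch, bandpass_array
from .selection import MIEstimatorConfig, choose_k, rank_mifs, rank_mrmr

__all__ = [
    "EvalPlan",
    "CellResult",
    "EvaluationReport",
    "run_grid",
    "merge_reports",
    "compare",
    "compare_vectors",
    "export_topomap_values",
    "REGIMES",
]

REGIMES = ("noscale_MIFS", "scale_MIFS", "scale_mRMR")


@dataclass(frozen=True)
class EvalPlan:
    """What to evaluate and how.

    ``max_k`` bounds the greedy ranking length (and hence the inner
    subset-size search); ``k_step`` thins the inner search grid to every
    ``k_step``-th prefix to save time on large grids.
    """

    regimes: tuple[str, ...] = REGIMES
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
    classifiers: tuple[str, ...] = ("svm", "elm")
    n_folds: int = 5
    alpha: float = 0.01
    rng_seed: int = 0
    mifs_beta: float = 0.5
    max_k: int = 64
    inner_folds: int = 5
    k_step: int = 4
    n_bins: int = 8
    svm_C: float = 1.0
    elm_hidden: int = 100
    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    window: WindowSpec = WindowSpec()
    ip_mean: str = "circular"

    def __post_init__(self) -> None:
        bad = set(self.regimes) - set(REGIMES)
        if bad:
            raise ConfigError(f"unknown regimes {sorted(bad)}")
        bad = set(self.feature_sets) - set(FEATURE_SETS)
        if bad:
            raise ConfigError(f"unknown feature sets {sorted(bad)}")
        bad = set(self.classifiers) - {"svm", "elm"}
        if bad:
            raise ConfigError(f"unknown classifiers {sorted(bad)}")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


@dataclass
class CellResult:
    """Per-fold accuracies and chosen subset sizes of one grid cell."""

    fold_accuracies: list[float]
    chosen_ks: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


@dataclass
class EvaluationReport:
    """Accuracy grid: cell key = (regime, feature_set, classifier)."""

    cells: dict[tuple[str, str, str], CellResult]
    n_folds: int
    alpha: float
    rng_seed: int

    def accuracy(self, regime: str, feature_set: str, classifier: str) -> float:
        return self.cells[(regime, feature_set, classifier)].mean

    def table(self, classifier: str) -> pd.DataFrame:
        """Regimes x feature-sets table of "mean +- sd" strings."""
        regimes = sorted({k[0] for k in self.cells if k[2] == classifier},
                         key=REGIMES.index)
        sets = list(dict.fromkeys(k[1] for k in self.cells if k[2] == classifier))
        data = {}
        for fs in sets:
            col = []
            for rg in regimes:
                cell = self.cells[(rg, fs, classifier)]
                col.append(f"{cell.mean:.2f} ± {cell.sd:.2f}")
            data[fs] = col
        return pd.DataFrame(data, index=regimes)

    def to_json(self, path=None) -> str:
        payload = {
            "n_folds": self.n_folds,
            "alpha": self.alpha,
            "rng_seed": self.rng_seed,
            "cells": [
                {
                    "regime": k[0],
                    "feature_set": k[1],
                    "classifier": k[2],
                    "mean": v.mean,
                    "sd": v.sd,
                    "fold_accuracies": list(map(float, v.fold_accuracies)),
                    "chosen_ks": list(map(int, v.chosen_ks)),
                }
                for k, v in self.cells.items()
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        cells = {
            (c["regime"], c["feature_set"], c["classifier"]): CellResult(
                c["fold_accuracies"], c["chosen_ks"]
            )
            for c in payload["cells"]
        }
        return cls(cells, payload["n_folds"], payload["alpha"], payload["rng_seed"])


def _rank_for_regime(regime, fm_train, plan, mi_cfg):
    if regime.endswith("mRMR"):
        return rank_mrmr(fm_train, mi_cfg, max_k=plan.max_k)
    return rank_mifs(fm_train, plan.mifs_beta, mi_cfg, max_k=plan.max_k)


def run_grid(
    epochs: Sequence[TrialEpoch],
    plan: EvalPlan,
    *,
    feature_matrix: FeatureMatrix | None = None,
) -> EvaluationReport:
    """Evaluate every (regime, feature set, classifier) cell by stratified CV.

    ``epochs`` are broadband (optionally Laplacian-filtered) trials; the
    full four-type feature matrix is assembled once and cells take column
    subsets, so every cell sees identical trials and fold splits.  Pass a
    pre-assembled unscaled four-type ``feature_matrix`` (from the same
    epochs) to amortize extraction across several plans.
    """
    from sklearn.model_selection import StratifiedKFold

    if not epochs and feature_matrix is None:
        raise FeatureError("no epochs given")
    full = feature_matrix
    if full is None:
        full = assemble(
            epochs, plan.bands, feature_types=("power", "IA", "IP", "IF"),
            spec=plan.window, ip_mean=plan.ip_mean,
        )
    if full.scaled:
        raise FeatureError("feature_matrix must be unscaled (regimes scale it)")
    labels = full.labels
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < plan.n_folds:
        raise ClassifierError("every class needs at least n_folds trials")
    mi_cfg = MIEstimatorConfig(n_bins=plan.n_bins)
    skf = StratifiedKFold(plan.n_folds, shuffle=True, random_state=plan.rng_seed)
    splits = list(skf.split(full.values, labels))

    cells: dict[tuple[str, str, str], CellResult] = {}
    for set_name in plan.feature_sets:
        sub = full.select_types(FEATURE_SETS[set_name])
        for regime in plan.regimes:
            for clf_kind in plan.classifiers:
                spec = ClassifierSpec(
                    kind=clf_kind, C=plan.svm_C, n_hidden=plan.elm_hidden,
                    rng_seed=plan.rng_seed,
                )
                accs: list[float] = []
                ks: list[int] = []
                for fold_i, (tr, te) in enumerate(splits):
                    with warnings.catch_warnings():
                        # constant-column warnings are routine here: windows of
                        # near-silent channels can be flat within one fold
                        warnings.simplefilter("ignore")
                        fm = (
                            scale(sub, fit_rows=tr)
                            if regime.startswith("scale")
                            else sub
                        )
                    fm_train = fm.subset_rows(tr)
                    sel = _rank_for_regime(regime, fm_train, plan, mi_cfg)
                    k = choose_k(
                        sel, fm_train, spec, plan.inner_folds,
                        k_step=plan.k_step, rng_seed=plan.rng_seed + fold_i,
                    )
                    cols = sel.order[:k]
                    clf = make_classifier(spec)
                    clf.fit(fm.values[np.ix_(tr, cols)], labels[tr])
                    pred = clf.predict(fm.values[np.ix_(te, cols)])
                    accs.append(float(np.mean(pred == labels[te])))
                    ks.append(int(k))
                cells[(regime, set_name, clf_kind)] = CellResult(accs, ks)
    return EvaluationReport(cells, plan.n_folds, plan.alpha, plan.rng_seed)


def merge_reports(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Pool per-fold accuracies of several sessions' reports cell-by-cell."""
    if not reports:
        raise ConfigError("no reports to merge")
    keys = set(reports[0].cells)
    for rep in reports[1:]:
        if set(rep.cells) != keys:
            raise ConfigError("reports have different grid cells")
    merged = {
        k: CellResult(
            sum((list(r.cells[k].fold_accuracies) for r in reports), []),
            sum((list(r.cells[k].chosen_ks) for r in reports), []),
        )
        for k in keys
    }
    first = reports[0]
    return EvaluationReport(merged, first.n_folds, first.alpha, first.rng_seed)


def compare_vectors(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.01, *, paired: bool = True
) -> int:
    """Indicator that condition A scores significantly below condition B.

    Paired t-test on per-fold accuracies by default (Welch's unpaired test
    with ``paired=False``).  Identical vectors give 0 with a warning; a
    constant nonzero paired difference is a certain ordering and returns the
    indicator of ``mean(a) < mean(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape and paired:
        raise ConfigError("paired comparison needs equal-length vectors")
    if paired:
        diff = b - a
        if np.allclose(diff.std(), 0.0):
            if np.allclose(diff, 0.0):
                warnings.warn("identical accuracy vectors; indicator 0",
                              stacklevel=2)
                return 0
            return int(a.mean() < b.mean())
        p = stats.ttest_rel(a, b, alternative="less").pvalue
    else:
        p = stats.ttest_ind(a, b, equal_var=False, alternative="less").pvalue
    return int((a.mean() < b.mean()) and (p < alpha))


def compare(
    report: EvaluationReport,
    condition_pairs: Sequence[tuple[tuple[str, str, str], tuple[str, str, str]]],
    alpha: float | None = None,
    *,
    paired: bool = True,
) -> pd.DataFrame:
    """Pairwise "A < B" significance indicators between grid cells.

    Each pair is two cell keys ``(regime, feature_set, classifier)``; the
    result row holds the two means and the indicator at level ``alpha``
    (default: the report's alpha).
    """
    alpha = report.alpha if alpha is None else alpha
    rows = []
    for key_a, key_b in condition_pairs:
        ca, cb = report.cells[key_a], report.cells[key_b]
        ind = compare_vectors(
            ca.fold_accuracies, cb.fold_accuracies, alpha, paired=paired
        )
        rows.append(
            {
                "A": "/".join(key_a),
                "B": "/".join(key_b),
                "mean_A": ca.mean,
                "mean_B": cb.mean,
                "A_lt_B": ind,
            }
        )
    return pd.DataFrame(rows)


def export_topomap_values(
    epochs: Sequence[TrialEpoch],
    feature_type: str = "power",
    band: str = "mu",
    window_s: tuple[float, float] = (0.0, 0.5),
    bands: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-channel class-mean feature values over a post-onset window.

    Returns a channels x classes table of the mean feature value inside
    ``window_s`` (seconds around task onset) — the data behind a scalp
    topography, without any rendering.  IP is averaged circularly.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    if band not in bands:
        raise ConfigError(f"unknown band {band!r}; have {sorted(bands)}")
    if feature_type not in ("power", "IA", "IP", "IF"):
        raise FeatureError(f"unknown feature type {feature_type!r}")
    if not epochs:
        raise FeatureError("no epochs given")
    chans = epochs[0].channel_labels
    fs = epochs[0].fs_hz
    spec = WindowSpec(
        win_len_s=window_s[1] - window_s[0], step_s=window_s[1] - window_s[0],
        range_s=window_s,
    )
    per_class: dict[int, list[np.ndarray]] = {}
    for ep in epochs:
        x = bandpass_array(ep.samples, bands[band], fs)
        vals = np.empty(len(chans))
        for ci in range(len(chans)):
            feats = analytic_signal(x[ci], fs)
            vals[ci] = window_average(
                feats.series(feature_type), fs, ep.t0_index, spec,
                circular=feature_type == "IP",
            )[0]
        per_class.setdefault(ep.label, []).append(vals)
    cols = {}
    for cls in sorted(per_class):
        stack = np.vstack(per_class[cls])
        if feature_type == "IP":
            cols[f"class_{cls}"] = np.angle(
                np.mean(np.exp(1j * stack), axis=0)
            )
        else:
            cols[f"class_{cls}"] = stack.mean(axis=0)
    return pd.DataFrame(cols, index=list(chans))
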