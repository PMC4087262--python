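"""Mutual information estimator and MIFS / mRMR greedy selection."""

import math

import numpy as np
import pytest

import tfpbci as t
from tfpbci.errors import SelectionError
from tfpbci.features import ColumnMeta, FeatureMatrix
from tfpbci.selection import MIEstimatorConfig, choose_k, rank_mifs, rank_mrmr


def _fm(values, labels):
    values = np.asarray(values, dtype=float)
    meta = tuple(
        ColumnMeta(f"c{j}", "mu", "power", 0) for j in range(values.shape[1])
    )
    return FeatureMatrix(values, meta, np.asarray(labels))


# ---------------------------------------------------------------------------
# independent oracles, deliberately naive
# ---------------------------------------------------------------------------


def brute_force_mi(x_codes, y_codes):
    """Plug-in MI (bits) from an explicitly looped contingency table."""
    n = len(x_codes)
    xs, ys = sorted(set(x_codes)), sorted(set(y_codes))
    mi = 0.0
    for xv in xs:
        for yv in ys:
            nxy = sum(1 for a, b in zip(x_codes, y_codes) if a == xv and b == yv)
            if nxy == 0:
                continue
            nx = sum(1 for a in x_codes if a == xv)
            ny = sum(1 for b in y_codes if b == yv)
            mi += (nxy / n) * math.log2(nxy * n / (nx * ny))
    return mi


def quantile_codes(x, n_bins):
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return list(np.searchsorted(edges, x, side="right"))


class TestMutualInfo:
    def test_perfect_binary_dependence_is_one_bit(self):
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        assert t.mutual_info(x, x) == pytest.approx(1.0)

    def test_constant_feature_carries_zero_bits(self):
        y = [0, 1, 0, 1, 0, 1]
        assert t.mutual_info(np.ones(6), y) == pytest.approx(0.0)

    def test_matches_brute_force_on_gaussian_sign_problem(self):
        """Continuous N(0,1) vs its sign, n = 2000: estimator agrees with a
        naive contingency-table loop to within 0.05 bit."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal(2000)
        y = (x > 0).astype(int)
        est = t.mutual_info(x, y, MIEstimatorConfig(n_bins=8))
        oracle = brute_force_mi(quantile_codes(x, 8), list(y))
        assert abs(est - oracle) < 0.05
        # and the quantities themselves agree closely (same discretization)
        assert est == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        y = rng.integers(0, 3, 300)
        assert t.mutual_info(x, y) == pytest.approx(t.mutual_info(y, x), abs=1e-12)
        assert t.mutual_info(x, y) >= 0

    def test_shuffled_feature_within_permutation_null(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(400)
        y = (x > 0).astype(int)
        null = [
            t.mutual_info(rng.permutation(x), y) for _ in range(60)
        ]
        observed = t.mutual_info(rng.permutation(x), y)
        assert observed < np.mean(null) + 3 * np.std(null)

    def test_length_mismatch_rejected(self):
        with pytest.raises(SelectionError):
            t.mutual_info([1, 2, 3], [1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(SelectionError):
            t.mutual_info([1, 2], [0, 1])


# ---------------------------------------------------------------------------
# greedy rankings
# ---------------------------------------------------------------------------


def _toy_redundant(n=400, seed=0):
    """Three columns: strong informative, its duplicate, weak independent."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    strong = y + 0.3 * rng.standard_normal(n)
    dup = strong.copy()
    weak = 0.6 * y + 1.0 * rng.standard_normal(n)
    return _fm(np.column_stack([strong, dup, weak]), y)


class TestRankings:
    def test_beta_zero_equals_descending_mi(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        cols = [y + s * rng.standard_normal(200) for s in (0.3, 1.0, 3.0, 0.5)]
        fm = _fm(np.column_stack(cols), y)
        sel = rank_mifs(fm, beta=0.0, max_k=4)
        mis = [t.mutual_info(fm.values[:, j], y) for j in range(4)]
        assert list(sel.order) == list(np.argsort(mis)[::-1])

    def test_duplicate_penalized_then_weak_feature_picked(self):
        """With beta = 1, an exact duplicate of the first pick loses exactly
        I(dup; first) of score and the weaker independent column wins step 2."""
        fm = _toy_redundant()
        sel = rank_mifs(fm, beta=1.0, max_k=3)
        assert sel.order[0] == 0  # strong
        assert sel.order[1] == 2  # weak independent, not the duplicate
        # J of the duplicate at step 2 is relevance - I(dup; strong) ~ <= 0
        rel_dup = t.mutual_info(fm.values[:, 1], fm.labels)
        red_dup = t.mutual_info(fm.values[:, 1], fm.values[:, 0])
        assert rel_dup - red_dup < sel.scores[1]

    def test_first_pick_identical_across_criteria(self):
        fm = _toy_redundant(seed=5)
        assert (
            rank_mifs(fm, beta=0.7, max_k=1).order[0]
            == rank_mrmr(fm, max_k=1).order[0]
        )

    def test_mrmr_second_step_equals_mifs_beta_one(self):
        fm = _toy_redundant(seed=6)
        assert list(rank_mrmr(fm, max_k=2).order) == list(
            rank_mifs(fm, beta=1.0, max_k=2).order
        )

    def test_max_k_one_is_argmax_mi(self):
        fm = _toy_redundant(seed=7)
        sel = rank_mrmr(fm, max_k=1)
        mis = [t.mutual_info(fm.values[:, j], fm.labels) for j in range(3)]
        assert len(sel.order) == 1 and sel.order[0] == int(np.argmax(mis))

    def test_empty_matrix_rejected(self):
        with pytest.raises((SelectionError, Exception)):
            rank_mrmr(_fm(np.zeros((0, 3)), np.zeros(0)), max_k=2)

    @pytest.mark.parametrize("criterion", ["mifs", "mrmr"])
    def test_greedy_trace_equals_exhaustive_recomputation(self, criterion):
        """On a 6-feature toy, every greedy step must agree with an
        independent exhaustive evaluation of the criterion."""
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 60)
        base = y + 0.5 * rng.standard_normal(120)
        cols = np.column_stack(
            [
                base,
                base + 0.1 * rng.standard_normal(120),
                y + 1.5 * rng.standard_normal(120),
                rng.standard_normal(120),
                0.5 * y + rng.standard_normal(120),
                base * 0.5 + rng.standard_normal(120),
            ]
        )
        fm = _fm(cols, y)
        beta = 0.5
        cfg = MIEstimatorConfig()
        if criterion == "mifs":
            sel = rank_mifs(fm, beta=beta, cfg=cfg, max_k=3)
        else:
            sel = rank_mrmr(fm, cfg=cfg, max_k=3)

        # oracle: recompute J for every candidate at every step via the
        # public single-pair MI on the pre-discretized columns
        def mi_pair(a, b):
            return t.mutual_info(a, b, cfg)

        selected = []
        for step, picked in enumerate(sel.order):
            best_j, best_col = -np.inf, None
            for j in range(6):
                if j in selected:
                    continue
                rel = mi_pair(cols[:, j], y)
                red = sum(mi_pair(cols[:, j], cols[:, s]) for s in selected)
                if criterion == "mifs":
                    jv = rel - beta * red
                else:
                    jv = rel - (red / len(selected) if selected else 0.0)
                if jv > best_j + 1e-12:
                    best_j, best_col = jv, j
            assert picked == best_col
            assert sel.scores[step] == pytest.approx(best_j, abs=1e-10)
            selected.append(picked)

    def test_mrmr_never_picks_exact_duplicate_before_informative(self):
        fm = _toy_redundant(seed=9)
        sel = rank_mrmr(fm, max_k=3)
        assert list(sel.order[:2]) == [0, 2]


# ---------------------------------------------------------------------------
# planted-feature recovery and subset-size choice
# ---------------------------------------------------------------------------


def _planted_matrix(seed, n=180, n_informative=10, n_noise=200, shift=1.2):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    informative = shift * y[:, None] + rng.standard_normal((n, n_informative))
    noise = rng.standard_normal((n, n_noise))
    x = np.column_stack([informative, noise])
    perm = rng.permutation(x.shape[1])
    return _fm(x[:, perm], y), perm


def test_mrmr_recovers_planted_informative_columns():
    """>= 8 of 10 planted columns among the first 20 picks (median, 20 seeds)."""
    hits = []
    for seed in range(20):
        fm, perm = _planted_matrix(seed)
        informative = set(np.flatnonzero(perm < 10))
        sel = rank_mrmr(fm, max_k=20)
        hits.append(len(informative & set(sel.order[:20])))
    assert np.median(hits) >= 8


class TestChooseK:
    def test_single_perfect_feature_gives_k_one(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        x = np.column_stack([y * 2.0 - 1.0, rng.standard_normal((60, 4))])
        fm = _fm(x, y)
        sel = rank_mrmr(fm, max_k=5)
        k = choose_k(sel, fm, rng_seed=0)
        assert sel.order[0] == 0
        assert k == 1  # ties broken toward the smallest subset

    def test_reports_accuracy_curve(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        fm = _fm(y[:, None] + 0.5 * rng.standard_normal((60, 3)), y)
        sel = rank_mrmr(fm, max_k=3)
        k, curve = choose_k(sel, fm, return_accuracies=True, rng_seed=0)
        assert set(curve) == {1, 2, 3}
        assert k == min(kk for kk, a in curve.items() if a == max(curve.values()))

    def test_planted_simulation_chooses_moderate_k(self):
        """Chosen subset size lands in [5, 40] for >= 80% of 20 seeds."""
        good = 0
        for seed in range(20):
            fm, _ = _planted_matrix(seed)
            sel = rank_mrmr(fm, max_k=40)
            k = choose_k(sel, fm, inner_folds=3, k_step=2, rng_seed=seed)
            good += int(5 <= k <= 40)
        assert good >= 16

    def test_degenerate_single_class_rejected(self):
        fm = _fm(np.random.default_rng(0).standard_normal((10, 3)), np.zeros(10))
        sel = rank_mifs(fm, beta=0.0, max_k=2)
        with pytest.raises(SelectionError):
            choose_k(sel, fm)
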