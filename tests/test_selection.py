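"""Screening, mutual information, collinearity pruning and consensus ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ctcpm
from ctcpm.errors import DomainError, ValidationError
from ctcpm.selection import _equal_freq_bins


def _mi_table_oracle(bx, by, n_bins):
    """Brute-force double sum over the discretized joint table, in nats."""
    n = len(bx)
    total = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            pxy = np.sum((bx == i) & (by == j)) / n
            if pxy == 0:
                continue
            px = np.sum(bx == i) / n
            py = np.sum(by == j) / n
            total += pxy * np.log(pxy / (px * py))
    return total


def _toy_cohort(x_cols, y):
    """Cohort whose first columns are the given vectors, rest zeros-free noise."""
    x_cols = np.asarray(x_cols, dtype=float)
    n, f = x_cols.shape
    p = 5  # E = 10 >= f
    ei = ctcpm.edge_index_for(p)
    rng = np.random.default_rng(99)
    x = rng.normal(size=(n, ei.n_edges)) * 0.01
    x[:, :f] = x_cols
    return ctcpm.ConnectomeCohort(
        subjects=[f"s{i}" for i in range(n)],
        X=x,
        y=np.asarray(y, dtype=float),
        edge_index=ei,
        atlas=ctcpm.synthetic_atlas(p),
    )


class TestScreen:
    def test_edge_equal_to_score_passes_with_r_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        cohort = _toy_cohort(y.reshape(-1, 1), y)
        screen = ctcpm.screen_edges(cohort, alpha=0.01)
        assert screen.r[0] == pytest.approx(1.0)
        assert 0 in screen.passing_edges
        assert screen.sign[0] == 1

    def test_p_values_match_t_test_oracle(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        n = 20
        y = rng.normal(size=n)
        x = np.column_stack([0.5 * y + rng.normal(size=n), rng.normal(size=n)])
        cohort = _toy_cohort(x, y)
        screen = ctcpm.screen_edges(cohort)
        for j in range(cohort.n_edges):
            r = np.corrcoef(cohort.X[:, j], y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert screen.r[j] == pytest.approx(r, abs=1e-12)
            assert screen.p[j] == pytest.approx(p, abs=1e-12)

    def test_constant_edge_never_passes(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=15)
        x = np.column_stack([np.full(15, 3.0), y])
        cohort = _toy_cohort(x, y)
        screen = ctcpm.screen_edges(cohort)
        assert screen.r[0] == 0 and screen.p[0] == 1.0
        assert 0 not in screen.passing_edges

    def test_constant_trait_rejected(self):
        cohort = _toy_cohort(np.random.default_rng(3).normal(size=(10, 2)), np.ones(10))
        with pytest.raises(ValidationError, match="constant"):
            ctcpm.screen_edges(cohort)

    def test_signs_recorded_for_passers(self, strong_cohort):
        cohort, truth = strong_cohort
        screen = ctcpm.screen_edges(cohort)
        assert np.all(screen.sign[screen.passing_edges] != 0)
        truth_sign = dict(zip(truth.edge_ids.tolist(), truth.signs.tolist()))
        hits = [e for e in screen.passing_edges if e in truth_sign]
        agree = np.mean([screen.sign[e] == truth_sign[e] for e in hits])
        assert agree > 0.95


class TestMutualInformation:
    def test_independent_product_table_is_zero(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert ctcpm.mutual_information(x, y, n_bins=2) == pytest.approx(0.0, abs=1e-12)

    def test_identical_fair_coin_gives_ln2(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert ctcpm.mutual_information(x, x, n_bins=2) == pytest.approx(np.log(2), abs=1e-12)

    def test_known_joint_table_value(self):
        # joint P(0,0)=P(1,1)=0.4, off-diagonal 0.1 each
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [4, 1, 1, 4])
        y = np.repeat([0.0, 1.0, 0.0, 1.0], [4, 1, 1, 4])
        expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)  # direct formula evaluation
        got = ctcpm.mutual_information(x, y, n_bins=2)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.192745, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, n_bins = 64, 8
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        bx = _equal_freq_bins(x, n_bins)
        by = _equal_freq_bins(y, n_bins)
        assert ctcpm.mutual_information(x, y, n_bins) == pytest.approx(
            _mi_table_oracle(bx, by, n_bins), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.3 * x
        base = ctcpm.mutual_information(x, y)
        assert ctcpm.mutual_information(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert ctcpm.mutual_information(x, y**3) == pytest.approx(base, abs=1e-12)

    def test_nonnegative_and_symmetric(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = ctcpm.mutual_information(x, y)
        assert a >= 0.0
        assert a == pytest.approx(ctcpm.mutual_information(y, x), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            ctcpm.mutual_information(np.ones(3), np.ones(4))


class TestPruneCollinear:
    def test_signal_member_of_collinear_pair_retained(self):
        rng = np.random.default_rng(5)
        n = 500
        y = rng.normal(size=n)
        a = 0.8 * y + 0.2 * rng.normal(size=n)  # carries signal
        b = a + 0.05 * rng.normal(size=n)  # near-duplicate, r ~ 0.99
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.99
        noise = rng.normal(size=n)
        x = np.column_stack([b, a, noise])
        kept = ctcpm.prune_collinear(x, y, edge_ids=np.array([10, 20, 30]))
        assert 30 in kept  # uncorrelated survives
        assert (20 in kept) != (10 in kept)  # exactly one of the pair
        assert 20 in kept  # the higher-MI (signal-carrying) member

    def test_all_uncorrelated_all_retained(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 6))
        y = rng.normal(size=200)
        kept = ctcpm.prune_collinear(x, y)
        assert np.array_equal(kept, np.arange(6))

    def test_identical_triplicate_keeps_exactly_one(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=100)
        x = np.column_stack([a, a, a])
        y = rng.normal(size=100)
        kept = ctcpm.prune_collinear(x, y)
        assert len(kept) == 1

    def test_collinear_block_with_signal_member(self):
        rng = np.random.default_rng(8)
        n = 500
        block = ctcpm.simulate_collinear_block(n, 3, rho=0.99, seed=8)
        y = 2.0 * block[:, 1] + 0.3 * rng.normal(size=n)  # member 1 drives the score
        kept = ctcpm.prune_collinear(block, y)
        assert kept.tolist() == [1]


class TestConsensus:
    def test_signal_beats_noise_feature(self):
        rng = np.random.default_rng(9)
        n = 500
        y = rng.normal(size=n)
        x = np.column_stack([y + 0.3 * rng.normal(size=n), rng.normal(size=n)])
        consensus, rankings = ctcpm.consensus_select(x, y, top_fraction=0.5, seed=0)
        assert consensus.tolist() == [0]
        assert len(rankings) == 24

    def test_top_fraction_one_keeps_everything(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        consensus, _ = ctcpm.consensus_select(x, y, top_fraction=1.0, seed=1)
        assert consensus.tolist() == [0, 1, 2, 3, 4]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(80, 10))
        y = rng.normal(size=80) + x[:, 0]
        c1, r1 = ctcpm.consensus_select(x, y, seed=42)
        c2, r2 = ctcpm.consensus_select(x, y, seed=42)
        assert np.array_equal(c1, c2)
        assert all(np.array_equal(a, b) for a, b in zip(r1, r2))

    @pytest.mark.parametrize("fractions", [(0.3, 0.6, 0.9)])
    def test_consensus_shrinks_with_top_fraction(self, fractions):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(100, 12))
        y = rng.normal(size=100) + 0.5 * x[:, 0] - 0.5 * x[:, 1]
        sets = []
        for tf in fractions:
            c, _ = ctcpm.consensus_select(x, y, top_fraction=tf, seed=7)
            sets.append(set(c.tolist()))
        assert sets[0] <= sets[1] <= sets[2]

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(DomainError):
            ctcpm.consensus_select(np.ones((4, 3)), np.arange(4.0), k_folds=6)


class TestFullSelection:
    def test_nesting_invariant(self, strong_cohort):
        cohort, _ = strong_cohort
        sel = ctcpm.select_features(cohort, seed=3)
        passing = set(sel.screen.passing_edges.tolist())
        pruned = set(sel.retained_after_collinearity.tolist())
        consensus = set(sel.consensus_edges.tolist())
        assert consensus <= pruned <= passing
        assert len(sel.rankings) == 24

    def test_empty_screen_short_circuits(self):
        cohort = ctcpm.simulate_null_cohort(40, 5, seed=14)
        sel = ctcpm.select_features(cohort, alpha=1e-9)
        assert sel.screen.passing_edges.size == 0
        assert sel.n_consensus == 0
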