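"""Rank tests against enumeration oracles, power analysis, bootstrap basics."""

import itertools

import numpy as np
import pytest

from attnspace import (
    PowerSpec,
    minimal_detectable_effect,
    power_of_effect,
    rank_sum_test,
    shuffle_split_stress_test,
    sign_rank_test,
)
from attnspace.errors import DomainError, NoSolutionError


# -- enumeration oracles ------------------------------------------------------


def rank_sum_enum(a, b):
    """Exact two-sided rank-sum p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2
    obs = abs(sum(ranks[v] for v in a) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        stat = abs(sum(ranks[pooled[i]] for i in combo) - mu)
        hits += stat >= obs - 1e-9
        total += 1
    return hits / total


def sign_rank_enum(diffs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    mu = ranks.sum() / 2
    obs = abs(ranks[d > 0].sum() - mu)
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        stat = abs(sum(r for r, s in zip(ranks, signs) if s) - mu)
        hits += stat >= obs - 1e-9
        total += 1
    return hits / total


class TestRankSum:
    def test_identical_samples(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) >= 0.99

    def test_fully_separated_small_samples(self):
        # the most extreme of C(6,3)=20 labelings, both tails: p = 2/20
        assert rank_sum_test([1, 2, 3], [101, 102, 103]) == pytest.approx(0.1)

    def test_two_vs_two(self):
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9), rng.integers(2, 9)
        # distinct values so no ties and the exact method applies
        vals = rng.permutation(100)[: n1 + n2].astype(float)
        a, b = vals[:n1], vals[n1:]
        assert rank_sum_test(a, b) == pytest.approx(rank_sum_enum(a, b),
                                                    abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            rank_sum_test([], [1.0])


class TestSignRank:
    def test_all_zero_differences_give_p_one(self):
        assert sign_rank_test([0.0, 0.0, 0.0]) == 1.0

    def test_all_positive_five(self):
        # most extreme of the 2^5 sign patterns, both tails: 2/32
        assert sign_rank_test([1, 2, 3, 4, 5]) == pytest.approx(0.0625)

    def test_sign_flip_invariance(self):
        d = np.array([1.5, -2.0, 3.0, 0.5, -1.0])
        assert sign_rank_test(d) == pytest.approx(sign_rank_test(-d))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = rng.integers(3, 9)
        d = rng.permutation(50)[:n].astype(float) + 0.5
        d *= np.where(rng.random(n) < 0.5, -1.0, 1.0)
        assert sign_rank_test(d) == pytest.approx(sign_rank_enum(d), abs=1e-12)


class TestPowerAnalysis:
    def test_closed_form_at_study_design(self):
        spec = PowerSpec(n=28, alpha=0.05, target_power=0.8, sd=1.0)
        delta = minimal_detectable_effect(spec)
        assert delta == pytest.approx(0.52945, abs=1e-5)

    def test_round_trip_power_exact(self):
        spec = PowerSpec(n=28, alpha=0.05, target_power=0.8, sd=2.3)
        delta = minimal_detectable_effect(spec)
        assert power_of_effect(delta, spec, both_tails=False) == pytest.approx(
            0.8, abs=1e-9)

    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(n=28, alpha=0.05, target_power=0.8, sd=1.0)
        assert power_of_effect(0.0, spec) == pytest.approx(0.05, abs=1e-12)

    def test_sd_scale_equivariance(self):
        a = minimal_detectable_effect(PowerSpec(sd=1.0))
        b = minimal_detectable_effect(PowerSpec(sd=2.0))
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_unreachable_power_rejected(self):
        with pytest.raises(NoSolutionError):
            minimal_detectable_effect(
                PowerSpec(n=28, alpha=0.9, target_power=0.01, sd=1.0))


class TestBootstrapBasics:
    def _arrays(self, rng, n_cells=10, reps=8):
        x = rng.uniform(5, 20, (n_cells, 3))
        p8 = rng.uniform(5, 20, (n_cells, 8))
        lam = x[:, :, None] * 0.5
        ta = rng.poisson(lam, (n_cells, 3, reps)) / 0.5
        tb = rng.poisson(lam, (n_cells, 3, reps)) / 0.5
        return x, p8, ta, tb

    def test_identical_conditions_give_zero_observed_and_p_one(self, rng):
        x, p8, ta, _ = self._arrays(rng)
        res = shuffle_split_stress_test(x, p8, ta, ta.copy(), n_boot=50, seed=0)
        assert res.observed_stress == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0  # every resampled stress exceeds zero

    def test_seeded_determinism(self, rng):
        x, p8, ta, tb = self._arrays(rng)
        r1 = shuffle_split_stress_test(x, p8, ta, tb, n_boot=40, seed=7)
        r2 = shuffle_split_stress_test(x, p8, ta, tb, n_boot=40, seed=7)
        assert np.array_equal(r1.null_stresses, r2.null_stresses)
        assert r1.p_value == r2.p_value

    def test_p_value_definition(self, rng):
        x, p8, ta, tb = self._arrays(rng)
        res = shuffle_split_stress_test(x, p8, ta, tb, n_boot=100, seed=3)
        assert res.p_value == np.mean(res.null_stresses > res.observed_stress)
        assert 0.0 <= res.p_value <= 1.0

    def test_zero_passive_vector_rejected(self, rng):
        x, p8, ta, tb = self._arrays(rng)
        x[0] = 0.0
        with pytest.raises(DomainError):
            shuffle_split_stress_test(x, p8, ta, tb, n_boot=10, seed=0)
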