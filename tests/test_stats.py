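"""Kernel-level tests against independent oracles: exact enumeration,
closed forms, scipy's independent implementations and brute-force draws."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirenrich.errors import DomainError
from mirenrich.stats import (
    UrnSpec,
    bh_adjust,
    camera_pr,
    estimate_bias_odds,
    fisher_combine,
    hypergeom_upper_tail,
    ks_test,
    mwu_test,
    wallenius_upper_tail,
)


def enumerate_draw_tail(N, K, n, k):
    """Oracle: P(overlap >= k) by enumerating every C(N, n) draw."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return Fraction(hits, total)


def wallenius_brute_tail(N, K, n, k, w):
    """Oracle: enumerate all in/out draw sequences with weighted probabilities."""
    total = 0.0
    for seq in itertools.product((0, 1), repeat=n):
        if sum(seq) > K or n - sum(seq) > N - K:
            continue
        p, drawn_in, drawn_out = 1.0, 0, 0
        for s in seq:
            rem_in = (K - drawn_in) * w
            rem_out = N - K - drawn_out
            if s:
                p *= rem_in / (rem_in + rem_out)
                drawn_in += 1
            else:
                p *= rem_out / (rem_in + rem_out)
                drawn_out += 1
        if sum(seq) >= k:
            total += p
    return total


class TestHypergeom:
    def test_worked_urn(self):
        res = hypergeom_upper_tail(UrnSpec(20, 5, 10, 5))
        assert res.p_value == pytest.approx(3003 / 184756, abs=1e-15)

    def test_full_upper_tail_at_zero(self):
        assert hypergeom_upper_tail(UrnSpec(17, 4, 9, 0)).p_value == 1.0

    def test_small_urn_by_enumeration(self):
        assert hypergeom_upper_tail(UrnSpec(6, 3, 3, 3)).p_value == pytest.approx(
            1 / 20, abs=1e-15
        )
        for N in range(1, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeom_upper_tail(UrnSpec(N, K, n, k)).p_value
                        want = float(enumerate_draw_tail(N, K, n, k))
                        assert got == pytest.approx(want, abs=1e-13)

    def test_invalid_urn_rejected(self):
        with pytest.raises(DomainError):
            UrnSpec(10, 12, 3, 1)
        with pytest.raises(DomainError):
            UrnSpec(10, 5, 3, 4)
        with pytest.raises(DomainError):
            hypergeom_upper_tail(UrnSpec(10, 5, 3, 1, odds=2.0))


class TestWallenius:
    def test_central_reduction(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            a = wallenius_upper_tail(UrnSpec(N, K, n, k, 1.0)).p_value
            b = hypergeom_upper_tail(UrnSpec(N, K, n, k)).p_value
            assert a == pytest.approx(b, abs=1e-9)

    def test_brute_force_small_urns(self):
        for w in (0.5, 2.0):
            for N in range(1, 9):
                for K in range(N + 1):
                    for n in range(N + 1):
                        for k in range(min(K, n) + 1):
                            got = wallenius_upper_tail(UrnSpec(N, K, n, k, w)).p_value
                            want = wallenius_brute_tail(N, K, n, k, w)
                            assert got == pytest.approx(want, abs=1e-9)

    def test_matches_scipy_wallenius(self):
        # independent implementation cross-check
        for (N, K, n, k, w) in [(50, 12, 20, 7, 2.5), (80, 30, 25, 5, 0.3)]:
            got = wallenius_upper_tail(UrnSpec(N, K, n, k, w)).p_value
            ref = sps.nchypergeom_wallenius.sf(k - 1, N, K, n, w)
            assert got == pytest.approx(ref, rel=1e-6)

    def test_large_odds_limit(self):
        # in-term balls drawn first: with n >= K, P(X >= K) -> 1
        res = wallenius_upper_tail(UrnSpec(20, 5, 10, 5, 1e9))
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_odds_rejected(self):
        with pytest.raises(DomainError):
            UrnSpec(10, 3, 4, 2, odds=0.0)


class TestBiasOdds:
    def test_constant_covariate_gives_unit_odds(self):
        universe = [f"g{i}" for i in range(50)]
        flags = {g: int(i % 3 == 0) for i, g in enumerate(universe)}
        bias = {g: 1.0 for g in universe}
        w = estimate_bias_odds(universe[:10], flags, bias, universe)
        assert w == pytest.approx(1.0)

    def test_manual_two_bin_oracle(self):
        # 20 genes at bias 0 (4 targeted), 20 at bias 1 (12 targeted);
        # term = 10 high-bias genes: w = (0.6/0.4)/((1/3)/(2/3)) = 3
        lo = [f"a{i:02d}" for i in range(20)]
        hi = [f"b{i:02d}" for i in range(20)]
        universe = lo + hi
        bias = {g: 0.0 for g in lo} | {g: 1.0 for g in hi}
        flags = {g: 1 for g in lo[:4]} | {g: 1 for g in hi[:12]}
        w = estimate_bias_odds(hi[:10], flags, bias, universe)
        assert w == pytest.approx(3.0, rel=1e-9)

    def test_degenerate_mean_clamped(self):
        universe = [f"g{i}" for i in range(30)]
        flags = {g: 1 for g in universe}  # everything targeted
        bias = {g: float(i) for i, g in enumerate(universe)}
        with pytest.warns(UserWarning):
            w = estimate_bias_odds(universe[:5], flags, bias, universe)
        assert math.isfinite(w) and w > 0


class TestFisherCombine:
    def test_all_ones(self):
        res = fisher_combine([1.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_half_half_closed_form(self):
        res = fisher_combine([0.5, 0.5])
        x = -2 * (math.log(0.5) + math.log(0.5))
        assert res.statistic == pytest.approx(x)
        # chi-square survival at df=4: e^(-x/2) (1 + x/2)
        assert res.p_value == pytest.approx(math.exp(-x / 2) * (1 + x / 2), rel=1e-12)
        assert res.p_value == pytest.approx(0.5966, abs=5e-5)

    def test_single_p_identity(self):
        for p in (0.001, 0.25, 0.8):
            assert fisher_combine([p]).p_value == pytest.approx(p, rel=1e-12)

    def test_zero_clamped_and_empty_rejected(self):
        with pytest.warns(UserWarning):
            res = fisher_combine([0.0, 0.5])
        assert 0 <= res.p_value < 1e-100
        with pytest.raises(DomainError):
            fisher_combine([])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariant(self, ps):
        a = fisher_combine(ps).p_value
        b = fisher_combine(list(reversed(ps))).p_value
        assert a == pytest.approx(b, rel=1e-12)


def mwu_enumeration_p(x, y, alternative):
    """Oracle: exact one/two-sided MWU p by enumerating all labelings."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        rx = sum(ranks[i] for i in idx)
        return rx - nx * (nx + 1) / 2

    u_obs = u_of(range(nx))
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), nx)]
    m = len(us)
    if alternative == "less":
        return sum(u <= u_obs for u in us) / m
    if alternative == "greater":
        return sum(u >= u_obs for u in us) / m
    lo = sum(u <= u_obs for u in us) / m
    hi = sum(u >= u_obs for u in us) / m
    return min(1.0, 2 * min(lo, hi))


class TestMWU:
    def test_worked_case(self):
        res = mwu_test([1, 2, 3], [4, 5, 6], "less")
        assert res.p_value == pytest.approx(1 / 20, abs=1e-12)
        assert res.method == "mwu_exact"

    def test_identical_multisets(self):
        res = mwu_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "two_sided")
        assert res.p_value == 1.0

    def test_all_identical_values_warns(self):
        with pytest.warns(UserWarning):
            res = mwu_test([2.0, 2.0], [2.0, 2.0], "less")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_exact_branch_equals_enumeration(self, alternative):
        rng = np.random.default_rng(11)
        for nx in range(1, 6):
            for ny in range(1, 11 - nx):
                vals = rng.permutation(np.arange(1.0, nx + ny + 1))
                x, y = vals[:nx], vals[nx:]
                got = mwu_test(x, y, alternative).p_value
                want = mwu_enumeration_p(x, y, alternative)
                assert got == pytest.approx(want, abs=1e-12)

    def test_exact_vs_normal_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            exact = mwu_test(x, y, "less").p_value
            approx = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
            assert abs(exact - approx) < 0.01


class TestKS:
    def test_identical_samples(self):
        res = ks_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "two_sided")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_supports(self):
        assert ks_test([1, 2], [3, 4], "two_sided").statistic == 1.0

    def test_orientation_of_less(self):
        # x far below y: one-sided "less" should be small, "greater" ~ 1
        x, y = [0.0, 0.1, 0.2, 0.3], [5.0, 5.1, 5.2, 5.3]
        assert ks_test(x, y, "less").p_value < 0.05
        assert ks_test(x, y, "greater").p_value > 0.9

    def test_exact_small_sample_vs_permutation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4)
        y = rng.normal(size=4) + 0.5
        pooled = np.concatenate([x, y])

        def d_two_sided(a, b):
            grid = np.sort(pooled)
            fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
            return np.max(np.abs(fa - fb))

        d_obs = d_two_sided(x, y)
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(8) if i not in idx]]
            total += 1
            if d_two_sided(a, b) >= d_obs - 1e-12:
                count += 1
        want = count / total
        got = ks_test(x, y, "two_sided").p_value
        assert got == pytest.approx(want, abs=1e-9)


class TestCameraPR:
    def test_symmetric_member_z_zero(self):
        stat = {f"g{i}": float(i) for i in range(11)}
        res = camera_pr(stat, {"g0", "g10"}, rho=0.0, alternative="less")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_rho_zero_matches_wilcoxon_normal(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=200)
        stat = {f"g{i}": float(v) for i, v in enumerate(vals)}
        member = {f"g{i}" for i in rng.choice(200, size=20, replace=False)}
        got = camera_pr(stat, member, rho=0.0, alternative="less").p_value
        x = [stat[g] for g in member]
        y = [stat[g] for g in stat if g not in member]
        ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert abs(got - ref) < 0.02

    def test_p_uniform_under_random_membership(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=500)
        stat = {f"g{i}": float(v) for i, v in enumerate(vals)}
        ps = []
        for _ in range(500):
            member = {f"g{i}" for i in rng.choice(500, size=20, replace=False)}
            ps.append(camera_pr(stat, member, rho=0.0, alternative="less").p_value)
        ks_p = sps.kstest(ps, "uniform").pvalue
        assert ks_p > 0.01

    def test_degenerate_membership_rejected(self):
        stat = {"a": 1.0, "b": 2.0}
        with pytest.raises(DomainError):
            camera_pr(stat, set(), rho=0.0)
        with pytest.raises(DomainError):
            camera_pr(stat, {"a", "b"}, rho=0.0)


class TestBHAdjust:
    def test_step_up_minima(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_empty(self):
        assert bh_adjust([]) == []

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        adj = bh_adjust(ps)
        assert len(adj) == len(ps)
        for raw, a in zip(ps, adj):
            assert a >= raw - 1e-15
            assert a <= 1.0


@given(
    st.integers(1, 40).flatmap(
        lambda N: st.tuples(
            st.just(N),
            st.integers(0, N),
            st.integers(0, N),
        )
    ),
    st.floats(0.1, 10.0),
    st.randoms(use_true_random=False),
)
@settings(deadline=None, max_examples=80)
def test_urn_p_values_always_in_unit_interval(nkn, w, rnd):
    N, K, n = nkn
    k = rnd.randint(0, min(K, n))
    assert 0.0 <= hypergeom_upper_tail(UrnSpec(N, K, n, k)).p_value <= 1.0
    assert 0.0 <= wallenius_upper_tail(UrnSpec(N, K, n, k, w)).p_value <= 1.0
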