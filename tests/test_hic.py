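"""Significance testing of Hi-C pairs: decay background, non-central
hypergeometric tail, odds calibration, FDR control and recurrence."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, nchypergeom_fisher

import nucstruct as ns
from nucstruct.hic import (
    OMEGA_FLOOR,
    DecayProfile,
    NCHGResult,
    SignificantCalls,
    call_significant,
    estimate_decay,
    nchg_pvalue,
    omega_for_pair,
    recurrence_filter,
)

CR = ns.ContactRecord


def central_tail_bruteforce(x: int, n_i: int, n_j: int, N: int) -> float:
    """Independent oracle: enumerate the central hypergeometric pmf."""
    kmin, kmax = max(0, n_i + n_j - N), min(n_i, n_j)
    w = [math.comb(n_i, k) * math.comb(N - n_i, n_j - k) for k in range(kmin, kmax + 1)]
    tot = sum(w)
    return sum(w[k - kmin] for k in range(max(x, kmin), kmax + 1)) / tot


class TestEstimateDecay:
    def test_direct_averages(self):
        recs = [CR("chr1", 0, "chr1", 1, 4), CR("chr1", 1, "chr1", 2, 2),
                CR("chr1", 0, "chr1", 2, 6)]
        p = estimate_decay(recs, 1, n_bins={"chr1": 3})
        assert p.expected_count[1] == pytest.approx(3.0)
        assert p.expected_count[2] == pytest.approx(6.0)

    def test_zero_counts_give_zero_expectation(self):
        recs = [CR("chr1", 0, "chr1", 1, 0), CR("chr1", 0, "chr1", 2, 0)]
        p = estimate_decay(recs, 1)
        assert np.all(p.expected_count == 0)

    def test_inter_expected(self):
        recs = [CR("chr1", 0, "chr1", 1, 1),
                CR("chr1", 0, "chr2", 0, 3), CR("chr1", 0, "chr2", 1, 5)]
        p = estimate_decay(recs, 1, n_bins={"chr1": 2, "chr2": 2})
        assert p.inter_expected == pytest.approx(8 / 4)

    def test_zero_pair_denominator_counts_unobserved_pairs(self):
        # one count at d=1 among 3 bins: 2 pairs at that distance
        p = estimate_decay([CR("chr1", 0, "chr1", 1, 6)], 1, n_bins={"chr1": 3})
        assert p.expected_count[1] == pytest.approx(3.0)

    def test_no_intra_data_rejected(self):
        with pytest.raises(ValueError, match="intra"):
            estimate_decay([CR("chr1", 0, "chr2", 0, 3)], 1)


class TestNCHGPvalue:
    def test_reduces_to_central_at_unit_odds(self):
        assert nchg_pvalue(3, 5, 5, 20, 1.0) == pytest.approx(
            central_tail_bruteforce(3, 5, 5, 20), rel=1e-12)

    def test_central_reduction_on_grid(self):
        for N in (5, 12, 23):
            for n_i in range(N + 1):
                for n_j in range(n_i + 1):
                    for x in range(min(n_i, n_j) + 1):
                        assert nchg_pvalue(x, n_i, n_j, N, 1.0) == pytest.approx(
                            central_tail_bruteforce(x, n_i, n_j, N), rel=1e-10)

    def test_whole_support_is_one(self):
        assert nchg_pvalue(0, 4, 4, 10, 3.7) == 1.0

    def test_explicit_five_term_enumeration(self):
        # N=10, n_i=n_j=4, omega=2: w(k) = C(4,k) C(6,4-k) 2^k, k=0..4
        w = [math.comb(4, k) * math.comb(6, 4 - k) * 2**k for k in range(5)]
        assert nchg_pvalue(4, 4, 4, 10, 2.0) == pytest.approx(w[4] / sum(w), rel=1e-12)

    def test_matches_scipy_on_random_grid(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            N = int(rng.integers(2, 200))
            n_i = int(rng.integers(1, N + 1))
            n_j = int(rng.integers(1, N + 1))
            x = int(rng.integers(0, min(n_i, n_j) + 1))
            omega = float(rng.uniform(0.05, 20.0))
            ours = nchg_pvalue(x, n_i, n_j, N, omega)
            ref = nchypergeom_fisher.sf(x - 1, N, n_i, n_j, omega)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_monotone_in_x_and_omega(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            N = int(rng.integers(4, 120))
            n_i = int(rng.integers(1, N + 1))
            n_j = int(rng.integers(1, N + 1))
            om = sorted(rng.uniform(0.1, 10.0, 2))
            xs = np.arange(0, min(n_i, n_j) + 1)
            p_lo = [nchg_pvalue(int(x), n_i, n_j, N, om[0]) for x in xs]
            p_hi = [nchg_pvalue(int(x), n_i, n_j, N, om[1]) for x in xs]
            # upper tail shrinks as the observation threshold x grows ...
            assert all(a >= b - 1e-12 for a, b in zip(p_lo, p_lo[1:]))
            # ... and grows with omega (larger odds tilt the null upward,
            # making any given count less surprising)
            assert all(lo <= hi + 1e-12 for lo, hi in zip(p_lo, p_hi))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            nchg_pvalue(1, 5, 5, 4, 1.0)
        with pytest.raises(ValueError):
            nchg_pvalue(6, 5, 5, 20, 1.0)
        with pytest.raises(ValueError):
            nchg_pvalue(1, 5, 5, 20, 0.0)


class TestOmega:
    @staticmethod
    def _full_matrix_oracle(profile: DecayProfile, pair):
        """Independent oracle: build the complete expected pair matrix and
        collapse it to a 2x2 table around the pair; return its odds ratio."""
        bins = [(c, b) for c, B in profile.n_bins.items() for b in range(B)]
        mu = {}
        for a in range(len(bins)):
            for b in range(a + 1, len(bins)):
                (ca, ia), (cb, ib) = bins[a], bins[b]
                key = (ca, ia * profile.binsize, cb, ib * profile.binsize)
                mu[key] = profile.expected(key)
        M = sum(mu.values())
        def marginal(c, b):
            return sum(v for k, v in mu.items()
                       if (k[0], k[1]) == (c, b) or (k[2], k[3]) == (c, b))
        m_i = marginal(pair[0], pair[1])
        m_j = marginal(pair[2], pair[3])
        E = mu[pair]
        return E * (M - m_i - m_j + E) / ((m_i - E) * (m_j - E))

    def test_matches_full_matrix_odds_ratio_oracle(self):
        rng = np.random.default_rng(3)
        profile = DecayProfile(
            binsize=1, distance_bins=np.arange(5),
            expected_count=np.r_[0.0, np.sort(rng.uniform(1, 20, 4))[::-1]],
            inter_expected=0.7, n_bins={"chr1": 5, "chr2": 4})
        for pair in [("chr1", 0, "chr1", 2), ("chr1", 1, "chr1", 4),
                     ("chr1", 0, "chr2", 3), ("chr2", 0, "chr2", 1)]:
            assert omega_for_pair(profile, pair) == pytest.approx(
                self._full_matrix_oracle(profile, pair), rel=1e-10)

    def test_unit_odds_iff_independence_expectation(self):
        """omega crosses 1 exactly where the decay expectation crosses the
        independence expectation m_i m_j / M."""
        profile = DecayProfile(
            binsize=1, distance_bins=np.arange(4),
            expected_count=np.array([0.0, 6.0, 3.0, 1.5]),
            inter_expected=0.5, n_bins={"chr1": 4, "chr2": 4})
        M = profile.expected_total()
        for pair in [("chr1", 0, "chr1", 1), ("chr1", 0, "chr1", 3),
                     ("chr1", 0, "chr2", 0)]:
            m_i = profile.expected_marginal(pair[0], pair[1])
            m_j = profile.expected_marginal(pair[2], pair[3])
            indep = m_i * m_j / M
            om = omega_for_pair(profile, pair, M)
            assert (om > 1) == (profile.expected(pair) > indep) or \
                om == pytest.approx(1.0, abs=1e-9)

    def test_zero_expectation_clamped(self):
        profile = DecayProfile(binsize=1, distance_bins=np.array([0, 1, 2]),
                               expected_count=np.array([0.0, 0.0, 0.0]),
                               inter_expected=1.0, n_bins={"chr1": 3, "chr2": 3})
        assert omega_for_pair(profile, ("chr1", 0, "chr1", 2)) == OMEGA_FLOOR

    def test_monotone_in_expectation(self):
        def om(e):
            profile = DecayProfile(binsize=1, distance_bins=np.arange(4),
                                   expected_count=np.array([0.0, 5.0, e, 5.0]),
                                   inter_expected=0.5, n_bins={"chr1": 4, "chr2": 4})
            return omega_for_pair(profile, ("chr1", 0, "chr1", 2))
        vals = [om(e) for e in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_undefined_distance_rejected(self):
        profile = DecayProfile(binsize=1, distance_bins=np.arange(2),
                               expected_count=np.ones(2), inter_expected=0.0,
                               n_bins={"chr1": 2})
        with pytest.raises(ValueError):
            profile.expected(("chr1", 0, "chr1", 5))


class TestCallSignificant:
    def test_power_and_fdr_on_planted_fixture(self):
        recoveries, fdps = [], []
        for seed in range(3):
            spec = ns.SyntheticSpec(seed=seed)
            records, truth = ns.make_synthetic_contacts(spec)
            calls = call_significant(records, spec.binsize, fdr_intra=1e-4)
            called = {r.pair for r in calls.intra}
            truth = set(truth)
            tp = len(called & truth)
            recoveries.append(tp / len(truth))
            fdps.append((len(called) - tp) / max(len(called), 1))
        assert np.mean(recoveries) >= 0.9
        assert np.mean(fdps) <= 0.05

    def test_null_yields_no_calls(self):
        spec = ns.SyntheticSpec(seed=123, planted_pairs=0)
        records, _ = ns.make_synthetic_contacts(spec)
        assert call_significant(records, spec.binsize, fdr_intra=1e-4).intra == []

    def test_null_pvalues_not_anticonservative(self):
        """Under a simulated null matching the decay profile, candidate
        p-values are stochastically >= uniform (one-sided ECDF check)."""
        from nucstruct.hic import _marginals

        spec = ns.SyntheticSpec(seed=5, planted_pairs=0, n_chrom=4)
        records, _ = ns.make_synthetic_contacts(spec)
        profile = estimate_decay(records, spec.binsize)
        marg, N = _marginals(records, spec.binsize)
        M = profile.expected_total()
        pvals = []
        for r in records:
            if not r.is_intra or r.count < 1:
                continue
            n_i, n_j = marg[(r.chromA, r.binA)], marg[(r.chromB, r.binB)]
            om = omega_for_pair(profile, r.key, M)
            pvals.append(nchg_pvalue(min(r.count, n_i, n_j), n_i, n_j, N, om))
        pvals = np.array(pvals)
        n = len(pvals)
        assert n > 3000
        for t in (0.001, 0.01, 0.05, 0.1):
            frac = float((pvals <= t).mean())
            assert frac <= t + 3 * math.sqrt(t * (1 - t) / n)

    def test_all_zero_counts_empty(self):
        recs = [CR("chr1", 0, "chr1", 1_000_000, 0)]
        calls = call_significant(recs, 1_000_000, min_count=1)
        assert calls.intra == [] and calls.inter == []

    def test_bh_rejections_nested_across_alpha(self):
        spec = ns.SyntheticSpec(seed=2)
        records, _ = ns.make_synthetic_contacts(spec)
        loose = {r.pair for r in call_significant(records, spec.binsize, fdr_intra=1e-2).intra}
        strict = {r.pair for r in call_significant(records, spec.binsize, fdr_intra=1e-5).intra}
        assert strict <= loose

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            call_significant([CR("chr1", 0, "chr1", 1, 5)], 1, fdr_intra=0.0)


class TestRecurrenceFilter:
    @staticmethod
    def _calls(keys_q, binsize=1_000_000, fdr=1e-4):
        inter = [NCHGResult(k, 5, 10, 10, 100, 1.0, 1.0, q, q) for k, q in keys_q]
        return SignificantCalls(binsize=binsize, fdr=fdr, intra=[], inter=inter)

    def test_strict_support_threshold(self):
        key = ("chr1", 0, "chr2", 0)
        focal = self._calls([(key, 1e-6)])
        hit = self._calls([(key, 1e-6)])
        miss = self._calls([(key, 0.5)])
        assert recurrence_filter(focal, [hit] * 5 + [miss] * 2, min_support=4) == [key]
        assert recurrence_filter(focal, [hit] * 4 + [miss] * 3, min_support=4) == []

    def test_empty_others_with_zero_support(self):
        key = ("chr1", 0, "chr2", 0)
        focal = self._calls([(key, 1e-6)])
        assert recurrence_filter(focal, [], min_support=0) == [key]

    def test_grid_mismatch_rejected(self):
        focal = self._calls([])
        other = self._calls([], binsize=500_000)
        with pytest.raises(ValueError, match="grid"):
            recurrence_filter(focal, [other])
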