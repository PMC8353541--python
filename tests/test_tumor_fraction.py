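"""Copy-number HMM: emission model, exact inference oracles, estimator recovery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import norm, spearmanr

from csflmd.coverage import BinnedCoverage, coverage_from_counts
from csflmd.simulate import (
    SimSampleConfig,
    random_cna_profile,
    simulate_binned_counts,
)
from csflmd.tumor_fraction import (
    HmmParams,
    classify_lmd,
    estimate_tumor_fraction,
    expected_log2_ratio,
    hmm_loglik,
    viterbi_path,
    viterbi_segments,
)


def brute_force_paths(x, params):
    """Independent oracle: enumerate all 6^n state paths, fully vectorized.

    Returns (log-sum over paths, best path score, one best path)."""
    n, k = len(x), params.n_states
    means = params.state_means()
    emis = norm.logpdf(np.asarray(x)[:, None], means[None, :], params.sigma)
    q = (1.0 - params.p_stay) / (k - 1)
    logT = np.full((k, k), math.log(q))
    np.fill_diagonal(logT, math.log(params.p_stay))
    paths = np.array(list(itertools.product(range(k), repeat=n)))
    scores = params.log_pi()[paths[:, 0]] + emis[0, paths[:, 0]]
    for t in range(1, n):
        scores = scores + logT[paths[:, t - 1], paths[:, t]] + emis[t, paths[:, t]]
    best = int(np.argmax(scores))
    return float(logsumexp(scores)), float(scores[best]), paths[best]


def path_score(x, copies, params):
    means = params.state_means()
    states = np.searchsorted(params.copy_states, copies)
    emis = norm.logpdf(np.asarray(x), means[states], params.sigma)
    q = (1.0 - params.p_stay) / (params.n_states - 1)
    trans = sum(
        math.log(params.p_stay) if a == b else math.log(q)
        for a, b in zip(states[:-1], states[1:])
    )
    return float(params.log_pi()[states[0]] + emis.sum() + trans)


class TestExpectedLog2Ratio:
    def test_pure_normal_is_zero_for_any_copy(self):
        assert all(expected_log2_ratio(c, 0.0) == 0.0 for c in range(6))

    def test_diploid_tumor_is_zero(self):
        assert expected_log2_ratio(2, 1.0) == 0.0

    def test_direct_values(self):
        assert expected_log2_ratio(4, 1.0) == pytest.approx(1.0)
        assert expected_log2_ratio(3, 0.5) == pytest.approx(math.log2(1.25), abs=1e-9)

    def test_homozygous_deletion_floored(self):
        assert expected_log2_ratio(0, 1.0) == -3.0

    @pytest.mark.parametrize("tf", [0.1, 0.5, 1.0])
    def test_strictly_increasing_in_copy_for_positive_tf(self, tf):
        vals = [expected_log2_ratio(c, tf) for c in range(6)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_log2_ratio(6, 0.5)
        with pytest.raises(ValueError):
            expected_log2_ratio(2, 1.5)


class TestExactInference:
    def test_single_bin_is_mixture_density(self):
        params = HmmParams(tf=0.4, sigma=0.2)
        x = np.array([0.37])
        expected = logsumexp(
            norm.logpdf(x[0], params.state_means(), 0.2) - math.log(6)
        )
        assert hmm_loglik(x, params) == pytest.approx(float(expected), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        data=st.lists(st.floats(-2.5, 1.5), min_size=1, max_size=6),
        tf=st.floats(0.0, 1.0),
        sigma=st.floats(0.05, 1.0),
        p_stay=st.floats(0.5, 0.999),
    )
    def test_forward_matches_exhaustive_paths(self, data, tf, sigma, p_stay):
        x = np.asarray(data)
        params = HmmParams(tf=tf, sigma=sigma, p_stay=p_stay)
        expected, _, _ = brute_force_paths(x, params)
        assert hmm_loglik(x, params) == pytest.approx(expected, abs=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        data=st.lists(st.floats(-2.5, 1.5), min_size=1, max_size=6),
        tf=st.floats(0.05, 1.0),
        sigma=st.floats(0.05, 1.0),
        p_stay=st.floats(0.5, 0.999),
    )
    def test_viterbi_matches_exhaustive_argmax(self, data, tf, sigma, p_stay):
        x = np.asarray(data)
        params = HmmParams(tf=tf, sigma=sigma, p_stay=p_stay)
        _, best_score, _ = brute_force_paths(x, params)
        copies = viterbi_path(x, params)
        assert path_score(x, copies, params) == pytest.approx(best_score, abs=1e-8)

    def test_eight_bin_instances_match_oracles(self, rng):
        for _ in range(3):
            x = rng.normal(0.2, 0.4, 8)
            params = HmmParams(tf=0.55, sigma=0.25, p_stay=0.95)
            log_sum, best_score, _ = brute_force_paths(x, params)
            assert hmm_loglik(x, params) == pytest.approx(log_sum, abs=1e-8)
            assert path_score(x, viterbi_path(x, params), params) == pytest.approx(
                best_score, abs=1e-8
            )

    def test_chromosomes_factorize(self, rng):
        x = rng.normal(0, 0.3, 12)
        params = HmmParams(tf=0.5, sigma=0.25)
        single = hmm_loglik(x, params)
        doubled = hmm_loglik(
            np.concatenate([x, x]), params, chrom=np.array(["1"] * 12 + ["2"] * 12)
        )
        assert doubled == pytest.approx(2 * single, abs=1e-9)

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            hmm_loglik(np.array([0.1, 0.2]), HmmParams(tf=0.2, sigma=0.2),
                       mask=np.array([False, False]))


class TestViterbiSegments:
    def test_flat_series_single_diploid_segment(self):
        x = np.zeros(50)
        params = HmmParams(tf=0.5, sigma=0.2)
        segs = viterbi_segments(x, params)
        assert len(segs) == 1
        assert segs.iloc[0].copy_number == 2 and segs.iloc[0].num_bins == 50

    def test_tf_zero_ties_resolve_to_diploid(self, rng):
        # at tf=0 every state has the same mean; preference must pick copy 2
        x = rng.normal(0, 0.2, 30)
        copies = viterbi_path(x, HmmParams(tf=0.0, sigma=0.2))
        assert (copies == 2).all()

    def test_recovers_simulated_arm_with_high_jaccard(self, mid_bins):
        from csflmd.simulate import CnaSegmentSpec

        seg = CnaSegmentSpec("5", 0, 15_000_000, 4)  # 15 of 20 bins on chr5
        cfg = SimSampleConfig(tumor_fraction=0.6, cna_profile=[seg], seed=21)
        counts = simulate_binned_counts(mid_bins, cfg)
        cov = coverage_from_counts(counts, mid_bins)
        est = estimate_tumor_fraction(cov)
        truth = (mid_bins.chrom == "5") & (mid_bins.end <= 15_000_000)
        called = np.zeros(len(mid_bins), bool)
        for _, s in est.segments[est.segments.copy_number != 2].iterrows():
            called |= (mid_bins.chrom == s.chrom) & (mid_bins.start >= s.start) & (
                mid_bins.end <= s.end
            )
        jaccard = (truth & called).sum() / (truth | called).sum()
        assert jaccard >= 0.9


class TestEstimator:
    def test_null_sample_selects_diploid_model(self, mid_bins):
        cfg = SimSampleConfig(tumor_fraction=0.0, seed=31)
        cov = coverage_from_counts(simulate_binned_counts(mid_bins, cfg), mid_bins)
        est = estimate_tumor_fraction(cov)
        assert est.lmd_call == "negative"
        assert est.tf_hat < 0.03 or est.delta_loglik < 2.0

    def test_typical_positive_sample_called_positive(self, full_bins, rng):
        # tumor fraction at the level typical of LMD-positive CSF (~0.59)
        profile = random_cna_profile(full_bins, rng, 0.25)
        cfg = SimSampleConfig(tumor_fraction=0.589, cna_profile=profile, seed=8)
        cov = coverage_from_counts(simulate_binned_counts(full_bins, cfg), full_bins)
        est = estimate_tumor_fraction(cov)
        assert est.lmd_call == "positive"
        assert abs(est.tf_hat - 0.589) <= 0.1

    def test_monotone_in_true_tf(self, full_bins):
        means = []
        for tf in (0.2, 0.4, 0.8):
            vals = []
            for rep in range(5):
                rng = np.random.default_rng(1000 + rep)
                profile = random_cna_profile(full_bins, rng, 0.25)
                cfg = SimSampleConfig(tumor_fraction=tf, cna_profile=profile,
                                      seed=2000 + rep)
                cov = coverage_from_counts(simulate_binned_counts(full_bins, cfg), full_bins)
                vals.append(estimate_tumor_fraction(cov).tf_hat)
            means.append(np.mean(vals))
        rho, _ = spearmanr([0.2, 0.4, 0.8], means)
        assert rho == 1.0

    def test_recovery_improves_with_depth(self, full_bins):
        errs = []
        for depth in (0.05, 0.2, 1.0):
            e = []
            for rep in range(8):
                rng = np.random.default_rng(3000 + rep)
                profile = random_cna_profile(full_bins, rng, 0.25)
                cfg = SimSampleConfig(tumor_fraction=0.6, mean_depth=depth,
                                      cna_profile=profile, seed=4000 + rep)
                cov = coverage_from_counts(simulate_binned_counts(full_bins, cfg), full_bins)
                e.append(abs(estimate_tumor_fraction(cov).tf_hat - 0.6))
            errs.append(np.mean(e))
        assert errs[0] > errs[1] > errs[2]

    def test_determinism(self, mid_bins, rng):
        profile = random_cna_profile(mid_bins, rng, 0.25)
        cfg = SimSampleConfig(tumor_fraction=0.5, cna_profile=profile, seed=55)
        cov = coverage_from_counts(simulate_binned_counts(mid_bins, cfg), mid_bins)
        a = estimate_tumor_fraction(cov)
        b = estimate_tumor_fraction(cov)
        assert a.tf_hat == b.tf_hat and a.loglik == b.loglik
        assert a.segments.equals(b.segments)

    def test_grid_must_include_zero(self, mid_bins):
        cfg = SimSampleConfig(tumor_fraction=0.0, seed=1)
        cov = coverage_from_counts(simulate_binned_counts(mid_bins, cfg), mid_bins)
        with pytest.raises(ValueError, match="include 0"):
            estimate_tumor_fraction(cov, grid=[0.1, 0.2])

    def test_too_few_bins_raises(self, small_bins):
        cfg = SimSampleConfig(tumor_fraction=0.0, seed=1)
        counts = simulate_binned_counts(small_bins, cfg)
        cov = coverage_from_counts(counts, small_bins)
        cov.mask[:] = False
        cov.mask[:5] = True
        with pytest.raises(ValueError, match="at least 10"):
            estimate_tumor_fraction(cov)

    def test_classify_lmd_rules(self, mid_bins):
        cfg = SimSampleConfig(tumor_fraction=0.0, seed=31)
        cov = coverage_from_counts(simulate_binned_counts(mid_bins, cfg), mid_bins)
        est = estimate_tumor_fraction(cov)
        est.tf_hat, est.loglik, est.loglik_diploid = 0.0, -10.0, -10.0
        assert classify_lmd(est) == "negative"
        est.tf_hat, est.loglik = 0.5, -5.0
        assert classify_lmd(est) == "positive"
        est.loglik = -9.5  # improvement below the likelihood margin
        assert classify_lmd(est) == "negative"
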