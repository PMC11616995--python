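"""Signed-rank tests, FDR, onset detection, bootstrap latency inference."""
import itertools

import numpy as np
import pytest
from scipy import stats as sps

import braillemvpa as bm
from braillemvpa.stats import _fast_group_pvals


def enumeration_wilcoxon(d, tail="greater"):
    """Brute-force oracle: exact p over all 2^n sign patterns.

    Pratt policy: zeros are ranked with the rest, then dropped; signs flip
    only on the non-zero entries.
    """
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    nz = np.flatnonzero(d != 0)
    w_obs = ranks[d > 0].sum()
    r = ranks[nz]
    n = len(r)
    ws = np.array([r[list(signs)].sum()
                   for k in range(n + 1)
                   for signs in itertools.combinations(range(n), k)])
    pg = (ws >= w_obs - 1e-12).mean()
    pl = (ws <= w_obs + 1e-12).mean()
    if tail == "greater":
        return pg
    if tail == "less":
        return pl
    return min(1.0, 2 * min(pg, pl))


class TestWilcoxon:
    def test_all_positive_signs_give_exact_minimum_p(self):
        values = 50.0 + np.arange(1, 12)
        p = bm.wilcoxon_signed_rank(values, mu=50.0, tail="greater")
        assert p == pytest.approx(1 / 2 ** 11)

    def test_symmetric_sample_is_null(self):
        values = 50.0 + np.array([-3, -2, -1, 1, 2, 3])
        p = bm.wilcoxon_signed_rank(values, mu=50.0, tail="greater")
        assert 0.4 < p < 0.7

    @pytest.mark.parametrize("tail", ["greater", "two_sided"])
    def test_matches_sign_pattern_enumeration(self, tail):
        """Exact p equals full 2^n enumeration for n <= 12, including
        ties and zeros."""
        rng = np.random.default_rng(0)
        for n in (5, 8, 12):
            for _ in range(10):
                d = rng.integers(-4, 5, size=n).astype(float)
                if (d == 0).all():
                    continue
                p = bm.wilcoxon_signed_rank(50.0 + d, mu=50.0, tail=tail)
                assert p == pytest.approx(enumeration_wilcoxon(d, tail))

    def test_matches_scipy_exact_when_clean(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=14)
        ours = bm.wilcoxon_signed_rank(d, mu=0.0, tail="greater")
        ref = sps.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref)

    def test_degenerate_all_at_mu(self):
        assert bm.wilcoxon_signed_rank(np.full(8, 50.0), mu=50.0) == 1.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            bm.wilcoxon_signed_rank(np.ones(4), mu=0.0)

    def test_normal_approximation_tracks_exact(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=24)
        pe = bm.wilcoxon_signed_rank(d, mu=0.0, mode="exact")
        pn = bm.wilcoxon_signed_rank(d, mu=0.0, mode="approx")
        assert pn == pytest.approx(pe, rel=0.25)

    def test_columnwise_matches_loop(self):
        rng = np.random.default_rng(3)
        X = rng.normal(50.5, 1.0, size=(9, 6))
        ps = bm.wilcoxon_signed_rank(X, mu=50.0)
        for t in range(6):
            assert ps[t] == bm.wilcoxon_signed_rank(X[:, t], mu=50.0)

    def test_fast_path_matches_exact_without_ties(self):
        rng = np.random.default_rng(4)
        X = rng.normal(50.2, 1.0, size=(11, 40))
        fast = _fast_group_pvals(X, 50.0, "greater")
        slow = bm.wilcoxon_signed_rank(X, mu=50.0, tail="greater")
        np.testing.assert_allclose(fast, slow)


class TestFdrBh:
    def test_single_test_reduces_to_raw_threshold(self):
        assert bm.fdr_bh(np.array([0.04]), q=0.05)[0]
        assert not bm.fdr_bh(np.array([0.06]), q=0.05)[0]

    def test_hand_applied_step_up(self):
        # thresholds i/m * q = .0125, .025, .0375, .05: 0.04 exceeds its
        # threshold, so the step-up rule keeps only the first two
        dec = bm.fdr_bh(np.array([0.01, 0.02, 0.04, 0.9]), q=0.05)
        np.testing.assert_array_equal(dec, [True, True, False, False])
        dec = bm.fdr_bh(np.array([0.01, 0.02, 0.037, 0.9]), q=0.05)
        np.testing.assert_array_equal(dec, [True, True, True, False])

    def test_all_ones_rejected_nothing(self):
        assert not bm.fdr_bh(np.ones(10), q=0.05).any()

    def test_matches_brute_force_step_up(self):
        """BH decisions equal the textbook step-up rule on random vectors."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            p = np.clip(p, 1e-12, 1.0)
            dec = bm.fdr_bh(p, q=0.05)
            order = np.argsort(p)
            thresh = 0.05 * (np.arange(1, m + 1)) / m
            passing = np.flatnonzero(p[order] <= thresh)
            expected = np.zeros(m, dtype=bool)
            if passing.size:
                expected[order[:passing[-1] + 1]] = True
            np.testing.assert_array_equal(dec, expected)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            bm.fdr_bh(np.array([]))
        with pytest.raises(ValueError, match="finite"):
            bm.fdr_bh(np.array([0.5, np.nan]))


class TestOnsetLatency:
    def test_uninterrupted_run_starts_at_first_point(self):
        times = np.arange(-100, 500)
        sig = times >= 62
        assert bm.onset_latency(sig, times, k=50) == 62.0

    def test_island_shorter_than_criterion_is_ignored(self):
        times = np.arange(-10, 200)
        sig = (times >= 20) & (times < 69)  # 49 points, then a gap
        assert np.isnan(bm.onset_latency(sig, times, k=50))
        sig2 = (times >= 20) & (times < 70)  # exactly 50
        assert bm.onset_latency(sig2, times, k=50) == 20.0

    def test_prestimulus_runs_do_not_count(self):
        times = np.arange(-60, 60)
        sig = times < 0
        assert np.isnan(bm.onset_latency(sig, times, k=10))

    def test_matches_sliding_window_scan(self):
        """Random traces against a brute-force scan over all windows."""
        rng = np.random.default_rng(6)
        times = np.arange(-20, 80, dtype=float)
        for _ in range(100):
            sig = rng.random(times.size) < 0.6
            k = int(rng.integers(1, 12))
            ours = bm.onset_latency(sig, times, k=k)
            expected = float("nan")
            for i in range(times.size - k + 1):
                if times[i] >= 0 and sig[i:i + k].all():
                    expected = times[i]
                    break
            if np.isnan(expected):
                assert np.isnan(ours)
            else:
                assert ours == expected

    def test_k_validated(self):
        with pytest.raises(ValueError, match=">= 1"):
            bm.onset_latency(np.ones(5, bool), np.arange(5), k=0)


def _planted_timecourses(n_sub, times, onset, amp=6.0, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    base = 50.0 + rng.normal(0, sd, size=(n_sub, times.size))
    base[:, times >= onset] += amp
    return base


class TestBootstrapOnset:
    def test_zero_variability_gives_zero_width_ci(self):
        times = np.arange(-20, 100, dtype=float)
        tc = np.tile(50.0 + 10.0 * (times >= 30), (8, 1))
        est = bm.bootstrap_onset_ci(tc, times, n_boot=100, seed=0, k=5)
        assert est.onset_ms == 30.0
        assert est.ci_low_ms == est.ci_high_ms == 30.0

    def test_fixed_seed_is_reproducible(self):
        times = np.arange(-20, 100, dtype=float)
        tc = _planted_timecourses(9, times, onset=40, seed=7)
        a = bm.bootstrap_onset_ci(tc, times, n_boot=200, seed=3, k=5)
        b = bm.bootstrap_onset_ci(tc, times, n_boot=200, seed=3, k=5)
        assert a.onset_ms == b.onset_ms
        np.testing.assert_array_equal(a.boot_onsets, b.boot_onsets)

    def test_planted_onset_covered(self):
        times = np.arange(-20, 120, dtype=float)
        covered = 0
        for rep in range(10):
            tc = _planted_timecourses(10, times, onset=50, amp=8.0,
                                      seed=100 + rep)
            est = bm.bootstrap_onset_ci(tc, times, n_boot=200,
                                        seed=rep, k=5)
            if est.ci_low_ms <= 50.0 <= est.ci_high_ms:
                covered += 1
        assert covered >= 9

    def test_undefined_onsets_flagged(self):
        times = np.arange(-20, 60, dtype=float)
        rng = np.random.default_rng(8)
        tc = 50.0 + rng.normal(size=(6, times.size))
        est = bm.bootstrap_onset_ci(tc, times, n_boot=50, seed=0, k=5)
        assert np.isnan(est.onset_ms)
        assert est.n_undefined == 50
        assert np.isnan(est.ci_low_ms)


class TestLatencyDifference:
    def test_equal_conditions_are_not_ordered(self):
        times = np.arange(-20, 100, dtype=float)
        tc = _planted_timecourses(9, times, onset=40, seed=9)
        res = bm.bootstrap_latency_difference(tc, tc, times, n_boot=100,
                                              seed=1, k=5)
        assert res.diff_ms == 0.0
        assert res.p == pytest.approx(1.0)

    def test_planted_delay_detected(self):
        times = np.arange(-20, 150, dtype=float)
        detected = 0
        for rep in range(10):
            a = _planted_timecourses(10, times, onset=40, amp=8.0,
                                     seed=200 + rep)
            b = _planted_timecourses(10, times, onset=90, amp=8.0,
                                     seed=300 + rep)
            res = bm.bootstrap_latency_difference(a, b, times, n_boot=200,
                                                  seed=rep, k=5)
            if res.p < 0.05:
                detected += 1
        assert detected >= 9

    def test_swapping_conditions_mirrors_the_distribution(self):
        times = np.arange(-20, 150, dtype=float)
        a = _planted_timecourses(9, times, onset=40, amp=8.0, seed=10)
        b = _planted_timecourses(9, times, onset=90, amp=8.0, seed=11)
        fwd = bm.bootstrap_latency_difference(a, b, times, n_boot=150,
                                              seed=2, k=5)
        rev = bm.bootstrap_latency_difference(b, a, times, n_boot=150,
                                              seed=2, k=5)
        assert fwd.diff_ms == -rev.diff_ms
        assert fwd.ci_low_ms == -rev.ci_high_ms
        assert fwd.ci_high_ms == -rev.ci_low_ms

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="subject pool"):
            bm.bootstrap_latency_difference(np.zeros((5, 10)),
                                            np.zeros((6, 10)),
                                            np.arange(10))
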