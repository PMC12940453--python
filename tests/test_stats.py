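"""Split-half stability, Bland–Altman agreement, block bootstrap and
permutation testing."""

import numpy as np
import pytest

from vibrotrack.quantify import DisplacementSeries
from vibrotrack.stats import (
    ResamplingSpec,
    SplitHalfPair,
    bland_altman,
    block_bootstrap_ci,
    compare_conditions,
    permutation_test_rms,
    split_half_pairs,
)


def _series(values, fps=1000.0):
    return DisplacementSeries.from_values(values, fps=fps)


def _tone_noise(rng, n, amp=2.0, freq=37.0, sigma=0.5, fps=1000.0):
    t = np.arange(n) / fps
    return amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)) + rng.normal(
        0, sigma, n
    )


class TestSplitHalf:
    def test_square_wave_halves_equal(self):
        pair = split_half_pairs(_series([1.0, -1.0, 1.0, -1.0]))
        assert pair.rms_first == pytest.approx(1.0)
        assert pair.rms_second == pytest.approx(1.0)

    def test_stationary_sinusoid_halves_agree(self):
        t = np.arange(2000) / 1000.0  # 20 whole 10 Hz cycles per half
        pair = split_half_pairs(_series(np.sin(2 * np.pi * 10 * t)))
        assert pair.rms_first == pytest.approx(pair.rms_second, rel=0.01)

    def test_amplitude_step_doubles_second_half(self):
        """Second-half amplitude 2x the first gives rms_second ~ 2*rms_first."""
        t = np.arange(1000) / 1000.0
        amp = np.where(t < 0.5, 1.0, 2.0)
        pair = split_half_pairs(_series(amp * np.sin(2 * np.pi * 20 * t)))
        assert pair.rms_second == pytest.approx(2 * pair.rms_first, rel=0.1)

    def test_odd_length_first_half_gets_extra_frame(self):
        v = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        pair = split_half_pairs(_series(v))
        # first half has 3 samples, second has 2
        assert pair.rms_first > 0 and pair.rms_second > 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            split_half_pairs(_series([1.0, -1.0, 1.0][:3]))


class TestBlandAltman:
    def test_identical_pairs_zero_mean_and_width(self):
        pairs = [SplitHalfPair(1.0, 1.0), SplitHalfPair(2.0, 2.0)]
        res = bland_altman(pairs)
        assert res.mean_diff_pct == 0.0
        assert res.loa_low_pct == res.loa_high_pct == 0.0

    def test_single_pair_percent_difference(self):
        res = bland_altman([SplitHalfPair(1.0, 0.9)])
        assert res.mean_diff_pct == pytest.approx(100 * 0.1 / 0.95, rel=1e-9)

    def test_three_pair_hand_computed_oracle(self):
        pairs = [SplitHalfPair(1.0, 1.0), SplitHalfPair(2.0, 2.0), SplitHalfPair(1.1, 0.9)]
        res = bland_altman(pairs)
        d = np.array([0.0, 0.0, 100 * 0.2 / 1.0])
        assert res.mean_diff_pct == pytest.approx(d.mean())  # 6.667%
        sd = d.std(ddof=1)
        assert res.loa_low_pct == pytest.approx(d.mean() - 1.96 * sd)
        assert res.loa_high_pct == pytest.approx(d.mean() + 1.96 * sd)

    def test_sign_convention_first_minus_second(self):
        """Negating every pair order negates the mean difference and mirrors
        the limits of agreement."""
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 2, 6), rng.uniform(1, 2, 6)
        fwd = bland_altman([SplitHalfPair(x, y) for x, y in zip(a, b)])
        rev = bland_altman([SplitHalfPair(y, x) for x, y in zip(a, b)])
        assert rev.mean_diff_pct == pytest.approx(-fwd.mean_diff_pct)
        assert rev.loa_low_pct == pytest.approx(-fwd.loa_high_pct)
        assert rev.loa_high_pct == pytest.approx(-fwd.loa_low_pct)

    def test_zero_sum_pair_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bland_altman([SplitHalfPair(0.0, 0.0)])


class TestBlockBootstrap:
    def test_same_series_ci_contains_zero(self):
        rng = np.random.default_rng(1)
        v = _tone_noise(rng, 1000)
        spec = ResamplingSpec(n_boot=500, n_perm=199, block_len_frames=50, seed=0)
        diff, lo, hi = block_bootstrap_ci(_series(v), _series(v.copy()), spec)
        assert lo <= 0 <= hi
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_tripled_amplitude_ci_excludes_zero(self):
        """b = 3a: the CI for rms(a)-rms(b) reliably excludes zero."""
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            a = _tone_noise(rng, 1200)
            b = 3 * a
            spec = ResamplingSpec(n_boot=500, n_perm=199, block_len_frames=50, seed=seed)
            _, lo, hi = block_bootstrap_ci(_series(b), _series(a), spec)
            hits += not (lo <= 0 <= hi)
        assert hits >= 24

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        a, b = _tone_noise(rng, 800), _tone_noise(rng, 800)
        spec = ResamplingSpec(n_boot=1000, n_perm=199, block_len_frames=40, seed=7)
        r1 = block_bootstrap_ci(_series(a), _series(b), spec)
        r2 = block_bootstrap_ci(_series(a), _series(b), spec)
        assert r1 == r2

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        a, b = _tone_noise(rng, 1000, amp=3.0), _tone_noise(rng, 1000, amp=1.0)
        spec = ResamplingSpec(n_boot=500, n_perm=199, block_len_frames=50, seed=1)
        diff, lo, hi = block_bootstrap_ci(_series(a), _series(b), spec)
        assert lo - 1e-9 <= diff <= hi + 1e-9

    def test_coverage_on_stationary_series(self):
        """95% CI covers the true RMS difference in >= 90% of simulations."""
        true_a, true_b = np.sqrt(2.0**2 / 2 + 0.5**2), np.sqrt(1.0**2 / 2 + 0.5**2)
        true_diff = true_a - true_b
        covered = 0
        n_sim = 100
        for seed in range(n_sim):
            rng = np.random.default_rng(1000 + seed)
            a = _tone_noise(rng, 1500, amp=2.0)
            b = _tone_noise(rng, 1500, amp=1.0)
            spec = ResamplingSpec(n_boot=300, n_perm=199, block_len_frames=100, seed=seed)
            _, lo, hi = block_bootstrap_ci(_series(a), _series(b), spec)
            covered += lo <= true_diff <= hi
        assert covered >= 90


class TestPermutation:
    def test_p_never_below_resolution_floor(self):
        rng = np.random.default_rng(4)
        a = _tone_noise(rng, 800, amp=5.0, sigma=0.1)
        b = _tone_noise(rng, 800, amp=0.0, sigma=0.1)
        spec = ResamplingSpec(n_boot=100, n_perm=199, block_len_frames=40, seed=0)
        p = permutation_test_rms(_series(a), _series(b), spec)
        assert p >= 1 / 200
        assert p <= 0.01

    def test_tripled_amplitude_strongly_significant(self):
        rng = np.random.default_rng(5)
        a = _tone_noise(rng, 1000)
        spec = ResamplingSpec(n_boot=100, n_perm=499, block_len_frames=50, seed=3)
        p = permutation_test_rms(_series(3 * a), _series(a), spec)
        assert p <= 0.01

    def test_seeded_determinism(self):
        rng = np.random.default_rng(6)
        a, b = _tone_noise(rng, 800), _tone_noise(rng, 800)
        spec = ResamplingSpec(n_boot=100, n_perm=199, block_len_frames=40, seed=11)
        assert permutation_test_rms(_series(a), _series(b), spec) == permutation_test_rms(
            _series(a), _series(b), spec
        )

    def test_mean_abs_variant_agrees_on_strong_effect(self):
        rng = np.random.default_rng(7)
        a = _tone_noise(rng, 600)
        spec = ResamplingSpec(n_boot=100, n_perm=199, block_len_frames=30, seed=2)
        p = permutation_test_rms(_series(3 * a), _series(a), spec, statistic="mean_abs_diff")
        assert p <= 0.01

    def test_compare_conditions_bundles_ci_and_p(self):
        rng = np.random.default_rng(8)
        a = _tone_noise(rng, 800)
        spec = ResamplingSpec(n_boot=200, n_perm=199, block_len_frames=40, seed=5)
        res = compare_conditions(_series(3 * a), _series(a), spec)
        assert res.rms_diff > 0
        assert res.p_two_sided <= 0.01
        assert not (res.ci_lo <= 0 <= res.ci_hi)
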