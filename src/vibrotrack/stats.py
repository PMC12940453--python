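"""Stability and significance statistics for displacement series.

Two questions are answered here. First, intra-run stability: each segment's
series is split at its midpoint and the two half RMS values are compared
across markers/axes with a Bland–Altman analysis of percent differences.
Second, idle-vs-scan significance: the RMS difference between two condition
series is given a 95% percentile bootstrap confidence interval and a
two-sided permutation p-value.

Displacement series are strongly autocorrelated (tonal vibration plus
bandpassed noise), so the resampling unit is a contiguous block of frames
(default ~0.1 s), not a single frame: blocks are resampled with replacement
for the bootstrap and relabeled across conditions for the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import DisplacementSeries

__all__ = [
    "SplitHalfPair",
    "BlandAltmanResult",
    "ResamplingSpec",
    "ComparisonResult",
    "split_half_pairs",
    "bland_altman",
    "block_bootstrap_ci",
    "permutation_test_rms",
    "compare_conditions",
]


@dataclass(frozen=True)
class SplitHalfPair:
    """First- and second-half RMS (µm) of one marker/axis/condition series."""

    rms_first: float
    rms_second: float
    marker_id: str = ""
    axis_label: str = ""
    condition_label: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference and limits of agreement (percent by default)."""

    mean_diff_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int


@dataclass(frozen=True)
class ResamplingSpec:
    """Replicate counts, block length (frames) and seed for resampling."""

    n_boot: int = 500
    n_perm: int = 499
    block_len_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 100 or self.n_perm < 100:
            raise ValueError("n_boot and n_perm must be >= 100")
        if self.block_len_frames < 1:
            raise ValueError("block_len_frames must be >= 1")


@dataclass(frozen=True)
class ComparisonResult:
    """Idle-vs-scan comparison of one marker/axis: RMS difference with CI and p."""

    rms_diff: float
    ci_lo: float
    ci_hi: float
    p_two_sided: float
    n_boot: int
    n_perm: int
    block_len_frames: int
    seed: int


def _values(series) -> np.ndarray:
    if isinstance(series, DisplacementSeries):
        return series.values
    return np.asarray(series, dtype=np.float64)


def _rms_centered(v: np.ndarray) -> float:
    v = v - v.mean()
    return float(np.sqrt(np.mean(v**2)))


def split_half_pairs(series: DisplacementSeries) -> SplitHalfPair:
    """Split a series at its midpoint and compute per-half RMS.

    Odd lengths give the extra frame to the first half; each half is
    re-centered on its own mean before the RMS.
    """
    v = _values(series)
    if v.size < 4:
        raise ValueError("series too short to split (need >= 4 samples)")
    mid = (v.size + 1) // 2
    return SplitHalfPair(
        rms_first=_rms_centered(v[:mid]),
        rms_second=_rms_centered(v[mid:]),
        marker_id=series.marker_id,
        axis_label=series.axis_label,
        condition_label=series.condition_label,
    )


def bland_altman(pairs: list[SplitHalfPair], percent: bool = True) -> BlandAltmanResult:
    """Bland–Altman agreement between paired first/second-half RMS values.

    Percent mode: ``d_i = 100 (a_i - b_i) / ((a_i + b_i)/2)``. Limits of
    agreement are ``mean(d) +/- 1.96 sd(d)`` with the sample SD (n-1). With a
    single pair the limits collapse onto the mean difference.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    a = np.array([p.rms_first for p in pairs], dtype=float)
    b = np.array([p.rms_second for p in pairs], dtype=float)
    if percent:
        denom = (a + b) / 2.0
        if np.any(denom == 0):
            raise ValueError("cannot form percent difference: a pair sums to zero")
        d = 100.0 * (a - b) / denom
    else:
        d = a - b
    mean = float(d.mean())
    if d.size < 2:
        return BlandAltmanResult(mean, mean, mean, int(d.size))
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, mean - 1.96 * sd, mean + 1.96 * sd, int(d.size))


def _block_aggregates(v: np.ndarray, block_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums and sums of squares (series trimmed to whole blocks)."""
    nb = v.size // block_len
    if nb < 4:
        raise ValueError(
            f"series of {v.size} samples has only {nb} blocks of {block_len}; need >= 4"
        )
    blocks = v[: nb * block_len].reshape(nb, block_len)
    return blocks.sum(axis=1), (blocks**2).sum(axis=1)


def _rms_from_aggregates(s: np.ndarray, q: np.ndarray, block_len: int) -> np.ndarray:
    """RMS of the re-centered concatenation of blocks, from block aggregates."""
    n = s.shape[-1] * block_len
    total = s.sum(axis=-1)
    mean = total / n
    msq = q.sum(axis=-1) / n
    return np.sqrt(np.maximum(msq - mean**2, 0.0))


def block_bootstrap_ci(
    series_a, series_b, spec: ResamplingSpec
) -> tuple[float, float, float]:
    """95% percentile block-bootstrap CI for ``rms(a) - rms(b)``.

    Each replicate resamples whole contiguous blocks with replacement within
    each series independently, re-centers, and recomputes the statistic.
    Returns ``(rms_diff, ci_lo, ci_hi)``; seeded and reproducible.
    """
    va, vb = _values(series_a), _values(series_b)
    bl = spec.block_len_frames
    sa, qa = _block_aggregates(va, bl)
    sb, qb = _block_aggregates(vb, bl)
    rng = np.random.default_rng(spec.seed)
    idx_a = rng.integers(0, sa.size, size=(spec.n_boot, sa.size))
    idx_b = rng.integers(0, sb.size, size=(spec.n_boot, sb.size))
    boot_a = _rms_from_aggregates(sa[idx_a], qa[idx_a], bl)
    boot_b = _rms_from_aggregates(sb[idx_b], qb[idx_b], bl)
    diffs = boot_a - boot_b
    observed = _rms_from_aggregates(sa[None, :], qa[None, :], bl)[0] - _rms_from_aggregates(
        sb[None, :], qb[None, :], bl
    )[0]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return float(observed), float(lo), float(hi)


def permutation_test_rms(
    series_a, series_b, spec: ResamplingSpec, statistic: str = "rms_diff"
) -> float:
    """Two-sided block permutation test for a difference in vibration level.

    Both series are cut into contiguous blocks; condition labels are permuted
    over the pooled blocks (group sizes preserved) and the statistic
    ``|rms(a*) - rms(b*)|`` recomputed. ``p = (1 + #{perm >= observed}) /
    (n_perm + 1)``, so p is never 0 and never below ``1/(n_perm+1)``.

    ``statistic="mean_abs_diff"`` swaps in the mean absolute displacement
    difference instead of the RMS difference.
    """
    if statistic not in ("rms_diff", "mean_abs_diff"):
        raise ValueError(f"unknown statistic {statistic!r}")
    va, vb = _values(series_a), _values(series_b)
    bl = spec.block_len_frames
    sa, qa = _block_aggregates(va, bl)
    sb, qb = _block_aggregates(vb, bl)
    na, nb = sa.size, sb.size
    rng = np.random.default_rng(spec.seed)

    if statistic == "mean_abs_diff":
        return _permutation_mean_abs(va, vb, bl, na, nb, spec, rng)

    s_pool = np.concatenate([sa, sb])
    q_pool = np.concatenate([qa, qb])
    observed = abs(
        _rms_from_aggregates(sa[None, :], qa[None, :], bl)[0]
        - _rms_from_aggregates(sb[None, :], qb[None, :], bl)[0]
    )
    # random permutations of pooled block indices, one row per replicate
    perm = np.argsort(rng.random((spec.n_perm, na + nb)), axis=1)
    pa, pb = perm[:, :na], perm[:, na:]
    stat = np.abs(
        _rms_from_aggregates(s_pool[pa], q_pool[pa], bl)
        - _rms_from_aggregates(s_pool[pb], q_pool[pb], bl)
    )
    return float((1 + np.sum(stat >= observed)) / (spec.n_perm + 1))


def _permutation_mean_abs(va, vb, bl, na, nb, spec, rng) -> float:
    blocks = np.concatenate(
        [va[: na * bl].reshape(na, bl), vb[: nb * bl].reshape(nb, bl)]
    )

    def stat(ia, ib):
        xa = blocks[ia].ravel()
        xb = blocks[ib].ravel()
        return abs(np.mean(np.abs(xa - xa.mean())) - np.mean(np.abs(xb - xb.mean())))

    observed = stat(np.arange(na), np.arange(na, na + nb))
    count = 0
    for _ in range(spec.n_perm):
        perm = rng.permutation(na + nb)
        if stat(perm[:na], perm[na:]) >= observed:
            count += 1
    return float((1 + count) / (spec.n_perm + 1))


def compare_conditions(series_a, series_b, spec: ResamplingSpec) -> ComparisonResult:
    """Bootstrap CI and permutation p for ``rms(a) - rms(b)`` in one call."""
    rms_diff, ci_lo, ci_hi = block_bootstrap_ci(series_a, series_b, spec)
    p = permutation_test_rms(series_a, series_b, spec)
    return ComparisonResult(
        rms_diff, ci_lo, ci_hi, p, spec.n_boot, spec.n_perm, spec.block_len_frames, spec.seed
    )
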