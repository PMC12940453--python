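"""Eulerian video magnification: temporal bandpass + spatial pyramid amplification.

Sub-pixel motion of an image feature shows up as a small temporal intensity
oscillation at each pixel (to first order, ``-delta(t) * dI/dx``). Bandpassing
each pixel's (or pyramid level's) time series inside the vibration band and
adding it back scaled by ``alpha`` makes a translation ``delta`` appear as
``(1 + alpha) * delta`` — large enough for an ordinary sub-pixel tracker.

The temporal filter is an ideal (DFT-mask) bandpass applied offline over the
whole clip: coefficients with ``f_lo <= |f| <= f_hi`` are kept, everything
else (including DC) is zeroed. On-bin tones pass through exactly, which makes
the filter's behavior testable in closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .frames import FrameStack

__all__ = [
    "BandSpec",
    "MagParams",
    "temporal_ideal_bandpass",
    "build_pyramid",
    "collapse_pyramid",
    "magnify_clip",
    "auto_n_levels",
]

logger = logging.getLogger(__name__)

# 5-tap binomial kernel used for pyramid reduce/expand
_PYR_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class BandSpec:
    """Temporal passband edges in Hz (inclusive)."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def validate_for_fps(self, fps: float) -> None:
        if self.f_hi > fps / 2:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz exceeds Nyquist {fps / 2} Hz"
            )


@dataclass(frozen=True)
class MagParams:
    """Amplification settings.

    alpha : amplification factor applied to the bandpassed signal; the
        effective motion gain is ``1 + alpha``.
    n_levels : spatial pyramid depth; ``None`` picks the deepest pyramid whose
        coarsest level is still >= 8 px per side.
    mode : "laplacian_pyramid" (default) amplifies every level of a Laplacian
        decomposition; "gaussian_blur" amplifies a single spatially lowpassed
        band.
    attenuate_fine_levels : optionally scale alpha per level (finest first)
        to suppress amplification noise at high spatial frequencies.
    """

    alpha: float = 100.0
    n_levels: int | None = None
    mode: str = "laplacian_pyramid"
    attenuate_fine_levels: bool = False
    fine_level_scales: tuple[float, ...] = (0.5,)
    gaussian_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_levels is not None and self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.mode not in ("laplacian_pyramid", "gaussian_blur"):
            raise ValueError(f"unknown mode {self.mode!r}")


def temporal_ideal_bandpass(
    series: np.ndarray, band: BandSpec, fps: float, axis: int = 0
) -> np.ndarray:
    """Ideal DFT-mask bandpass along ``axis``.

    Keeps DFT coefficients whose frequency magnitude lies in
    ``[f_lo, f_hi]`` (edges inclusive), zeroes all others including DC, and
    returns the inverse transform. The output is zero-mean by construction.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[axis]
    if n < 4:
        raise ValueError("need at least 4 samples along the time axis")
    band.validate_for_fps(fps)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    spec = np.fft.rfft(series, axis=axis)
    shape = [1] * series.ndim
    shape[axis] = mask.size
    spec *= mask.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def _reduce(img: np.ndarray) -> np.ndarray:
    """Blur with the binomial kernel and downsample by 2 (last two axes)."""
    sm = ndimage.correlate1d(img, _PYR_KERNEL, axis=-2, mode="reflect")
    sm = ndimage.correlate1d(sm, _PYR_KERNEL, axis=-1, mode="reflect")
    return sm[..., ::2, ::2]


def _expand_1d(a: np.ndarray, n_out: int) -> np.ndarray:
    """Polyphase 2x upsampling along the last axis (binomial interpolation).

    Even outputs sit on coarse samples filtered by [1, 6, 1]/8; odd outputs
    are the midpoint average of their two coarse neighbors. Boundaries
    reflect on the coarse grid, so constants map to constants exactly.
    """
    even = ndimage.correlate1d(a, np.array([1.0, 6.0, 1.0]) / 8.0, axis=-1, mode="reflect")
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    odd = 0.5 * (a + right)
    out = np.empty(a.shape[:-1] + (n_out,), dtype=a.dtype)
    out[..., ::2] = even[..., : (n_out + 1) // 2]
    out[..., 1::2] = odd[..., : n_out // 2]
    return out


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Upsample the last two axes to ``shape`` by separable interpolation."""
    out = _expand_1d(np.swapaxes(img, -1, -2), shape[0])
    out = _expand_1d(np.swapaxes(out, -1, -2), shape[1])
    return out


def auto_n_levels(frame_shape: tuple[int, int], min_size: int = 8) -> int:
    """Deepest pyramid whose coarsest level is >= ``min_size`` px per side."""
    n = 1
    h, w = frame_shape
    while min(h, w) // 2 >= min_size:
        h, w = (h + 1) // 2, (w + 1) // 2
        n += 1
    return n


def build_pyramid(
    frame: np.ndarray, n_levels: int, mode: str = "laplacian_pyramid"
) -> list[np.ndarray]:
    """Spatial decomposition of a frame (or a (T, H, W) stack, vectorized).

    Laplacian mode returns ``n_levels`` bands, finest first, the last being
    the coarsest Gaussian level; ``collapse_pyramid`` reconstructs the input
    exactly. Gaussian-blur mode returns a single lowpassed band.
    """
    h, w = frame.shape[-2:]
    if min(h, w) < 4 * 2 ** (n_levels - 1):
        raise ValueError(
            f"frame {h}x{w} too small for {n_levels} pyramid levels "
            f"(needs >= {4 * 2 ** (n_levels - 1)} px per side)"
        )
    if mode == "gaussian_blur":
        g = frame
        for _ in range(n_levels - 1):
            g = _reduce(g)
        return [g]
    levels: list[np.ndarray] = []
    g = np.asarray(frame, dtype=np.float64)
    for _ in range(n_levels - 1):
        g_next = _reduce(g)
        levels.append(g - _expand(g_next, g.shape[-2:]))
        g = g_next
    levels.append(g)
    return levels


def collapse_pyramid(pyramid: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`build_pyramid` (Laplacian mode) exactly."""
    out = pyramid[-1]
    for level in pyramid[-2::-1]:
        out = level + _expand(out, level.shape[-2:])
    return out


def _level_alphas(params: MagParams, n_levels: int) -> np.ndarray:
    alphas = np.full(n_levels, float(params.alpha))
    if params.attenuate_fine_levels:
        for i, s in enumerate(params.fine_level_scales):
            if i < n_levels:
                alphas[i] *= s
    return alphas


def magnify_clip(
    clip: FrameStack, band: BandSpec, params: MagParams | None = None
) -> FrameStack:
    """Amplify in-band temporal variation of a clip.

    Per pyramid level (Laplacian mode), ``output = original +
    alpha * bandpass(original)``; the stack is then reconstructed and clamped
    to ``[0, 1]``. A saturation fraction above 1% is logged as a warning.
    """
    if params is None:
        params = MagParams()
    band.validate_for_fps(clip.fps)
    frames = clip.frames
    n_levels = params.n_levels or auto_n_levels(clip.frame_shape)

    if params.mode == "gaussian_blur":
        low = ndimage.gaussian_filter(
            frames, sigma=(0.0, params.gaussian_sigma_px, params.gaussian_sigma_px)
        )
        out = frames + params.alpha * temporal_ideal_bandpass(low, band, clip.fps, axis=0)
    elif not params.attenuate_fine_levels:
        # uniform alpha: the Laplacian decomposition is a linear identity and
        # the temporal filter commutes with it, so amplifying every level by
        # the same alpha and collapsing equals amplifying the frames directly
        out = frames + params.alpha * temporal_ideal_bandpass(frames, band, clip.fps, axis=0)
    else:
        levels = build_pyramid(frames, n_levels, mode="laplacian_pyramid")
        alphas = _level_alphas(params, n_levels)
        for i, level in enumerate(levels):
            if alphas[i] == 0:
                continue
            level += alphas[i] * temporal_ideal_bandpass(level, band, clip.fps, axis=0)
        out = collapse_pyramid(levels)

    saturated = np.mean((out < 0.0) | (out > 1.0))
    if saturated > 0.01:
        logger.warning(
            "magnification saturated %.1f%% of pixels (clamped to [0, 1])",
            100 * saturated,
        )
    return FrameStack(np.clip(out, 0.0, 1.0), clip.fps)
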