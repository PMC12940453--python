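"""Sub-pixel tracking of cross fiducials by normalized cross-correlation.

Markers are located by NCC against a rendered noise-free cross template
(illumination-invariant), the integer-pixel peak is refined by a 2-D
quadratic (paraboloid) fit to the 3x3 correlation neighborhood, and the known
physical marker dimensions calibrate the mm-per-pixel scale. Tracking runs
frame by frame inside a search window centered on the previous position, so
tracks can never jump farther than the search radius.

Coordinates are (x, y) = (column, row), origin at the top-left pixel center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .frames import FrameStack
from .scene_sim import MarkerSpec, render_cross

__all__ = [
    "Template",
    "Track",
    "Calibration",
    "TrackingError",
    "make_template",
    "detect_markers",
    "refine_subpixel",
    "refine_centroid",
    "track_clip",
    "calibrate",
    "DEFAULT_CALIBRATION",
]

logger = logging.getLogger(__name__)


class TrackingError(RuntimeError):
    """Raised when a marker cannot be followed reliably."""


@dataclass
class Template:
    """Matching template: rendered noise-free cross plus its physical size."""

    patch: np.ndarray
    arm_length_mm: float
    arm_width_mm: float

    def __post_init__(self) -> None:
        h, w = self.patch.shape
        if h % 2 == 0 or w % 2 == 0:
            raise ValueError("template patch must be odd-sized")

    @property
    def half(self) -> tuple[int, int]:
        return self.patch.shape[1] // 2, self.patch.shape[0] // 2  # (hx, hy)


@dataclass
class Track:
    """Per-frame sub-pixel positions of one marker."""

    marker_id: str
    positions: np.ndarray  # (T, 2) continuous (x, y) in px
    quality: np.ndarray  # (T,) peak NCC

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.positions)),
                "marker_id": self.marker_id,
                "x_px": self.positions[:, 0],
                "y_px": self.positions[:, 1],
                "quality": self.quality,
            }
        )


@dataclass(frozen=True)
class Calibration:
    """Pixel pitch per axis with first-order uncertainty."""

    mm_per_px_x: float
    mm_per_px_y: float
    uncertainty_mm_per_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mm_per_px_x <= 0 or self.mm_per_px_y <= 0:
            raise ValueError("pixel pitch must be positive")


#: Pitch of the processed-video field of view used as a fallback when no
#: calibration is supplied: 0.49 mm/px (x), 0.46 mm/px (y), each +/- 0.01.
DEFAULT_CALIBRATION = Calibration(0.49, 0.46, (0.01, 0.01))


def make_template(
    spec: MarkerSpec,
    pixel_pitch_mm: tuple[float, float] = (0.49, 0.46),
    supersample: int | None = None,
    psf_sigma_px: float = 0.7,
) -> Template:
    """Render the NCC template for a marker (noise-free, centered cross).

    ``psf_sigma_px`` should match the optical blur of the imaged scene so the
    template's edge profile matches what the camera records.
    """
    patch = render_cross(
        spec,
        offset_px=(0.0, 0.0),
        supersample=supersample,
        pixel_pitch_mm=pixel_pitch_mm,
        psf_sigma_px=psf_sigma_px,
    )
    return Template(patch, spec.arm_length_mm, spec.arm_width_mm)


def detect_markers(
    frame: np.ndarray, template: Template, min_corr: float = 0.8
) -> list[tuple[int, int]]:
    """Find candidate marker centers in one frame.

    Local NCC maxima with correlation >= ``min_corr``, greedily
    non-max-suppressed within one template width, sorted by correlation
    descending (ties broken row-major). Returns integer (x, y) positions;
    empty list when nothing correlates.
    """
    if frame.shape[0] <= template.patch.shape[0] or frame.shape[1] <= template.patch.shape[1]:
        raise ValueError("frame must be larger than the template")
    corr = match_template(frame, template.patch, pad_input=True)
    ys, xs = np.nonzero(corr >= min_corr)
    if ys.size == 0:
        return []
    vals = corr[ys, xs]
    order = np.lexsort((xs, ys, -vals))
    ys, xs, vals = ys[order], xs[order], vals[order]
    width = max(template.patch.shape)
    picked: list[tuple[int, int]] = []
    for y, x in zip(ys, xs):
        if all(max(abs(y - py), abs(x - px)) >= width for px, py in picked):
            picked.append((int(x), int(y)))
    return picked


# design matrix for a full 2-D quadratic on the 3x3 offset grid
_OFFSETS = np.array([(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1)], dtype=float)
_DESIGN = np.column_stack(
    [
        np.ones(9),
        _OFFSETS[:, 0],
        _OFFSETS[:, 1],
        _OFFSETS[:, 0] ** 2,
        _OFFSETS[:, 0] * _OFFSETS[:, 1],
        _OFFSETS[:, 1] ** 2,
    ]
)
_DESIGN_PINV = np.linalg.pinv(_DESIGN)


def refine_subpixel(
    corr_surface: np.ndarray, peak: tuple[int, int]
) -> tuple[tuple[float, float], bool]:
    """Paraboloid refinement of an integer correlation peak.

    Fits ``a + b x + c y + d x^2 + e xy + f y^2`` to the 3x3 neighborhood of
    ``peak`` (given as (x, y)) and returns the stationary point of the fit,
    plus an ``ok`` flag. Offsets beyond 1 px per axis are clipped to +/-0.5
    with a warning; a singular (non-concave) fit returns the integer peak
    with ``ok=False``.
    """
    x0, y0 = peak
    if not (1 <= y0 < corr_surface.shape[0] - 1 and 1 <= x0 < corr_surface.shape[1] - 1):
        raise ValueError("peak must not lie on the correlation surface border")
    patch = corr_surface[y0 - 1 : y0 + 2, x0 - 1 : x0 + 2].ravel()
    _, b, c, d, e, f = _DESIGN_PINV @ patch
    hess = np.array([[2 * d, e], [e, 2 * f]])
    det = np.linalg.det(hess)
    if det <= 0:  # saddle/flat: not a concave peak
        return (float(x0), float(y0)), False
    dx, dy = np.linalg.solve(hess, [-b, -c])
    if abs(dx) > 1 or abs(dy) > 1:
        logger.warning(
            "sub-pixel offset (%.2f, %.2f) exceeds 1 px; clipping to +/-0.5", dx, dy
        )
        dx = float(np.clip(dx, -0.5, 0.5))
        dy = float(np.clip(dy, -0.5, 0.5))
    return (x0 + float(dx), y0 + float(dy)), True


def refine_centroid(
    frame: np.ndarray, peak: tuple[int, int], template: Template
) -> tuple[float, float]:
    """Centroid-based alternative refinement.

    Intensity-weighted centroid of the background-subtracted (inverted)
    marker neighborhood; exact for a symmetric marker on a uniform
    background, more noise-sensitive than the paraboloid fit.
    """
    hx, hy = template.half
    x0, y0 = peak
    win = frame[y0 - hy : y0 + hy + 1, x0 - hx : x0 + hx + 1]
    weights = np.clip(win.max() - win, 0.0, None)
    total = weights.sum()
    if total == 0:
        return float(x0), float(y0)
    ys, xs = np.mgrid[-hy : hy + 1, -hx : hx + 1]
    return (x0 + float((weights * xs).sum() / total), y0 + float((weights * ys).sum() / total))


def track_clip(
    clip: FrameStack,
    init_positions: list[tuple[float, float]],
    template: Template,
    search_radius_px: int = 5,
    quality_floor: float = 0.3,
    marker_ids: list[str] | None = None,
    method: str = "paraboloid",
) -> list[Track]:
    """Track each marker through the clip with sub-pixel precision.

    Per frame, NCC is evaluated in a window of +/-``search_radius_px`` around
    the previous position and the peak refined by :func:`refine_subpixel`
    (or the centroid method). Raises :class:`TrackingError` when the peak
    correlation drops below ``quality_floor`` in more than 5% of frames.
    """
    if method not in ("paraboloid", "centroid"):
        raise ValueError(f"unknown refinement method {method!r}")
    frames = clip.frames
    n, h, w = frames.shape
    hx, hy = template.half
    r = int(search_radius_px)
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(len(init_positions))]
    tracks: list[Track] = []
    for mid, init in zip(marker_ids, init_positions):
        positions = np.empty((n, 2))
        quality = np.empty(n)
        prev = np.asarray(init, dtype=float)
        for t in range(n):
            cx, cy = int(round(prev[0])), int(round(prev[1]))
            x0, x1 = cx - hx - r, cx + hx + r + 1
            y0, y1 = cy - hy - r, cy + hy + r + 1
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise TrackingError(
                    f"marker {mid!r}: search window leaves the frame at frame {t}"
                )
            corr = match_template(frames[t, y0:y1, x0:x1], template.patch)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            quality[t] = corr[py, px]
            # guard the 3x3 neighborhood; the window is padded so interior
            # peaks are the norm
            px = int(np.clip(px, 1, corr.shape[1] - 2))
            py = int(np.clip(py, 1, corr.shape[0] - 2))
            if method == "centroid":
                pos = refine_centroid(frames[t], (x0 + px + hx, y0 + py + hy), template)
            else:
                (sx, sy), _ = refine_subpixel(corr, (px, py))
                pos = (x0 + sx + hx, y0 + sy + hy)
            positions[t] = pos
            prev = positions[t]
        bad = quality < quality_floor
        if bad.mean() > 0.05:
            lo, hi = np.nonzero(bad)[0][[0, -1]]
            raise TrackingError(
                f"marker {mid!r}: peak correlation below {quality_floor} in "
                f"{100 * bad.mean():.1f}% of frames (frames {lo}-{hi})"
            )
        tracks.append(Track(mid, positions, quality))
    return tracks


def calibrate(
    physical_extent_mm: tuple[float, float],
    measured_extent_px: tuple[float, float],
    extent_error_px: float = 0.5,
) -> Calibration:
    """Pixel pitch from the known physical marker extent.

    ``mm_per_px = physical / measured`` per axis, with uncertainty from
    first-order propagation of a +/-``extent_error_px`` pixel-counting error:
    ``physical / measured**2 * extent_error_px``.
    """
    phys = np.asarray(physical_extent_mm, dtype=float)
    meas = np.asarray(measured_extent_px, dtype=float)
    if np.any(phys <= 0) or np.any(meas <= 0):
        raise ValueError("physical and measured extents must be positive")
    pitch = phys / meas
    unc = phys / meas**2 * extent_error_px
    return Calibration(float(pitch[0]), float(pitch[1]), (float(unc[0]), float(unc[1])))
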