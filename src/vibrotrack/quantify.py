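"""Physical displacement series and the displacement metrics (RMS, peak-to-peak).

Tracked pixel positions are converted to micrometer displacement about the
segment-mean position through the pixel pitch and divided by the effective
motion gain ``g`` (``1 + alpha`` for Eulerian amplification), yielding the
estimated physical motion before amplification. Per condition segment the
series is re-centered on its own mean before any metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track import Calibration, Track

__all__ = [
    "GainSpec",
    "SegmentPlan",
    "DisplacementSeries",
    "MetricsRow",
    "PooledSummary",
    "to_displacement",
    "segment_series",
    "rms",
    "peak_to_peak",
    "pool_summary",
    "metrics_table",
]


@dataclass(frozen=True)
class GainSpec:
    """Effective motion gain from true to amplified displacement (>= 1)."""

    g: float = 101.0

    def __post_init__(self) -> None:
        if self.g < 1:
            raise ValueError("gain must be >= 1")


@dataclass(frozen=True)
class SegmentPlan:
    """Ordered, non-overlapping (condition_label, t_start_s, t_end_s) entries."""

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for label, t0, t1 in self.segments:
            if not t0 < t1:
                raise ValueError(f"segment {label!r}: t_start must be < t_end")
            if t0 < prev_end:
                raise ValueError(f"segment {label!r} overlaps the previous one")
            prev_end = t1

    def __iter__(self):
        return iter(self.segments)


@dataclass
class DisplacementSeries:
    """Zero-mean displacement (µm) of one marker axis within one segment."""

    marker_id: str
    condition_label: str
    axis_label: str
    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 2:
            raise ValueError("a displacement series needs at least 2 samples")
        if abs(self.values.mean()) > 1e-9:
            raise ValueError("displacement series must be zero-mean (re-center it)")

    @classmethod
    def from_values(
        cls, values, fps, marker_id="m0", condition_label="", axis_label="x"
    ) -> "DisplacementSeries":
        """Build a series, re-centering on the mean."""
        v = np.asarray(values, dtype=np.float64)
        return cls(marker_id, condition_label, axis_label, v - v.mean(), fps)


@dataclass(frozen=True)
class MetricsRow:
    marker_id: str
    axis_label: str
    condition_label: str
    rms_um: float
    pp_um: float

    def __post_init__(self) -> None:
        if self.rms_um < 0 or self.pp_um < 0 or self.pp_um < self.rms_um:
            raise ValueError("need pp_um >= rms_um >= 0")


@dataclass(frozen=True)
class PooledSummary:
    """Median and range over a pool of metric values (µm)."""

    median: float
    min: float
    max: float
    n: int


def to_displacement(
    track: Track,
    cal: Calibration,
    gain: GainSpec = GainSpec(),
    fps: float = 1.0,
    axis_labels: tuple[str, str] = ("x", "y"),
    condition_label: str = "",
) -> tuple[DisplacementSeries, DisplacementSeries]:
    """Convert a pixel track to per-axis µm displacement about the track mean.

    ``delta(t) = (p(t) - mean(p)) * mm_per_px * 1000 / g`` per axis. Segment
    the result with :func:`segment_series` to apply per-segment re-centering.
    """
    if len(track.positions) < 2:
        raise ValueError("track must contain at least 2 frames")
    pitch = np.array([cal.mm_per_px_x, cal.mm_per_px_y])
    dev_px = track.positions - track.positions.mean(axis=0)
    dev_um = dev_px * pitch[None, :] * 1000.0 / gain.g
    return tuple(  # type: ignore[return-value]
        DisplacementSeries.from_values(
            dev_um[:, j],
            fps=fps,
            marker_id=track.marker_id,
            condition_label=condition_label,
            axis_label=axis_labels[j],
        )
        for j in (0, 1)
    )


def segment_series(
    series: DisplacementSeries, plan: SegmentPlan
) -> list[DisplacementSeries]:
    """Slice a series into condition segments, re-centering each on its mean."""
    out = []
    n = series.values.size
    for label, t0, t1 in plan:
        i0 = int(round(t0 * series.fps))
        i1 = int(round(t1 * series.fps))
        if i0 < 0 or i1 > n or i1 - i0 < 2:
            raise ValueError(
                f"segment {label!r} ({t0}-{t1} s) is empty or outside the series"
            )
        out.append(
            DisplacementSeries.from_values(
                series.values[i0:i1],
                fps=series.fps,
                marker_id=series.marker_id,
                condition_label=label,
                axis_label=series.axis_label,
            )
        )
    return out


def rms(series: DisplacementSeries | np.ndarray) -> float:
    """Root-mean-square displacement (µm) of a re-centered series."""
    v = series.values if isinstance(series, DisplacementSeries) else np.asarray(series)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sqrt(np.mean(v**2)))


def peak_to_peak(series: DisplacementSeries | np.ndarray) -> float:
    """Peak-to-peak displacement (µm): max minus min."""
    v = series.values if isinstance(series, DisplacementSeries) else np.asarray(series)
    if v.size < 2:
        raise ValueError("need at least 2 samples")
    return float(v.max() - v.min())


def pool_summary(values) -> PooledSummary:
    """Median (midpoint convention for even n), min and max of pooled metrics."""
    if hasattr(values, "__len__") and len(values) and isinstance(values[0], MetricsRow):
        values = [r.rms_um for r in values]
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot pool an empty set of metrics")
    return PooledSummary(float(np.median(v)), float(v.min()), float(v.max()), int(v.size))


def metrics_table(series_list: list[DisplacementSeries]) -> pd.DataFrame:
    """Metrics rows (marker x axis x condition, RMS and p-p in µm) as a table."""
    rows = [
        MetricsRow(s.marker_id, s.axis_label, s.condition_label, rms(s), peak_to_peak(s))
        for s in series_list
    ]
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in rows],
            "axis": [r.axis_label for r in rows],
            "condition": [r.condition_label for r in rows],
            "rms_um": [r.rms_um for r in rows],
            "pp_um": [r.pp_um for r in rows],
        }
    )
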