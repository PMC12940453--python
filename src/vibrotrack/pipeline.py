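"""End-to-end orchestration: simulate/load -> magnify -> track -> analyze.

A run is described by a single YAML-style mapping (see
``profiles/desk_test.yaml``). Two modes are supported:

* **pair mode** — the config carries a ``scene`` and ``scan_tones``: an
  idle/scan clip pair is simulated and processed identically, and the idle
  condition is compared against the scan condition per marker and axis
  (bootstrap CI + permutation p on the RMS difference).
* **single mode** — one clip (simulated or loaded from file) is processed
  and optionally cut into condition segments by a segment plan.

Identical config + seed reproduces byte-identical outputs; every report
carries the package version and a hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .frames import FrameStack
from .io import load_stack, save_json, save_stack_tiff, save_tracks_csv, save_yaml
from .magnify import BandSpec, MagParams, magnify_clip
from .quantify import (
    DisplacementSeries,
    GainSpec,
    SegmentPlan,
    metrics_table,
    pool_summary,
    segment_series,
    to_displacement,
)
from .scene_sim import MarkerSpec, SceneConfig, Tone, make_condition_pair, simulate_clip
from .spectra import amplitude_spectrum
from .stats import ResamplingSpec, bland_altman, compare_conditions, split_half_pairs
from .track import Calibration, Template, detect_markers, make_template, track_clip

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    scene: SceneConfig | None = None
    input_path: str | None = None
    input_fps: float | None = None
    scan_tones: tuple[Tone, ...] = ()
    band: BandSpec = field(default_factory=lambda: BandSpec(10.0, 1000.0))
    mag: MagParams = field(default_factory=MagParams)
    gain: GainSpec | None = None  # None -> 1 + alpha
    calibration: Calibration | None = None  # None -> scene pixel pitch
    segments: SegmentPlan | None = None
    resampling: ResamplingSpec = field(default_factory=ResamplingSpec)
    search_radius_px: int = 5
    min_corr: float = 0.6
    track_method: str = "paraboloid"
    template_psf_sigma_px: float = 0.7
    axis_labels: dict[str, tuple[str, str]] = field(default_factory=dict)
    f_max_hz: float | None = 500.0
    output_dir: str = "vibrotrack_out"
    write_clips: bool = False
    raw: dict = field(default_factory=dict, repr=False)

    def effective_gain(self) -> GainSpec:
        return self.gain if self.gain is not None else GainSpec(1.0 + self.mag.alpha)

    def effective_calibration(self) -> Calibration:
        if self.calibration is not None:
            return self.calibration
        if self.scene is not None:
            px, py = self.scene.pixel_pitch_mm
            return Calibration(px, py)
        from .track import DEFAULT_CALIBRATION

        return DEFAULT_CALIBRATION

    def config_hash(self) -> str:
        d = dict(self.raw) if self.raw else _config_to_dict(self)
        d.pop("output_dir", None)  # where results land is not part of the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _config_to_dict(cfg: RunConfig) -> dict:
    return {
        "scene": dataclasses.asdict(cfg.scene) if cfg.scene else None,
        "input": cfg.input_path,
        "scan_tones": [dataclasses.asdict(t) for t in cfg.scan_tones],
        "band": dataclasses.asdict(cfg.band),
        "mag": dataclasses.asdict(cfg.mag),
        "gain": cfg.effective_gain().g,
        "segments": list(cfg.segments) if cfg.segments else None,
        "resampling": dataclasses.asdict(cfg.resampling),
        "tracking": {
            "search_radius_px": cfg.search_radius_px,
            "min_corr": cfg.min_corr,
            "method": cfg.track_method,
            "template_psf_sigma_px": cfg.template_psf_sigma_px,
        },
    }


def load_run_config(source: dict | str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file path or an already-parsed mapping."""
    if not isinstance(source, dict):
        import yaml

        source = yaml.safe_load(Path(source).read_text())
    d = dict(source)
    cfg = RunConfig(raw=d)
    if "scene" in d and d["scene"] is not None:
        sd = dict(d["scene"])
        markers = []
        for i, md in enumerate(sd.pop("markers", [])):
            md = dict(md)
            tones = tuple(Tone(**td) for td in md.pop("tones", []))
            md.setdefault("marker_id", f"m{i}")
            md["center_px"] = tuple(md["center_px"])
            markers.append(MarkerSpec(tones=tones, **md))
        if "pixel_pitch_mm" in sd:
            sd["pixel_pitch_mm"] = tuple(sd["pixel_pitch_mm"])
        cfg.scene = SceneConfig(markers=tuple(markers), **sd)
    cfg.input_path = d.get("input")
    cfg.input_fps = d.get("input_fps")
    cfg.scan_tones = tuple(Tone(**td) for td in d.get("scan_tones", []))
    if "band" in d:
        cfg.band = BandSpec(float(d["band"]["f_lo"]), float(d["band"]["f_hi"]))
    if "magnification" in d:
        cfg.mag = MagParams(**d["magnification"])
    if "gain" in d and d["gain"] is not None:
        cfg.gain = GainSpec(float(d["gain"]))
    if d.get("calibration"):
        cd = d["calibration"]
        cfg.calibration = Calibration(
            float(cd["mm_per_px_x"]),
            float(cd["mm_per_px_y"]),
            tuple(cd.get("uncertainty_mm_per_px", (0.0, 0.0))),
        )
    if d.get("segments"):
        cfg.segments = SegmentPlan(
            tuple((s["label"], float(s["t_start_s"]), float(s["t_end_s"])) for s in d["segments"])
        )
    if "resampling" in d:
        rd = dict(d["resampling"])
        if "block_len_s" in rd:
            fps = cfg.scene.fps if cfg.scene else (cfg.input_fps or 1000.0)
            rd["block_len_frames"] = max(1, int(round(rd.pop("block_len_s") * fps)))
        cfg.resampling = ResamplingSpec(**rd)
    tr = d.get("tracking", {})
    cfg.search_radius_px = int(tr.get("search_radius_px", cfg.search_radius_px))
    cfg.min_corr = float(tr.get("min_corr", cfg.min_corr))
    cfg.track_method = tr.get("method", cfg.track_method)
    cfg.template_psf_sigma_px = float(
        tr.get("template_psf_sigma_px", cfg.template_psf_sigma_px)
    )
    cfg.axis_labels = {k: tuple(v) for k, v in d.get("axis_labels", {}).items()}
    cfg.f_max_hz = d.get("f_max_hz", cfg.f_max_hz)
    cfg.output_dir = d.get("output_dir", cfg.output_dir)
    cfg.write_clips = bool(d.get("write_clips", False))
    return cfg


@dataclass
class RunReport:
    """All quantitative outputs of one run."""

    metrics: pd.DataFrame
    pooled: dict
    spectra: dict
    stability: dict
    comparisons: dict
    config_hash: str
    version: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "pooled": self.pooled,
            "stability": self.stability,
            "comparisons": self.comparisons,
        }


def _template_for(cfg: RunConfig) -> Template:
    cal = cfg.effective_calibration()
    if cfg.scene is not None and cfg.scene.markers:
        spec = cfg.scene.markers[0]
    else:
        spec = MarkerSpec(center_px=(0.0, 0.0))
    return make_template(
        spec,
        pixel_pitch_mm=(cal.mm_per_px_x, cal.mm_per_px_y),
        psf_sigma_px=cfg.template_psf_sigma_px,
    )


def _process_clip(
    cfg: RunConfig,
    clip: FrameStack,
    template: Template,
    init_positions: list[tuple[float, float]],
    marker_ids: list[str],
    condition_label: str,
) -> list[DisplacementSeries]:
    """magnify -> track -> µm displacement for every marker, both axes."""
    amplified = magnify_clip(clip, cfg.band, cfg.mag)
    tracks = track_clip(
        amplified,
        init_positions,
        template,
        search_radius_px=cfg.search_radius_px,
        marker_ids=marker_ids,
        method=cfg.track_method,
    )
    cal = cfg.effective_calibration()
    gain = cfg.effective_gain()
    series: list[DisplacementSeries] = []
    for trk in tracks:
        labels = cfg.axis_labels.get(trk.marker_id, ("x", "y"))
        series.extend(
            to_displacement(
                trk,
                cal,
                gain,
                fps=clip.fps,
                axis_labels=labels,
                condition_label=condition_label,
            )
        )
    return series


def _init_positions(
    cfg: RunConfig, clip: FrameStack, template: Template
) -> tuple[list[tuple[float, float]], list[str]]:
    if cfg.scene is not None and cfg.scene.markers:
        return (
            [m.center_px for m in cfg.scene.markers],
            [m.marker_id for m in cfg.scene.markers],
        )
    detections = detect_markers(clip.frames[0], template, min_corr=cfg.min_corr)
    if not detections:
        raise RuntimeError("no markers detected in the first frame")
    return [(float(x), float(y)) for x, y in detections], [
        f"m{i}" for i in range(len(detections))
    ]


def run_pipeline(config: RunConfig | dict | str | Path, write: bool = True) -> RunReport:
    """Execute the full pipeline and (optionally) write all artifacts."""
    cfg = config if isinstance(config, RunConfig) else load_run_config(config)
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    template = _template_for(cfg)

    all_series: list[DisplacementSeries] = []
    comparisons: dict[str, dict] = {}
    ground_truths = {}

    if cfg.scan_tones:
        if cfg.scene is None:
            raise ValueError("pair mode (scan_tones) requires a scene config")
        (idle_clip, idle_gt), (scan_clip, scan_gt) = make_condition_pair(
            cfg.scene, list(cfg.scan_tones)
        )
        ground_truths = {"idle": idle_gt, "scan": scan_gt}
        init, mids = _init_positions(cfg, idle_clip, template)
        idle_series = _process_clip(cfg, idle_clip, template, init, mids, "idle")
        scan_series = _process_clip(cfg, scan_clip, template, init, mids, "scan")
        all_series = idle_series + scan_series
        if cfg.write_clips and write:
            save_stack_tiff(idle_clip, out / "idle.tiff")
            save_stack_tiff(scan_clip, out / "scan.tiff")
        for s_idle, s_scan in zip(idle_series, scan_series):
            key = f"{s_scan.marker_id}/{s_scan.axis_label}"
            res = compare_conditions(s_scan, s_idle, cfg.resampling)
            comparisons[key] = dataclasses.asdict(res)
    else:
        if cfg.scene is not None:
            clip, gt = simulate_clip(cfg.scene)
            ground_truths = {"clip": gt}
        elif cfg.input_path:
            clip = load_stack(cfg.input_path, fps=cfg.input_fps)
        else:
            raise ValueError("config needs either a scene or an input path")
        init, mids = _init_positions(cfg, clip, template)
        full_series = _process_clip(cfg, clip, template, init, mids, "all")
        if cfg.segments is not None:
            for s in full_series:
                all_series.extend(segment_series(s, cfg.segments))
        else:
            all_series = full_series
        if cfg.write_clips and write:
            save_stack_tiff(clip, out / "clip.tiff")

    metrics = metrics_table(all_series)
    pooled = {}
    for cond, grp in metrics.groupby("condition", sort=False):
        for col in ("rms_um", "pp_um"):
            summ = pool_summary(grp[col].to_numpy())
            pooled[f"{cond}/{col}"] = dataclasses.asdict(summ)

    spectra_out = {}
    by_key: dict[tuple[str, str], list[DisplacementSeries]] = {}
    for s in all_series:
        by_key.setdefault((s.marker_id, s.condition_label), []).append(s)
    for (mid, cond), pair in by_key.items():
        if len(pair) == 2 and pair[0].values.size >= 16:
            spec = amplitude_spectrum(pair[0], pair[1], f_max=cfg.f_max_hz)
            spectra_out[f"{mid}/{cond}"] = spec

    stability: dict[str, dict] = {}
    pairs_by_cond: dict[str, list] = {}
    for s in all_series:
        if s.values.size >= 4:
            pairs_by_cond.setdefault(s.condition_label, []).append(split_half_pairs(s))
    for cond, pairs in pairs_by_cond.items():
        stability[cond] = dataclasses.asdict(bland_altman(pairs))

    report = RunReport(
        metrics=metrics,
        pooled=pooled,
        spectra=spectra_out,
        stability=stability,
        comparisons=comparisons,
        config_hash=cfg.config_hash(),
        version=__version__,
        seed=cfg.scene.seed if cfg.scene else cfg.resampling.seed,
    )

    if write:
        metrics.to_csv(out / "metrics.csv", index=False)
        save_json(report.to_dict(), out / "report.json")
        from .spectra import plot_spectrum

        for key, spec in spectra_out.items():
            safe = key.replace("/", "_")
            pd.DataFrame(
                {"freq_hz": spec.freqs, "density_um_per_hz": spec.density}
            ).to_csv(out / f"spectrum_{safe}.csv", index=False)
            plot_spectrum(spec, out / f"spectrum_{safe}.png", title=key)
        if ground_truths and cfg.write_clips:
            for label, gt in ground_truths.items():
                gt.to_dataframe().to_csv(out / f"ground_truth_{label}.csv", index=False)
        save_yaml(cfg.raw or _config_to_dict(cfg), out / "resolved_config.yaml")
    return report
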