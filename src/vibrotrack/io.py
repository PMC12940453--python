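"""File I/O: TIFF/PNG frame stacks, CSV tracks and metrics, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import FrameStack
from .track import Calibration, Track

__all__ = [
    "save_stack_tiff",
    "save_stack_png_sequence",
    "load_stack",
    "save_tracks_csv",
    "load_tracks_csv",
    "save_calibration_json",
    "load_calibration_json",
    "save_yaml",
    "load_yaml",
    "save_json",
]


def save_stack_tiff(clip: FrameStack, path: str | Path) -> None:
    """Write a clip as a 16-bit grayscale multi-page TIFF (fps in metadata)."""
    data = np.clip(clip.frames, 0.0, 1.0)
    u16 = np.round(data * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, u16, metadata={"fps": clip.fps})


def save_stack_png_sequence(clip: FrameStack, directory: str | Path, prefix: str = "frame") -> None:
    """Write a clip as numbered 8-bit PNGs plus a small fps sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    u8 = np.round(np.clip(clip.frames, 0, 1) * 255).astype(np.uint8)
    for t in range(clip.n_frames):
        iio.imwrite(directory / f"{prefix}_{t:06d}.png", u8[t])
    (directory / "fps.json").write_text(json.dumps({"fps": clip.fps}))


def load_stack(path: str | Path, fps: float | None = None) -> FrameStack:
    """Load a multi-page TIFF or a directory of numbered PNGs as a FrameStack."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files]).astype(np.float64) / 255.0
        if fps is None:
            sidecar = path / "fps.json"
            if not sidecar.exists():
                raise ValueError("fps not given and no fps.json sidecar present")
            fps = json.loads(sidecar.read_text())["fps"]
    else:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray().astype(np.float64)
            if fps is None:
                meta = tf.shaped_metadata or tf.imagej_metadata or {}
                if isinstance(meta, (list, tuple)):
                    meta = meta[0] if meta else {}
                fps = meta.get("fps")
                if fps is None:
                    raise ValueError("fps not given and not stored in TIFF metadata")
        if frames.dtype.kind in "ui" or frames.max() > 1.5:
            frames = frames / np.iinfo(np.uint16).max
    return FrameStack(frames, float(fps))


def save_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    pd.concat([t.to_dataframe() for t in tracks], ignore_index=True).to_csv(
        path, index=False
    )


def load_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for mid, grp in df.groupby("marker_id", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                str(mid),
                grp[["x_px", "y_px"]].to_numpy(dtype=float),
                grp["quality"].to_numpy(dtype=float),
            )
        )
    return tracks


def save_calibration_json(cal: Calibration, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "mm_per_px_x": cal.mm_per_px_x,
                "mm_per_px_y": cal.mm_per_px_y,
                "uncertainty_mm_per_px": list(cal.uncertainty_mm_per_px),
            },
            indent=2,
        )
    )


def load_calibration_json(path: str | Path) -> Calibration:
    d = json.loads(Path(path).read_text())
    return Calibration(
        d["mm_per_px_x"], d["mm_per_px_y"], tuple(d.get("uncertainty_mm_per_px", (0, 0)))
    )


def save_yaml(obj, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
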