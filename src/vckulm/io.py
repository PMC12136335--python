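"""Frame-stack container and file I/O (TIFF / HDF5 / CSV / YAML).

All positions in this package are 0-based pixels with x = column index,
y = row index, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml


@dataclass
class FrameStack:
    """Time-ordered stack of 2D intensity frames with acquisition metadata.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Envelope / B-mode-like intensity data.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size_um : float
        Isotropic pixel pitch in micrometres.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size_um: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (n_frames, rows, cols)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy_with(self, frames: np.ndarray, frame_rate: float | None = None) -> "FrameStack":
        return replace(self, frames=frames,
                       frame_rate=self.frame_rate if frame_rate is None else frame_rate)


def write_stack(path: str | Path, stack: FrameStack) -> None:
    """Write a stack as multipage 32-bit float TIFF or HDF5 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=stack.frames.astype(np.float32))
            ds.attrs["frame_rate_hz"] = stack.frame_rate
            ds.attrs["pixel_size_um"] = stack.pixel_size_um
    else:
        tifffile.imwrite(
            path, stack.frames.astype(np.float32),
            metadata={"frame_rate_hz": stack.frame_rate,
                      "pixel_size_um": stack.pixel_size_um},
        )


def read_stack(path: str | Path, frame_rate: float | None = None,
               pixel_size_um: float | None = None) -> FrameStack:
    """Read a multipage TIFF or HDF5 stack.

    For TIFF the metadata is recovered from the ImageJ/shaped-metadata block
    when present; explicit arguments override the stored values.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["frames"]
            frames = ds[...]
            fr = float(ds.attrs.get("frame_rate_hz", 0.0))
            px = float(ds.attrs.get("pixel_size_um", 10.0))
    else:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            fr = float(meta.get("frame_rate_hz", 0.0))
            px = float(meta.get("pixel_size_um", 10.0))
    if frame_rate is not None:
        fr = frame_rate
    if pixel_size_um is not None:
        px = pixel_size_um
    if fr <= 0:
        raise ValueError("frame rate missing from file; pass frame_rate=")
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames=np.asarray(frames, dtype=np.float64),
                      frame_rate=fr, pixel_size_um=px)


def write_tracks_csv(path: str | Path, tracks) -> None:
    """Write tracks as CSV with columns track_id, frame, x, y, brightness."""
    rows = []
    for tr in tracks:
        for (frame, x, y, b) in tr.points:
            rows.append((tr.track_id, frame, x, y, b))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "brightness"])
    df.to_csv(path, index=False, float_format="%.6f")


def write_detections_csv(path: str | Path, detections) -> None:
    rows = [(d.frame, d.x, d.y, d.brightness) for d in detections]
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "brightness"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_detections_csv(path: str | Path):
    from .localize import Detection
    df = pd.read_csv(path)
    return [Detection(frame=int(r.frame), x=float(r.x), y=float(r.y),
                      brightness=float(r.brightness))
            for r in df.itertuples()]


def write_motion_csv(path: str | Path, displacements: np.ndarray) -> None:
    """Per-frame global (dx, dy) in pixels."""
    df = pd.DataFrame({"frame": np.arange(len(displacements)),
                       "dx": displacements[:, 0], "dy": displacements[:, 1]})
    df.to_csv(path, index=False, float_format="%.9f")


def load_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)
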