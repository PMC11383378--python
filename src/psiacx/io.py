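"""Readers and writers for the pipeline's on-disk formats.

Movies travel as multi-page TIFF; trial schedules, ROI centers, HTR event
times, and result tables as CSV; ground truth and reports as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocol import ToneProtocol

__all__ = [
    "save_movie",
    "load_movie",
    "save_schedule",
    "load_schedule",
    "save_roi_centers",
    "load_roi_centers",
    "save_htr_times",
    "load_htr_times",
    "save_json",
    "load_json",
]


def save_movie(path, movie: np.ndarray) -> None:
    """Write an (n_frames, H, W) stack as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def load_movie(path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def save_schedule(path, protocol: ToneProtocol) -> None:
    """Trial schedule CSV with columns trial, frequency_khz, onset_s."""
    protocol.to_frame().to_csv(path, index=False)


def load_schedule(path, tone_duration_s: float = 0.5) -> ToneProtocol:
    return ToneProtocol.from_frame(pd.read_csv(path), tone_duration_s=tone_duration_s)


def save_roi_centers(path, centers: np.ndarray) -> None:
    """ROI-center CSV with columns x, y (column, row pixel coordinates)."""
    centers = np.atleast_2d(np.asarray(centers))
    pd.DataFrame({"x": centers[:, 1], "y": centers[:, 0]}).to_csv(path, index=False)


def load_roi_centers(path) -> np.ndarray:
    """Return (n, 2) [row, col] centers from an x/y CSV."""
    tab = pd.read_csv(path)
    return np.column_stack([tab["y"].to_numpy(float), tab["x"].to_numpy(float)])


def save_htr_times(path, times_s) -> None:
    pd.DataFrame({"t_s": np.asarray(times_s, dtype=float)}).to_csv(path, index=False)


def load_htr_times(path) -> np.ndarray:
    return pd.read_csv(path)["t_s"].to_numpy(float)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
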