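"""Video-based quantification of free-roaming movement (cage exploration).

From a video V, sequential frame differences V′(f) = V(f+1) − V(f) are
reduced to a one-dimensional trace D by summing |V′| over pixels per frame;
the movement trace M is the low-passed Hilbert-envelope of D. Spatial
movement maps average |V′| per pixel over a time window with a 2-SEM noise
floor; windowed means of M and correlation against a binned head-twitch
(HTR) time-course summarize each session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "MovementTrace",
    "SpatialMovementMap",
    "HtrTemplate",
    "frame_difference",
    "frame_energy",
    "movement_envelope",
    "movement_trace",
    "spatial_movement_map",
    "normalize_maps",
    "window_means",
    "htr_template",
    "template_correlation",
]


@dataclass
class MovementTrace:
    """Per-frame movement summary of one video.

    ``D`` is the summed |frame difference| per frame, ``M`` its low-passed
    Hilbert envelope; both have length n_frames − 1 with sample f timestamped
    between frames f and f+1.
    """

    M: np.ndarray
    D: np.ndarray
    fps: float

    @property
    def t_s(self) -> np.ndarray:
        return (np.arange(self.M.size) + 0.5) / self.fps

    @property
    def duration_s(self) -> float:
        return (self.M.size + 1) / self.fps


@dataclass
class SpatialMovementMap:
    """Per-pixel mean movement over a time window, noise-floored and
    (optionally jointly) peak-normalized."""

    values: np.ndarray
    window_min: tuple[float, float]
    norm: float | None = None


@dataclass
class HtrTemplate:
    """Binned head-twitch counts over time."""

    counts: np.ndarray
    bin_width_s: float
    label: str = ""

    @property
    def duration_s(self) -> float:
        return self.counts.size * self.bin_width_s


def frame_difference(video: np.ndarray) -> np.ndarray:
    """Signed successive frame differences V′(f) = V(f+1) − V(f)."""
    video = np.asarray(video)
    if video.ndim != 3 or video.shape[0] < 2:
        raise ValueError("video must be (n_frames >= 2, H, W)")
    return np.diff(video.astype(np.float64), axis=0)


def frame_energy(vprime: np.ndarray) -> np.ndarray:
    """Per-frame movement energy: sum of |V′| over pixels.

    Absolute values are summed — signed differences of a brightness-conserving
    moving object would cancel to ≈ 0.
    """
    return np.abs(np.asarray(vprime, dtype=float)).sum(axis=(1, 2))


def movement_envelope(D: np.ndarray, fps: float, lowpass_hz: float = 0.5) -> np.ndarray:
    """Low-passed Hilbert-envelope of the frame-energy trace.

    The analytic-signal magnitude of D is smoothed with a zero-phase
    Butterworth low-pass at ``lowpass_hz`` and clamped at 0. The envelope is
    taken on D itself (not on a mean-removed copy): D is a nonnegative
    activity signal, and rectifying it around its global mean would fold
    quiescent below-mean stretches upward, masking exactly the hypoactivity
    the trace is meant to expose.
    """
    D = np.asarray(D, dtype=float)
    if lowpass_hz >= fps / 2.0:
        raise ValueError("lowpass cutoff must be below the Nyquist frequency")
    env = np.abs(hilbert(D))
    sos = butter(4, lowpass_hz, btype="low", fs=fps, output="sos")
    M = sosfiltfilt(sos, env)
    return np.clip(M, 0.0, None)


def movement_trace(video: np.ndarray, fps: float, lowpass_hz: float = 0.5) -> MovementTrace:
    """Full chain video → V′ → D → M."""
    D = frame_energy(frame_difference(video))
    return MovementTrace(M=movement_envelope(D, fps, lowpass_hz), D=D, fps=float(fps))


def spatial_movement_map(
    vprime: np.ndarray,
    fps: float,
    window_min: tuple[float, float] = (0.0, 10.0),
) -> SpatialMovementMap:
    """Per-pixel mean |V′| within a time window, with a 2-SEM noise floor.

    The noise floor is computed per pixel from that pixel's |V′| values
    across the whole video: window-mean values below twice the standard
    error of the per-frame mean are set exactly to 0.
    """
    vabs = np.abs(np.asarray(vprime, dtype=float))
    n = vabs.shape[0]
    lo = int(round(window_min[0] * 60.0 * fps))
    hi = min(n, int(round(window_min[1] * 60.0 * fps)))
    if lo >= hi:
        raise ValueError("empty time window")
    sem = vabs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(vabs.shape[1:])
    mean_map = vabs[lo:hi].mean(axis=0)
    values = np.where(mean_map < 2.0 * sem, 0.0, mean_map)
    return SpatialMovementMap(values=values, window_min=tuple(window_min))


def normalize_maps(maps: list[SpatialMovementMap]) -> list[SpatialMovementMap]:
    """Jointly normalize a set of maps to the peak value across all of them.

    After normalization the global maximum over the compared maps equals 1
    (when any map is nonzero) and the zero floor is preserved.
    """
    peak = max(float(m.values.max()) for m in maps)
    if peak <= 0:
        return [SpatialMovementMap(m.values.copy(), m.window_min, norm=1.0) for m in maps]
    return [
        SpatialMovementMap(m.values / peak, m.window_min, norm=peak) for m in maps
    ]


def window_means(
    M: np.ndarray,
    fps: float,
    windows_min: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 60.0)),
) -> dict[tuple[float, float], float]:
    """Time-mean of M in each window (minutes).

    Windows extending beyond the trace are truncated with a warning
    (sessions are typically 40–60 min); a window with no samples raises.
    """
    M = np.asarray(M, dtype=float)
    out: dict[tuple[float, float], float] = {}
    for w0, w1 in windows_min:
        lo = int(round(w0 * 60.0 * fps))
        hi = int(round(w1 * 60.0 * fps))
        if hi > M.size:
            warnings.warn(
                f"window {w0}-{w1} min truncated to the {M.size / fps / 60.0:.1f}-min trace",
                RuntimeWarning,
                stacklevel=2,
            )
            hi = M.size
        if lo >= hi:
            raise ValueError(f"window {w0}-{w1} min has no samples")
        out[(w0, w1)] = float(M[lo:hi].mean())
    return out


def htr_template(
    event_times_s,
    duration_s: float,
    bin_width_s: float = 60.0,
    label: str = "",
) -> HtrTemplate:
    """Bin head-twitch event times into contiguous counts."""
    edges = np.arange(0.0, duration_s + bin_width_s, bin_width_s)
    counts, _ = np.histogram(np.asarray(event_times_s, dtype=float), bins=edges)
    return HtrTemplate(counts=counts.astype(float), bin_width_s=float(bin_width_s), label=label)


def template_correlation(M: np.ndarray, fps: float, template: HtrTemplate) -> float:
    """Pearson correlation between the movement trace and an HTR time-course.

    M is binned to the template's bins (mean per bin) over the overlapping
    time support. Returns NaN (with a warning) when either series has zero
    variance or fewer than two overlapping bins exist.
    """
    M = np.asarray(M, dtype=float)
    n_bins = min(template.counts.size, int(M.size / fps / template.bin_width_s))
    if n_bins < 2:
        warnings.warn("fewer than two overlapping bins", RuntimeWarning, stacklevel=2)
        return float("nan")
    per_bin = int(round(template.bin_width_s * fps))
    binned = M[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
    counts = template.counts[:n_bins]
    if binned.std() == 0 or counts.std() == 0:
        warnings.warn(
            "zero-variance series: template correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(binned, counts)[0, 1])
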