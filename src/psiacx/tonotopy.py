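"""Pixel-wise tonotopic maps from widefield movies.

The chain: homomorphic filtering to suppress smooth multiplicative
illumination, per-pixel per-trial ΔF/F averaged over repeats of each tone
frequency, the ΔF/F₉₀ criterion (keep frequencies whose averaged-trace peak
is within 90% of the pixel's maximum), and assignment of each pixel's
tonotopic frequency as the median of the surviving frequencies on the octave
axis (geometric mean of the middle pair for even-sized sets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .protocol import ToneProtocol

__all__ = [
    "PixelDff",
    "TonotopicMap",
    "homomorphic_filter",
    "pixel_dff",
    "dff90_select",
    "tonotopic_map",
    "map_tonotopy",
]


def _frames(seconds: float, frame_rate_hz: float) -> int:
    return int(np.floor(seconds * frame_rate_hz + 0.5))


@dataclass
class PixelDff:
    """Repeat-averaged per-pixel ΔF/F traces, one per tone frequency.

    ``traces`` has shape (n_frequencies, n_time, H, W); pixels with a
    nonpositive baseline on any contributing trial are NaN.
    """

    traces: np.ndarray
    time_s: np.ndarray
    frequencies_khz: np.ndarray
    frame_rate_hz: float


@dataclass
class TonotopicMap:
    """Per-pixel tonotopic frequency assignment.

    ``bf_map`` holds the assigned frequency (kHz; NaN where undefined),
    ``response_map`` the grand-average peak ΔF/F, and ``selected`` the
    boolean (n_frequencies, H, W) ΔF/F₉₀ survivor sets.
    """

    bf_map: np.ndarray
    response_map: np.ndarray
    selected: np.ndarray
    frequencies_khz: np.ndarray


def homomorphic_filter(frame_stack: np.ndarray, blur_sigma_px: float = 50.0) -> np.ndarray:
    """Remove smooth multiplicative illumination from each frame.

    Per frame: log-transform, subtract a large-kernel Gaussian blur of the
    log image, exponentiate. Structures much smaller than ``blur_sigma_px``
    pass through; illumination varying on larger scales is divided out.
    Pixel values must be positive; a nonpositive stack is shifted to a small
    positive floor first (with a warning).
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (n_frames, H, W)")
    mn = stack.min()
    if mn <= 0:
        offset = -mn + 1e-3 * max(np.ptp(stack), 1.0)
        warnings.warn(
            f"nonpositive pixel values; adding offset {offset:.3g} before the log",
            RuntimeWarning,
            stacklevel=2,
        )
        stack = stack + offset
        if stack.min() <= 0:
            raise ValueError("pixel values nonpositive even after offset")
    log = np.log(stack)
    # edge-replicating boundary keeps the illumination estimate tracking
    # smooth gradients up to the frame border
    blurred = gaussian_filter(log, sigma=(0.0, blur_sigma_px, blur_sigma_px), mode="nearest")
    return np.exp(log - blurred)


def pixel_dff(
    frame_stack: np.ndarray,
    protocol: ToneProtocol,
    frame_rate_hz: float = 5.0,
    baseline_window_s: float = 2.0,
    post_window_s: float = 3.0,
) -> PixelDff:
    """Per-pixel ΔF/F traces averaged over the repeats of each frequency.

    The same ΔF/F construction as the 2P pipeline — baseline-mean
    subtraction and division over [−baseline, tone + post] — applied to
    every pixel, then averaged across each frequency's trials.
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (n_frames, H, W)")
    fr = frame_rate_hz
    nb = _frames(baseline_window_s, fr)
    npost = _frames(protocol.tone_duration_s + post_window_s, fr)
    onset_f = np.floor(protocol.trial_onset_s * fr + 0.5).astype(int)
    rel = np.arange(-nb, npost + 1)
    H, W = stack.shape[1:]
    nf = protocol.n_frequencies

    out = np.zeros((nf, rel.size, H, W))
    counts = np.zeros((nf, H, W))
    bad_baseline = 0
    for t in range(protocol.n_trials):
        lo, hi = onset_f[t] - nb, onset_f[t] + npost
        if lo < 0 or hi >= stack.shape[0]:
            continue
        seg = stack[lo : hi + 1]
        base = seg[:nb].mean(axis=0)
        ok = base > 0
        if not ok.all():
            bad_baseline += int((~ok).sum())
        j = protocol.trial_freq_idx[t]
        d = np.where(ok[None], (seg - base[None]) / np.where(ok, base, 1.0)[None], 0.0)
        out[j] += np.where(ok[None], d, 0.0)
        counts[j] += ok
    if bad_baseline:
        warnings.warn(
            f"{bad_baseline} pixel-trial(s) with nonpositive baseline excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        traces = out / counts[:, None, :, :]
    traces[np.broadcast_to((counts == 0)[:, None], traces.shape)] = np.nan
    return PixelDff(
        traces=traces,
        time_s=rel / fr,
        frequencies_khz=protocol.frequencies_khz,
        frame_rate_hz=fr,
    )


def dff90_select(pdff: PixelDff, threshold: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel set of frequencies within ``threshold`` of the maximum peak.

    For each pixel, each frequency's averaged trace is reduced to its
    temporal peak; frequencies whose peak is at least ``threshold`` times the
    pixel's maximum peak survive. Pixels whose peaks are all nonpositive (or
    undefined) select nothing. Returns ``(selected, peak_map)`` where
    ``selected`` is boolean (n_frequencies, H, W) and ``peak_map`` is the
    per-pixel maximum peak.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peaks = np.nanmax(pdff.traces, axis=1)        # (F, H, W)
        m = np.nanmax(peaks, axis=0)                  # (H, W)
    valid = np.isfinite(m) & (m > 0)
    selected = np.zeros(peaks.shape, dtype=bool)
    sel = peaks >= threshold * np.where(valid, m, np.inf)[None]
    selected[:, valid] = sel[:, valid]
    return selected, np.where(valid, m, np.nan)


def tonotopic_map(
    selected: np.ndarray,
    frequencies_khz: np.ndarray,
    response_map: np.ndarray | None = None,
) -> TonotopicMap:
    """Assign each pixel the median surviving frequency on the octave axis.

    The median is taken over log2 frequency, so an even-sized set maps to the
    geometric mean of its two middle frequencies. Pixels with an empty
    survivor set are NaN.
    """
    frequencies_khz = np.asarray(frequencies_khz, dtype=float)
    logf = np.log2(frequencies_khz)
    nf, H, W = selected.shape
    bf = np.full((H, W), np.nan)
    counts = selected.sum(axis=0)
    flat_sel = selected.reshape(nf, -1)
    flat_bf = bf.reshape(-1)
    for p in np.flatnonzero(counts.reshape(-1)):
        flat_bf[p] = 2.0 ** np.median(logf[flat_sel[:, p]])
    if response_map is None:
        response_map = np.where(counts > 0, np.nan, np.nan)
    return TonotopicMap(
        bf_map=bf,
        response_map=response_map,
        selected=selected,
        frequencies_khz=frequencies_khz,
    )


def map_tonotopy(
    frame_stack: np.ndarray,
    protocol: ToneProtocol,
    frame_rate_hz: float = 5.0,
    baseline_window_s: float = 2.0,
    post_window_s: float = 3.0,
    threshold: float = 0.9,
    blur_sigma_px: float = 50.0,
    homomorphic: bool = True,
) -> TonotopicMap:
    """Full widefield chain: filter → pixel ΔF/F → ΔF/F₉₀ → median map."""
    stack = homomorphic_filter(frame_stack, blur_sigma_px) if homomorphic else frame_stack
    pdff = pixel_dff(
        stack,
        protocol,
        frame_rate_hz=frame_rate_hz,
        baseline_window_s=baseline_window_s,
        post_window_s=post_window_s,
    )
    selected, peak_map = dff90_select(pdff, threshold=threshold)
    return tonotopic_map(selected, protocol.frequencies_khz, response_map=peak_map)
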