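"""Somatic/neuropil trace extraction and ΔF/F trial rasters for 2P imaging.

The processing chain mirrors standard GCaMP practice: ring-like somatic ROIs
around supplied cell centers, an outer neuropil ring starting a few pixels
beyond the soma, pixel-mean raw traces, neuropil correction
C(t) = C_raw(t) − 0.7·N(t), a positivity QC on the time-mean of C, per-trial
ΔF/F against a silent pre-stimulus baseline, 1-s post-onset response
amplitudes, and per-neuron normalization by the trial-to-trial standard
deviation of those amplitudes (ΔF/F(σ)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .protocol import ToneProtocol

__all__ = [
    "RoiMaskSet",
    "CellTraces",
    "TrialTensor",
    "build_roi_masks",
    "extract_traces",
    "neuropil_correct",
    "qc_filter_cells",
    "compute_dff",
    "response_amplitude",
    "sigma_normalize",
]


def _frames(seconds: float, frame_rate_hz: float) -> int:
    """Round a duration to the nearest whole number of frames."""
    return int(np.floor(seconds * frame_rate_hz + 0.5))


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------


@dataclass
class RoiMaskSet:
    """Per-neuron somatic-annulus and neuropil-ring pixel sets.

    ``somatic`` and ``neuropil`` are lists of ``(rows, cols)`` integer index
    arrays into an image of shape ``image_shape``. Somatic sets are pairwise
    disjoint and disjoint from every neuropil set.
    """

    centers: np.ndarray
    somatic: list[tuple[np.ndarray, np.ndarray]]
    neuropil: list[tuple[np.ndarray, np.ndarray]]
    image_shape: tuple[int, int]
    dropped: list[int]

    @property
    def n_neurons(self) -> int:
        return len(self.somatic)


def _annulus(
    center: np.ndarray,
    r_in: float,
    r_out: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices with r_in <= distance-to-center <= r_out, clipped to the image."""
    cy, cx = float(center[0]), float(center[1])
    y0 = max(0, int(np.floor(cy - r_out)))
    y1 = min(shape[0] - 1, int(np.ceil(cy + r_out)))
    x0 = max(0, int(np.floor(cx - r_out)))
    x1 = min(shape[1] - 1, int(np.ceil(cx + r_out)))
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    d = np.hypot(yy - cy, xx - cx)
    sel = (d >= r_in) & (d <= r_out)
    return yy[sel], xx[sel]


def build_roi_masks(
    centers,
    image_shape: tuple[int, int],
    somatic_radii: tuple[float, float] = (2.0, 6.0),
    neuropil_gap_px: float = 3.0,
    neuropil_width_px: float = 10.0,
) -> RoiMaskSet:
    """Build ring-like somatic ROIs and outer neuropil rings around cell centers.

    The somatic ROI is the annulus between the inner and outer somatic radii
    (the ring-like appearance of membrane-labelled GCaMP somata); the neuropil
    ring begins ``neuropil_gap_px`` beyond the somatic outer radius and is
    ``neuropil_width_px`` wide. Pixels claimed by more than one somatic ROI
    are removed from all of them, and neuropil pixels overlapping any somatic
    ROI are removed from the neuropil rings.

    Rings truncated by the image border are kept (with a warning for
    truncated neuropil); a neuron whose somatic set ends up empty is dropped
    with a warning and recorded in ``dropped``.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[1] != 2:
        raise ValueError("centers must be (n, 2) [row, col]")
    r_in, r_out = somatic_radii
    if r_in < 0 or r_out <= 0 or r_in >= r_out:
        raise ValueError("somatic_radii must satisfy 0 <= inner < outer")
    if np.any(centers < 0) or np.any(centers[:, 0] > image_shape[0] - 1) or np.any(
        centers[:, 1] > image_shape[1] - 1
    ):
        raise ValueError("centers must lie inside the image")

    som_raw = [_annulus(c, r_in, r_out, image_shape) for c in centers]
    np_in = r_out + neuropil_gap_px
    np_out = np_in + neuropil_width_px
    npil_raw = [_annulus(c, np_in, np_out, image_shape) for c in centers]

    # occupancy counts over original somatic sets
    count = np.zeros(image_shape, dtype=np.int32)
    for rows, cols in som_raw:
        count[rows, cols] += 1
    somatic_union = count > 0
    shared = count > 1

    somatic, neuropil, dropped = [], [], []
    for i, c in enumerate(centers):
        rows, cols = som_raw[i]
        keep = ~shared[rows, cols]
        srows, scols = rows[keep], cols[keep]
        if srows.size == 0:
            warnings.warn(
                f"neuron {i}: somatic ROI empty after overlap exclusion; dropped",
                RuntimeWarning,
                stacklevel=2,
            )
            dropped.append(i)
            continue
        nrows, ncols = npil_raw[i]
        full = _ring_area(r_out, neuropil_gap_px, neuropil_width_px)
        if nrows.size < 0.9 * full:
            warnings.warn(
                f"neuron {i}: neuropil ring truncated at the image border",
                RuntimeWarning,
                stacklevel=2,
            )
        keep_np = ~somatic_union[nrows, ncols]
        neuropil.append((nrows[keep_np], ncols[keep_np]))
        somatic.append((srows, scols))

    kept = [i for i in range(len(centers)) if i not in dropped]
    return RoiMaskSet(
        centers=centers[kept],
        somatic=somatic,
        neuropil=neuropil,
        image_shape=tuple(image_shape),
        dropped=dropped,
    )


def _ring_area(r_out: float, gap: float, width: float) -> float:
    """Approximate pixel count of a full (untruncated) neuropil ring."""
    return np.pi * ((r_out + gap + width) ** 2 - (r_out + gap) ** 2)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


@dataclass
class CellTraces:
    """Per-neuron fluorescence traces on one frame timebase.

    ``C_raw`` and ``N`` are (n_neurons, n_frames) somatic and neuropil pixel
    means; ``C`` is the neuropil-corrected trace, present only after
    :func:`neuropil_correct` (or :meth:`corrected`).
    """

    C_raw: np.ndarray
    N: np.ndarray
    frame_rate_hz: float
    C: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.C_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.C_raw.shape[1]

    def corrected(self, coeff: float = 0.7) -> "CellTraces":
        """Return a copy with ``C = C_raw − coeff·N``."""
        return replace(self, C=neuropil_correct(self.C_raw, self.N, coeff))

    def subset(self, idx) -> "CellTraces":
        return CellTraces(
            C_raw=self.C_raw[idx],
            N=self.N[idx],
            frame_rate_hz=self.frame_rate_hz,
            C=None if self.C is None else self.C[idx],
        )


def extract_traces(
    movie: np.ndarray, masks: RoiMaskSet, frame_rate_hz: float = 30.0
) -> CellTraces:
    """Average pixels in each somatic and neuropil ROI per frame.

    ``movie`` is a registered (n_frames, H, W) stack matching
    ``masks.image_shape``.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[1:] != masks.image_shape:
        raise ValueError("movie shape does not match the mask image shape")
    n = masks.n_neurons
    C_raw = np.empty((n, movie.shape[0]))
    N = np.empty((n, movie.shape[0]))
    for i in range(n):
        srows, scols = masks.somatic[i]
        nrows, ncols = masks.neuropil[i]
        if srows.size == 0 or nrows.size == 0:
            raise ValueError(f"neuron {i} has an empty pixel set")
        C_raw[i] = movie[:, srows, scols].mean(axis=1)
        N[i] = movie[:, nrows, ncols].mean(axis=1)
    return CellTraces(C_raw=C_raw, N=N, frame_rate_hz=float(frame_rate_hz))


def neuropil_correct(C_raw: np.ndarray, N: np.ndarray, coeff: float = 0.7) -> np.ndarray:
    """Neuropil-corrected fluorescence, pointwise ``C_raw − coeff·N``."""
    C_raw = np.asarray(C_raw, dtype=float)
    N = np.asarray(N, dtype=float)
    if C_raw.shape != N.shape:
        raise ValueError("C_raw and N must have the same shape")
    return C_raw - coeff * N


def qc_filter_cells(traces: CellTraces) -> np.ndarray:
    """Indices of neurons whose corrected trace has a strictly positive time-mean.

    A nonpositive mean of C(t) indicates that neuropil contamination dominated
    the somatic signal; those cells are excluded.
    """
    if traces.C is None:
        raise ValueError("run neuropil correction before QC")
    return np.flatnonzero(traces.C.mean(axis=1) > 0)


# ---------------------------------------------------------------------------
# Trial tensor
# ---------------------------------------------------------------------------


@dataclass
class TrialTensor:
    """Stimulus-aligned ΔF/F raster: neurons × trials × time.

    ``dff[i, t]`` spans ``[-baseline_window_s, tone_duration + post_window_s]``
    around trial t's tone onset (frame 0 = onset frame). ``valid`` flags
    trials excluded for a nonpositive baseline or an out-of-range window
    (their samples are NaN). After :func:`sigma_normalize`, values are in
    ΔF/F(σ) units and ``sigma`` holds each neuron's amplitude SD.
    """

    dff: np.ndarray
    time_s: np.ndarray
    frame_rate_hz: float
    frequencies_khz: np.ndarray
    trial_freq_idx: np.ndarray
    baseline_window_s: float
    post_window_s: float
    tone_duration_s: float
    valid: np.ndarray
    sigma: np.ndarray | None = None
    normalized: bool = False
    neuron_ids: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]

    @property
    def trial_frequencies_khz(self) -> np.ndarray:
        return self.frequencies_khz[self.trial_freq_idx]


def compute_dff(
    traces: CellTraces,
    protocol: ToneProtocol,
    baseline_window_s: float = 2.0,
    post_window_s: float = 3.0,
) -> TrialTensor:
    """Per-trial ΔF/F against the silent pre-stimulus baseline.

    For each trial, the baseline F is the mean of the corrected trace over the
    ``baseline_window_s`` seconds before tone onset; ΔF/F(t) =
    (F(t) − F̄_base)/F̄_base from −baseline_window to tone offset +
    ``post_window_s``. Trials with a nonpositive baseline (or a window
    falling off the recording) are flagged invalid, filled with NaN, and
    reported with a warning.
    """
    if traces.C is None:
        raise ValueError("compute_dff requires neuropil-corrected traces (traces.C)")
    fr = traces.frame_rate_hz
    nb = _frames(baseline_window_s, fr)
    npost = _frames(protocol.tone_duration_s + post_window_s, fr)
    if nb < 1:
        raise ValueError("baseline window shorter than one frame")
    onset_f = np.floor(protocol.trial_onset_s * fr + 0.5).astype(int)
    rel = np.arange(-nb, npost + 1)
    n_neurons, n_frames = traces.C.shape
    n_trials = protocol.n_trials

    dff = np.full((n_neurons, n_trials, rel.size), np.nan)
    valid = np.ones((n_neurons, n_trials), dtype=bool)
    n_base_bad = 0
    n_range_bad = 0
    for t in range(n_trials):
        lo, hi = onset_f[t] - nb, onset_f[t] + npost
        if lo < 0 or hi >= n_frames:
            valid[:, t] = False
            n_range_bad += 1
            continue
        seg = traces.C[:, lo : hi + 1]
        base = seg[:, :nb].mean(axis=1)
        ok = base > 0
        if not ok.all():
            n_base_bad += int((~ok).sum())
            valid[~ok, t] = False
        dff[ok, t] = (seg[ok] - base[ok, None]) / base[ok, None]
    if n_range_bad:
        warnings.warn(
            f"{n_range_bad} trial(s) fall outside the recording and were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_base_bad:
        warnings.warn(
            f"{n_base_bad} neuron-trial(s) had nonpositive baseline F and were excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return TrialTensor(
        dff=dff,
        time_s=rel / fr,
        frame_rate_hz=fr,
        frequencies_khz=protocol.frequencies_khz,
        trial_freq_idx=protocol.trial_freq_idx.copy(),
        baseline_window_s=float(baseline_window_s),
        post_window_s=float(post_window_s),
        tone_duration_s=float(protocol.tone_duration_s),
        valid=valid,
        neuron_ids=np.arange(n_neurons),
    )


def response_amplitude(tensor: TrialTensor, window_s: float = 1.0) -> np.ndarray:
    """Mean ΔF/F over the half-open window (onset, onset + window_s].

    Returns an (n_neurons, n_trials) array; invalid trials are NaN.
    """
    nw = _frames(window_s, tensor.frame_rate_hz)
    nb = _frames(tensor.baseline_window_s, tensor.frame_rate_hz)
    if nw < 1:
        raise ValueError("window shorter than one frame")
    onset_pos = nb  # index of relative frame 0
    win = tensor.dff[:, :, onset_pos + 1 : onset_pos + nw + 1]
    if win.shape[2] < nw:
        raise ValueError("response window exceeds the trial raster")
    return win.mean(axis=2)


def sigma_normalize(tensor: TrialTensor, window_s: float = 1.0) -> TrialTensor:
    """Normalize each neuron's ΔF/F by its response-amplitude SD (σ).

    σ_i is the sample SD (ddof=1) over trials of neuron i's ``window_s``
    post-onset mean amplitudes. Neurons with σ = 0 (or fewer than two valid
    trials) are flagged and excluded from the normalized output; retained
    original indices are carried in ``neuron_ids``.
    """
    if tensor.n_trials < 2:
        raise ValueError("sigma normalization needs at least two trials")
    amps = response_amplitude(tensor, window_s=window_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        sigma = np.nanstd(amps, axis=1, ddof=1)
    good = np.isfinite(sigma) & (sigma > 0)
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} neuron(s) with zero/undefined amplitude SD "
            "excluded from sigma-normalized output",
            RuntimeWarning,
            stacklevel=2,
        )
    ids = tensor.neuron_ids if tensor.neuron_ids is not None else np.arange(tensor.n_neurons)
    return TrialTensor(
        dff=tensor.dff[good] / sigma[good, None, None],
        time_s=tensor.time_s,
        frame_rate_hz=tensor.frame_rate_hz,
        frequencies_khz=tensor.frequencies_khz,
        trial_freq_idx=tensor.trial_freq_idx,
        baseline_window_s=tensor.baseline_window_s,
        post_window_s=tensor.post_window_s,
        tone_duration_s=tensor.tone_duration_s,
        valid=tensor.valid[good],
        sigma=sigma[good],
        normalized=True,
        neuron_ids=np.asarray(ids)[good],
    )
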