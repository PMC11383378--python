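"""Frequency tuning and pairwise noise correlations.

Tuning curves (FTCs) are mean 1-s response amplitudes per tone frequency;
Best Frequency (BF) is the FTC peak. Noise correlations — a functional
connectivity proxy — are Pearson correlations of stimulus-mean-subtracted
trial responses between neuron pairs, with residuals pooled over all tone
frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurveSet",
    "GroupedFtc",
    "NoiseCorrelationResult",
    "tuning_curve",
    "peak_normalize",
    "group_average_ftc",
    "off_bf_ratio",
    "noise_correlations",
]


@dataclass
class TuningCurveSet:
    """Per-neuron frequency tuning curves on a common frequency grid.

    ``mean_response`` is (n_neurons, n_frequencies); ``bf_idx``/``bf_khz``
    give each neuron's Best Frequency (argmax of the curve, ties broken to
    the lowest frequency).
    """

    frequencies_khz: np.ndarray
    mean_response: np.ndarray
    n_trials_per_freq: np.ndarray
    bf_idx: np.ndarray
    bf_khz: np.ndarray
    normalized: bool = False

    @property
    def n_neurons(self) -> int:
        return self.mean_response.shape[0]


@dataclass
class GroupedFtc:
    """BF-grouped averages of peak-normalized tuning curves."""

    frequencies_khz: np.ndarray
    bf_khz: np.ndarray            # one entry per nonempty BF group
    curves: np.ndarray            # (n_groups, n_frequencies) pointwise means
    sems: np.ndarray              # (n_groups, n_frequencies)
    counts: np.ndarray            # neurons per group


@dataclass
class NoiseCorrelationResult:
    """Pairwise noise-correlation matrix and its experiment-level mean.

    ``pair_matrix`` is symmetric with unit diagonal; pairs undefined because
    of a zero-variance residual vector are NaN and excluded from
    ``experiment_mean`` (the mean over distinct pairs).
    """

    pair_matrix: np.ndarray
    experiment_mean: float


def tuning_curve(
    amplitudes: np.ndarray,
    trial_freq_idx: np.ndarray,
    frequencies_khz: np.ndarray,
) -> TuningCurveSet:
    """Mean response amplitude per frequency, per neuron, and the BF.

    ``amplitudes`` is (n_neurons, n_trials) of 1-s response amplitudes (NaN
    for excluded trials); ``trial_freq_idx`` indexes ``frequencies_khz`` per
    trial. Every frequency must have at least one valid trial. Ties at the
    peak resolve to the lowest frequency.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    trial_freq_idx = np.asarray(trial_freq_idx)
    frequencies_khz = np.asarray(frequencies_khz, dtype=float)
    nf = frequencies_khz.size
    counts = np.bincount(trial_freq_idx, minlength=nf)
    if (counts == 0).any():
        missing = frequencies_khz[counts == 0]
        raise ValueError(f"no trials for frequencies {missing} kHz")

    mean = np.empty((amplitudes.shape[0], nf))
    for j in range(nf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[:, j] = np.nanmean(amplitudes[:, trial_freq_idx == j], axis=1)
    bf_idx = np.nanargmax(mean, axis=1)  # first max -> lowest frequency on ties
    return TuningCurveSet(
        frequencies_khz=frequencies_khz,
        mean_response=mean,
        n_trials_per_freq=counts,
        bf_idx=bf_idx,
        bf_khz=frequencies_khz[bf_idx],
    )


def peak_normalize(curves: TuningCurveSet) -> TuningCurveSet:
    """Scale each neuron's FTC so its peak equals 1.

    Neurons with a nonpositive peak are excluded with a warning.
    """
    peaks = curves.mean_response[np.arange(curves.n_neurons), curves.bf_idx]
    good = peaks > 0
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} neuron(s) with nonpositive FTC peak excluded "
            "from peak normalization",
            RuntimeWarning,
            stacklevel=2,
        )
    return TuningCurveSet(
        frequencies_khz=curves.frequencies_khz,
        mean_response=curves.mean_response[good] / peaks[good, None],
        n_trials_per_freq=curves.n_trials_per_freq,
        bf_idx=curves.bf_idx[good],
        bf_khz=curves.bf_khz[good],
        normalized=True,
    )


def group_average_ftc(curves: TuningCurveSet) -> GroupedFtc:
    """Average peak-normalized FTCs within each BF group.

    Returns one pointwise-mean curve (with per-frequency SEM) per nonempty BF
    group; with the canonical 10-frequency protocol this yields up to 10
    curves per condition. Empty groups are simply absent.
    """
    groups = []
    for j in range(curves.frequencies_khz.size):
        members = curves.mean_response[curves.bf_idx == j]
        if members.shape[0] == 0:
            continue
        n = members.shape[0]
        sem = (
            members.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(members.shape[1])
        )
        groups.append((j, members.mean(axis=0), sem, n))
    if not groups:
        raise ValueError("no tuning curves to group")
    js, means, sems, ns = zip(*groups)
    return GroupedFtc(
        frequencies_khz=curves.frequencies_khz,
        bf_khz=curves.frequencies_khz[list(js)],
        curves=np.vstack(means),
        sems=np.vstack(sems),
        counts=np.asarray(ns),
    )


def off_bf_ratio(curves: TuningCurveSet) -> np.ndarray:
    """Mean off-BF response as a percentage of the at-BF response, per neuron.

    Neurons whose BF response is nonpositive are returned as NaN with a
    warning. A flat FTC gives 100%; a response only at BF gives 0%.
    """
    n, nf = curves.mean_response.shape
    at_bf = curves.mean_response[np.arange(n), curves.bf_idx]
    off_mask = np.ones((n, nf), dtype=bool)
    off_mask[np.arange(n), curves.bf_idx] = False
    off_mean = np.where(off_mask, curves.mean_response, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        off_mean = np.nanmean(off_mean, axis=1)
    out = np.full(n, np.nan)
    good = at_bf > 0
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} neuron(s) with nonpositive BF response excluded "
            "from off-BF ratio",
            RuntimeWarning,
            stacklevel=2,
        )
    out[good] = 100.0 * off_mean[good] / at_bf[good]
    return out


def noise_correlations(
    amplitudes: np.ndarray, trial_freq_idx: np.ndarray
) -> NoiseCorrelationResult:
    """Pairwise Pearson correlations of stimulus-mean-subtracted responses.

    Per neuron, the mean response to each frequency is subtracted from that
    frequency's trials; residuals are pooled over all trials and correlated
    per neuron pair. Requires at least two neurons and two trials per
    frequency. Neurons with zero residual variance yield undefined (NaN)
    pairs, excluded from ``experiment_mean`` with a warning.
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    trial_freq_idx = np.asarray(trial_freq_idx)
    n, n_trials = amplitudes.shape
    if n < 2:
        raise ValueError("noise correlations need at least two neurons")
    nf = int(trial_freq_idx.max()) + 1
    counts = np.bincount(trial_freq_idx, minlength=nf)
    if (counts[np.unique(trial_freq_idx)] < 2).any():
        raise ValueError("every frequency needs at least two trials")

    resid = amplitudes.copy()
    for j in np.unique(trial_freq_idx):
        sel = trial_freq_idx == j
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            resid[:, sel] -= np.nanmean(amplitudes[:, sel], axis=1, keepdims=True)

    # pairwise Pearson on pooled residuals, tolerating NaN trials
    finite = np.isfinite(resid)
    use = finite.all(axis=0)  # pool only trials valid for every neuron
    r = resid[:, use]
    sd = r.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} neuron(s) with zero residual variance: "
            "their pairs are undefined and excluded from the experiment mean",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(r)
    mat[degenerate, :] = np.nan
    mat[:, degenerate] = np.nan
    np.fill_diagonal(mat, np.where(degenerate, np.nan, 1.0))
    iu = np.triu_indices(n, k=1)
    upper = mat[iu]
    mean = float(np.nanmean(upper)) if np.isfinite(upper).any() else float("nan")
    return NoiseCorrelationResult(pair_matrix=mat, experiment_mean=mean)
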