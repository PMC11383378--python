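"""Pure-tone stimulus protocols.

A protocol is a geometric ladder of pure-tone frequencies together with a
randomized trial schedule: each frequency is repeated a fixed number of times,
trials are shuffled, and successive tone onsets are separated by the tone
duration plus a randomly drawn inter-stimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ToneProtocol", "make_tone_protocol"]


@dataclass(frozen=True)
class ToneProtocol:
    """A pure-tone presentation schedule.

    Attributes
    ----------
    frequencies_khz
        Strictly ascending geometric series of tone frequencies (kHz).
    repeats_per_freq
        Number of presentations of each frequency.
    isi_choices_s
        Candidate silent inter-stimulus intervals (s); each inter-onset gap
        equals ``tone_duration_s`` plus one of these.
    tone_duration_s
        Tone duration in seconds.
    level_db_spl
        Presentation level (dB SPL); metadata only.
    trial_freq_idx
        Per-trial index into ``frequencies_khz``.
    trial_onset_s
        Per-trial tone-onset time in seconds, strictly increasing.
    """

    frequencies_khz: np.ndarray
    repeats_per_freq: int
    isi_choices_s: tuple[float, ...]
    tone_duration_s: float
    level_db_spl: float
    trial_freq_idx: np.ndarray
    trial_onset_s: np.ndarray
    seed: int | None = field(default=None, compare=False)

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies_khz)

    @property
    def n_trials(self) -> int:
        return len(self.trial_freq_idx)

    @property
    def trial_frequencies_khz(self) -> np.ndarray:
        """Frequency (kHz) presented on each trial."""
        return self.frequencies_khz[self.trial_freq_idx]

    @property
    def duration_s(self) -> float:
        """Time from the session start to the end of the last analysis-relevant
        window (last onset + tone + a generous 5 s tail)."""
        return float(self.trial_onset_s[-1] + self.tone_duration_s + 5.0)

    def to_frame(self) -> pd.DataFrame:
        """Trial schedule as a table (trial, frequency_khz, onset_s)."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "frequency_khz": self.trial_frequencies_khz,
                "onset_s": self.trial_onset_s,
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        tone_duration_s: float = 0.5,
        level_db_spl: float = 70.0,
    ) -> "ToneProtocol":
        """Rebuild a protocol from a trial-schedule table.

        The frequency set is the sorted unique set of presented frequencies;
        ISI choices are inferred from the inter-onset gaps.
        """
        freqs = np.sort(frame["frequency_khz"].unique())
        onsets = np.asarray(frame["onset_s"], dtype=float)
        order = np.argsort(onsets)
        onsets = onsets[order]
        idx = np.searchsorted(freqs, np.asarray(frame["frequency_khz"])[order])
        counts = np.bincount(idx, minlength=len(freqs))
        gaps = np.diff(onsets) - tone_duration_s
        isi = tuple(sorted(set(np.round(gaps, 6)))) if len(gaps) else (0.0,)
        return cls(
            frequencies_khz=freqs,
            repeats_per_freq=int(counts.max()) if len(counts) else 0,
            isi_choices_s=isi,
            tone_duration_s=float(tone_duration_s),
            level_db_spl=float(level_db_spl),
            trial_freq_idx=idx,
            trial_onset_s=onsets,
        )


def make_tone_protocol(
    f_lo_khz: float,
    f_hi_khz: float,
    tones_per_octave: int = 2,
    repeats: int = 20,
    isi_choices_s: tuple[float, ...] = (6.0, 7.0, 8.0),
    tone_duration_s: float = 0.5,
    level_db_spl: float = 70.0,
    seed: int | None = None,
    start_s: float = 3.0,
    endpoint_tol: float = 0.01,
) -> ToneProtocol:
    """Build a randomized pure-tone protocol on a geometric frequency ladder.

    Frequencies are ``f_lo * 2**(k / tones_per_octave)`` for k = 0, 1, ...
    while the value does not exceed ``f_hi * (1 + endpoint_tol)``; the 1%
    default tolerance admits the conventional rounded upper endpoint (e.g.
    45.25 kHz for a nominal 2-45 kHz range at 2 tones/octave). Each frequency
    appears exactly ``repeats`` times in a seeded random order, with
    inter-onset gaps of ``tone_duration_s`` plus a seeded draw from
    ``isi_choices_s``.

    Parameters
    ----------
    start_s
        Onset time of the first tone, leaving a silent pre-stimulus baseline.
    """
    if f_lo_khz <= 0:
        raise ValueError("f_lo_khz must be positive")
    if f_lo_khz > f_hi_khz:
        raise ValueError("f_lo_khz must not exceed f_hi_khz")
    if tones_per_octave < 1:
        raise ValueError("tones_per_octave must be >= 1")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not isi_choices_s:
        raise ValueError("isi_choices_s must be nonempty")

    n_oct = np.log2(f_hi_khz * (1.0 + endpoint_tol) / f_lo_khz)
    k_max = int(np.floor(n_oct * tones_per_octave + 1e-12))
    k = np.arange(k_max + 1)
    freqs = f_lo_khz * 2.0 ** (k / tones_per_octave)
    if freqs.size == 0:
        raise ValueError("empty frequency set")

    rng = np.random.default_rng(seed)
    idx = rng.permutation(np.repeat(np.arange(freqs.size), repeats))
    gaps = tone_duration_s + rng.choice(np.asarray(isi_choices_s, float), size=idx.size)
    onsets = start_s + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return ToneProtocol(
        frequencies_khz=freqs,
        repeats_per_freq=repeats,
        isi_choices_s=tuple(float(x) for x in isi_choices_s),
        tone_duration_s=float(tone_duration_s),
        level_db_spl=float(level_db_spl),
        trial_freq_idx=idx,
        trial_onset_s=onsets,
        seed=seed,
    )
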