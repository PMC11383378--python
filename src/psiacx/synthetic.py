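"""Synthetic ground-truth data for every pipeline stage.

Three generators:

* :func:`simulate_experiment` — tone-evoked GCaMP6s-like somatic traces with
  log-frequency Gaussian tuning, per-condition response gain, a shared-latent
  trial noise giving a controllable pairwise noise correlation ρ, and neuropil
  contamination at a known coefficient.
* :func:`simulate_widefield` — widefield movies with a spatial tonotopic
  gradient along one axis, optionally under a smooth multiplicative
  illumination field.
* :func:`simulate_behavior_video` — an arena video of a moving Gaussian blob
  whose programmed speed follows a control or hypoactive profile, with brief
  head-twitch micro-events.

Each generator records the ground truth needed to predict the pipeline's
output analytically, and is bit-reproducible from its seed.

The shared-latent noise model: the trial-to-trial residual of neuron i is
ε_i = sd · (√ρ·z + √(1−ρ)·η_i) with z shared across neurons and η_i private,
both unit normal per trial, so every neuron pair has noise correlation ρ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import ToneProtocol

__all__ = [
    "SynthNeuralConfig",
    "SyntheticSession",
    "SyntheticExperiment",
    "WidefieldMovie",
    "SyntheticBehaviorVideo",
    "gcamp_kernel",
    "simulate_experiment",
    "render_session_movie",
    "simulate_widefield",
    "simulate_behavior_video",
    "decaying_htr_rate",
    "constant_htr_rate",
]

#: GCaMP6s-like double-exponential kernel timescales (s). The slow indicator
#: decay sustains responses through the 1-s post-onset analysis window.
GCAMP_RISE_S = 0.18
GCAMP_DECAY_S = 1.5

#: Default condition labels of the three imaging sessions.
CONDITIONS = ("Pre", "Post1", "Post2")


def gcamp_kernel(
    frame_rate_hz: float,
    rise_s: float = GCAMP_RISE_S,
    decay_s: float = GCAMP_DECAY_S,
    duration_s: float = 8.0,
) -> np.ndarray:
    """Peak-normalized causal double-exponential calcium-transient kernel."""
    t = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


@dataclass
class SynthNeuralConfig:
    """Ground-truth parameters of a synthetic 2P imaging experiment.

    Attributes
    ----------
    n_neurons, frame_rate_hz
        Population size and imaging rate.
    bf_khz
        Per-neuron Best Frequency (kHz); if None, drawn uniformly from the
        protocol's frequency grid (so BF recovery is exact at zero noise).
    tuning_width_oct
        SD of the log2-frequency Gaussian tuning curve, in octaves.
    base_amplitude
        Evoked ΔF/F at BF per neuron (scalar or per-neuron array).
    condition_gain
        Multiplicative response gain per condition, e.g. ``{"Pre": 1.0,
        "Post1": 1.4, "Post2": 0.8}`` (a 3-tuple is accepted).
    shared_noise_rho
        Target pairwise noise correlation in [0, 1); scalar or per-condition
        mapping.
    trial_noise_sd
        SD of the trial-to-trial evoked-amplitude residual.
    neuropil_coeff
        Contamination coefficient: raw soma = true soma + coeff · neuropil.
    baseline_fluorescence
        Strictly positive baseline offset (arbitrary units) keeping ΔF/F
        well-defined.
    """

    n_neurons: int = 50
    frame_rate_hz: float = 30.0
    bf_khz: np.ndarray | None = None
    tuning_width_oct: float = 0.8
    base_amplitude: float | np.ndarray = 0.5
    condition_gain: dict[str, float] | tuple[float, ...] = (1.0,)
    shared_noise_rho: float | dict[str, float] = 0.0
    trial_noise_sd: float = 0.15
    neuropil_coeff: float = 0.7
    baseline_fluorescence: float = 1.0
    seed: int | None = None

    def gains(self) -> dict[str, float]:
        if isinstance(self.condition_gain, dict):
            g = dict(self.condition_gain)
        else:
            g = {CONDITIONS[i]: float(v) for i, v in enumerate(self.condition_gain)}
        if any(v <= 0 for v in g.values()):
            raise ValueError("condition gains must be positive")
        return g

    def rho(self, condition: str) -> float:
        r = (
            self.shared_noise_rho[condition]
            if isinstance(self.shared_noise_rho, dict)
            else self.shared_noise_rho
        )
        if not (0.0 <= r < 1.0):
            raise ValueError("shared_noise_rho must lie in [0, 1)")
        return float(r)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.baseline_fluorescence <= 0:
            raise ValueError("baseline_fluorescence must be positive")
        self.gains()


@dataclass
class SyntheticSession:
    """One imaging session (one condition) of a synthetic experiment."""

    condition: str
    raw_somatic: np.ndarray       # (n_neurons, n_frames) contaminated traces
    neuropil: np.ndarray          # (n_neurons, n_frames)
    true_somatic: np.ndarray      # (n_neurons, n_frames) uncontaminated truth
    evoked_amplitudes: np.ndarray  # (n_neurons, n_trials) ground-truth amplitudes
    protocol: ToneProtocol


@dataclass
class SyntheticExperiment:
    """Sessions plus the ground truth sufficient to predict their statistics."""

    sessions: dict[str, SyntheticSession]
    truth: SynthNeuralConfig
    bf_khz: np.ndarray
    base_amplitude: np.ndarray
    protocol: ToneProtocol


def _tuning_gain(bf_khz: np.ndarray, freq_khz: np.ndarray, width_oct: float) -> np.ndarray:
    """Gaussian tuning in octave distance: (n_neurons, n_freqs)."""
    d = np.log2(freq_khz)[None, :] - np.log2(bf_khz)[:, None]
    return np.exp(-(d**2) / (2.0 * width_oct**2))


def _traces_from_amplitudes(
    amplitudes: np.ndarray,
    protocol: ToneProtocol,
    frame_rate_hz: float,
    baseline: float,
) -> np.ndarray:
    """Convolve per-trial evoked amplitudes with the calcium kernel."""
    n_frames = int(round(protocol.duration_s * frame_rate_hz))
    onset_f = np.floor(protocol.trial_onset_s * frame_rate_hz + 0.5).astype(int)
    impulses = np.zeros((amplitudes.shape[0], n_frames))
    np.add.at(impulses, (slice(None), onset_f), amplitudes)
    kernel = gcamp_kernel(frame_rate_hz)
    from scipy.signal import fftconvolve

    conv = fftconvolve(impulses, kernel[None, :], axes=1)[:, :n_frames]
    return baseline + conv


def simulate_experiment(
    config: SynthNeuralConfig,
    protocol: ToneProtocol,
    conditions: tuple[str, ...] | None = None,
) -> SyntheticExperiment:
    """Simulate raw somatic + neuropil traces for each condition.

    Per trial t at frequency f, neuron i's evoked amplitude is

        gain_c · base_i · exp(−(log2 f − log2 BF_i)² / (2 w²)) + ε_it,

    with ε the shared-latent residual described in the module docstring.
    The true somatic trace is the baseline plus the kernel-convolved
    amplitude train; the raw trace adds ``neuropil_coeff`` times a neuropil
    trace (slow positive background with its own fluctuations), so neuropil
    correction at the true coefficient recovers the truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    gains = config.gains()
    if conditions is None:
        conditions = tuple(gains)
    nf = protocol.n_frequencies
    if config.bf_khz is None:
        bf = protocol.frequencies_khz[rng.integers(0, nf, size=config.n_neurons)]
    else:
        bf = np.broadcast_to(np.asarray(config.bf_khz, float), (config.n_neurons,)).copy()
    base = np.broadcast_to(
        np.asarray(config.base_amplitude, float), (config.n_neurons,)
    ).copy()

    tuning = _tuning_gain(bf, protocol.frequencies_khz, config.tuning_width_oct)
    fr = config.frame_rate_hz
    n_frames = int(round(protocol.duration_s * fr))

    sessions: dict[str, SyntheticSession] = {}
    for cond in conditions:
        g = gains[cond]
        rho = config.rho(cond)
        signal = g * base[:, None] * tuning[:, protocol.trial_freq_idx]
        z = rng.standard_normal(protocol.n_trials)
        eta = rng.standard_normal((config.n_neurons, protocol.n_trials))
        eps = config.trial_noise_sd * (np.sqrt(rho) * z[None, :] + np.sqrt(1 - rho) * eta)
        amplitudes = signal + eps
        true = _traces_from_amplitudes(
            amplitudes, protocol, fr, config.baseline_fluorescence
        )
        # neuropil: slow positive background with smooth fluctuations plus a
        # weak copy of the bulk evoked signal
        bulk = (true.mean(axis=0) - config.baseline_fluorescence)[None, :]
        slow = rng.standard_normal((config.n_neurons, n_frames))
        from scipy.ndimage import gaussian_filter1d

        slow = gaussian_filter1d(slow, sigma=fr * 0.5, axis=1) * 0.05
        neuropil = 0.5 * config.baseline_fluorescence + 0.3 * bulk + slow
        raw = true + config.neuropil_coeff * neuropil
        sessions[cond] = SyntheticSession(
            condition=cond,
            raw_somatic=raw,
            neuropil=neuropil,
            true_somatic=true,
            evoked_amplitudes=amplitudes,
            protocol=protocol,
        )
    return SyntheticExperiment(
        sessions=sessions,
        truth=config,
        bf_khz=bf,
        base_amplitude=base,
        protocol=protocol,
    )


def render_session_movie(
    session: SyntheticSession,
    masks,
    background: float = 0.2,
) -> np.ndarray:
    """Paint a session's traces into a registered movie.

    Each neuron's somatic pixels carry its raw (contaminated) trace and its
    neuropil-ring pixels carry its neuropil trace, so pixel-mean extraction
    recovers both exactly. Returns an (n_frames, H, W) float32 stack.
    """
    n_frames = session.raw_somatic.shape[1]
    movie = np.full((n_frames,) + masks.image_shape, background, dtype=np.float64)
    for i in range(masks.n_neurons):
        nrows, ncols = masks.neuropil[i]
        movie[:, nrows, ncols] = session.neuropil[i][:, None]
    for i in range(masks.n_neurons):
        srows, scols = masks.somatic[i]
        movie[:, srows, scols] = session.raw_somatic[i][:, None]
    return movie


# ---------------------------------------------------------------------------
# Widefield
# ---------------------------------------------------------------------------


@dataclass
class WidefieldMovie:
    """Widefield stack with ground-truth pixel Best Frequencies."""

    frames: np.ndarray            # (n_frames, H, W)
    frame_rate_hz: float
    bf_map_true: np.ndarray       # (H, W) kHz
    protocol: ToneProtocol
    illumination: np.ndarray | None = None


def simulate_widefield(
    protocol: ToneProtocol,
    shape: tuple[int, int] = (48, 48),
    gradient_axis: int = 1,
    tuning_width_oct: float = 0.5,
    amplitude: float = 0.5,
    baseline: float = 1.0,
    noise_sd: float = 0.05,
    illumination: np.ndarray | None = None,
    frame_rate_hz: float = 5.0,
    quantize_bf: bool = True,
    seed: int | None = None,
) -> WidefieldMovie:
    """Widefield movie with a monotone tonotopic gradient along one axis.

    Pixel BFs ramp linearly in log2 frequency across ``gradient_axis`` over
    the protocol's frequency range; with ``quantize_bf`` (default) each
    pixel's BF snaps to the nearest stimulus frequency, so in the noiseless
    limit the analysis recovers the truth exactly. Each pixel's response to a
    tone is a log-frequency Gaussian around its BF, convolved with the
    calcium kernel. ``illumination`` is an optional (H, W) multiplicative
    field applied to every frame (exercises the homomorphic filter).
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    lo, hi = np.log2(protocol.frequencies_khz[0]), np.log2(protocol.frequencies_khz[-1])
    ramp = np.linspace(lo, hi, shape[gradient_axis])
    log_bf = np.broadcast_to(
        ramp[None, :] if gradient_axis == 1 else ramp[:, None], (H, W)
    ).copy()
    if quantize_bf:
        grid = np.log2(protocol.frequencies_khz)
        log_bf = grid[np.abs(log_bf.ravel()[:, None] - grid[None, :]).argmin(axis=1)]
        log_bf = log_bf.reshape(H, W)
    bf_map = 2.0**log_bf

    # per-frequency amplitude map (H, W) and per-frequency time course
    d = np.log2(protocol.frequencies_khz)[:, None, None] - log_bf[None, :, :]
    amp_maps = amplitude * np.exp(-(d**2) / (2.0 * tuning_width_oct**2))

    n_frames = int(round(protocol.duration_s * frame_rate_hz))
    onset_f = np.floor(protocol.trial_onset_s * frame_rate_hz + 0.5).astype(int)
    kernel = gcamp_kernel(frame_rate_hz)
    from scipy.signal import fftconvolve

    frames = np.full((n_frames, H, W), baseline, dtype=np.float64)
    for j in range(protocol.n_frequencies):
        imp = np.zeros(n_frames)
        np.add.at(imp, onset_f[protocol.trial_freq_idx == j], 1.0)
        tc = fftconvolve(imp, kernel)[:n_frames]
        frames += tc[:, None, None] * amp_maps[j][None, :, :]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    if illumination is not None:
        illumination = np.asarray(illumination, dtype=float)
        if illumination.shape != (H, W):
            raise ValueError("illumination field must match the frame shape")
        frames *= illumination[None, :, :]
    return WidefieldMovie(
        frames=frames,
        frame_rate_hz=float(frame_rate_hz),
        bf_map_true=bf_map,
        protocol=protocol,
        illumination=illumination,
    )


# ---------------------------------------------------------------------------
# Behavior video
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBehaviorVideo:
    """Arena video of a moving blob with programmed speed and head-twitches."""

    frames: np.ndarray            # (n_frames, H, W) grayscale, nonnegative
    fps: float
    truth_speed: np.ndarray       # programmed blob speed per frame (px/s)
    htr_times_s: np.ndarray
    switch_time_s: float | None


def decaying_htr_rate(peak_per_min: float = 3.0, t_end_s: float = 600.0):
    """Head-twitch rate (events/s) decaying linearly from its peak to 0 at
    ``t_end_s`` — the psilocybin-like profile."""

    def rate(t: float) -> float:
        return max(0.0, peak_per_min / 60.0 * (1.0 - t / t_end_s))

    return rate


def constant_htr_rate(per_min: float = 0.2):
    """Constant low head-twitch rate — the saline-like profile."""

    def rate(t: float) -> float:
        return per_min / 60.0

    return rate


def simulate_behavior_video(
    duration_s: float,
    fps: float = 30.0,
    shape: tuple[int, int] = (64, 64),
    profile: str = "control",
    switch_time_s: float | None = None,
    base_speed_px_s: float = 30.0,
    hypo_speed_px_s: float = 4.0,
    bursty: bool = True,
    bout_mean_s: float = 4.0,
    pause_mean_s: float = 2.0,
    hypo_pause_mean_s: float = 20.0,
    htr_rate=None,
    blob_sigma_px: float = 2.5,
    blob_amplitude: float = 1.0,
    background: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SyntheticBehaviorVideo:
    """Render a Gaussian blob roaming an arena at a programmed speed.

    ``profile`` is ``"control"`` (a stationary movement regime) or
    ``"hypoactive"`` (base regime before ``switch_time_s``, a slow sparse
    regime after). With ``bursty`` (default), motion alternates between
    movement bouts at the regime speed and pauses, with exponential sojourn
    times — the bout structure real rodent exploration shows and the
    envelope analysis expects; ``bursty=False`` gives continuous motion at
    the programmed speed. Head-twitch events, drawn from the optional
    ``htr_rate`` (events/s as a function of time), appear as ≤0.2 s bursts
    of high-amplitude positional jitter. The programmed per-frame speed and
    the event times are returned as ground truth.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    if profile not in ("control", "hypoactive"):
        raise ValueError("profile must be 'control' or 'hypoactive'")
    if profile == "hypoactive" and switch_time_s is None:
        raise ValueError("hypoactive profile needs switch_time_s")
    rng = np.random.default_rng(seed)
    H, W = shape
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps

    hypo = np.zeros(n_frames, dtype=bool)
    if profile == "hypoactive":
        hypo = t > switch_time_s
    speed = np.where(hypo, float(hypo_speed_px_s), float(base_speed_px_s))
    if bursty:
        gate = np.empty(n_frames, dtype=bool)
        moving = True
        p_stop = 1.0 / (bout_mean_s * fps)
        for f in range(n_frames):
            pause = hypo_pause_mean_s if hypo[f] else pause_mean_s
            p_start = 1.0 / (pause * fps)
            if moving:
                moving = rng.random() >= p_stop
            else:
                moving = rng.random() < p_start
            gate[f] = moving
        speed = speed * gate

    # head-twitch event times by thinning an inhomogeneous Poisson process
    htr_times = []
    if htr_rate is not None:
        rmax = max(htr_rate(x) for x in np.linspace(0, duration_s, 512)) + 1e-12
        tt = 0.0
        while True:
            tt += rng.exponential(1.0 / rmax)
            if tt >= duration_s:
                break
            if rng.random() < htr_rate(tt) / rmax:
                htr_times.append(tt)
    htr_times = np.asarray(htr_times)
    htr_frames = np.zeros(n_frames, dtype=bool)
    burst = max(1, int(round(0.2 * fps)))  # <= 0.2 s per event
    for et in htr_times:
        f0 = int(et * fps)
        htr_frames[f0 : f0 + burst] = True

    # random-walk heading, reflective walls
    margin = 3.0 * blob_sigma_px
    pos = np.empty((n_frames, 2))
    pos[0] = (H / 2.0, W / 2.0)
    heading = rng.uniform(0, 2 * np.pi)
    dtheta = rng.normal(0.0, 0.4, size=n_frames)
    step = speed / fps
    for f in range(1, n_frames):
        heading += dtheta[f]
        p = pos[f - 1] + step[f] * np.array([np.sin(heading), np.cos(heading)])
        for ax, lim in enumerate((H, W)):
            if p[ax] < margin:
                p[ax] = 2 * margin - p[ax]
                heading += np.pi / 2
            elif p[ax] > lim - 1 - margin:
                p[ax] = 2 * (lim - 1 - margin) - p[ax]
                heading += np.pi / 2
        pos[f] = p

    # head-twitch jitter: fast alternating offset around the body position
    jitter = np.zeros((n_frames, 2))
    amp = 4.0 * blob_sigma_px
    signs = np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)
    jitter[htr_frames, 0] = amp * signs[htr_frames]
    render_pos = np.clip(pos + jitter, 0, [[H - 1, W - 1]])

    yy = np.arange(H)[None, :, None]
    xx = np.arange(W)[None, None, :]
    frames = background + blob_amplitude * np.exp(
        -(
            (yy - render_pos[:, 0, None, None]) ** 2
            + (xx - render_pos[:, 1, None, None]) ** 2
        )
        / (2.0 * blob_sigma_px**2)
    )
    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, noise_sd, frames.shape), 0, None)
    return SyntheticBehaviorVideo(
        frames=frames.astype(np.float32),
        fps=float(fps),
        truth_speed=speed,
        htr_times_s=htr_times,
        switch_time_s=switch_time_s if profile == "hypoactive" else None,
    )
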