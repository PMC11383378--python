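"""End-to-end study orchestration.

A study mirrors the three-session design — a preinjection session (Pre) and
two postinjection sessions (Post1, ~5–8 min; Post2, ~34–43 min) — for a
treatment and a control group. For synthetic studies every input is
generated with known ground truth; the imaging arm runs trace extraction →
ΔF/F → σ-normalized 1-s amplitudes → tuning → noise correlations, the
behavior arm runs frame differencing → movement envelope → windowed means →
HTR-template correlation, and all condition pairs are compared with the
pooled bootstrap mean test.

Statistical units follow the study's conventions: response amplitudes and
off-BF ratios pool neurons across experiments within a condition; noise
correlations contribute one experiment-average per experiment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import behavior as bhv
from . import fluorescence as fl
from . import population as pop
from .bootstrap import bootstrap_mean_test
from .protocol import make_tone_protocol
from .synthetic import (
    SynthNeuralConfig,
    constant_htr_rate,
    decaying_htr_rate,
    simulate_behavior_video,
    simulate_experiment,
)

__all__ = ["GroupSpec", "StudyConfig", "ComparisonReport", "run_study"]

CONDITION_PAIRS = (("Pre", "Post1"), ("Post1", "Post2"), ("Pre", "Post2"))


@dataclass
class GroupSpec:
    """Design of one treatment arm of the reference synthetic study.

    The treatment defaults (gain 1 → 1.4 → 0.8; noise correlation
    0.10 → 0.10 → 0.25) encode the qualitative biphasic pattern the pipeline
    is meant to detect — an early response-gain increase, a late decrease,
    and a late rise in functional connectivity; they are calibration choices
    of the synthetic study, not measured values.
    """

    n_experiments: int = 6
    n_neurons: int = 60
    condition_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_corr_rho: tuple[float, float, float] = (0.1, 0.1, 0.1)
    behavior_profile: str = "control"  # "control" | "hypoactive"
    n_mice: int = 5


@dataclass
class StudyConfig:
    """Parameters of a full synthetic study."""

    seed: int = 0
    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: {
            "treatment": GroupSpec(
                condition_gain=(1.0, 1.4, 0.8),
                noise_corr_rho=(0.10, 0.10, 0.25),
                behavior_profile="hypoactive",
            ),
            "control": GroupSpec(),
        }
    )
    conditions: tuple[str, str, str] = ("Pre", "Post1", "Post2")
    # stimulus protocol
    f_lo_khz: float = 2.0
    f_hi_khz: float = 45.0
    tones_per_octave: int = 2
    repeats: int = 20
    isi_choices_s: tuple[float, ...] = (6.0, 7.0, 8.0)
    tone_duration_s: float = 0.5
    # generator / analysis
    frame_rate_hz: float = 30.0
    base_amplitude: float = 0.5
    tuning_width_oct: float = 0.8
    trial_noise_sd: float = 0.15
    neuropil_coeff: float = 0.7
    baseline_window_s: float = 2.0
    post_window_s: float = 3.0
    amplitude_window_s: float = 1.0
    n_boot: int = 10_000
    # behavior arm (scaled-down session: 20 min at 10 fps, 32 px arena)
    include_behavior: bool = True
    behavior_duration_s: float = 1200.0
    behavior_fps: float = 10.0
    behavior_shape: tuple[int, int] = (32, 32)
    behavior_switch_s: float = 600.0
    behavior_windows_min: tuple[tuple[float, float], ...] = ((0.0, 10.0), (10.0, 60.0))
    htr_bin_s: float = 60.0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(open(path)) or {}
        groups = {
            name: GroupSpec(**{**spec, **{
                k: tuple(v) for k, v in spec.items() if isinstance(v, list)
            }})
            for name, spec in raw.pop("groups", {}).items()
        }
        tupled = {
            k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
            if isinstance(v, list)
            else v
            for k, v in raw.items()
        }
        cfg = cls(**tupled)
        if groups:
            cfg.groups = groups
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    """All descriptive statistics and bootstrap comparisons of a study run."""

    config: dict
    descriptives: dict  # group -> condition -> {measure: {mean, sem, n}}
    tests: list[dict]   # each: group(s), measure, pair, delta_mu, p, sig, n, m, seed
    behavior: dict      # group -> per-mouse window means and template correlations

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "descriptives": self.descriptives,
            "tests": self.tests,
            "behavior": self.behavior,
        }

    def test(self, measure: str, group: str, pair: tuple[str, str]) -> dict:
        for t in self.tests:
            if (
                t["measure"] == measure
                and t["group"] == group
                and tuple(t["pair"]) == tuple(pair)
            ):
                return t
        raise KeyError((measure, group, pair))


def _mean_sem(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    sem = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {"mean": float(x.mean()) if n else float("nan"), "sem": sem, "n": int(n)}


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _imaging_arm(config: StudyConfig, spec: GroupSpec, group_ss: np.random.SeedSequence):
    """Simulate and analyze every imaging session of one group."""
    amp: dict[str, list] = {c: [] for c in config.conditions}
    offbf: dict[str, list] = {c: [] for c in config.conditions}
    nc: dict[str, list] = {c: [] for c in config.conditions}
    for exp_ss in group_ss.spawn(spec.n_experiments):
        proto_ss, sim_ss = exp_ss.spawn(2)
        neural = SynthNeuralConfig(
            n_neurons=spec.n_neurons,
            frame_rate_hz=config.frame_rate_hz,
            base_amplitude=config.base_amplitude,
            tuning_width_oct=config.tuning_width_oct,
            condition_gain=dict(zip(config.conditions, spec.condition_gain)),
            shared_noise_rho=dict(zip(config.conditions, spec.noise_corr_rho)),
            trial_noise_sd=config.trial_noise_sd,
            neuropil_coeff=config.neuropil_coeff,
            seed=_child_seed(sim_ss),
        )
        protocol = make_tone_protocol(
            config.f_lo_khz,
            config.f_hi_khz,
            config.tones_per_octave,
            repeats=config.repeats,
            isi_choices_s=config.isi_choices_s,
            tone_duration_s=config.tone_duration_s,
            seed=_child_seed(proto_ss),
        )
        experiment = simulate_experiment(neural, protocol)
        for cond, session in experiment.sessions.items():
            traces = fl.CellTraces(
                C_raw=session.raw_somatic,
                N=session.neuropil,
                frame_rate_hz=config.frame_rate_hz,
            ).corrected(config.neuropil_coeff)
            traces = traces.subset(fl.qc_filter_cells(traces))
            tensor = fl.compute_dff(
                traces,
                protocol,
                baseline_window_s=config.baseline_window_s,
                post_window_s=config.post_window_s,
            )
            tensor = fl.sigma_normalize(tensor, window_s=config.amplitude_window_s)
            amps = fl.response_amplitude(tensor, window_s=config.amplitude_window_s)
            amp[cond].append(np.nanmean(amps, axis=1))
            curves = pop.tuning_curve(
                amps, protocol.trial_freq_idx, protocol.frequencies_khz
            )
            offbf[cond].append(pop.off_bf_ratio(curves))
            nc[cond].append(
                pop.noise_correlations(amps, protocol.trial_freq_idx).experiment_mean
            )
    return (
        {c: np.concatenate(v) for c, v in amp.items()},
        {c: np.concatenate(v) for c, v in offbf.items()},
        {c: np.asarray(v) for c, v in nc.items()},
    )


def _behavior_arm(config: StudyConfig, ss: np.random.SeedSequence):
    """Simulate and analyze every behavior session, per group."""
    videos: dict[str, list] = {}
    traces: dict[str, list] = {}
    children = ss.spawn(len(config.groups))
    for g_idx, (name, spec) in enumerate(sorted(config.groups.items())):
        group_ss = children[g_idx]
        videos[name] = []
        traces[name] = []
        hypo = spec.behavior_profile == "hypoactive"
        rate = (
            decaying_htr_rate(t_end_s=config.behavior_switch_s)
            if hypo
            else constant_htr_rate()
        )
        for mouse_ss in group_ss.spawn(spec.n_mice):
            video = simulate_behavior_video(
                duration_s=config.behavior_duration_s,
                fps=config.behavior_fps,
                shape=config.behavior_shape,
                profile="hypoactive" if hypo else "control",
                switch_time_s=config.behavior_switch_s if hypo else None,
                htr_rate=rate,
                seed=_child_seed(mouse_ss),
            )
            videos[name].append(video)
            traces[name].append(bhv.movement_trace(video.frames, config.behavior_fps))
    return videos, traces


def run_study(config: StudyConfig | None = None) -> ComparisonReport:
    """Execute the full study and return every comparison.

    Deterministic: one top-level seed fans out (via ``SeedSequence.spawn``)
    to the protocol shuffles, the neural and behavior generators, and every
    bootstrap test; identical configs yield byte-identical reports.
    """
    config = config or StudyConfig()
    root = np.random.SeedSequence(config.seed)
    imaging_ss, behavior_ss, tests_ss = root.spawn(3)

    descriptives: dict = {}
    tests: list[dict] = []
    test_seeds = iter(tests_ss.spawn(256))

    def run_test(measure, group, pair, a, b):
        res = bootstrap_mean_test(
            a, b, n_boot=config.n_boot, seed=_child_seed(next(test_seeds))
        )
        tests.append(
            {
                "measure": measure,
                "group": group,
                "pair": list(pair),
                "delta_mu": res.delta_mu,
                "p_value": res.p_value,
                "sig_level": res.sig_level,
                "n": res.n,
                "m": res.m,
                "n_boot": res.n_boot,
                "seed": res.seed,
            }
        )
        return res

    group_children = imaging_ss.spawn(len(config.groups))
    for g_idx, (name, spec) in enumerate(sorted(config.groups.items())):
        amp, offbf, nc = _imaging_arm(config, spec, group_children[g_idx])
        descriptives[name] = {
            c: {
                "amplitude": _mean_sem(amp[c]),
                "off_bf_ratio": _mean_sem(offbf[c]),
                "noise_correlation": _mean_sem(nc[c]),
            }
            for c in config.conditions
        }
        for pair in CONDITION_PAIRS:
            run_test("amplitude", name, pair, amp[pair[0]], amp[pair[1]])
            run_test("off_bf_ratio", name, pair, offbf[pair[0]], offbf[pair[1]])
            run_test("noise_correlation", name, pair, nc[pair[0]], nc[pair[1]])

    behavior_report: dict = {}
    if config.include_behavior:
        videos, mtraces = _behavior_arm(config, behavior_ss)
        # HTR template from the first hypoactive-group mouse (falling back to
        # the first group) — one manually scored mouse defines the template
        hypo_groups = [
            n for n, s in sorted(config.groups.items()) if s.behavior_profile == "hypoactive"
        ]
        template_group = hypo_groups[0] if hypo_groups else sorted(config.groups)[0]
        template = bhv.htr_template(
            videos[template_group][0].htr_times_s,
            duration_s=config.behavior_duration_s,
            bin_width_s=config.htr_bin_s,
            label=template_group,
        )
        wm: dict[str, dict] = {}
        tc: dict[str, list] = {}
        for name in sorted(config.groups):
            wins = [
                bhv.window_means(tr.M, config.behavior_fps, config.behavior_windows_min)
                for tr in mtraces[name]
            ]
            wm[name] = {
                f"{w0:g}-{w1:g}": [w[(w0, w1)] for w in wins]
                for (w0, w1) in config.behavior_windows_min
            }
            tc[name] = [
                bhv.template_correlation(tr.M, config.behavior_fps, template)
                for tr in mtraces[name]
            ]
            behavior_report[name] = {
                "window_means": wm[name],
                "template_correlations": tc[name],
                "htr_counts": [len(v.htr_times_s) for v in videos[name]],
            }
            keys = list(wm[name])
            if len(keys) >= 2:
                run_test(
                    "movement", name, (keys[0], keys[1]), wm[name][keys[0]], wm[name][keys[1]]
                )
        names = sorted(config.groups)
        if len(names) >= 2:
            late = f"{config.behavior_windows_min[-1][0]:g}-{config.behavior_windows_min[-1][1]:g}"
            run_test("movement", "between-groups", (names[0], names[1]),
                     wm[names[0]][late], wm[names[1]][late])
            run_test("template_correlation", "between-groups", (names[0], names[1]),
                     tc[names[0]], tc[names[1]])

    return ComparisonReport(
        config=config.to_dict(),
        descriptives=descriptives,
        tests=tests,
        behavior=behavior_report,
    )
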