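# psiacx

Analysis pipeline for studying how a systemic pharmacological manipulation
(e.g. a serotonergic psychedelic) changes sound-evoked activity, functional
connectivity, frequency tuning, and free-roaming behavior in mouse auditory
cortex. It is written for experimenters who have motion-registered two-photon
(2P) GCaMP movies, widefield movies, arena videos, and stimulus schedules,
and who want the complete chain from raw pixels to statistical comparisons —
plus synthetic ground-truth generators so every stage can be validated
without real data.

## What it computes

**Two-photon arm.** Ring-like somatic ROIs are built around supplied cell
centers with an outer neuropil ring starting 3 px beyond the soma; pixel
means give raw somatic C_raw(t) and neuropil N(t) traces. Neuropil-corrected
fluorescence is C(t) = C_raw(t) − 0.7·N(t); cells whose time-mean C(t) is not
positive are discarded. Per trial, ΔF/F(t) = (F(t) − F̄_base)/F̄_base against
a 2-s silent baseline, out to 3 s after the tone. The response amplitude is
the mean ΔF/F over the 1 s after tone onset, and each neuron's raster is
normalized by the standard deviation σ of its trial amplitudes, giving
ΔF/F(σ). From the σ-normalized amplitudes the pipeline derives frequency
tuning curves (FTCs), Best Frequency (BF = argmax of the FTC), the off-BF
response ratio (mean off-BF response as % of the BF response), and pairwise
noise correlations: Pearson correlations of stimulus-mean-subtracted
responses, pooled over all tone frequencies, summarized per experiment.

**Widefield arm.** Frames pass through a homomorphic filter
(log → large-σ Gaussian high-pass → exp) to remove smooth multiplicative
illumination; per-pixel ΔF/F traces are averaged over the repeats of each
tone; frequencies whose trace peak is within 90% of the pixel's maximum
(ΔF/F₉₀) survive, and the pixel's tonotopic frequency is the median of the
surviving set on the octave axis.

**Behavior arm.** From an arena video V, frame differences
V′(f) = V(f+1) − V(f) are reduced to D(f) = Σ|V′(f)| and smoothed into a
movement trace M (low-passed Hilbert envelope). The pipeline reports spatial
movement maps with a 2-SEM noise floor, windowed means of M (0–10 and
10–60 min), and the Pearson correlation of M against a binned head-twitch
(HTR) time-course.

**Statistics.** All condition comparisons use a pooled bootstrap mean test:
with samples A (size n) and B (size m), Δµ = |mean A − mean B|; A* and B* of
size min(n, m) are drawn with replacement from the pooled sample 10,000
times, and p is the fraction of replicates with Δµ* > Δµ, categorized at the
0.05 / 0.01 / 0.0001 levels.

## Worked example

Simulate one three-session experiment (Pre / Post1 / Post2) with a designed
biphasic response gain (1.0 → 1.4 → 0.8) and a late rise in shared trial
noise (ρ: 0.10 → 0.10 → 0.25), then run the full 2P analysis chain:

```python
import numpy as np
import psiacx
from psiacx.fluorescence import (CellTraces, compute_dff, qc_filter_cells,
                                 response_amplitude, sigma_normalize)
from psiacx.population import noise_correlations

protocol = psiacx.make_tone_protocol(2, 45, 2, repeats=20, seed=0)
print(np.round(protocol.frequencies_khz, 2))
# [ 2.    2.83  4.    5.66  8.   11.31 16.   22.63 32.   45.25]   (200 trials)

config = psiacx.SynthNeuralConfig(
    n_neurons=50,
    condition_gain={"Pre": 1.0, "Post1": 1.4, "Post2": 0.8},
    shared_noise_rho={"Pre": 0.10, "Post1": 0.10, "Post2": 0.25},
    seed=1,
)
experiment = psiacx.simulate_experiment(config, protocol)

for cond, session in experiment.sessions.items():
    traces = CellTraces(session.raw_somatic, session.neuropil, 30.0).corrected(0.7)
    traces = traces.subset(qc_filter_cells(traces))
    tensor = sigma_normalize(compute_dff(traces, protocol))
    amps = response_amplitude(tensor)
    nc = noise_correlations(amps, protocol.trial_freq_idx)
    print(cond, np.nanmean(amps), nc.experiment_mean)
```

Output:

```
Pre: mean amplitude 0.697 dF/F(sigma), noise correlation 0.102
Post1: mean amplitude 0.813 dF/F(sigma), noise correlation 0.090
Post2: mean amplitude 0.668 dF/F(sigma), noise correlation 0.236
```

The recovered pattern is the designed one: amplitudes rise in Post1 and fall
in Post2 while the Post2 noise correlation climbs toward the generator's
ρ = 0.25. Comparing per-neuron Pre vs Post1 amplitudes with the bootstrap
test gives Δµ = 0.115 ΔF/F(σ), p < 0.0001.

The same analyses are scriptable from the shell (`psiacx simulate`,
`psiacx extract`, `psiacx tuning`, `psiacx noisecorr`, `psiacx tonotopy`,
`psiacx behavior`, `psiacx boottest`), and `psiacx run --config study.yaml
--out results/` executes a whole multi-group, three-session study and writes
the comparison report.

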