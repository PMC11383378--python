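# Methods

This note documents the models, conventions, and parameter choices behind
psiacx: what each analysis stage computes, what the synthetic generators
emulate (and deliberately do not), and where the design was genuinely open.

## Stimulus protocol

Pure-tone protocols are geometric frequency ladders
f_k = f_lo · 2^(k / tones_per_octave), truncated at f_hi with a 1% endpoint
tolerance so that conventionally rounded ranges keep their full count (the
canonical 2–45 kHz ladder at 2 tones/octave has 10 tones ending at
45.25 kHz). Trials are a seeded random permutation of `repeats` copies of
each frequency; inter-onset gaps are the 0.5-s tone duration plus a seeded
draw from the ISI set {6, 7, 8} s. The first onset defaults to 3 s so a full
2-s silent baseline precedes every trial, including the first.

## Two-photon trace model and extraction

**ROIs.** Somatic ROIs are annuli (default radii 2–6 px at ~0.8 µm/px —
soma-scale; the ring shape reflects membrane-localized GCaMP) around
supplied centers; the neuropil ring starts 3 px beyond the somatic outer
radius and is 10 px wide. Pixels claimed by two somatic ROIs are removed
from both; neuropil pixels overlapping any somatic ROI are removed. Rings
truncated by the image border are kept with a warning; neurons with empty
somatic sets are dropped. The somatic radii and neuropil width are package
defaults — only the 3-px gap and the overlap-exclusion rules are dictated by
the analysis conventions this pipeline implements.

**Correction and QC.** C(t) = C_raw(t) − 0.7·N(t); cells are kept only if
mean_t C(t) > 0 (strict inequality; a nonpositive mean indicates
neuropil-dominated signal).

**ΔF/F.** Per trial, the baseline F̄ is the mean corrected fluorescence over
the 2 s before tone onset; ΔF/F(t) = (F(t) − F̄)/F̄ from −2 s to tone offset
+ 3 s. The 2-s baseline fits comfortably inside the shortest (6-s) ISI.
Trials with nonpositive baselines, or windows that fall off the recording,
are flagged invalid (NaN) with a warning rather than failing the run.
Window edges are half-open on the frame grid, (onset, onset + w], with
durations rounded to the nearest frame.

**Amplitude and σ-normalization.** The response amplitude is the mean ΔF/F
over (onset, onset + 1 s]. σ per neuron is the sample SD (ddof = 1) over
trials of these amplitudes — the trial-to-trial reading of "SD of response
amplitude"; all samples of the neuron's raster are divided by it. Neurons
with σ = 0 are excluded from normalized output. After normalization the
recomputed amplitude SD is exactly 1, which the tests assert.

## Population metrics

Tuning curves are mean 1-s amplitudes per frequency (σ-normalized units);
BF is the argmax with ties broken deterministically to the lowest frequency.
FTCs are peak-normalized (nonpositive peaks excluded) and averaged within BF
groups with per-frequency SEM. The off-BF ratio is
100 · mean(off-BF responses) / BF response.

Noise correlations subtract each neuron's mean response to each frequency
from that frequency's trials, pool the raw residuals over all trials, and
take pairwise Pearson correlations; the experiment summary is the mean over
distinct pairs. Residuals are not z-scored per frequency before pooling —
the plain mean-subtracted construction; with σ-normalized inputs the
difference is minor, and the correlation is in any case invariant to
per-neuron affine rescaling. Statistical units for condition comparisons:
amplitudes and off-BF ratios pool neurons across experiments; noise
correlations contribute one experiment mean each.

## Widefield tonotopy

The homomorphic filter is log → Gaussian blur (σ = 50 px by default, i.e.
~10% of a 512-px frame) → subtract → exp, with edge-replicating boundary
handling so smooth illumination gradients are tracked to the frame border.
On a flat scene under a 0.5–2.0× illumination ramp it removes >90% of the
coefficient of variation while preserving the position of structures much
smaller than the blur scale.

Pixel ΔF/F uses the same construction as the 2P arm at 5 Hz, averaged over
each frequency's repeats. The ΔF/F₉₀ rule keeps, per pixel, frequencies
whose averaged-trace temporal peak is ≥ 0.9 × that pixel's maximum peak —
"within 90% of the maximum" read as the top decade of the pixel's own
response range (the ≥10% alternative would keep nearly everything and make
the rule useless for frequency assignment), and the maximum read per pixel
since the output is a per-pixel set. The assigned frequency is the median
of the surviving set on the log2 axis, so even-sized sets resolve to the
geometric mean of the two middle tones (e.g. {8, 11.31} kHz → 9.51 kHz).
Pixels with empty sets are undefined (NaN).

## Behavior

V′(f) = V(f+1) − V(f); D(f) sums |V′| over pixels — absolute values, since
signed sums over a brightness-conserving moving object cancel toward zero.
M is the magnitude of the analytic signal of D, zero-phase Butterworth
low-passed at 0.5 Hz (seconds-scale smoothing) and clamped at 0. The
envelope is taken on D directly rather than on a mean-removed copy: D is a
nonnegative activity signal, and rectifying it about its global mean would
fold quiescent (below-mean) stretches upward and mask hypoactivity — the
phenomenon the trace exists to measure.

Spatial maps average |V′| per pixel in a time window, zero pixels whose
window mean falls below twice that pixel's full-video standard error, and
are normalized jointly to the peak across the compared map set. Windowed
means default to 0–10 and 10–60 min, truncating (with a warning) to the
actual session length. HTR templates bin event times at 60 s (the binning
is a package choice); M is averaged into the same bins before the Pearson
correlation.

Videos recorded faster than the 30-fps analysis rate should be decimated by
frame selection before entering the chain; the pipeline itself is
rate-agnostic and takes `fps` explicitly.

## Bootstrap mean test

Δµ = |mean A − mean B|; A* and B*, each of size min(n, m), are drawn
independently with replacement from the pooled sample; p is the strict
exceedance fraction over 10,000 replicates by default (an add-one smoothed
variant is available but off by default). Significance categories are the
strictest of {0.05, 0.01, 0.0001} with p strictly below. The pool is sorted
before resampling so the test is exactly symmetric in its arguments at a
fixed seed; every result records its seed and sample sizes. Measured on
2,000 null simulations (n = m = 20 standard normal, 1,000 replicates each)
the 0.05-level rejection rate is ~0.055, within the calibration band the
acceptance checks require.

## Synthetic generators

The generators exist to give every stage inputs with analytically
predictable outputs; all are bit-reproducible from their seeds.

**Neural.** Neuron i's evoked amplitude on a trial at frequency f is
gain_c · a_i · exp(−(log2 f − log2 BF_i)² / 2w²) + ε, with
ε = sd·(√ρ·z + √(1−ρ)·η): z shared across neurons per trial, η private, so
every pair has noise correlation ρ. Defaults: BF drawn from the stimulus
grid (making BF recovery exact at zero noise), w = 0.8 octaves (typical
A1 L2/3 bandwidth), a = 0.5 ΔF/F (a robust GCaMP6s tone response),
sd = 0.15, baseline fluorescence 1.0 (arbitrary units, strictly positive so
ΔF/F is well-defined). Amplitude trains are convolved with a peak-normalized
double-exponential kernel (rise 0.18 s, decay 1.5 s — GCaMP6s-literature
timescales that sustain the 1-s analysis window). The raw somatic trace is
exactly truth + 0.7 × neuropil trace, so correction at the true coefficient
recovers truth to machine precision. Not modeled: spiking-to-calcium
biophysics, optical PSF, motion artifacts — the pipeline assumes registered
input, and the generator emits it.

**Widefield.** Pixel BFs ramp linearly in log2 frequency along one axis and
by default snap to the stimulus grid, so the noiseless analysis output
matches truth exactly (tie structure included); a continuous-gradient mode
exists for rank-vs-position checks. Gaussian pixel noise (default SD 0.05,
i.e. 10% of the response amplitude) and an optional multiplicative
illumination field exercise the denoising and homomorphic stages.

**Behavior.** A Gaussian blob (σ 2.5 px) performs a random-heading walk
with reflective walls. By default motion is bursty — exponential bouts
(mean 4 s) and pauses (mean 2 s), the bout structure real rodent
exploration shows and the envelope analysis expects — at 30 px/s; the
hypoactive profile switches to 4 px/s with 20-s mean pauses after the
switch time. Head-twitches are drawn from an inhomogeneous Poisson rate
(psilocybin-like: decaying linearly from 3/min to zero at 10 min;
control-like: constant 0.2/min) and rendered as ≤0.2-s bursts of
high-amplitude positional jitter. The programmed per-frame speed and event
times are recorded as ground truth. Recovery claims compare the movement
trace against the identically smoothed truth speed; the raw bout-gate
square wave differs from any band-limited estimate by construction. The
generator does not attempt realistic mouse appearance, lighting noise, or
bedding motion, so passing tests demonstrate correctness of the measurement
chain, not robustness to real-world video artifacts.

## Reference study and problem sizes

The reference synthetic study mirrors the three-session, two-group design:
treatment gains (1.0, 1.4, 0.8) with ρ stepping 0.10 → 0.25 in the last
session, control flat — calibration choices encoding the qualitative effect
pattern the pipeline must detect, not measured values. Full-scale defaults
are 6 experiments × 60 neurons per group with 20 repeats per tone and
10,000 bootstrap replicates.

The verification runs use deliberately reduced sizes chosen to keep ample
statistical headroom: power/stability sweeps use 4 experiments × 40 neurons
× 12 repeats × 4,000 replicates over 20 runs (tuning stability: 30-neuron
cohorts over 50 runs); behavior checks use 20-min, 10-fps, 32×32-px videos
with the hypoactivity switch at 10 min, over 50 runs; widefield checks use
24×24-px frames with 4 repeats per tone. Noise-correlation recovery runs at
the reference 50 neurons × 200 trials, where the estimate's seed-to-seed SD
is ~0.02 (dominated by the shared-latent sample covariance), comfortably
inside the ±0.05 recovery band.

## Known limitations

- The bootstrap p-value uses strict exceedance without smoothing, so p = 0
  is reportable; the smoothed option exists for users who object.
- Noise-correlation residuals pool across frequencies without per-frequency
  variance equalization; strongly heteroscedastic responses would weight
  loud frequencies more.
- The ΔF/F₉₀ reading ("≥ 90% of the per-pixel maximum") is one of two
  defensible interpretations of the rule's wording; it is the one that
  makes the rule selective.
- Behavior analysis measures gross movement only — no pose estimation, no
  automated HTR detection (event times are supplied or generated).
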