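# Methods

## Problem setting and model

A nearest-neighbor fNIRS montage measures one channel per adjacent
transmitter–receiver (T–R) optode pair. A motion artifact is an *optode-level*
event: a displaced optode or swaying fiber corrupts every channel incident to
that optode and no others. The method rests on the consequence that the
channels around a displaced optode become statistically unbalanced relative to
their other-side neighbor sets, while under artifact-free conditions neighbor
channels — which sample overlapping cortex — share signal features.

### Entropy unbalance

For channel *ch* with samples a(i), the windowed signal entropy is

    E(n) = −(1/N) Σ_{i ∈ [n−N/2, n+N/2)} a(i) log₂|a(i)|,

with `0·log|0| := 0`, the absolute value inside the logarithm, and signals
used in raw physical units (no pre-normalization). The half-open window
contains exactly N samples; N defaults to 20 (2 s at 10 Hz). The series is
computed at every sample index with reflect padding at the edges.

Each channel has two entropy cross-correlations, against the mean entropy
series of its T-side and of its R-side neighbor sets:

    Γ_T = Σ_i E_ch(i) · Ē_T(i),    Γ_R = Σ_i E_ch(i) · Ē_R(i),

summed over the full series. The raw inner product (not Pearson) is the
default; it makes Γ amplitude-dependent, which is intentional — a large
entropy excursion should produce a large unbalance — but a normalized variant
is available (`normalized=True`) for amplitude-insensitive analyses. Then

    UD_ch = |Γ_T − Γ_R|,    UI_opt = Σ_{ch incident to opt} UD_ch.

Identification scans the R-optode UIs (configurable): the maximal-UI R-optode,
its maximal-UD incident channel, and that channel's T-optode (the presumptive
artifact site). Ties break toward the lowest id, so the procedure is
deterministic.

### The "no contamination" decision

UI has no absolute scale (it grows with entropy magnitude and recording
length), so the flag is an outlier test on the UI distribution across
optodes:

    (max UI − median UI) / (1.4826 · median|UI − median UI|) > k.

Median statistics keep the scale estimate immune to the artifact's own
excursion (an artifact inflates up to two R-optode UIs out of twelve). The
default k = 8 was calibrated on clean simulated recordings, where the score
stays below ~5, while single-optode jumps or drifts of ordinary amplitude
(≥5× the white-noise σ) push it above ~25. Low-energy spike trains can remain
sub-threshold — a known limitation shared with the underlying statistic.

### Wavelet multiresolution features

Each channel is decomposed with a 10-level Daubechies-6 discrete wavelet
transform ("db6", 6 vanishing moments, filter length 12) into 11 sub-bands.
The network consumes *MRA components*: the full-length time-domain
contribution of each sub-band, obtained by inverting the coefficient tree
with all other sub-bands zeroed. Components sum samplewise to the signal,
which makes the per-sample 11-vector well defined and lets `keep`-subset
reconstruction act as a projection. Periodized boundaries give exact
additivity (≤1e−8 relative) and Parseval energy equality; signals whose
length is not a multiple of 2¹⁰ are reflect-padded and the components
cropped, which preserves additivity on the original support. Inputs shorter
than 2^levels reduce the depth automatically with a warning.

### Corrector network

11 inputs → hidden layers (128, 96, 64, 64, 48, 32) → 1 linear output;
rectifier activations (hyperbolic tangent available). "Six hidden layers
with more than 400 neurons" is read as a total across layers (432 here);
per-layer 400 would be grossly over-parameterized for an 11-dimensional
input. Inputs are standardized per sub-band (parameters stored in the
model); the target stays in physical units. Training is full-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8, lr = 1e−3) on MSE against the neighbor-mean
target, with early stopping when the relative improvement over a 500-epoch
window falls below 1e−6 (cap: 2000 epochs by default). Initialization is
He-scaled from a seeded generator, and every training path is bit-
deterministic per seed.

Weight transfer copies the trained model to a sibling channel sharing the
faulty optode and fine-tunes with a fresh optimizer for 100 iterations on
the sibling's *own* neighbor-mean target; `iters=0` is a pure forward pass
and reproduces the source channel's output bit-exactly.

### Pipeline

Iterate: report → identify → decompose → train on the identified channel
(target from its clean-side optode's neighbors, using the current state of
the recording, since corrections are sequential) → transfer to the
implicated optode's other channels → smooth corrected channels with the
hemodynamic kernel → repeat. Stopping: the no-contamination flag; the mean
absolute deviation of the scanned UIs dropping below σ_th (default: 0.1× the
first iteration's MAD, since an absolute σ_th would be unit-dependent); a
channel being re-identified without its UD having risen since its
correction; or the iteration cap (10). Only corrected channels are ever
modified — untouched channels leave the loop bit-identical.

### Smoothing and CNR

HRF smoothing convolves with the canonical double-gamma kernel
(peak-normalized g(t;6,1) − g(t;16,1)/6, truncated at 30 s, >99% of its
mass, unit sum) with reflected padding. The default is causal — an impulse
maps to the kernel, peaking ~5 s later — matching the method's use as a
hemodynamically-informed low-pass filter. Inside the pipeline the corrected
channels are smoothed with the group delay compensated (output advanced by
the kernel's peak latency): corrected channels are compared against
unsmoothed ones under a fixed task-window convention, and an uncompensated
5 s delay would shift response energy out of the delay-adjusted task windows
and penalize exactly the channels that were repaired.

CNR uses task/rest windows shifted (onsets *and* offsets) by the 4 s
hemodynamic delay, all blocks pooled, sample variances (ddof = 1). A zero
denominator yields CNR 0 with a `defined=False` flag. Wavelet denoising (a
comparison baseline) soft-thresholds each detail level at σ_j·√(2 ln L) with
σ_j = median(|d_j|)/0.6745.

## Synthetic study conditions

The generator emulates 10 Hz ΔHbO block-design recordings: per block 20 s
rest, 20 s task, 20 s rest (default 3 blocks, 1800 samples); a boxcar ⊛ HRF
response of amplitude 0.1 (arbitrary concentration·pathlength units);
sinusoidal physiology with per-channel random phases — cardiac 1.1 Hz,
respiration 0.25 Hz, Mayer waves 0.1 Hz, amplitude 0.01 each — and white
noise σ = 0.02. These are standard physiological bands; all are
configurable. Artifacts are added at optode level to every incident channel:
steps (jumps), saturating ramps (drift), or 0.2 s Gaussian transients every
2 s (spikes).

By default *all* channels are active: the montage covers motor and sensory
cortex engaged throughout a walking task, and the detector's premise is that
neighbor channels share features absent artifacts. Restricting activation to
a sub-region (e.g. the `ROI_CHANNELS` set) creates an activation boundary
whose entropy unbalance can rival an artifact's — a genuine failure mode of
boundary-localized activation that users should be aware of; the uniform
default keeps the study conditions inside the method's assumptions.

What the generator does **not** model: superficial/systemic physiology
distinct per scalp layer, spatially correlated noise, HbR coupling,
raw-intensity nonlinearity, or slow per-channel drifts unrelated to motion.
Passing tests therefore demonstrate correctness of the mechanics and
recovery under the method's assumptions, not clinical performance on real
gait data.

## Problem sizes

Stochastic properties are measured on 30-seed ensembles of 3-block
(180 s, 1800-sample) 40-channel recordings, with training capped at 800
epochs (400 inside the iterative pipeline, which corrects several channels
per run). These sizes keep a full verification run to minutes on one CPU
while leaving the detection margins (UI outlier scores ~25+ vs ~5
background) and correction margins (correlation gains ~+0.1) far from their
thresholds.

## Known limitations

- Globally contaminated recordings (most channels corrupted) break the
  unbalance premise; the method is explicitly not a bad-recording
  classifier.
- Low-energy spike trains may evade the UI outlier flag.
- The unnormalized Γ makes UI unit-dependent; comparisons across recordings
  require consistent units (or the normalized variant).
- Weight transfer assumes the sibling's artifact shares the source
  channel's sub-band signature (true for optode-level events, not for
  independent per-channel faults).
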