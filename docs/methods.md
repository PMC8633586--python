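# Methods

This note documents the models, numerical choices and open design
decisions behind `vmibci`, and what the synthetic-data results do and do
not establish about real EEG.

## The decoding model

The working hypothesis encoded by the pipeline is that imagined movement
direction modulates the *dynamics* of the occipital alpha rhythm's
amplitude envelope, not its mean voltage. Accordingly the feature path is:

    epoch (3 s, one channel) → EMD → Σ IMF₁..₃ → analytic signal →
    amplitude envelope A(t) → mean-centre, trim 5 % per edge → Burg AR(6)

for O1 and O2, giving a 12-vector per trial, classified pairwise by an
RBF-kernel SVM (C = 1, gamma = "scale") inside stratified 10-fold CV with
the standardizer refit per training fold.

### Empirical mode decomposition

Sifting subtracts the mean of the upper and lower natural-cubic-spline
envelopes through the local maxima and minima. Choices where the
procedure is conventionally underdetermined:

- **Stopping rule per IMF**: Cauchy-type SD = Σ m²/Σ h² < 0.3 *and* the
  IMF counting condition (|#extrema − #zero-crossings| ≤ 1), capped at
  100 iterations. 0.2–0.3 is the canonical SD range; requiring the
  counting condition as well guarantees every emitted IMF satisfies the
  defining property.
- **Boundary handling**: the two extrema nearest each end are mirrored
  across the end sample before spline fitting. Without mirroring the
  envelopes diverge at the edges and corrupt weak slow modes (verified
  against a planted weak 2 Hz tone, which mirroring recovers exactly).
- **Plateaus**: a run of equal samples that is a local extremum
  contributes its midpoint index (lower index for even runs).
- **Decomposition stop**: residual monotonic or with ≤ 1 extremum, or
  12 IMFs (termination guarantee; band-limited epochs stop naturally at
  2–5).
- **Degenerate input**: a constant series yields zero IMFs with the input
  as residual.

Reconstruction Σ IMFs + residual is exact by construction (telescoping);
the test suite verifies < 1e−9 relative error on random signals and
equivalence with an independently written reference EMD (see below).

### Energy series

The running mean-square energy has two branches: for
sample index N within the first second, (1/N)·Σ₁..N C²; beyond one second
the sum runs over the trailing Fs samples but the prefactor stays 1/N.
That prefactor makes the trailing-window branch decay as 1/N, which is
unusual; `norm="window_length"` switches to the conventional 1/Fs
normalization. N = Fs uses the first branch. The energy series is
computed and reported but does not enter the feature vector — the AR model
is fitted to the amplitude envelope (an AR model of a single scalar
average would be meaningless, so "average instantaneous amplitude" is read
as the amplitude time series).

### Burg AR estimation

Classic order-recursive Burg: reflection coefficients minimize the summed
forward/backward prediction error, so |k| < 1 and the fitted model is
always stable. Sign convention: x_t = Σ aₖ x_{t−k} + e_t (positive
feedback), matching statsmodels' `burg`/`yule_walker`, against which the
implementation is tested to 1e−8. The envelope is mean-centred before
fitting (it is strictly positive; an uncentred fit is dominated by the DC
term) and trimmed 5 % per edge to suppress EMD/Hilbert edge artifacts.

## The synthetic session generator

The generator emulates the *assumptions* of the analysis so that every
stage has a recoverable ground truth:

- **Montage/paradigm**: 18 channels (Fp2…Oz); each block is a 10 s cross,
  then per direction (order permuted per block) 5 s observe + 5 s imagine,
  then 5 s rest — 55 s per block. Defaults are desk-scale (250 Hz,
  10 blocks); `SynthConfig.acquisition_scale()` selects 1,000 Hz, 50 blocks,
  25 subjects.
- **Background**: per-channel 1/f (pink) noise, RMS 10 µV — a typical
  broadband EEG floor; its 8–13 Hz component has ≈ 2.5 µV RMS.
- **Alpha carrier**: 10 Hz cosine on O1/O2 during observe and imagine
  events, baseline amplitude 15 µV (textbook prominent occipital alpha),
  fresh random phase per event and channel.
- **Task effect**: during imagine events the envelope is
  A(t) = 15 µV · (1 + 0.9·tanh(0.4·effect_scale·u(t))), where u is the
  unit-variance AR(6) process of the event's task. The tanh keeps the
  envelope strictly positive and bounded, is linear in the effect for
  small scales, and saturates rather than degrades for large ones — which
  makes decoding accuracy monotone in `effect_scale`. `effect_scale = 0`
  gives a constant envelope: the four task distributions are then
  identical by construction, to the last bit.
- **Envelope profiles**: forward = resonator at 0.3 Hz with pole radius
  0.996 (quoted at 250 Hz and rescaled as r^(250/fs)), reverse = 1.2 Hz /
  0.985, left = 2.0 Hz / 0.95, right = a broadband lag-1 process (a₁ =
  0.5). The profiles span slow-to-broadband dynamics *within* the ≈2.5 Hz
  envelope bandwidth that an 8–13 Hz bandpass leaves observable around a
  10 Hz carrier; class differences faster than that would be filtered
  into a common shape. Left vs right is deliberately the most distinct
  pair.
- **Artifacts**: baseline wander as three random sub-0.5 Hz sinusoids per
  channel (20 µV total scale); blinks as 100 µV Gaussian deflections
  (σ = 0.1 s) at Poisson times, with a fixed spatial pattern (1.0 on Fp2
  decaying front-to-back to 0.05 occipitally) so ICA has a deterministic
  target.
- **Connectivity source** (optional): band-limited 8–13 Hz noise added
  *verbatim* to a chosen channel pair during imagine events. A shared
  noise waveform — unlike a shared tone — is incoherent with every alpha
  carrier, so only the genuinely shared signal survives Fisher-z
  averaging across trials.
- **Determinism**: all draws derive from `default_rng([seed, subject])`;
  identical (config, subject) gives bit-identical sessions.

What the generator does **not** emulate: volume conduction and realistic
source mixing, ERP morphology, non-stationary artifact statistics,
subject-level variability in alpha frequency/amplitude, or subject
exclusion. Passing tests therefore demonstrate that the *pipeline*
recovers the structure it assumes, at realistic amplitudes and SNR — not
that real VMI EEG contains that structure.

## Preprocessing decisions

- Baseline correction = per-channel least-squares linear detrend (removes
  DC and linear drift; the simplest rule consistent with "deviation from
  the baseline"). Whether a pre-stimulus reference interval should be
  used instead is unknowable from the source description.
- Elliptic bandpass: order 4, 0.5 dB passband ripple, 40 dB stopband,
  forward–backward (net 8th order, zero phase; net response ≥ 0.89 at
  10 Hz, ≤ 0.032 at 2 Hz, ≥ 30 dB down at 4 and 26 Hz — asserted from the
  designed transfer function).
- ICA: seeded scikit-learn FastICA fitted on 0.5 Hz high-passed data,
  applied to the full recording (continuous data, not 3 s epochs, so the
  unmixing is well conditioned). Rejection rule: |Pearson r| vs Fp2 ≥ 0.7
  or excess kurtosis ≥ 10. The pipeline's default stage order applies ICA *after* the
  alpha bandpass, which removes most blink energy first; the pipeline
  follows that order by default and exposes `ica_stage="pre-band"` for
  the more conventional broadband cleanup.
- Epochs: half-open sample window [onset + 1 s, onset + 4 s), 0-based,
  i.e. exactly round(3·fs) samples; epochs are re-detrended after
  filtering.

## Statistics decisions

- "Two-way ANOVA" with per-lead df = 3 rows is internally ambiguous (a
  genuine two-factor model yields one task effect, not 18). The stage
  therefore reports per-lead one-way ANOVAs across the four tasks on
  subject-level means (df_between = 3), BH-corrected across the 18 leads,
  *plus* a pooled two-factor task × lead model, separately.
- The dependent variable is the per-trial mean of the preprocessed signal
  per lead, averaged within subject × task. A detrended, band-passed
  signal has near-zero mean regardless of task, so on synthetic sessions
  this analysis is a correctly behaving null — the ANOVA/FDR machinery is
  power-tested on directly synthesized mean tables with a planted
  single-lead effect instead. Descriptives are reported in µV.
- An all-equal table is reported as F = 0, p = 1 (the 0/0 case).
- Connectivity: Pearson correlation between channel time courses per
  epoch, Fisher-z averaged across the task's epochs, back-transformed;
  zero-variance channels contribute zero correlation with a warning.
  `strongest_pair` breaks |r| ties lexicographically.

## Problem sizes

The test suite and acceptance script run entirely on generated data at
250 Hz: 10-block sessions (40 imagine trials) for unit and property
checks, a 100-block strong-effect session (100 trials per direction,
effect_scale 3) for the decodability checks, a 50-block default-condition
session for the six-pair grand mean, and 10 seeds × 10 blocks for the
connectivity and monotonicity properties. Acquisition-scale settings
(1,000 Hz, 50 blocks, 25 subjects) remain available through
`SynthConfig.acquisition_scale()` and the pipeline config.

## Known limitations

- EMD mode allocation beyond the dominant IMFs is implementation-
  sensitive for content that is unresolvable inside a 3 s epoch (sub-Hz
  drift fragments); equivalence with the reference implementation is
  therefore asserted for modes carrying ≥ 1 % of source variance.
- AR(6) coefficients of a heavily oversampled envelope (250 Hz sampling,
  ≤ 2.5 Hz content) have intrinsically high estimation variance on 750
  samples; this bounds single-trial decodability and mirrors the modest
  accuracies typical of this feature family.
- The EDF writer is minimal (16-bit, 1 s records, integer sampling
  rates); quantization error is bounded by the per-channel range / 2¹⁶.
- The pairwise grand sd is defined as the mean of the
  per-pair across-subject sds, not the sd of the pair means across
  pairs.
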