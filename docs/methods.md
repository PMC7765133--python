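# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analysis model

The pipeline treats a simultaneous EEG–fMRI sleep session as follows.
Expert-style annotations partition the session into an initial-wake
interval (the minutes after placement in the scanner), awakening epochs
(`A`), transition-to-sleep epochs (`T`), and unlabelled sleep. EEG
spectral content is summarised as *relative band power*: multitaper
power in delta (0.5–4.5 Hz), theta (4.5–8.5 Hz), alpha (8.5–13.0 Hz) and
beta (13.0–30.0 Hz), divided by the four-band total, so each
(channel, window) carries shares summing to one. Normalisation makes
subjects comparable despite skull-conductivity differences; it also
means the four shares are *not* independent — see the GLM note below.

Two integration routes feed the BOLD analysis:

1. **Condition regressors.** A/T occurrence vectors (boxcars on a
   microtime grid of 16 bins per scan) convolved with a canonical
   double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions
   1 s, peak:undershoot ratio 6, 32 s kernel; the kernel is normalised
   to peak 1 and its argmax falls at 5.0 s).
2. **BLP regressors.** Windowed relative power (2 s windows, 1 s step,
   Slepian tapers with NW = 2, K = 3), averaged over a selected
   electrode set, linearly interpolated to the microtime grid,
   HRF-convolved and z-scored. The electrode set comes from the most
   significant cluster of the electrode-space group comparison for that
   band, with an all-channel fallback when no cluster is significant.

First-level models are ordinary least squares per voxel with columns
`[conditions | BLP bands | 6 motion | initial wake | intercept]`; motion
plus initial wake form the seven-column interference block. Second-level
maps are one-sample t-tests across subjects (df = n − 1), thresholded at
the uncorrected two-sided t quantile (p = 0.01 primary, 0.05 when the
primary level yields nothing) with a minimum cluster extent of 10 voxels
under 6-connectivity. Groups are compared by the *signed intersection*
of their thresholded maps: joint voxels partitioned into same-sign and
opposite-sign parts, explicitly without a significance level attached.

Two modelling choices deserve emphasis:

- **All BLP covariates enter one GLM jointly.** Relative band powers are
  negatively correlated by construction (shares sum to one): when alpha
  rises, the other shares fall. Fitting one band at a time therefore
  attenuates each coupling through omitted-variable bias — on synthetic
  cohorts the attenuation reached a factor of three and halved the
  sign-recovery rate. The joint fit removes the bias; per-band
  hypothesis families are reported as contrasts of the joint model.
- **Steady-state HRF convolution for state regressors.** Band power is
  an ongoing state, not an event train starting at t = 0, so the
  convolution is padded with the initial value. Without the padding the
  z-scored regressor opens with an artificial −4 σ kernel-onset ramp
  that dominates its variance.

No AR(1) prewhitening is applied at the first level and no voxel-level
multiple-comparison correction at the second level; both omissions are
recorded in the output metadata of every run.

## Electrode-space statistics

Per-channel independent-samples t statistics (pooled variance;
constant-data channels get t = 0 with a flag) are thresholded at the
two-sided per-channel alpha of 0.05; suprathreshold channels of equal
sign are clustered under a sensor adjacency (neighbours iff Euclidean
distance ≤ 1.6 × the median nearest-neighbour distance, which gives a
median degree of ~5 on the default 32-sensor layout). Each cluster's
summed t is referred to the Monte-Carlo distribution of the maximal
|cluster statistic| over random group relabelings (default 1000; the
observed labeling is always counted, so p is never zero; an exact
enumeration mode covers small designs).

## EEG artifact removal

The chain is AAS → heartbeat detection → OBS → eye ICA → band-pass +
notch + mastoid reference. Three design points came out of adversarial
testing against the planted ground truth:

- **Template window.** `remove_gradient_artifact` uses a sliding window
  of the 30 nearest other epochs by default (appropriate for drifting
  gradients), but the chain passes the widest possible window: with
  TR = 1 s and a heart rate near 60 bpm, a narrow sliding template
  inherits a locally beat-phase-locked neighbour-mean of the cardiac
  artifact, which the OBS step then absorbs into its own estimate. The
  chain also runs a second pass that re-estimates the gradient template
  on pulse-subtracted data and refits the OBS on the comb-free record.
- **OBS basis size and pooling.** The chain uses a single basis
  component: the cardiac artifact is a spatial template with a per-beat
  scale (rank one per channel), and additional components absorb
  band-limited brain signal, which has low effective rank over a 0.8 s
  window. The per-beat scale is solved jointly across channels
  (energy-weighted least squares) because the scale is spatially
  coherent; pooling divides the brain-signal leakage into the fit by
  roughly the channel count. Per-beat onsets are realigned by a pooled
  cross-channel matched filter (two rounds) before fitting, since
  detection jitter is identical across channels.
- **Beat detection.** Envelope peak-picking (0.5–20 Hz band, squared,
  80 ms smoothing, 0.35 s refractory) is followed by dynamic-programming
  beat tracking with an interval prior derived from the envelope
  autocorrelation: a multi-lobed cardiac waveform otherwise makes raw
  peak-picking alternate between lobes, which template fitting cannot
  tolerate.

Eye artifacts: temporal ICA (FastICA, fixed random state), zeroing
components whose |correlation| with the blink reference (a named channel
or the frontal-quarter average) reaches the threshold (default 0.7).
The per-channel removal error scales with that channel's share of the
total blink energy, so removal quality depends on the blink topography
being spatially broad — which real blinks are.

Filtering: forward–backward (zero-phase) Butterworth band-pass of order
4, 0.5–30 Hz, plus a 50 Hz notch (Q = 30; EU mains default,
configurable); zero-phase filtering avoids phase distortion that would
bias the BLP–BOLD lag.

## The synthetic-cohort generator

Defaults are desk-scale: 8 controls and 9 patients, 300 s sessions at
TR = 1 s, 32 EEG channels at 250 Hz on an upper-hemisphere Fibonacci
layout (last two sensors are mastoid analogs), a 12 × 14 × 12 voxel grid
at 3 mm. The full-scale acquisition the design mirrors (256 channels,
1 kHz, ~83 min, 64-slice volumes) is reachable through `CohortSpec`.

**Events.** One initial-wake interval (15–35 s), then non-overlapping
A/T epochs: counts Poisson with per-group per-minute rates matching the
study-scale inventories (A: 0.455/min controls, 0.280/min patients;
T: 0.292 and 0.110), minimum one of each so every subject contributes;
per-occurrence durations log-normal with the published group
mean/variance magnitudes, clipped to 2–15 s.

**EEG.** Four band-passed Gaussian carriers amplitude-modulated by the
planted band-power trajectory, plus 1/f noise (30% amplitude ratio).
The trajectory combines (a) per-subject, per-channel baseline shares
around (0.38, 0.24, 0.20, 0.18) for delta/theta/alpha/beta; (b) state
modulations during A and T epochs, identical for both groups; (c) slow
multiplicative per-band fluctuations (log-Gaussian, 0.03 Hz low-pass,
σ = 0.25) shared across channels — these are the BLP drivers for the
BOLD couplings; and (d) the planted group effect: patients' shares of
the affected bands rise during A epochs on a contiguous posterior patch
of 10 electrodes by d × σ (d = 1.5 by default), compensated from beta.
Between-subject share variability (σ = 0.02 per channel) splits into a
small subject-global part (0.008) and a dominant channel-local part
(0.0183); the effect size is defined against the quadrature sum. The
global part is kept small deliberately: a per-electrode effect size is
only a meaningful detection target if the channel-wise t-fields are not
perfectly correlated across the cap.

**Artifacts.** Gradient: a deterministic multi-harmonic waveform
(harmonics of 1/TR, 1/h amplitude decay, per-channel gains) added at
every volume trigger, 25 × brain RMS. Pulse: a damped-oscillation
template with per-channel signed gains, added at cardiac onsets
(62 bpm, 40 ms beat-to-beat jitter) with per-beat scales (σ = 0.2),
3 × brain RMS. Blinks: a fixed frontal mixing vector times a sparse
bump train. The contaminated record equals clean + gradient + pulse +
blink exactly, and all components are reconstructable from the stored
ground truth.

**BOLD.** `y = Xβ + ε` with the true design `[A, T, alpha/theta/delta
drivers, initial wake, intercept]`; the drivers are the HRF-convolved,
z-scored channel-mean relative-power trajectories. Planted couplings
follow a nine-cell region × band sign table over three labelled regions
(secondary visual cortex, precuneus, dorsal posterior cingulate) with
amplitude 3 BOLD units per unit z-scored driver and signs that differ
between groups (the visual region flips sign for every band; the
precuneus has no delta coupling in controls). Condition responses
(amplitude 2 and 1.5) are planted in a frontal label; two resting
networks (a medial precuneus+cingulate map and a visual map) add slowly
fluctuating structured signal; i.i.d. Gaussian noise (σ = 1) completes
the model. A small drifting motion trace is generated as covariates but
not applied to the volumes at desk scale (rigid realignment is validated
separately on planted transforms).

**What the generator does not emulate.** Anatomy, physiological fMRI
noise beyond the planted networks, spatial autocorrelation of the BOLD
noise, gradient-waveform drift, k-space physics, non-stationary heart
rate, or realistic sleep-stage microstructure. Passing tests therefore
demonstrate that the *algorithms* recover what they model, under noise
levels and sample sizes matching the study design — not that the
pipeline is robust to everything real data contain.

## Validation analyses

- **Occipital alpha GLM.** The all-electrode average alpha regressor is
  fitted (together with condition, motion and wake covariates), and the
  second-level map thresholded at p = 0.05 must localise to the visual
  label. This validation runs on a cohort that plants only the
  well-established occipital alpha coupling (negative, both groups): in
  the full sign table the visual-cortex alpha coupling flips sign
  between groups, so an across-subject one-sample t there cancels by
  construction.
- **Resting-network ICA.** Spatial ICA (FastICA on voxels × time of the
  concatenated wake segments, fixed seed, components ordered by
  explained variance) must recover the two planted network templates by
  absolute spatial correlation. This runs on a cohort without band
  couplings, since region-specific coupling signals otherwise dominate
  the wake-epoch decomposition and split the medial network.

## Numerical choices

- Band-edge bins are half-open `[lo, hi)` except beta, which closes at
  30 Hz; no bin is counted twice. Total power is the sum over the four
  defined bands only.
- The multitaper spectrum is scaled so its sum over all bins equals the
  taper-weighted mean square of the signal (discrete Parseval);
  relative shares are scale-invariant either way.
- All-zero spectra map to uniform shares (1/4) rather than NaN;
  zero-variance voxels get t = 0 with a flag rather than NaN, so maps
  stay composable.
- Rigid-body realignment: integer-shift initialisation by FFT
  cross-correlation, Powell refinement with physiological bounds
  (±10 mm, ±8°), cost evaluated with cubic interpolation on a fixed
  eroded-interior region (trilinear interpolation biases rotation
  estimates toward zero; a parameter-dependent mask lets edge fill or
  overlap shrinkage game the objective). Output resampling is trilinear.
  The two-pass scheme aligns to volume 0, then to the mean volume.
- Smoothing uses a truncated (6 σ) Gaussian divided by its in-grid
  mass, so constants survive at the edges exactly.
- Monte-Carlo p-values always count the observed labeling; ties in
  electrode selection break toward the larger |cluster statistic|.
- Determinism: every stochastic step draws from a seed derived from the
  cohort seed via `numpy` seed sequences; a fixed seed reproduces a
  cohort bit for bit, and the pipeline manifest records content hashes.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
one fully contaminated subject for the artifact chain, 200 null and 50
effect cohorts (statistics tables only) for permutation calibration,
20 cohorts for coupling-sign recovery, 20 for the alpha validation, and
one for ICA. At these sizes the suite completes in about two minutes and
the acceptance script in about one.

## Known limitations

- At desk scale each subject has only one to three A epochs, so the
  electrode-space comparisons computed from *measured* spectra are
  underpowered at d = 1.5 (within-subject estimation noise roughly
  halves the effective effect size); the calibration statistics
  therefore operate on the generator's emitted band-power tables, which
  carry the planted between-subject structure exactly. Full-scale
  sessions (~83 min) would provide ~20× more epochs. The BOLD-side
  coupling-sign table is recovered from measured EEG even at desk scale.
- OLS first-level models ignore temporal autocorrelation of fMRI noise;
  with i.i.d. synthetic noise this is exact, with real data it would
  inflate first-level t-values.
- The intersection report is descriptive; no inference is attached to
  overlap counts, by design.
- EDF input/output is not provided; recordings travel as a `.npy`
  matrix plus JSON sidecar (rate, labels, positions, events).
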