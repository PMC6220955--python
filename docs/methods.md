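# Methods

`alphakit` is a simulation-plus-analysis package for one question: does
quasi-rhythmic visual stimulation in the theta (4–7 Hz), alpha (8–13 Hz) or
beta (14–20 Hz) band entrain the parieto-occipital alpha rhythm, or does
intrinsic alpha sail on unchanged?  Because the question is about what an
analysis chain *would* detect, the package pairs a generative model with
ground truth (stimuli → EEG → behaviour) with the full inference chain
(spectra → alpha observables → statistics), so that every stage can be
validated by recovery rather than by eyeballing.

## Stimulus model

Each trial presents two peripheral patches whose peak luminance follows

  L(t) = L_min + (L_max − L_min) · (1 + sin φ(t)) / 2,
  φ(t) = φ₀ + 2π ∫₀ᵗ f(τ) dτ,

with L_min = 7.5 and L_max = 29.1 cd/m² on a 6.5 cd/m² background, a 100
frames/s grid, and an instantaneous frequency f(t) confined to the
condition's band.  The trajectory f(t) is built from uniform draws on the
band at ~1-s knot spacing, interpolated with a shape-preserving (PCHIP)
spline and passed through a slew-rate limiter enforcing |df/dt| ≤ one
bandwidth per second (e.g. 3 Hz/s for theta).  The limiter output chases
its input with bounded steps, so band containment and the rate bound hold
exactly, not just in expectation.  The phase integral runs on an 8×
oversampled grid before decimation, to avoid integration error at beta-band
rates.  The two concurrent trajectories are rejection-sampled (batched)
until their Pearson correlation satisfies |r| < 0.05; initial phases φ₀
are uniform per patch per trial.  Transient target/distracter "flashes"
(0.3 s) occur in one third of trials, at most twice per trial with ≥ 0.8 s
between onsets.

The exact stochastic law of the frequency wander is not uniquely
determined by its published constraints; the knot/PCHIP/slew construction
is one admissible realization that satisfies all of them and produces
smooth, meandering trajectories with band-limited spectra (≥ 90% of the
contrast modulation's spectral mass inside the band ± 0.5 Hz).

## EEG generator

Per hemisphere h ∈ {left, right}, an alpha source

  s_h(t) = A·g_att·E_h(t)·sin φ_h(t)

combines a slow positive envelope E_h (Gaussian-lowpassed noise, ~1 Hz
bandwidth, mean 1, depth 0.4 — this gives the spectral peak its width) with
a phase obeying an Adler equation during stimulation:

  dφ_h/dt = 2π·IAF_true + ε·sin(φ_stim − φ_h),

where φ_stim is the attended patch's contrast-modulation phase and ε
(rad/s) is the entrainment coupling; ε = 0 recovers a free-running
oscillator at the subject's true alpha frequency.  Attention scales the
source amplitude: the hemisphere contralateral to the attended side by
10^(−a/20) and the ipsilateral one by 10^(+a/20), so cluster *power* moves
by ∓a dB (default a = 2 dB).  A frequency-following response
d·sin(φ_stim) (default d = 0.5) is added over posterior channels during
stimulation.  Sources project to the montage through Gaussian-on-the-sphere
kernels (σ = 0.35 rad) centred on the two parieto-occipital clusters of a
laterally symmetric cap montage (golden-angle spiral on one half, mirrored;
configurable 16–128 channels).  Background noise is spectrally shaped
1/f^χ (default χ = 1, unit RMS) per channel plus a 0.3-weighted
common-mode stream.  Recordings run at 512 Hz by default (≥ 256 Hz
required); trials are 0.5 s cue + 3.5 s stimulation.

Behavioural accuracy follows logit(acc) = β₀ + β₁·z(IAP) + noise
(σ = 0.3), evaluated per subject per condition.

The default cohort holds 17 subjects with IAF ~ N(10.2, 0.9²) truncated to
[8, 13] Hz and amplitudes uniform on [2, 5].  None of the generator
structure claims biophysical realism — no volume conduction, no ocular or
muscular artifacts, no trial-order effects, no non-sinusoidal alpha.
Passing recovery tests therefore demonstrates that the *analysis chain* is
correct and calibrated under its own assumptions, not that real data would
behave this way.

### The entrainment counterfactual

The coupling "on" regime uses ε = 2π·2 rad/s in the alpha condition only.
The choice is deliberate: the Adler locking range is ±ε/2π around the
detuning, and the quasi-rhythmic drive wanders over 8–13 Hz.  With weak
coupling (ε ≤ 2π·1.5) only subjects whose IAF sits near the drive get
pulled, by about one 0.5-Hz grid step.  With very strong coupling
(ε ≥ 2π·3) the oscillator is fully enslaved and its spectrum mirrors the
drive's broad occupancy — the spectral *peak* then becomes an unstable
statistic and the apparent pull is noisy.  ε = 2π·2 (locking range ≈ the
band half-width) is the intermediate regime in which the oscillator keeps
an identifiable peak that is visibly displaced toward the 10.5-Hz band
centre; the pull is assessed by a one-sided paired test of |IAF − 10.5|
during alpha-band stimulation against the rest measurement, alongside the
omnibus Friedman test on the distance distributions.

## Spectral decomposition

1-s epochs with 0.5-s overlap; during-stimulation data contribute a 3-s
window starting 0.5 s after stimulation onset (dropping the onset-evoked
response and the final 0.5 s), with event-containing trials excluded.
Epochs are converted to scalp current densities with Perrin-style
spherical splines (spline order m = 4, 20 Legendre terms, regularization
λ = 10⁻⁴ — m and the truncation are conventional defaults for the method;
λ is the published setting).  SCD is a single (channels × channels) matrix
applied per sample, so linearity and the zero response to spatially
constant potentials hold by construction.  Each epoch is then mean/trend
detrended, Hann-tapered and zero-padded to an exact 0.5-Hz grid
(1024-point FFT at 512 Hz; ceil(2·fs) otherwise); power is the squared
magnitude, averaged across epochs *on the raw scale* and only then
converted to dB (10·log₁₀) — averaging raw power before the log is the
default because the log of an average is the better-behaved estimator for
epoch-varying power; the round trip raw↔dB is exact.

## Alpha observables

IAF: the cluster-averaged raw spectrum P(f) is differentiated twice
(central differences on the 0.5-Hz grid), sign-flipped and smoothed with an
11-point, 3rd-order Savitzky–Golay filter; IAF is the frequency of the
largest positive interior maximum in the 6–14 Hz search window (window and
the lower-frequency tie-break are declared choices; SG edge bins are
excluded).  The curvature route accentuates shallow peaks on a steep 1/f
background while agreeing with the naive argmax when the peak is clear —
both properties are tested.  A spectrum whose curvature has no positive
interior maximum yields a "no peak" outcome (subject excluded listwise,
with a count in the report), distinct from an error.

IAP: mean dB power over the five grid points in IAF ± 1 Hz.
Lateralization: IAP over the cluster contralateral to the attended side
minus ipsilateral; negative under contralateral suppression.  A
phase-locking value utility (band-pass, Hilbert phase, across-epoch vector
mean) is provided as plumbing for stimulus-tracking checks.

## Inference battery

* **Cluster permutation** (paired, two condition topographies): channel
  neighbourhoods from Delaunay triangulation of azimuthally projected
  electrode positions; per-channel paired t thresholded at two-tailed
  α = 0.05 (conventional default); supra-threshold channels clustered by
  connectivity; cluster statistic = sum of t; null distribution from
  within-subject sign flips with the maximum-cluster statistic (1,000
  permutations); p doubled for two-sidedness and floored at
  1/(n_perm + 1).  The permutation loop is fully vectorized (sign flips
  leave per-channel second moments invariant).
* **RM-ANOVA**: fully-crossed within-subject decomposition via orthonormal
  (Helmert) contrasts; Greenhouse–Geisser ε from the covariance of the
  contrast scores, ε ≡ 1 for single-df effects; effect size
  ω²p = df·(F−1) / (df·(F−1) + df + df_err + 1), truncated at zero.
* **JZS Bayes-factor ANOVA**: per term, BF₁₀ compares
  {intercept + subject + term} against {intercept + subject}.  The subject
  block is integrated out under a noninformative flat prior; standardized
  effects carry the JZS mixture-of-g prior (g ~ InvGamma(1/2, r²/2),
  r = 0.5).  Conditional on g the marginal likelihood ratio is closed-form
  (Woodbury/eigen identities); the one-dimensional g integral is Monte
  Carlo with 10⁵ draws and a reported proportional error (flagged above
  5%).  The flat subject block was chosen over a subject g-prior because
  it makes a single two-level factor reduce *exactly* to the one-sample
  JZS t Bayes factor on the paired differences — giving an independent
  quadrature oracle (`jzs_ttest_bf`) that the MC route must match within
  its MC error; BF₁₀ is scale invariant and BF₀₁ = 1/BF₁₀ exactly.
* **Robust regression**: IRLS with Tukey bisquare weights (tuning 4.685),
  scale re-estimated each iteration as MAD/0.6745; Cook's distances from an
  ordinary fit screen gross points first (threshold 4/n — the cutoff is a
  declared default, the published analyses do not state one).  R² and the
  F test against the constant model use the converged weights.  The IRLS
  core is batch-vectorized so it can serve as a bootstrap statistic.
* **BCa bootstrap**: subjects resampled with replacement (paired across
  conditions); bias correction from the bootstrap distribution's position
  relative to the point estimate, acceleration from jackknife skewness.
  Slope differences between conditions use a Bonferroni-adjusted
  confidence level 1 − 0.05/3, read as testing at α = 0.05/3; H₀ is
  rejected iff the interval excludes zero.  Default 10,000 resamples with
  1,000 accepted via config (both counts appear in the source material for
  this design; the coverage suite uses 1,000).
* **Friedman test** on complete blocks (midranks, tie correction; the
  fully tied case returns χ² = 0, p = 1), logit transform with clipping to
  [1/(2n), 1 − 1/(2n)], Holm–Bonferroni step-down correction.

## Pipeline

`run_study(StudyConfig)` wires everything: cohort → stimuli (with
simulated 25% artifact rejection; at least two event-free trials per cell
are always retained) → recordings → SCD spectra → per-subject topographies
and alpha profiles → the battery.  The attention analysis feeds
hemisphere × position × frequency cell means of 8–12 Hz log-power (the
fixed group band, distinct from the per-subject IAF ± 1 Hz band) into the
ANOVA and Bayes ANOVA; cluster-defined and montage-defined parieto-
occipital clusters coincide in this generator, and the montage clusters
are used for metrics so the analysis is deterministic given the config.
IAF is z-scored before the rest→during regressions (its intercept is
meaningless); IAP is regressed raw so the intercept can index a global
power change.  All randomness flows from a single config seed through
spawned seed sequences; config → report is a pure function.

## Problem sizes in the replication suites

The package-level test suite replicates its calibration claims at reduced
problem sizes chosen to keep a full run in tens of minutes on one core:
17 subjects, 16 channels, 256 Hz, 12 trials per condition × side, 30-s
rest segments, 20,000 MC draws, cluster test computed in its own dedicated
500-replicate calibration rather than inside every pipeline replicate.
The stimulus suite checks 1,000 trials per band; IAF recovery uses 200
spectra; cluster type-I error and BCa coverage use 500 replicates each;
the null-pattern and entrainment-detection checks use 100 full-pipeline
replicates each.

## Known limitations

* The generator's topography is a two-source Gaussian-kernel cartoon;
  cluster tests on it say nothing about source localization.
* IAF lives on a 0.5-Hz grid; all pull and regression statements inherit
  that quantization.
* The frequency-following response adds power at stimulation frequencies,
  which overlaps the 8–12 Hz analysis band in the alpha condition; at the
  default drive amplitude this leak is ≲ 0.1 dB and does not disturb the
  null pattern, but very large `drive_snr` values will masquerade as an
  alpha-power effect.
* The JZS Bayes factors treat subjects as a flat nuisance block rather
  than as a g-prior random factor; for designs far from balanced
  within-subject layouts the two conventions can diverge.
* `simulate_behavior` draws accuracies from the logit-linear model
  directly rather than from per-trial Bernoulli outcomes.
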