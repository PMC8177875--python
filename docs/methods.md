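# Methods

## Generative model of the synthetic cohorts

Each simulated signal (sensor channel or region trace) is

```
x_c(t) = aperiodic_c(t) + Σ_k w_kc · a_k · osc_k(t) + artifacts_c(t)
```

* **Aperiodic background.**  Independent Gaussian noise per signal,
  spectrally shaped so the one-sided PSD is `(2/fs) · 10^offset / f^χ`,
  flattened below 1 Hz so total variance is finite.  Defaults: offset 0,
  exponent χ = 1 (per-subject SD 0.1).  A log–log straight-line fit over the
  oscillator-free 20–80 Hz band recovers χ to within ±0.3 at 300 s.
* **Oscillators.**  Gaussian noise shaped by a Gaussian spectral bump:
  centre frequency, bandwidth (FWHM, default 2 Hz — matching the few-Hz-wide
  alpha peaks seen in group-average resting spectra), RMS amplitude (default
  0.04, lognormal across subjects with σ_log = 0.2).  One time course per
  oscillator, shared across signals through a nonnegative topography.  The
  default sensor topography is posterior-weighted (0.4 baseline + Gaussian
  bump at the occipital pole) so every sensor sees alpha but posterior
  sensors see most; region-level default is uniform.
* **Group templates.**  Controls: one peak at 10.25 Hz.  Patients: a
  mixture over peak sets with proportions 4/21 (8.25 Hz), 11/21 (9.25 Hz),
  4/21 (both, amplitude split √2), 2/21 (no clear peak, i.e. zero oscillator
  amplitude).  Per-subject centre frequencies are jittered with SD 0.25 Hz
  (the within-group variability is not empirically constrained; this value
  keeps individual peaks within one–two spectral bins of the group peak).
  The default amplitude was chosen analytically so a full-weight control
  channel lands near ratio ≈ 0.7 and a 9.25 Hz patient channel near ≈ 0.9:
  with background ratio `mean(1/f; 7–9)/mean(1/f; 9–11) ≈ 1.25`, an
  oscillator-to-background contribution of ~0.8 at the fast band produces
  the observed case-control ordering.  Whole-head averages sit higher than
  single posterior channels because anterior channels approach the
  background-only ratio of ~1.25 in both groups.
* **Artifacts.**  Cardiac: a Mexican-hat (QRS-like) waveform at quasi-
  periodic beat times (60 bpm, 5 % inter-beat jitter) with a fixed random
  signed topography.  Ocular: slow Gaussian transients (σ = 80 ms) at
  Poisson times (12/min, 1 s refractory) with a frontal topography.
  Powerline: a common sinusoid (50 Hz, per-channel gains 0.8–1.2).
  Amplitudes (0.3 / 0.5 / 0.05 on the strongest channel) sit well above the
  background (channel SD ≈ 0.16) without dominating it.  Clean reference
  traces (plus 1 % sensor noise) are attached for event detection.
* **Covariates.**  Truncated-at-zero normals: patients pain VAS 5.0 ± 2.4,
  pain duration 10 ± 9 y, depression score 9 ± 4; controls 0/0 and 1 ± 2.
  An optional correlation couples a covariate to the subject's alpha
  slowing; the default of 0 makes correlation analyses a true null, so
  near-zero r values in reports are expected, not bugs.
* **Seeding.**  A master seed spawns one stream for the cohort draw and one
  integer seed per subject (stored in the subject table); identical specs
  and seeds give bit-identical recordings.

What the generator does **not** emulate: biophysical forward fields and
sensor covariance structure, head movement, non-stationarity of rhythms,
heavy-tailed artifact diversity, or any relation between covariates and
spectra beyond the single optional coupling.  Passing tests therefore
demonstrate that the *analysis machinery* is correct and calibrated, not
that the biomarker separates real clinical populations.

## Sampling rate and channel count

Defaults are 600 Hz and 64 channels on a circular 2-D layout (275-channel
and 2400 Hz configurations are supported via the spec objects).  All
analysis frequencies are ≤ 90 Hz, and the emulated acquisition chain was
already anti-alias-filtered below 600 Hz, so 600 Hz loses nothing relevant
while keeping simulations desk-sized.

## Preprocessing

* **Notch**: forward–backward IIR (`iirnotch`), default quality factor 50.
  At Q = 50 the bidirectional notch attenuates the target line by far more
  than 30 dB while altering frequencies ≥ 2 Hz away by < 1 dB; a lower Q
  (e.g. 30) would violate the 1 dB passband bound once applied in both
  directions.
* **Bandpass**: 4th-order Butterworth, forward–backward (`sosfiltfilt`),
  default 1–200 Hz.  Zero-phase filtering preserves peak frequencies and
  event latencies.
* **Event detection**: the reference trace is bandpassed 5–35 Hz (cardiac)
  or lowpassed 5 Hz (ocular), z-scored, and thresholded at 2.5 with a
  refractory period (0.3 s cardiac, 0.5 s ocular).  Flat references yield
  an empty event list with a warning.
* **SSP**: the projector basis is the leading left singular vector(s) of
  the event-locked average epoch (default 1 component per artifact kind,
  windows −0.2…+0.4 s cardiac, −0.3…+0.5 s ocular).  At least 5 usable
  epochs are required; with fewer (e.g. few blinks in a short recording)
  the projector is skipped and logged rather than estimated from noise.
  Projection `(I − BBᵀ)` is idempotent and never increases variance.
* **Segments**: bad spans are annotations (inputs — inspection is manual in
  the emulated workflow); complement segments shorter than one Welch window
  are discarded with a logged count.  Welch runs per segment and pools
  periodograms weighted by window count, avoiding concatenation
  discontinuities.

## Spectral features

Welch with a 4-s Hamming window and 50 % overlap gives Δf = 1/4 s =
0.25 Hz exactly; all band edges align to this grid.  One-sided density
normalisation (integral ≈ variance, verified to 5 % on white noise).
Per-window mean removal (`detrend='constant'`).  DC and Nyquist bins are
excluded from every band.

Band powers are arithmetic **means** over bins (bands of different widths
stay comparable).  Named bands use closed intervals — the printed band
edges are all bin centres and the bands are disjoint.  The ratio bands are
half-open, `[7, 9)` and `[9, 11)`, so the shared 9 Hz edge is counted
exactly once, in the fast band; the convention is configurable and logged
(the underlying "7 to 9" / "9 to 11" wording does not resolve the edge).

The alpha peak is the argmax over the closed 7–13 Hz search range, ties
broken toward the lower frequency (fixed, documented).  The
**no-clear-peak flag** compares the spectrum against its own aperiodic
trend: a log–log line is fitted over the search range and the maximum of
the 3-bin-smoothed residual must exceed 1.5 × the median residual.  A raw
max-over-median rule cannot work here: a pure 1/f background already has
max/median ≈ 1.43 across 7–13 Hz, so any fixed raw threshold either never
flags a peakless 1/f spectrum or flags genuine peaks.  Detrending makes
flat and 1/f-only spectra both flag reliably while a default-amplitude
peak (~3 × background) never does.

Peak-bin fidelity: the PSD argmax equals the bin nearest the configured
centre frequency only when the oscillator bump is spectrally resolvable.
At the default 2 Hz FWHM, adjacent 0.25 Hz bins differ by < 5 % and
realization noise flips the argmax between them (~60 % exact-bin at
300 s); at 0.5–1 Hz FWHM the argmax is essentially always exact.  The
fidelity tests therefore use narrow, high-amplitude oscillators; group
analyses never depend on exact-bin recovery.

Whole-head (or whole-atlas) averages are arithmetic means over signals;
signals flagged no-clear-peak are excluded from the peak-frequency mean
only (logged), and an all-flagged subject yields NaN for that one feature
with a warning.

Regions are kept when they contain **strictly more than 20** source grid
points; region traces are unweighted means over member grid points.

## Statistics

* **Permutation t-test**: pooled-variance Student t (Welch-type available
  via `equal_var=False`; under the permutation null either flavour is
  valid).  When the number of distinct label assignments C(n, n_a) is at
  most `n_perm`, the null is enumerated exhaustively and
  p = #{|t*| ≥ |t_obs|}/total (identity included, so p ≥ 1/total).
  Otherwise `n_perm` random assignments are drawn and
  p = (1 + #{|t*| ≥ |t_obs|})/(1 + n_perm), keeping p strictly positive.
  Ties |t*| = |t_obs| are counted with a 1e-10 relative tolerance so exact
  enumeration matches independent oracles bit-for-bit.
* **Shared schedule**: one label-shuffle schedule (one seed) is applied to
  all signals × features jointly, preserving their dependence structure;
  per-column results are identical to independent calls with the same
  schedule.
* **FDR**: Benjamini–Hochberg step-up over the flattened signals × all-7-
  features family by default (`per_feature` families available).  Peak
  frequency and ratio are corrected inside the same family as the band
  powers because all seven features are tested identically.
* **Correlations**: product-moment r with a two-sided t-based p, missing
  pairs dropped (never imputed) and the retained n reported; reported post
  hoc and uncorrected.
* **Lateralization**: LI = (L − R)/(L + R) per homologous pair, requiring
  positive inputs (band powers and ratios are positive); antisymmetric and
  bounded in (−1, 1).  With this sign convention a *right*-hemisphere ratio
  increase yields *negative* LI.

## Simulation sizes in tests and the acceptance script

Chosen so the full suite runs in about a minute and the acceptance script
in a few minutes on one CPU, while keeping every check statistically
meaningful; all sizes are stated where used.

* Type-I error: 1,000 null cohorts (8 vs 8 subjects from the control
  template, 12 s at 200 Hz, 4 channels), 999 permutations, α = 0.05;
  the empirical rate is compared with the binomial band [0.032, 0.071].
* FDR: 200 null + 50 effect cohorts at the feature level (64 signals × 7
  features, 20 vs 20 subjects) via the generator's feature-level surrogate
  `simulate_feature_matrix` — the FDR property concerns the statistics
  layer, so time-series simulation adds nothing but runtime here.  True
  effects are mean shifts of d = 1.5 in 10 % of cells.
* Group-contrast recovery: 100 fully simulated cohorts of 25 controls vs
  21 patients (default templates), 20 s at 250 Hz, 8 channels.
* Lateralization: 10 vs 10 subjects, 8 regions (4 L/R pairs), 60 s at
  250 Hz; patients slowed either on the right only or bilaterally.
* The acceptance script's study-scale run uses 120 s at 600 Hz with 32
  sensors / 16 regions and 10,000 permutations.

## Known limitations

* The artifact models are stereotyped; SSP performance against real
  heterogeneous artifacts is untested by construction.
* The no-clear-peak flag assumes an approximately power-law background
  within 7–13 Hz; spectra with strong knees inside the search range could
  be misflagged.
* Region homology comes from the metadata's pair links; no anatomical
  pairing scheme is implemented.
* Automatic bad-segment detection is out of scope; annotations are inputs.
* p-values from sampled permutation schedules have resolution
  1/(n_perm + 1); families much larger than ~10 × n_perm cannot push
  BH thresholds below that resolution.
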