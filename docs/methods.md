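# Methods

This note documents the models, numerical choices and design decisions
behind `biodyn`, and what the synthetic data do and do not emulate.

## Speckle and its fluctuation spectrum

Living-tissue speckle is modeled per pixel as a stationary complex
circular Gaussian process `E(t)`; the camera records `I(t) = |E(t)|²`.
For such a process the intensity autocovariance is the squared magnitude
of the field autocovariance (Siegert relation), so the intensity
fluctuation spectrum is the autocorrelation of the field power spectrum.
Because the measured quantity is the *intensity* spectrum — modeled as a
knee curve `S(f) = s0/(1+(f/f_k)^p) + floor`, similar in shape to a
diffusive spectrum but produced by actively driven intracellular motion
— synthesis requires the inverse map. We solve `u ⋆ u = q` for the
non-negative per-bin field powers `u` (`q` is the two-sided per-bin
intensity target) with a damped multiplicative fixed point,
`u ← u · √(q / u⋆u)`, run for a fixed 50 iterations and rescaled by
least squares, so the result is deterministic. Two safeguards matter:

* **Feasibility projection.** A self-correlation spectrum is positive
  definite (its DFT is `|FFT(u)|² ≥ 0`). Steep, floor-free targets can
  violate this, and the raw iteration then diverges; we first project
  the target onto its positive-definite part. For realistic knee
  spectra with a noise floor the projection is a no-op and the residual
  mismatch is below ~0.3% per bin.
* **Nyquist convention.** The one-sided periodogram uses the
  Parseval-exact convention (factor 2 on all bins except the single
  Nyquist bin). A smooth self-correlation cannot produce the one-bin
  spike that would make the measured Nyquist bin equal `S(f_N)`, so the
  synthesis uses the smooth half-weight target and the measured top bin
  sits at `S(f_N)/2`. The spectrogram `D` depends only on ratios of
  spectra, so the convention cancels everywhere downstream.

Generation is circular (FFT-based) with independent complex Gaussian
Fourier coefficients, which makes the expected periodogram match the
target bin by bin and keeps per-pixel Parseval exact to rounding. The
lowest few lag-frequency bins of an intensity periodogram carry excess
variance (overlapping product terms of the same field coefficients);
this is a property of the estimator, not of the synthesis.

## Holography

The recording plane is the Fourier plane, so reconstruction is a single
unnormalized forward 2D FFT with a quadrant shift; no digital
propagation. The plane reference is tilted along x by the crossing
angle, giving fringes of period `Λ = λ/sin θ` (32 µm at 840 nm and
1.5°; exactly 4 camera pixels of 8 µm) and a carrier at
`pixel_pitch/Λ = 0.25 cycles/pixel`. The simulator snaps the carrier to
the nearest FFT bin so the reference is periodic over the frame;
without this, finite-aperture leakage smears the carrier across the
Fourier plane and the noise-free round trip cannot exceed ~0.93
intensity correlation (it is 1.000 with the snap). Sidebands are
isolated with a circular hard window whose default radius is half the
carrier offset; windows that would overlap the zero-order region raise.
The two sidebands of the real hologram are exact complex-conjugate
mirrors; the one at minus the carrier holds the un-mirrored image and
is the default.

## Spectroscopy

Per-pixel one-sided periodograms of mean-subtracted intensity (no
taper; DC excluded; `f_k = k·fps/T`, `k = 1…T/2`) are combined across
pixels in quadrature (root-sum-of-squares, the literal instrument
description) or by plain averaging — the choice cancels in `D`, which
is scale-invariant. Log-frequency rebinning uses geometric bins (20 per
decade by default), geometric-mean bin centers, the top edge clamped to
the measured band, and drops empty low-frequency bins. The baseline
`S̄(ω, t₀)` is the geometric mean of the pre-treatment loop spectra —
the natural average for log-domain differencing, and it makes the
pre-treatment columns of `D = ln S − ln S̄` average to zero exactly.
Natural logarithm, so small `D` reads as fractional spectral change
(`D = 0.26` ≈ a 30% change). Zero densities are floored at 1e−12 of the
spectrum maximum before the log.

## Features (40) and biomarkers (12)

* **Global (9).** Inner products of the post-treatment `D(x, y)` with
  polynomials of degree 0–2 in normalized log-frequency `x` and
  normalized time `y`. The polynomials are built by Gram–Schmidt under
  the trapezoid weights of the actual grid, so orthogonality is exact
  (plain Legendre polynomials on a finite grid leak at O(h²)); they
  agree with `1, x, (3x²−1)/2`-shaped patterns up to scale. Raw inner
  products are reported (no normalization by the polynomial norm):
  for `D = x`, `g10 = ⟨x²⟩`.
* **Local (9).** Mean of `D` over a 3×3 partition into log-frequency
  thirds × post-treatment time thirds.
* **Preconditions (9).** Pre-treatment sample-health metrics: NSD
  (temporal speckle contrast std/mean when intensity statistics are
  available, otherwise the square root of the integrated spectral
  power as a monotone spectral surrogate), DR (10·log10 of the
  low/high-frequency density ratio, dB), HW (log-frequency centroid ≈
  average Doppler frequency), KN (fitted knee frequency), BB
  (backscatter brightness or total spectral power), SF (high-frequency
  log-log slope), SE (normalized spectral entropy), S0 (low-frequency
  plateau), HT (bright-pixel fraction, 1.0 when only spectra exist).
  The knee fit is a deterministic grid search over (knee, slope) with
  closed-form plateau/floor at each node and parabolic refinement —
  no iterative optimizer, ~0.3 ms per spectrum, knee recovered within
  a few percent noise-free.
* **Deltas (9).** The same metrics on the final third of the
  post-treatment loops, minus their pre-treatment values (DKN, DNSD, …).
* **Baseline (3).** Mean |D|, linear drift slope and detrended residual
  of the pre-treatment columns.
* **Data quality (1).** Fraction of loops passing finite/positive/SNR
  checks; SNR is the mid-band median density over the top-half-decade
  median (a floor estimate), threshold 3.

Pooling into the 12 biomarkers is a weighted mean of z-scored member
features; z statistics are fitted once per trial and reused, making the
map deterministic. The exact member lists of the instrument's pools
are not published in detail, so the shipped `pooling_map.yaml` is an
editable stand-in with the documented semantics (ALLF broad response,
ALLFT broad response linear in time, SDIP/CDIP mid-band, HI
high-frequency, SDIP2 late second-order, DNSD/DKN precondition changes,
NSD/DR/HW/DQ passthrough); a replacement map drops in by file path.

## Phenotyping

Well similarity is the Pearson correlation of biomarker vectors. By
default the correlation runs over the 8 drug-response biomarkers: the
4 precondition/quality entries are near-constant within a patient, so
including them clusters wells by patient identity rather than by
response shape (measured: ARI vs planted archetypes 0.42 with all 12,
0.99 with the response subset); `response_only=False` restores the full
vector. Clustering is average-linkage on `1 − correlation`; the tree is
cut to k = 4 by default, with a largest-gap rule available as evidence
for k. Each cluster's time-averaged post-treatment frequency profile is
correlated with the four archetype templates (±P₁, ∓P₂ in normalized
log-frequency) to assign phenotype numbers (1 blue, 2 red, 3
mid-enhanced, 4 mid-suppressed); ties break toward the lower number,
zero-profile clusters stay unassigned, and two clusters may share an
archetype. Negative-control (medium) wells have no drug response to
classify: the pipeline leaves them unlabeled and they are never
censored.

## Chemosensitivity prediction

Patient-level tables average biomarkers over surviving replicate wells
per (patient, drug); preconditions average over all the patient's
wells. Empty cells after censoring are imputed by the trial column mean
and flagged; columns imputed for more than 30% of patients (and their
bilinear descendants) are excluded from selection — their WB ratios are
artifacts of the imputation structure. Bilinear biomarkers are
mean-subtracted products of each drug-response column with NSD, DR and
HW, capturing precondition-dependent response reversals; inside
cross-validation the centering means, the WB ranking and the feature
standardization are all computed on the training patients only, which
makes per-fold biomarker selection provably independent of the held-out
pair (verified by a mutation test).

WB is oriented between/within — the standard deviation of the two
cohort means over the pooled within-cohort standard deviation — so
that the most discriminating column has the largest WB; it is capped at
100 when the within-spread vanishes. The classifier is a minimal
shallow network (two hidden layers of 8 tanh units, logistic output,
cross-entropy with L2 penalty 1e−3) trained full-batch by a
quasi-Newton optimizer, deterministic under its seed, with standardized
inputs. Double-holdout cross-validation draws one resistant and one
sensitive patient uniformly at random per run, with replacement across
the 60 runs; held-out (and permanently held-out) patients are scored
each run and per-patient scores are collated as means. ROC/AUC uses a
threshold sweep with midpoint tie handling (Mann–Whitney convention).
Prevalence tables count selected columns, features (a bilinear column
credits both its response biomarker and its precondition) and drugs
across the hold-out passes.

## The synthetic trial: what it emulates and what it does not

The generator reproduces the *structure* of a two-cohort assay: 14+14
patients, four drugs plus growth-medium controls, 5 replicate wells per
drug and 6 controls, 40-minute loops with a 4-hour (6-loop)
pre-treatment baseline and 18 post-treatment loops, per-patient base
spectra (log-normal variation of plateau and knee around s0 = 1,
f_k = 0.4 Hz, p = 1.7, floor 1e−3), well responses built from the four
archetype shapes ramped linearly from treatment onset with ~30% peak
amplitude, i.i.d. log-normal spectral noise (sd 0.05 per bin/loop), and
a planted fraction (default 0.2) of "unhealthy" red-shifted wells.

Design choices worth knowing:

* **Signal placement.** The cohort effect is carried by the response
  *amplitude* on two informative drugs (sensitive patients respond more
  strongly; `effect_size` is the cohort mean separation in units of the
  patient-level amplitude sd of 0.05). Correlation similarity is
  scale-invariant, so phenotype clustering is unaffected by the signal
  while patient-level averages carry it — shape and amplitude are
  deliberately orthogonal roles.
* **Phenotype composition.** Two drugs respond blue-shifted (the
  majority phenotype), one mid-enhanced (the minority), one
  mid-suppressed and uninformative — so censoring phenotype 4 removes
  nothing informative, while the red wells are the noise mechanism.
* **Red noise wells.** Replaced treated wells respond red-shifted with
  a cohort-independent random amplitude (mean 0.35, sd 0.15). Their
  −P₁ projection lands directly on the informative response direction,
  so averaging them into replicates corrupts the patient signal without
  adding any; this is exactly what phenotype-2 censoring recovers.

Not emulated: multiple scattering, sample drift and aberrations, 3D
tissue geometry, real drug pharmacology, inter-feature correlation
structure of real tissue, or the clinical outcome distributions — so
passing tests demonstrate the correctness and calibration of the
*analysis machinery* under the stated generative model, not clinical
performance. The clinical AUC levels of real trials require patient
data and are out of scope.

## Calibration and problem sizes

The predictor calibration checks run the full spectral pipeline on
clean trials (no red wells): with no planted effect the mean collated
AUC over 20 seeded 28-patient trials (60 CV runs each) is ~0.5
(per-seed sd ≈ 0.15, so individual trials range widely — a property of
collated small-cohort CV, not a bias); at a 2σ effect the mean AUC
exceeds 0.9. The censoring experiment uses 30% red wells and compares
three CV passes sharing one hold-out schedule. Simulation sizes used in
tests (e.g. 512-frame, 4096-pixel stacks for spectrum recovery; 256
frames for Parseval and speckle statistics) were chosen to make
sampling error comfortably smaller than the tolerances they check.
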