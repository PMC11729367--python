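# Methods

This note documents the models, algorithms and numerical choices behind
`specurve`, what the synthetic-data generator does and does not emulate,
and the problem sizes used by the test suite and the acceptance script.

## Spectral model and fitting

A power spectrum on a uniform frequency grid is modeled in log₁₀ power as
an aperiodic Lorentzian plus N Gaussian peaks:

    model(F) = b − log₁₀(k + F^χ) + Σᵢ hᵢ · exp(−(F − cᵢ)² / (2 wᵢ²))

`b` is the offset (log₁₀-power units), `k ≥ 0` the knee (absent in *fixed*
mode, where the aperiodic part is a straight line of slope −χ against
log₁₀ F), `χ` the aperiodic exponent, and each peak has center `cᵢ` (Hz),
height `hᵢ` (log₁₀ power above the aperiodic part) and width `wᵢ` (Gaussian
SD, Hz). The model is fit to log₁₀ power against *linear* frequency;
region-level spectra are averaged in *linear* power, and logs are taken only
inside the fitting stage.

The fitting procedure (the specparam/FOOOF scheme):

1. **Robust aperiodic fit.** A seed least-squares fit of L(F) over the fit
   range; the flattened spectrum (data − seed fit, negatives clipped to 0)
   is thresholded at its 2.5th percentile and the fit is repeated on the
   bins at or below that threshold. In fixed mode both passes are exact
   linear least squares (the model is linear in (b, χ) after the log
   transform). In knee mode the offset is profiled out analytically and the
   remaining 2-D problem in (log k, χ) is solved by Levenberg–Marquardt;
   because the knee model nests the kneeless one, a second start from the
   straight-line solution is tried whenever the first basin ends up worse,
   and the better optimum is kept.
2. **Peak extraction.** Iteratively take the maximum of the flattened
   spectrum; accept it as a peak while it exceeds
   max(2.0 · SD(flattened), min_peak_height, 1e−9). The SD is that of the
   flattened spectrum *before* any removal: a fixed noise scale, so the
   loop terminates even on spectra whose bin noise is uncorrelated. (The
   1e−9 log₁₀-unit floor suppresses phantom peaks on residuals that are
   zero to machine precision.) The width guess comes from the half-maximum
   crossings (FWHM/2.355), using one side if only one crossing exists and
   the midpoint of the width limits if neither does; tied maxima resolve to
   the lower frequency.
3. **Joint peak refit.** All Gaussians are refit together by bounded
   least squares; each center is constrained to ±2 SD around its guess
   (preventing neighbouring peaks from collapsing onto each other), heights
   to (0, ∞) and widths to the limits.
4. **Final aperiodic refit** on the peak-removed spectrum, then the full
   model and its diagnostics: MAE = mean |data − model| and
   R² = 1 − SS_res/SS_tot, both in log₁₀ power.

Defaults: fit range 2–40 Hz, fixed mode, peak width limits [1, 12] Hz (the
1 Hz minimum equals twice a 0.5 Hz frequency resolution), peak threshold
2.0 SD, min peak height 0, unbounded peak count, robust percentile 2.5.
Solver: relative tolerance 1e−8, at most 5000 function evaluations;
exhausting the budget marks the fit non-converged rather than raising, and
non-converged subjects are excluded from the affected specification's
statistics (both variables of a correlation at once). All of these are
constructor arguments of `SpectralFit`.

**Solver.** Both nonlinear stages use an in-package box-constrained
Levenberg–Marquardt (`specurve._solvers`, numba-compiled with a pure-Python
fallback): damped Gauss–Newton steps with an active-set reduction (a
variable pinned at a bound whose gradient points outward is frozen for that
iteration) and projection of the step onto the box. Termination: step norm below xtol·(1+‖x‖), a negligible cost gain from
a full-size (small-damping) step, five consecutive near-zero gains, or — as
non-convergence — the function-evaluation budget. On noiseless inputs
within the model class it reproduces the truth to ≈1e−9; on the
deliberately hostile 40–60 Hz + knee specifications it can and does flag
non-convergence, which is the behavior the exclusion bookkeeping exists
for.

## PSD estimation

Continuous signals are segmented into 2 s or 5 s epochs with 50 % overlap
(trailing partial windows dropped), demeaned per epoch, tapered, and
Fourier transformed; the PSD is the mean over tapers and epochs of the
one-sided density (interior bins doubled; |X|²/(fs·Σw²) scaling, so the
integrated PSD matches the signal variance). The grid spacing is exactly
1/epoch-length: 0.5 Hz for 2 s, 0.2 Hz for 5 s, restricted to 1–100 Hz.
`dpss` mode uses Slepian tapers with ±1 Hz smoothing — ⌊2·T·W − 1⌋ tapers,
i.e. 3 for 2 s and 9 for 5 s epochs; `hanning` mode a single Hann taper. A
zero-phase 4th-order Butterworth band-pass (0.5–100.5 Hz) is available for
external time series; synthetic signals contain no out-of-band content and
skip it.

## Statistics

- **Age control:** simple OLS residualization of every tested variable on
  age. Default is one pooled regression over all subjects entering a test
  (protecting the group contrast from differential detrending); a
  per-group variant is available (`residualization="per_group"`), since
  descriptions of this step in the field vary between the two readings.
- **Bayes factors:** JZS two-sample t-test BF via the scale-mixture form of
  the Cauchy(0, √2/2) prior (δ | g ~ N(0, g), g ~ InvGamma(1/2, r²/2)),
  leaving a one-dimensional elementary integral evaluated by adaptive
  quadrature; correlation BF by integrating the exact sampling density of r
  against a stretched-beta prior of width 1/3 on ρ. Both prior scales are
  arguments. Evidence categories partition BF₁₀ at 1/10, 1/3, 3, 10
  (half-open at the null side, closed at 3 and 10).
- **Frequentist companions:** pooled-variance (Student) t-test — matching
  the equal-variance assumption of the Bayesian model — and the Pearson
  t-test; signed z = sign(effect)·Φ⁻¹(1 − p/2); Stouffer aggregation
  Z = Σ sᵢzᵢ/√K.
- **Sensitivity analysis:** the smallest d with two-tailed power ≥ target,
  by root-finding on the noncentral-t power function with noncentrality
  d·√(n₁n₂/(n₁+n₂)). For 149 vs 115 at α = 0.05, power = 0.95 this is
  d = 0.4491 (cross-checked against an independent R oracle).
- **Resampling FDR:** thresholds are the observed p-values; E[V(t)] is the
  mean count of permutation-null p ≤ t per resample, FDR(t) =
  E[V(t)]/max(R(t), 1), and a region's adjusted p is the minimum estimated
  FDR over thresholds at or above its own p (which makes adjusted p-values
  monotone in raw p by construction). The point estimator is used; the
  permutation mechanism is group-label (or rating) shuffling.
- **Matched subsampling:** iterative draws of a healthy subsample with the
  subgroup's per-dataset counts, accepted when Bayesian t-tests on age and
  on 0/1-coded gender both give BF₁₀ < 1/3. Two practical facts the
  implementation accommodates: (i) the emulated study's healthy pool is
  empty in one source dataset, so per-dataset targets are capped by pool
  size and deficits reallocated to datasets with spare capacity (largest
  pool first); (ii) below ≈17 subjects per group, BF₁₀ at t = 0 cannot fall
  under 1/3, so Bayesian matching is infeasible for very small subgroups.

## Multiverse and curve inference

The 48 specifications are the Cartesian product (epoch length 2/5 s) ×
(dpss/hanning) × (average-PSD / average-parameters) × (2–40, 40–60,
1–100 Hz) × (knee no/yes), enumerated in that nested order with the listed
option order; the preregistered member is (2 s, dpss, average-PSD, 2–40 Hz,
no knee). Exponents are computed once per (subject, specification) — the
spectral stage does not depend on group labels or pain ratings — and reused
across all permutations; on stored spectra the taper axis cannot alter the
data and shares a cache entry.

Curve inference builds B null curves by shuffling group labels (group
analysis) or pain ratings among pain subjects (correlation), and compares
three statistics with add-one permutation p-values (k+1)/(B+1): the median
effect, the share of specifications with BF₁₀ > 3 and the curve's dominant
sign, and the Stouffer Z. Each curve's statistics are taken in *that
curve's own* dominant direction (for median and Z this is equivalent to
comparing magnitudes). The alternative — evaluating null curves in the
observed curve's direction — doubles the type-I rate, because the
direction is chosen by the data; it remains available as
`observed_direction=True` for comparability with strictly one-sided
descriptions of the method. A median of exactly zero counts as positive.
Inside the permutation loop the BF₁₀ > 3 criterion is translated once per
(n₁, n₂) into an equivalent threshold on |t| (or |r|) — BF₁₀ is strictly
increasing in the statistic's magnitude at fixed n — so null curves need no
quadrature.

The whole-brain analysis applies the frequentist tests per region at the
preregistered spectral settings and adjusts with the resampling FDR; no
multiverse is run over regions.

## Synthetic data

`generate_cohort` emulates the study composition: 149 pain (80 CBP, 33 CWP,
36 other) and 115 healthy subjects by default, drawn across three source
datasets with the study's proportions (healthy participants exist only in
datasets 1 and 3), gender ratios ≈98f/53m and 74f/41m, ages uniform on
18–86. Pain ratings are drawn as a continuous latent N(5, 1.8) clipped to
[0, 10] and rounded to integers (numeric-rating-scale semantics); the
pre-rounding latent is kept in a private column so correlation targets are
defined before rounding.

`assign_ground_truth` realizes per-subject aperiodic parameters:

    χᵢ = 1.10 + age_slope·(ageᵢ − mean age) + 𝟙[pain]·group_d·σ + eᵢ

with σ = 0.16 (the age-independent SD), age_slope = −0.003 per year (a mild
flattening with age, consistent in direction with the aging literature; the
uniform 18–86 age range then contributes ≈0.06, giving a total SD ≈0.17
around a mean of 1.10), and eᵢ constructed so that, within the pain group,
corr(e, standardized latent pain) = pain_rho. `group_d` and `pain_rho`
default to 0 — the null configuration, matching what the motivating study
observed. Offsets are N(1.0, 0.2); the knee defaults to 0; each subject
gets one alpha peak (center N(10, 1) clipped to 8–13 Hz, height N(0.6,
0.15) floored at 0.2, width N(1.5, 0.25) clipped to 1–2.5 Hz).

Spectra come either from the **direct path** — model log₁₀ power plus
i.i.d. N(0, noise_sd) per bin, noise_sd = 0.05 by default (no published
per-bin noise figure exists for spectra of this kind; 0.05 was chosen once
as giving R² ≈ 0.98 fits, the quality real resting-state spectra reach)
— or from **time-domain synthesis**: white Gaussian noise shaped in the
frequency domain by the square root of the model spectrum, so the expected
PSD follows the model exactly. Every generator is a pure function of its
arguments and a seed; per-(subject, region) streams are derived by hashing
the identifiers into a `SeedSequence`.

What the generator does *not* emulate: eye/muscle artifacts, line noise,
electrode-space mixing, volume conduction, non-Gaussian amplitude
distributions, inter-regional correlation beyond shared subject truth, and
any systematic difference in how CWP pain ratings were collected. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis machinery* under a faithful spectral model — not robustness to
real-EEG artifact structure.

## Problem sizes in tests and the acceptance script

The mPFC is represented by 4 opaque region labels (whole-brain mode: 100).
Replicate-study simulations scale down, as their purpose is calibration of
the label-permutation inference, which is downstream of the spectral fits:
they use the direct-spectrum path, 2 regions, 1.0 Hz grids for both epoch
lengths (each epoch length keeps its own noise stream), n = 40/40 null
studies and n = 50/50 for power, B = 200 permutations. The test suite runs
400 null and 20 power replicates; the acceptance script 40 and 10. The
full-size run in the acceptance script uses the complete default
configuration (264 subjects, 4 regions, native 0.5/0.2 Hz grids, B = 500).
FDR control is evaluated on directly generated exponent matrices (100
regions, n = 40/40, B = 200, 100–200 replicates) — the spectral stage is
irrelevant to that property.

## Known limitations

- The Gaussian-peak stage models i.i.d. bin noise less gracefully than the
  smooth spectra it was designed for; on the hostile 40–60 Hz range it may
  fit a few noise peaks (harmless for the exponent, which is refit on the
  peak-removed spectrum).
- `_lm_box` is tuned for the small dense problems it serves (≤ ~20
  parameters); it is not a general-purpose replacement for scipy's
  least-squares solvers.
- The correlation analysis treats rounded 0–10 ratings as continuous, as
  the emulated analysis does; rounding attenuates the realized correlation
  by ≲2 %.
- Bayesian matching cannot certify balance for subgroups below ≈17
  subjects per group (see above) — a property of the criterion, not a bug.
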