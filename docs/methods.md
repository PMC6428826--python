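# Methods

This note documents the models, numerical choices and simulation
conditions behind `prewhiten`, and what the synthetic-data experiments
do and do not demonstrate about real scans.

## The problem being modeled

A task fMRI GLM assumes white errors after high-pass filtering; real
BOLD noise is positively autocorrelated. All mainstream pipelines
therefore (1) fit OLS, (2) estimate a temporal noise covariance `V` from
the residuals, (3) pre-whiten data and design with `W = chol(V)⁻¹` and
refit, then carry the resulting t→z maps into Gaussian-random-field
cluster inference. If `V` under-fits, the contrast variance is
underestimated exactly at the frequencies where the assumed design
lives; for low-frequency block designs this inflates false positives.
The package reproduces this mechanism end to end on data with known
autocorrelation.

## Synthetic data generator

Noise families (per voxel, zero mean, marginal sd `sigma`):

| kind          | autocorrelation at lag k (TR grid)                      |
|---------------|---------------------------------------------------------|
| `white`       | 0 for k ≥ 1                                             |
| `ar1`         | `a^k`                                                   |
| `arma11`      | `rho1 · a^(k-1)`, `rho1 = (1+ab)(a+b)/(1+2ab+b²)`       |
| `ar1_plus_wn` | `(1-w) · a^k` (w = white-noise variance fraction)       |
| `exp_acf`     | `exp(-k·TR/tau)` (generated as AR(1) with `a=e^(-TR/tau)`) |

Series are produced by filtering unit Gaussian innovations through the
ARMA recursion, scaled so the marginal variance is exactly `sigma²`; a
burn-in of `10·max(1/(1-|a|), tau/TR)` samples (minimum 10) is
discarded. Each voxel draws from an independent child stream of the
master seed (`SeedSequence(seed).spawn`), so generation is reproducible
and voxels are independent before optional spatial smoothing. Smoothing
is a Gaussian kernel of the requested FWHM (mm), volume-wise, with the
marginal variance renormalized afterwards; drift is a cosine of period
2× the run plus a linear term (both below the 1/100 Hz cutoff, random
signs from the seed). The default grid is 64×64×33 voxels of
3.1×3.1×3.6 mm, T = 225, TR = 2 s — a typical resting-state acquisition.

Designs: `boxcarK` is K s rest followed by K s stimulus, repeating
(fundamental frequency `1/(2K)` Hz); event designs draw inter-stimulus
intervals uniformly from `[isi_low, isi_high]` (defaults 3–6 s) with
0.1 s events. Task signal is the stimulus timeline convolved with the
canonical HRF on a microtime grid (TR/16, capped at 0.1 s for sub-TR
events), peak-normalized, and scaled by the effect size expressed as
percent signal change against the nominal 100-unit BOLD baseline —
i.e. `effect_size` image units, with noise `sigma` in the same units.

What the generator does *not* emulate: physiological (cardiac or
respiratory) noise, motion, multi-tissue autocorrelation differences,
and scanner nonstationarities. Passing calibration on this generator
shows the estimators are correct *for their own model families*; it
cannot show how far real BOLD noise departs from those families, which
is exactly the question the diagnostic spectra are for.

## HRF and design matrix

Canonical double-gamma HRF: gamma(shape 6, scale 1) minus
gamma(shape 15, scale 1)/6, sampled on [0, 32] s and peak-normalized.
This puts the response peak at 5.00 s and the undershoot minimum at
15.1 s on a 0.01 s grid. (The widely used undershoot shape of 16 puts
the minimum at 15.75 s; shape 15 was chosen so both landmark times
round to their conventional values of 5 s and 15 s.) The temporal
derivative is the finite-difference gradient on the same grid.

High-pass filtering is implemented as an orthonormal DCT basis inside
the design matrix (`k = floor(2·T·TR/cutoff + 1)` columns including the
constant; cutoff 100 s by default), so every method sees identical
filtering. Columns are ordered task, temporal derivative, optional six
motion confounds, intercept, drift terms; the task contrast is the unit
vector on the task column, used one-sided throughout.

## Noise-model estimators

**ARMA(1,1) grid (voxel-wise).** For each voxel, `(a, b)` is chosen
from the grid `{0, ±0.05, …, ±0.9}²` by the exact Gaussian REML
likelihood of the OLS residuals. The likelihood is computed in O(T) per
grid point: applying the AR(1) filter `z_t = y_t − a·y_{t−1}` makes the
covariance tridiagonal (an MA(1) band plus one corner element), so a
banded Cholesky gives the determinant and quadratic form, vectorized
over voxels; the REML terms (`logdet X'V⁻¹X` and the GLS quadratic
form) are computed from the same factors. REML rather than plain ML
matters: the DCT basis removes precisely the low frequencies where the
AR signature is strongest, and an unrestricted likelihood on projected
residuals underestimates `(a, b)` enough to leave ~20% excess
low-frequency power after whitening. Because `b = −a` cancels the AR
pole, ARMA(1,1) contains an exact white-noise ridge; a parsimony guard
keeps `(0, 0)` unless the grid maximum beats the white model by the
χ²(2) likelihood-ratio quantile (default level 0.01), which prevents
null voxels from being assigned arbitrary ridge points. Parameters are
not spatially smoothed.

**Tukey taper (voxel-wise).** The per-voxel biased sample ACF of the
residuals is multiplied by the cosine lag window
`w(k) = (1 + cos(πk/M))/2` and truncated at `M = floor(2√T)` by default
(T = 225 ⇒ M = 30). Tapered ACFs need not be positive definite; when a
Cholesky fails, eigenvalues are floored at 1e−6 of the largest.
Within-mask spatial smoothing of the tapered ACF is available but off
by default (synthetic data has one tissue class).

**Global AR(1)+white noise.** Fisher-scoring ReML of
`V = λ₁ I + λ₂ Q(a)` with the AR(1) kernel fixed at `a = 0.2`
(configurable), fitted to the pooled residual second moment. The
estimation can be restricted to the voxels with unwhitened task
p < 0.001 (`unwhitened_task_selection`), falling back to all voxels
with a log message when the selection is empty or there is no task
column.

**FAST-style dictionary.** `3p` Toeplitz components — for each of `p`
time constants `tau_j` (geometric on `[TR/2, 8·TR]`): `exp(−k·TR/tau_j)`
plus its first and second derivatives with respect to `1/tau` — with
global ReML mixture weights (18 components at the default `p = 6`).
The dictionary is strongly collinear, so the scoring step uses the
pseudoinverse of the expected information (rcond 1e−10), which
truncates the likelihood-ridge directions along which weights drift
without changing `V`; convergence is declared on a relative restricted
log-likelihood change below 1e−6 within 64 iterations, and
non-convergence raises with the last iterate attached.

Whitening uses the inverse-Cholesky convention `W V Wᵀ = I`; voxel-wise
models are applied per voxel, batching voxels that share an ACF (all
voxels in one ARMA grid cell share one transform). The t→z transform is
quantile matching through log survival functions (`ndtri_exp`), exact
and monotone out to |t| ≈ 40.

## Whitening diagnostics

Each residual series is demeaned and scaled to sample variance 1; the
spectrum is `|DFT|²` at the positive frequencies `k/(T·TR)` up to
Nyquist `0.5/TR`, normalized so the mean over frequencies is exactly 1
(Parseval) and white noise sits at 1 in expectation at every bin (for
even T the unpaired Nyquist bin carries half weight, the usual
one-sided periodogram convention). Voxels are averaged within subject,
then subjects with equal weight. Flatness is summarized by per-band
means over `(f_min, Nyquist]`; set `f_min` to the high-pass cutoff
(0.01 Hz) when judging whitening — below the cutoff the drift
regressors null the residual spectrum for every method identically, so
band means there measure the filter, not the noise model. The
regression dip at the assumed design frequency (e.g. 0.05 Hz for
boxcar10) is likewise a design artifact, visible in the spectra by
construction.

## Cluster inference and group models

Smoothness is estimated from the 4D residual maps FSL-`smoothest`
style: residual series are standardized voxel-wise, the pooled lag-1
spatial correlation `rho` along each axis is mapped to a Gaussian-ACF
FWHM via `sigma² = −1/(4 ln rho)` (clipped for `rho ≤ 0`; an iid field
therefore reports FWHM ≈ 0), and
`DLH = (4 ln 2)^{3/2} / Π FWHM_vox`, `resels = V / Π FWHM_vox`. This
estimator recovers a known 3-voxel kernel within ~2% and an 8 mm kernel
within 10%.

Cluster correction is the classical GRF recipe on `z ≥ 3.09` (the 99.9%
normal quantile), 26-connectivity, one-sided: expected cluster count
`E[m] = resels · (4 ln 2)^{3/2} (2π)^{-2} (u²−1) e^{−u²/2}`, expected
suprathreshold volume `E[N] = V·Φ(−u)`, cluster-size tail
`P(S ≥ s) = exp(−β s^{2/3})` with `β = (Γ(5/2)·E[m]/E[N])^{2/3}`, and
corrected `p = 1 − exp(−E[m]·P(S ≥ s))`. On exact Gaussian stationary
nulls this family is calibrated in the continuum regime (measured FWER
0.047 at FWHM 10 voxels on 64×64×33, 500 fields) and mildly
conservative at low smoothness-to-voxel ratios (FWER ≈ 0.02 at FWHM
2–5 voxels) — a documented property of lattice sampling, not of the
implementation; the calibration test therefore runs at FWHM 10, and a
separate test pins the conservative direction at FWHM 2.5.

Group models: the summary-statistic approach is a voxel-wise one-sample
t (df = n−1) on first-level coefficients, t→z, with zero-variance
voxels flagged and assigned `sign(mean)·38`. The mixed-effects model
weights subjects by `1/(se_i² + tau²)` with `tau² ≥ 0` from the REML
fixed-point iteration (50 iterations, DerSimonian–Laird fallback,
logged) and refers the weighted mean to t(n−1). With equal standard
errors and dominant between-subject variance it reduces to the
summary-statistic z — the regime in which scaling all within-subject
variances by 10 changes z by under 5%, i.e. the model responds to the
within/between ratio, not absolute variability.

## Evaluation battery

`BatteryConfig` crosses datasets (each with its own grid, noise, cohort
and assumed-design list) with methods and group models; every
(dataset, design) cell is classified null (rest data, or task data
under a design other than its true one) or true-design. The canonical
study layout — 10 datasets × 16 boxcar designs plus one event-related
dataset × 4 designs, 2 group models × 4 methods — enumerates to 1312
group analyses, 164 per (group model, method) combination, 159 of them
null. The default 16-design list is boxcar10 plus boxcar12…40 in 2 s
steps (only a few of the 16 are pinned by convention; the list is
configurable). Subject seeds are `master_seed + 10⁴·dataset_index +
subject_index` (kept below 2³¹), making the battery bit-reproducible
across process restarts; per-cell errors are caught and recorded in the
report rather than aborting the run.

## Simulation sizes used by the test suite

Chosen so the full suite runs comfortably on one CPU: whitening
calibration uses 5200 voxels at T = 225 per method (band means over
passband quintiles, required within [0.9, 1.1]); the design-frequency
experiment uses 48 synthetic subjects on a 30×30×12 grid with 8 mm
smoothing and AR(1) a = 0.5; parameter recovery uses 48 voxels of
T = 5000 (ARMA grid), 5200 voxels at T = 225 (FAST, ±0.05 on lags 1–10;
AR(1)+WN, ±0.03 on lag 1); FWER calibration uses 500 null fields at
FWHM 10 voxels; type-I calibration uses 4000 independent voxels with
the binomial 95% band.

## Known limitations

- The estimators are faithful to the published *descriptions* of the
  four noise models, not byte-level reimplementations of AFNI, FSL or
  SPM binaries (whose grids, taper lengths and internal expansions are
  partly undocumented); defaults for the unpublished constants are
  exposed as parameters.
- GRF cluster p-values inherit the classical formula's mild
  conservativeness at low smoothness (above).
- The generator's stationary Gaussian families cannot produce the
  heavy-tailed, spatially heterogeneous autocorrelation of real scans;
  conclusions about real-data specificity require the diagnostic
  spectra on real residuals.
- Slice-timing correction, registration, physiological regressors and
  permutation inference are out of scope.
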