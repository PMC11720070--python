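# Methods

This note documents the models, conventions and design decisions behind
`alphatau`: what the pipeline computes, what the synthetic cohort
generator does and does not emulate, and which numerical choices matter.

## Overview

The package reproduces a resting-state EEG (rsEEG) biomarker analysis for
prodromal Alzheimer's disease. Three groups are modeled — cognitively
healthy older adults (Healthy, n = 45), patients with mild cognitive
impairment without CSF evidence of AD (noADMCI, n = 45), and with such
evidence (ADMCI, n = 70). For each subject the pipeline:

1. harmonizes a 19-channel 10–20 recording (band-pass 0.1–45 Hz, 256 Hz),
2. cuts it into non-overlapping 2-s epochs, flags high-frequency artifact
   epochs, re-references to the common average,
3. estimates Welch power spectra (0.5 Hz resolution) and the per-subject
   spectral landmarks — transition frequency TF (3–8 Hz minimum) and
   individual alpha frequency IAF (6–14 Hz peak),
4. builds the individualized eight-band scheme
   (delta = [TF−4, TF−2), theta = [TF−2, TF), alpha1 = [TF, mid),
   alpha2 = [mid, IAF), alpha3 = [IAF, IAF+2) with
   mid = (TF+IAF)/2, plus fixed beta1 [14, 20), beta2 [20, 30),
   gamma [30, 40)),
5. estimates distributed cortical current density with an eLORETA-style
   standardized weighted minimum-norm inverse on a spherical head model,
   normalizes each voxel × frequency-bin value by the grand mean over
   all voxels and 0.5–45 Hz bins, and collapses voxels into five
   Brodmann-area macro-ROIs (frontal, central, parietal, occipital,
   temporal),
6. analyzes the log10 regional activities with a Group × Band × ROI
   split-plot ANOVA, Duncan's multiple-range post hoc, standardized-β
   GLMs against log10 CSF markers (Aβ42, p-tau, t-tau), and iterative
   Grubbs outlier screening.

Because no recordings are publicly deposited, a first-class synthetic
cohort generator supplies subjects and recordings with the statistical
structure the analysis assumes; the generator's defaults encode the
published group-level calibration (sample sizes, CSF means, landmark
means, effect sizes).

## Synthetic cohort generator

### CSF markers under the positivity constraint

CSF analytes are lognormal (right-skewed, strictly positive) with
group-level target means and standard deviations; SDs are back-derived
from the published standard errors as SE × √n because within-group SDs
are not printed. log p-tau and log t-tau correlate at 0.8; log Aβ42 is
independent of both.

Diagnostic grouping imposes a hard constraint: every ADMCI subject has
Aβ42/p-tau below the APOE4-dependent cutoff (15.2 for carriers, 8.9 for
non-carriers) and every noADMCI subject is at or above it. Conditioning
lognormal draws on this event shifts their means — by up to ~10% for
non-carrier ADMCI p-tau — so naive rejection sampling would miss the
calibration targets. The generator therefore solves, per (group, APOE4)
cell, for location parameters such that the *post-constraint* means equal
the targets. The constraint is linear in the jointly normal logs
(s = log Aβ42 − log p-tau < log cutoff), so conditional means of the
lognormals have closed forms
(E[e^x | s < c] = e^{μ_x+σ_x²/2} Φ((c−μ_s−cov(x,s))/σ_s)/Φ((c−μ_s)/σ_s));
two equations are solved numerically for (μ_Aβ42, μ_p-tau) and μ_t-tau
follows directly. Log-variances are held at the values implied by the
target coefficients of variation (the conditional SDs differ slightly
from SE × √n; the means are what the calibration checks).

### Latent spectral parameters and coupling

Each subject carries latent TF, IAF and a log10 posterior-alpha source
power. TF and IAF are truncated normals at the published group means with
SE × √n dispersions, drawn on the 0.5 Hz analysis grid (landmarks are
only ever observed at that resolution) with IAF restricted to
[7, 13] Hz and TF to [3.5, 7.5] Hz with IAF − TF ≥ 1.5 Hz (an
individual alpha range narrower than that cannot host the alpha1/alpha2
split).

The log10 alpha power is
μ_group + σ · (Σ_m ρ_m z_m + √(1−Σρ²) ε), where z_m are the
standardized log-CSF markers (standardization uses the exact conditional
moments under the positivity constraint, per APOE4 cell) and ρ_m the
configured standardized couplings. By construction the population
correlation between log10 marker and log10 alpha power equals ρ_m. The
defaults are ρ_p-tau = −0.367 in ADMCI and ρ_Aβ42 = +0.436 in noADMCI —
the headline association effect sizes — with no coupling in Healthy.
σ = 0.35 (log10 units) makes alpha power span roughly an order of
magnitude across a group, consistent with the large inter-individual
variability of resting alpha. Group geometric means are 1.0 (Healthy),
0.65 (noADMCI) and 0.40 (ADMCI) in source units, encoding the published
posterior-alpha group ordering.

Group MRI thickness markers use the published parietal/precuneus means
and SE × √n dispersions, with modest configurable couplings to z_Aβ42
and z_t-tau; demographics (age, education, MMSE, sex ratio) follow the
published cohort table. MMSE is a truncated discrete draw clipped to
[24, 30] per the inclusion criteria.

### Recording synthesis

Recordings are defined in the frequency domain and mixed through the same
spherical head model the inverse uses:

* **Posterior alpha component** — a constant-amplitude oscillator whose
  instantaneous frequency slowly sweeps the quantiles of
  N(IAF, width²) (width 1.0 Hz, clipped at ±2.5 widths) along a
  triangle schedule with a 15-s period. The epoch-averaged spectrum is a
  Gaussian bump at the IAF while the realization is deterministic up to
  the starting phase, so band powers scale exactly with the configured
  source power rather than fluctuating with a random envelope. A width
  of 0 degenerates to a pure sinusoid (used by analytic-oracle tests).
  The source is a fixed coherent set of radially oriented posterior
  dipoles (parietal, occipital, posterior-temporal).
* **Slow (delta–theta) component** — the same construction, width
  1.5 Hz, total power equal to the group-mean alpha power, co-located
  with the alpha source. Its center frequency is solved per subject
  (1-d root finding on the analytic posterior-sensor spectrum) so that
  the 3–8 Hz minimum of the total spectrum falls exactly at the
  subject's latent TF; without this step the detected-TF mean is biased
  away from the calibration. When no solution exists (very weak alpha)
  the mirror point 2·TF − IAF is used and the detected TF carries the
  boundary-fallback flag.
* **Distributed background** — 40 radial dipoles on a fixed subsampled
  grid share one PSD composed of a shallow 1/f continuum (exponent 1.0,
  level 0.01 at 9 Hz), a low-delta block below ~2 Hz (total power 2.0,
  steep tenth-order roll-off) and a small flat beta–gamma floor above
  ~13 Hz (0.015, EMG-like). The steep delta roll-off keeps the 3–8 Hz
  valley's slope budget intact (the TF location is sensitive to any
  broadband slope there) while carrying most broadband power, which in
  turn keeps the alpha component a modest share of the grand-mean
  normalizer. Because all dipoles share one spectrum, the sensor-space
  background is synthesized directly through the Cholesky factor of its
  spatial covariance — distributionally identical and cheaper.
* **Sensor noise** — white, 10⁻⁴ source units²/Hz.

What this generator does *not* emulate: amplitude waxing/waning of the
alpha rhythm (spindling), ocular/cardiac/movement artifacts beyond
optional high-frequency bursts, inter-channel differences in electrode
quality, non-stationarity, and realistic anatomy. In particular, the
deterministic oscillator envelope means Welch estimates of the
oscillatory bands have far less variance than real data; passing
recovery tests therefore demonstrates calibration and absence of
pipeline bias, not robustness to physiological variability.

## Preprocessing

The 0.1–45 Hz band-pass is zero-phase by construction: the spectrum is
multiplied by the squared magnitude of an order-4 Butterworth band-pass —
the exact response of a forward–backward pass, without edge transients.
Recordings above 256 Hz are polyphase-resampled first; below 256 Hz they
are rejected. Epochs are 2 s, non-overlapping, with the remainder
dropped.

Artifact screening replaces expert visual inspection with an automated
robust threshold: an epoch is flagged when its channel-mean log10 power
in 30–70 Hz exceeds the per-recording median by k = 4 MAD-based standard
deviations. Epochs are flagged, never deleted, so retained fractions can
be reported; only unflagged epochs enter the spectral estimates. The
common average reference subtracts the instantaneous channel mean
(idempotent; applied after screening, matching the screening statistic to
the as-recorded spectra).

## Spectral conventions

Welch segments are the 2-s artifact-free epochs themselves — Hanning
window, no sub-segmentation, no overlap ("no phase shift" is read as no
segment shift). The window is power-normalized so a pure sinusoid of
amplitude A integrates to A²/2. The grid is 0.5–45 Hz at 0.5 Hz.

Landmark detection uses the mean density over the seven posterior
channels (T5, P3, Pz, P4, T6, O1, O2) by default; the landmark
definitions do not themselves fix a channel set, and `all` is available
as a policy. TF is
the 3–8 Hz argmin (a boundary minimum is accepted but flagged); IAF is
the largest local 6–14 Hz peak with plateau ties resolved upward. When no
local peak exists, or the TF–IAF gap is under 1 Hz, the 9 Hz fallback is
used (then the 5.5 Hz TF fallback if needed) and flagged — fallback
counts are reported as a data-quality signal.

Band edges snap to the 0.5 Hz grid (ties upward); bands are half-open
[lo, hi) so the individualized chain delta…alpha3 partitions its union
exactly. The delta lower edge clamps at the 0.5 Hz grid start. When
IAF + 2 > 14 Hz, alpha3 overlaps the fixed beta1 band; bands are always
reported independently and never summed across that boundary. Band power
is the rectangle-rule sum of bins whose centers fall in [lo, hi).

## Source estimation

The head model is an analytic three-shell concentric-sphere conductor
(brain/skull/scalp radii 0.87/0.92/1.0, conductivities 0.33/0.0042/0.33)
with the 19 idealized 10–20 electrodes and a quasi-uniform Fibonacci grid
on a cortical shell (radius 0.79). The spherical-harmonic lead field is
solved per degree with a transfer-matrix formulation (exact for
concentric isotropic shells; validated against the closed-form dipole
potential). Brodmann-area codes are assigned by deterministic angular
sectors (frontal/central/parietal/occipital/temporal regions of the cap)
cycling through each ROI's BA list, so the BA → ROI collapsing logic is
exercised with the published BA sets. This replaces the anatomical
6239-voxel template: the mathematics (linear inverse, bin-level
normalization, ROI means) is preserved, anatomical realism is not — a
documented limitation.

The inverse is the standardized weighted minimum norm with eLORETA block
weights computed by fixed-point iteration (W_j ← (K_jᵀ M K_j)^{1/2},
M = (K W⁻¹ Kᵀ + αH)⁺ on the average-reference subspace); it has zero
localization error for noise-free point sources, which the test suite
verifies by exhaustive scans. Regularization defaults to an SNR-based
scale, α = trace(K W⁻¹ Kᵀ)/(n_ch · SNR²) with SNR = 10. A plain
minimum norm (`method="mne"`) is available for ablation.

The sensor statistic is the per-bin Hermitian cross-spectral matrix
averaged over unflagged epochs (orientation-resolved power needs the
cross terms). Voxel power is the quadratic form summed over the three
orientations. Normalization divides by the grand mean over all voxels
and all 0.5–45 Hz bins (even though bands stop at 40 Hz); ROI × band
values are means over ROI voxels of band-integrated normalized density —
averaging band-integrated values equals integrating ROI-averaged spectra
because both operations are linear.

The batched cohort engine integrates cross-spectra over bands *before*
applying the inverse quadratic form; by linearity this is algebraically
identical to the bin-level path and is verified to machine precision in
double precision. Its default single-precision signal arithmetic agrees
with the double-precision path to ~10⁻⁵ relative and exists purely for
Monte-Carlo throughput.

## Statistics

* **ANOVA** — univariate split-plot design, Group between subjects, Band
  and ROI within, subject as the random blocking factor; error strata are
  subject(group), subject × band, subject × roi and the within-cell
  residual. No sphericity correction is applied by default (a conservative
  choice is available to users who add one downstream).
* **Duncan's multiple-range test** — ordered means compared against
  stepwise critical ranges q_p · SE with protection level
  1−(1−α)^{p−1}; quantiles come from `scipy.stats.studentized_range`
  rather than hard-coded tables (agreement with published table values
  is a test, not a data source). Non-significant stretches protect the
  pairs they span, as the stepwise procedure requires. Unequal group
  sizes use the harmonic mean.
* **Standardized-β GLM** — all variables z-scored with the n−1 SD,
  ordinary least squares, the predictor's coefficient reported with
  t = β/SE and its two-sided p on the residual df. With no covariates
  the β equals the Pearson correlation; covariates (e.g. white-matter
  hypo-intensity) are partialled by inclusion in the design. Perfect
  fits report p at the smallest positive float.
* **Grubbs screening** — iterative leave-one-out extreme-studentized
  deviate test at α = 0.001, critical value from the Student-t quantile;
  constant data yields no outliers; terminates below n = 3.
* **Multiple-comparison families** mirror the analysis exactly: 40
  (8 bands × 5 ROIs) for the post hoc grid, 15 for CSF × EEG (the
  published division by 15 is used even though the text's wording
  implies 10), 6 for CSF × MRI, 10 for MRI × EEG, 9 for the
  neuropsychological battery.

## Monte-Carlo problem sizes

The landmark-recovery checks run one cohort each (70 ADMCI / 45 Healthy)
at the full 5-minute recording length and a 200-voxel grid. The two
coefficient-recovery studies average 500 simulated cohorts each; they use
45-second recordings and a 100-voxel grid, which keeps the full
two-study run to roughly a quarter of an hour on one core while leaving
the estimator's small attenuation (see below) well inside the
calibration tolerance. All randomness derives from one base seed via
counter-based per-subject streams, so any subset of a cohort is
reproducible in isolation.

## Attenuation of the recovered coupling

The recovered standardized β is the configured ρ times the correlation
between measured and latent log alpha activity. That correlation is
eroded by (i) Welch estimation noise (small by the deterministic
envelope), (ii) jitter of the individualized band edges through TF/IAF
detection noise, (iii) leakage floors in the inverse, and (iv) the alpha
component's own share of the grand-mean normalizer, which shrinks the
signal relative to the other noise terms. The generator's noise model
was designed so that the combined attenuation stays within the ±0.02
convergence contract of the latent coupling: measured chain correlations
are ≈0.95 (ADMCI parietal alpha2) and ≈0.98 (noADMCI parietal alpha3)
at the Monte-Carlo problem sizes, giving mean recovered coefficients of
about −0.35 and +0.43 for configured values of −0.367 and +0.436.

## Known limitations

* Spherical geometry and sector-based BA tags: ROI activities are
  stylized; no claim of anatomical localization accuracy is made.
* The generator's deterministic oscillator envelopes understate
  real-world spectral estimator variance (see above).
* TF is only a well-defined spectral feature when the alpha peak is
  strong enough to carve a 3–8 Hz minimum; for the weakest-alpha
  subjects the slow-bump placement falls back and the TF flag is set.
* Subjects with IAF below ~7 Hz are not generated: with the slow
  activity modeled, a sub-7 Hz "alpha" peak merges into the delta–theta
  shoulder and the landmark rules degenerate.
* Real-data ingestion validates channels, sampling rate and the CSF
  positivity rule, but no artifact repair beyond the automated screen is
  provided (no ICA, no channel interpolation).
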