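# Methods

This note documents the models, numerical choices and design decisions
behind `tacdose`, and what the synthetic-data experiments do and do not
demonstrate about real patient data.

## Kinetic models and fitting

A VOI's time–activity curve is modelled as a one- or two-component
exponential washout on top of the fixed physical decay of ¹⁷⁷Lu
(λ_phys = 4.34·10⁻³ h⁻¹, T½ ≈ 159.7 h). All four candidate models carry
exactly two free parameters per VOI: the mono-exponential fits (A₀, λ_bio);
the bi-exponential variants fix one parameter — the fast fraction γ, the
clearance rate λ_bio, or the slow amplitude A₁ — at a population value and
fit the remaining two. Time is in hours, activity in MBq; the
time-integrated activity (TIA) has the closed forms A₀/λ_eff (mono),
A₀γ/λ_eff + A₀(1−γ)/λ_phys (bi1) and A₀/λ_eff + A₁/λ_phys (bi2), with
λ_eff = λ_bio + λ_phys.

Fitting is unweighted nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, analytic Jacobians, tolerances 1e-14). Weighting is
an open methodological question for SPECT TACs; with only two to four points
per curve an estimated noise model would be poorly identified, so the
unweighted objective is the default and only option. Initial values are
deterministic: A₀ by log-linear extrapolation of the first two points,
λ_bio from the log-linear slope of all points minus λ_phys clipped at zero,
γ = 0.9, A₁ = 0.1·A₀; three deterministic perturbed restarts are tried if
the first attempt fails, so fits are reproducible bit-for-bit. Parameter
bounds are A₀ > 0, λ_bio ≥ 0 (pure washout — the data of interest show no
net uptake after day 1; a `FitOptions` switch admits negative λ_bio, with
integration refused when λ_eff ≤ 0), 0 < γ < 1, A₁ ≥ 0.

Standard errors come from the residual-variance-scaled inverse Gauss–Newton
curvature, s²(JᵀJ)⁻¹ with s² = SSE/(n−k); the coefficient of variation of a
parameter is 100·SE/|estimate|. With n = k the fit interpolates and no CV is
reported. Note that the λ_bio ≥ 0 bound makes CV(λ_bio) arbitrarily large
for VOIs whose washout is indistinguishable from pure physical decay; this
is a property of the parametrisation, not a fit failure.

### Population-shared parameters (jackknife)

For each held-out patient, the bi-exponential model is fitted jointly to
every VOI of all other patients, with the shared parameter common across
VOIs and (A₀, rate/fraction) VOI-specific; the parameter vector is
[shared, per-VOI blocks] with an exact block Jacobian. The population value
is the mean of the per-patient estimates, its SD the sample SD. The kidney
fast fraction defaults to the published population value γ = 0.963 rather
than a cohort jackknife, because kidney cohorts are small (two VOIs per
patient); the jackknife estimate remains available.

### Model ranking

Candidates with any failed fit or a maximum CV above 100% are excluded.
Among survivors, all models have the same number of free parameters, so the
mean SSE is the model-quality criterion and ranks first; mean SSEs within
10% relative — differences that are not meaningful for cohort averages over
a few dozen VOIs — are treated as tied and resolved by the mean CV
(precision criterion); if the CVs also tie (1e-3 relative), the model
without a population-shared parameter wins (parsimony). This ordering was
chosen over a CV-first rule after simulation showed CV ordering to be
essentially random between near-equivalent models, whereas SSE separates
the generating model cleanly; it also reproduces the published reference
choices for both tissue classes (mono-exponential for lesions,
shared-γ bi-exponential for kidneys).

## Dose chain

Absorbed dose follows the MIRD self-dose formalism (source region = target
region, appropriate for the short beta range of ¹⁷⁷Lu): D = TIA·S with TIA
converted to MBq·s. S-values are rescaled from their reference masses by
S ∝ 1/m (exact under local energy deposition); reference values are
2.33·10⁻⁵ Gy MBq⁻¹ s⁻¹ for a 1 g unit-density tumour sphere and
7.38·10⁻⁸ Gy MBq⁻¹ s⁻¹ for 310 g kidneys. No recovery correction is
applied — object-shape dependence would make it an additional uncertainty
source. The VOI mass is volume × density averaged over time points
(day-wise segmented volumes drift; a first-time-point option exists), with
density from the linear HU calibration ρ = 7.94·10⁻⁵·HU + 0.964 g/ml
established on a tissue-mimicking CT phantom.

The biologically effective dose uses the linear-quadratic model with
repair: BED = D·RE, RE = 1 + D·G/(α/β), where µ = ln2/T_µ. Defaults:
tumour α/β = 3.1 Gy, T_µ = 1.9 h; kidney α/β = 2.6 Gy, T_µ = 2.8 h. The
Lea–Catcheside factor is λ_eff/(µ+λ_eff) for mono-exponential washout and
the four-term two-component expression (rates λ₁ = λ_eff, λ₂ = λ_phys;
t = 0 dose-rate fractions a₁, a₂ with a₁+a₂ = 1) for bi-exponential
washout; the BED of a bi-exponential fit uses the TIA of that same fit.
Note G is monotone decreasing in µ and increasing under a joint scaling of
both clearance rates, but *not* in each rate separately: raising one rate
with the t = 0 fractions fixed also shrinks that component's share of the
total dose.

The patient-level total tumour dose pools all lesions of one patient:
activity concentrations are averaged per time point (volume-weighted by
default, which makes the pooled curve the ratio of summed activities to
summed volumes; an unweighted mean is available), lesion masses are summed,
the reference model is refitted to the pooled curve and the dose chain
evaluated at the summed mass. Two identical lesions therefore yield the
same BED as one — dose rate per gram is unchanged.

## Sampling-schedule study

Each VOI is refitted on subsets of the nominal acquisition days {1, 2, 3, 7}
(seven predefined reduced schedules) using the same model as the four-point
reference, and scored by RD = 100·(BED−BED_ref)/BED_ref, MD = mean |RD| ± SD,
the fraction within ±10% (inclusive), the fraction overestimated, and
Bland–Altman difference-versus-mean statistics with ±1.96·SD limits.
Nominal days are matched to the nearest sample within ±9 h of 24·day: the
study's actual acquisition times (19, 42, 66, 170 h) sit up to 6 h from the
nominal day marks before jitter, so a ±6 h window would spuriously reject
day-2/3 matches; ±9 h accepts them and stays unambiguous at 24 h spacing.
The kidney shared γ is estimated once (or taken from the literature default)
and reused unchanged for every reduced schedule, so that schedule effects
are not conflated with re-estimation effects. VOIs whose reduced fit fails
are excluded from aggregates and counted.

The outlier diagnostic correlates each lesion's RD with the deviation of
its fitted effective half-life from the patient's mean lesion half-life
(Pearson r plus an OLS line). The half-lives are taken from the fits under
the reduced schedule: that is the quantity actually available when no late
scan exists, and an untypically long fitted half-life flags a lesion whose
dose estimate should be treated with care.

## Synthetic cohorts

The generator emulates a five-patient therapy cohort: 4–15 lesions and two
kidneys per patient, acquisition times 19/42/66/170 h with per-patient
Gaussian jitter (SD 1, 1, 1, 2 h), multiplicative Gaussian noise with CV 5%
truncated at zero (a Poisson option exists). Lesion kinetics default to
mono-exponential with λ_eff drawn uniformly in rate between ln2/160 and
ln2/30 h⁻¹ — matching the observed lesion clearance-rate population
(λ_bio ≈ 0.013 ± 0.006 h⁻¹, typical half-lives near 40 h) with a thin tail
of slow, near-physical-decay lesions — and log-normal A₀ (median 10 MBq,
σ = 0.7). Kidneys are bi-exponential with γ ∈ (0.95, 0.97) and
λ_bio ≈ 0.02 ± 0.002 h⁻¹. Volumes are log-uniform 5–100 ml for lesions
(the isocontour reliability limit is 5 ml) and ≈150 ml per kidney; mean HU
priors are ≈300 (bone lesions, 38/43 of lesions), ≈50 (soft tissue) and
≈30 (kidneys). All randomness flows from one seed; ground-truth parameters
are returned for recovery tests.

Model-selection experiments use cohorts with half-lives restricted to
30–100 h. This is the identifiable regime the published fit precisions
imply (lesion mono CVs ≤ 15%): at the λ_bio → 0 boundary the CV of the
clearance rate diverges and the CV > 100% exclusion rule removes every
candidate, so no ranking exists there.

What the generator does *not* emulate: reconstruction-driven correlated
noise and partial-volume coupling between activity and volume, day-wise
segmentation variability (volumes are constant per VOI), inter-lesion
kinetic correlation within a patient, and net uptake phases before the
first scan. Passing tests therefore demonstrate correctness of the
estimation and comparison machinery under the stated statistical structure,
not clinical accuracy of dose values on real images.

## Phantom analysis

Synthetic sphere phantoms rasterise the six NEMA IEC sphere volumes
(0.52–26.52 ml, centres on a 57.2 mm ring) at 1046 kBq/ml over a 65 kBq/ml
background (16:1) on a 2 mm grid, blur with an isotropic Gaussian PSF and
add Gaussian noise scaled by √intensity — a stand-in reproducing the two
dominant effects (partial volume, count noise), not a SPECT reconstruction
simulation; measured recovery values from real systems are therefore not
reproduced quantitatively, only their qualitative structure (RC → 1 for
large spheres, monotone decline with volume, strong isocontour volume
inflation below 5 ml). CT-style VOIs are analytic spheres of known diameter
(voxel-centre inclusion); isocontour segmentation places a 12 mm seed
sphere at the maximum-concentration voxel within 30 mm of the user hint
(single pass, no re-centring), thresholds at 30% of the seed-sphere mean
and keeps the 26-connected supra-threshold component containing the
maximum. A mask touching the image boundary is flagged degenerate (no
closed contour, e.g. contrast-free images). Recovery coefficients divide
the in-mask mean by the true filled concentration without background
subtraction.

## Numerical conventions and edge cases

- Exact analytic Jacobians everywhere; fits are deterministic given data.
- TIA and Lea–Catcheside closed forms are verified against independent
  adaptive-quadrature oracles to 1e-6 relative over 1000 random draws in
  the test suite.
- γ = 1 is admitted as a degenerate bi-exponential boundary (collapses to
  the mono-exponential result); a₂ = 0 routes through the mono factor.
- Division guards: zero reference BED, zero estimate in a CV, non-positive
  density, empty masks and out-of-grid spheres raise typed exceptions.
- Schedule matching failures (a nominal day without a sample in window) are
  typed errors; in cohort aggregation they become per-VOI exclusions with a
  count.
- Problem sizes in the test suite (500-lesion recovery cohorts, 20-seed
  schedule and selection batches, 2 mm phantom grids) were chosen as the
  smallest sizes at which the checked contrasts are stable.

## Known limitations

- Unweighted least squares may underweight late, low-count time points.
- The jackknife joint fit assumes the shared parameter is truly common;
  heterogeneity (e.g. per-lesion γ) biases the population SD downward.
- The inverse-mass S-value scaling ignores the mass dependence of the
  absorbed-fraction geometry beyond self-dose.
- Single-time-point methods and continuous schedule optimisation are out of
  scope; schedules are restricted to subsets of the four study days.
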