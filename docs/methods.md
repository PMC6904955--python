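# Methods

This package re-creates a longitudinal quantitative-MRI (qMRI) treatment-response
analysis — weekly T2 and ADC mapping of the prostate during a five-fraction
radiotherapy course — as a fully synthetic, testable pipeline.  Because the
clinical cohort it models is not publicly deposited, a digital phantom cohort
with known ground truth stands in for the patient data; every downstream
stage (map fitting, rigid registration, region statistics) is validated
against that truth.

## The phantom and its ground truth

The phantom is a geometric pelvis: an ellipsoidal prostate (semi-axes
23 × 20 × 20 mm) containing an anteriorly shifted central-gland (CG)
ellipsoid so that the posterior crescent forms the peripheral zone (PZ), a
spherical tumor (radius 6.5 mm, ≈1150 voxels at 1 mm) embedded in the PZ, a
body ellipsoid, a urine-filled bladder (long T2, free-water ADC) and a dark
rectum tube.  The bladder and rectum are not analysed; they exist because a
mutual-information registration needs through-plane intensity structure to
pin down rotations about the in-plane axes.

Ground-truth T2 and ADC values are piecewise constant per region at the
population medians (T2: CG 93 ms, PZ 110 ms, tumor 80 ms; ADC for the
fine-voxel dialect: 1.09 / 1.24 / 0.90 ·10⁻³ mm²/s; a second dialect carries
its own ADC table at 1.30 / 1.37 / 1.07), optionally modulated by a smooth
within-region field that is renormalized so the regional *median* stays at
the configured baseline exactly.  Proton density S0 carries an additional
smooth multiplicative texture (CV 0.15, correlation length ≈4 mm) inside all
tissue: real anatomy is not piecewise constant, and without texture the
rotational component of registration is under-constrained.

Per-patient baselines are drawn lognormally around the population medians
with spread matched to the published interquartile ranges.  Treatment
response is a per-week multiplicative factor per (stratum, region, map),
linear from 1.0 at week 0 to the week-5 factor; defaults follow the cohort
medians (hormonal therapy: CG −12 % T2 / −8 % ADC, PZ −17 % / −18 %, tumor
+5 % / +7 %; no hormonal therapy: tumor +20 % ADC, CG −4 % / PZ −5 % ADC;
T2 without hormonal therapy defaults to flat because no cohort-level value
was quantified for that small stratum).  Each patient's week-5 factor is
jittered lognormally (σ = 0.02).  This patient-level spread is deliberately
modest so that a 20-patient cohort estimates the injected effects to within
about one percentage point; real cohorts scatter far more, which is exactly
why the original analysis reports medians and nonparametric tests.  A
side-effect worth knowing: with such tight spread even small injected
effects (−4 % ADC) are sign-consistent across patients and reach Wilcoxon
significance, so the demo cohort's significance pattern is not expected to
mirror a clinical one except where the effects are large; type-I behaviour
is instead verified on flat-effect cohorts.

## Forward simulation

Signals follow the mono-exponential models the fitting stage inverts:
S(TE) = S0·exp(−TE/T2) for the 12-echo spin-echo series (TE = 32…208 ms,
16 ms spacing) and S(b) = S0·exp(−b·ADC) for DWI.  Noise is Rician — the
magnitude of the noiseless signal plus complex Gaussian noise with
per-channel σ = S0_prostate / SNR.  The default quantitative-series SNR is
30; the anatomical T2-weighted scan, a high-SNR turbo-spin-echo acquisition,
uses its own SNR of 100 relative to S0 (≈30 relative to its tissue signal
at TE = 120 ms).

Two protocol dialects are modelled.  Dialect A acquires six b-values
(0–1000 s/mm²) on a coarse 3.0 × 3.0 × 4 mm DWI grid and no echo series;
dialect B acquires b = 0/200/800 on 2.3 × 2.4 × 3 mm plus the echo series.
DWI volumes are simulated on the protocol's *reconstructed* grid
(1.1 × 1.1 × 3 mm and 2.5 × 2.5 × 4 mm), which is where scanners deliver
ADC-ready data; the acquired voxel sizes define the 2.2× voxel-volume ratio
between the dialects.  Quantitative series are formed by sampling the truth
parameter maps onto the acquisition grid (trilinear) and applying the decay
model per voxel, so each voxel's decay is exactly mono-exponential — the
property the fitting validation relies on — at the cost of simplified
partial-volume behaviour at region boundaries.  The anatomical T2-weighted
volume is instead formed in signal space: decay model on the truth grid, a
Gaussian acquisition point-spread (σ = 0.5/0.5/1.0 mm), then resampling.
Without that band-limiting step the sharp truth lattice aliases into the
registration metric and biases recovered rotations by several tenths of a
degree.

Weekly exams are misaligned from the pretreatment frame by random rigid
transforms drawn uniformly within ±5 mm / ±5° and recorded in JSON sidecars
(the transform that maps the exam back onto the pretreatment grid — exactly
what registration must recover).  Weeks 1–5 are each missing with
probability 0.1.  Everything is reproducible bit-for-bit from the seed.

A trajectory-level generator produces per-patient region-median series
directly (same baselines, effects, missingness; lognormal median error
σ = 0.02 standing in for test-retest variation).  It exists for
statistics-heavy experiments — e.g. the 100-replicate null calibration —
where re-simulating images would add hours and no information.

## Map fitting

ADC: ordinary least squares of ln S(b) on b over a perfusion-insensitive
subset (dialect A: 300/500/800; dialect B: 200/800, where the two-point
closed form applies); b = 0 never enters.  T2: weighted log-linear
regression over the 12 echoes.  The default weighting is two rounds of
iteratively reweighted LS with *predicted*-signal-squared weights: weighting
by the measured signal squared (the single-pass textbook choice) correlates
the weights with the noise and biases the median fitted T2 upward by ≈7–10 %
at SNR 20, whereas the iterated weights keep the median within 1 % of truth.
Single-pass and unweighted strategies remain selectable.  Voxels with
non-positive signal or estimates outside (0, 4·10⁻³] mm²/s / (0, 1000] ms
are flagged invalid and excluded from every downstream statistic.

## Registration and propagation

Rigid 6-DOF alignment by histogram-based Mattes mutual information
(50 bins), Euler-XYZ parameterization about the volume center, in three
stages: a 3-level multi-resolution capture at an internal 1.4 × 1.4 × 3 mm
working resolution (random 25 % metric sampling), a full-sampling
scale-space refinement at the working resolution, and an optional
native-resolution polish.  The recovery contract — misalignments up to
±5 mm / ±5° recovered to 0.5 mm / 0.5° on phantom exams — is enforced in the
test suite over 20 random cases.  The pipeline's bulk registrations use the
capture stage only (≈1 s/exam, ≈0.3° typical error): region medians inside
2 mm-eroded masks are insensitive at that level, and the full scheme is
exercised where the contract itself is tested.

Each exam's maps reach the pretreatment frame through composed chains
(b0→exam-T2w ∘ exam-T2w→pre-T2w for ADC; selected-echo→exam-T2w ∘ … for T2)
and are interpolated exactly once, onto a patient-specific 1 mm isotropic
grid bounding the prostate with a 20 mm pad.  Simulated exams are internally
co-registered, so the within-exam links default to identity; the chain
machinery and a manual-override path (the analog of manually adapted
registrations) are implemented and tested.  The echo used for the T2 chain
is the one closest to TE = 120 ms; the 112/128 ms tie breaks to the earlier,
higher-signal echo.

## Region statistics

CG is derived as prostate AND NOT PZ (PZ voxels outside the prostate are
clipped with a warning).  Each region is eroded by a 2 mm Euclidean-distance
margin on the 1 mm grid.  Note that a voxel-center distance transform cannot
reproduce continuous erosion exactly: eroding a rasterized 6 mm ball by 2 mm
yields neither the rasterized 4 mm ball's voxel count under any threshold
convention; the implementation uses the literal rule (distance to the
nearest background voxel strictly greater than the margin), and the tests
bound the discrepancy to a one-voxel shell.  Medians are taken over valid
voxels only; an empty intersection yields a missing value, never zero.

Weekly medians are normalized to week 0.  Interior missing weeks may be
linearly interpolated for display and population medians; interpolated
points are flagged and never enter significance tests or persistence calls,
and nothing is extrapolated past the last measured week.

## Statistics

Patients enter the ADC analysis with ≥3 of 6 exams, one DWI dialect
throughout, and a pretreatment ADC; the T2 analysis additionally requires a
pretreatment T2 map.  The test battery is fixed at nine paired Wilcoxon
signed-rank tests (T2 × {CG, PZ, tumor} in the hormonal-therapy stratum;
ADC × 3 regions × 2 strata) of pretreatment vs week-5 medians, judged at the
Bonferroni level 0.05/9 (displayed 0.0056; compared unrounded).  Patients
missing week 5 contribute their last measured week, flagged as an imputed
endpoint; a strict drop-those-patients policy is available and both are
reported.  The Wilcoxon null is computed exactly for n ≤ 25 by convolving
the tie-aware rank distribution over all 2ⁿ sign assignments (zeros
discarded by the classical convention; a Pratt-style option retains their
ranks); larger n falls back to the tie-corrected normal approximation.

Persistence per patient/region/map: a change is persistent when some
measured week's normalized value leaves the test-retest repeatability
interval (11 % for T2, 47 % for ADC) and every later measured week stays
outside on the same side through the endpoint.  The strict sustained
definition is used: a transient excursion that returns inside the interval
does not count, and the classifier is provably monotone in the threshold.

## Problem sizes and noise floors

The default study configuration is 20 patients (10 per stratum — the
smallest strata in which the exact Wilcoxon can reach p < 0.0056), SNR 30,
dialect B, 10 % missing weeks.  The eroded tumor holds ≈100 effective DWI
voxels, so a single exam's tumor-ADC median carries ≈2 % sampling noise at
SNR 30; per-exam agreement with truth below that level is not achievable by
any estimator, which is why registration-error isolation compares the same
exam under estimated vs true transforms.  The 100-replicate type-I
calibration of the nine-test battery runs on the trajectory-level generator.

## Known limitations

No k-space simulation, B0/B1 inhomogeneity, EPI distortion, or prostate
deformation/swelling (the analysis is rigid by design); no IVIM/kurtosis or
multi-compartment T2 behaviour; quantitative series use parameter-space
sampling, so cross-boundary partial volume is simplified; the phantom's
anatomy is geometric, so passing tests demonstrate correctness of the
estimators and plumbing under the stated noise model, not performance on
clinical images.
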