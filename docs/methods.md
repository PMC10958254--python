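# Methods

## Scope and data model

The package consumes binary per-B-scan segmentation masks of the three
CAM-defined constituent features of geographic atrophy — RPE loss,
photoreceptor degeneration (PRD) and hypertransmission (HTR) — for OCT
volumes of nominally 6×6×2 mm³ with at least 25 B-scans. Probability
thresholding, the segmentation model and fovea localisation are upstream:
masks and a recorded fovea position are inputs. Volumes below the
25-B-scan floor are excluded; when one eye-visit has several
acquisitions, the one with the most B-scans is analysed, ties broken by
the lexicographically smallest acquisition identifier so selection is
order-independent.

On disk a volume is a multi-page TIFF (one 8-bit 0/255 page per B-scan)
with a JSON sidecar `<stem>.meta.json`. Coordinates: raster row 0 is the
superior-most B-scan; physical positions are mm from the volume's
superior-temporal corner; all indices 0-based.

## En-face reduction and composite features

An en-face pixel (one row per B-scan, one column per A-scan) is true iff
any voxel of that A-scan's mask column is true. Composites are pixelwise
boolean algebra — RORA = RPE ∧ PRD ∧ HTR; isolated PRD = PRD ∧ ¬RPE ∧
¬HTR; intact macula = 6 mm disc ∧ ¬(RPE ∨ PRD ∨ HTR) — so the partition
identities (PRD splits exactly into isolated and overlapped parts; intact
macula is the exact disc complement of the feature union) hold by
construction and are asserted in tests.

Areas, the primary endpoint, are counted on the native anisotropic grid
(row pitch = B-scan spacing, column pitch = A-scan spacing): no
inter-B-scan interpolation or resampling touches the endpoint. The
consequence, documented rather than hidden, is a small positive bias of
order perimeter × B-scan spacing / 2, because a band containing any
positive voxel marks its whole row height; it largely cancels in
change-from-baseline. Nearest-neighbour resampling to 0.01 mm isotropic
pixels is used only where geometry demands it: ETDRS masks, morphology,
registration.

## ETDRS topography

The grid is three fovea-centred circles of radius 0.5/1.5/3.0 mm split by
the ±45° diagonals into a central subfield, four inner and four outer
quadrants (default numbering 1; 2–5 inner superior/nasal/inferior/
temporal; 6–9 outer likewise — the numbering is configurable because no
universal convention exists). Nasal/temporal assignment follows
laterality, so left-eye grids mirror right-eye grids exactly. Pixels are
assigned by centre with strict radius inequalities and half-open angular
bins: the nine subfields partition the disc exactly, making disc
occupancy the exact area-weighted mean of subfield occupancies.

Ring naming follows the source study's usage — foveal (1 mm disc),
perifoveal (1–3 mm), parafoveal (3–6 mm) — which inverts the more common
parafoveal/perifoveal order; the names carry their mm ranges to avoid
ambiguity. Occupancy is 100 × area(feature ∧ region)/area(region).

Because the 6 mm disc is exactly inscribed in a 6×6 mm field, any
off-centre fovea clips the outer quadrants slightly. Clipping up to 5% of
a region's analytic area is tolerated (at the default 0.05 mm fovea
jitter this admits ~5σ excursions); beyond that the grid constructor
raises, naming the truncated regions.

## Morphometrics

Focality is the number of 8-connected components of the en-face RORA map
(diagonal bridges of a growing lesion must not split the count).
Components under 0.05 mm² (configurable) are excluded from focality and
perimeter as noise specks but retained in total area. Perimeter is the
summed sub-pixel contour length of retained components: marching squares
at level 0.5 on a Gaussian-smoothed (σ = 1.5 px) copy of each component.
The smoothing matters — on a raw binary raster the 0.5-level staircase
overestimates a smooth curve's length by ~6%, while the smoothed level
set tracks a rendered circle's circumference to <0.5% at 0.01 mm/px.
Contours are extracted per component inside padded bounding boxes, so
perimeter is exactly additive over disjoint lesions.

## Longitudinal registration

Translation-only, matching a workflow anchored on fovea localisation:
each follow-up is shifted so its recorded fovea lands on baseline's, then
refined within ±0.25 mm (integer pixels, evaluated in one FFT
cross-correlation) to maximise binary RORA overlap with baseline, ties
broken by the smallest shift. The aligned series carries a consensus
fovea — the mean of per-visit foveae mapped into the aligned frame —
which averages independent per-visit localisation jitter and is what the
simulator-based test checks (consensus error < raw per-visit RMS).
Rotation and scale are deliberately out of scope.

## Trial endpoints

The response is √area(t) − √area(baseline) in mm; baseline rows are
excluded from the fit. Fixed effects: treatment arm and visit
(categorical), their interaction, and the centred baseline RORA area with
visit-specific slopes — the full-rank equivalent of a baseline main
effect plus a visit×baseline interaction. A random intercept per eye
captures within-eye correlation; estimation is REML (statsmodels
MixedLM; an lbfgs→bfgs→powell fallback guards against optimizer
excursions). Eyes missing a visit contribute their observed rows; there
is no imputation. The baseline covariate is internally scaled to unit
variance for conditioning; LS means are evaluated at the grand-mean
baseline, where the scaling cancels.

LS means and sham contrasts use Wald z inference. No denominator-degree-
of-freedom correction (Satterthwaite/Kenward–Roger) is applied — a
deliberate choice for reproducibility without package-specific df
approximations; at the simulated trial sizes (≥90 eyes) the simulation
suite shows type-I error within [0.02, 0.09] at α = 0.05, and the known
treatment effect is covered by the contrast's 95% CI in ≥90% of
replicates. Baseline arm comparability uses the two-sided Wilcoxon
rank-sum test, appropriate for the non-normal baseline area
distributions. Percent reduction is 100 × (1 − active/sham), rounded to
integer for reporting; it is scale-invariant.

## Growth prediction

Per-eye growth to month 12 regressed on baseline PRD/RPE-loss ratio,
isolated PRD area and intact macula area (OLS). "Bootstrapped R²" is
read as refitting on 100 eye-level resamples with replacement and
reporting the mean and 2.5–97.5 percentile interval of the per-resample
R²; coefficients get percentile intervals from the same resamples, and a
single identity resample reproduces the in-sample fit exactly. Growth can
be measured as √area change (mm, default — the scale of the trial
endpoint) or raw area change (mm²); both are supported because the two
are not equivalent and sources differ, and the choice is recorded in
every report. Quartile stratification uses sample quartiles with values
equal to a cut assigned to the lower quartile (deterministic); summaries
are n/mean/SD/median of growth per quartile plus the Spearman correlation
of quartile index against quartile means.

## The synthetic cohort

The simulator is the package's stand-in for trial imaging; it defines the
study conditions under which everything is validated.

Growth law: per eye, √area(t) = √area(0) + m·g·(t/12), with g the sham
rate 0.277 mm/yr and m the arm multiplier (sham 1, every-other-month
0.202/0.277 ≈ 0.73, monthly 0.151/0.277 ≈ 0.55 — the ratios of the
published 12-month means). Rendering thresholds an offset distance field
min_j(|x − s_j| + o_j) over k seed points, with the radius solved so the
mask hits the target area exactly (up to pixel ties); foci are nested in
the radius, so lesions merge but never split and the affine √area law
holds to pixelisation error at every visit. Seed count is drawn from a
truncated geometric on 1–12 with mean 3.14 (the observed focality
distribution); the first focus is dominant (offset 0) and satellites
carry offsets of 0.3–0.9 mm so they render smaller, as in real multifocal
GA. Rendered focality at baseline is somewhat below the seed-count mean
because nearby foci have already merged — a property of the growth
model, not a bug. PRD is the RPE-loss region dilated by a 0.25 mm halo
(so isolated PRD is the halo annulus and PRD ⊋ RPE loss); HTR equals RPE
loss with boundary pixels retained with probability 0.95 (interior always
retained, keeping the RORA oracle exact at agreement 1). The recorded
fovea is jittered by N(0, 0.05² mm) independently per visit; the true
fovea is the field centre.

Defaults not fixed by the growth law are calibration choices: baseline
√area ~ Normal(2.6, 0.6²) mm truncated to [1.26, 4.07] (reproducing a
7.0 mm² mean and the observed 1.6–16.6 mm² range), between-eye growth a
lognormal multiplier with CV 0.4 (consistent with reported growth SDs ≈
40% of the mean), and — in the tabular generator only — per-visit
measurement noise of SD 0.10 mm on the √area scale, chosen so the
12-month sham SD of √area change is ≈ 0.21 mm. All randomness splits
from one root seed per eye via `SeedSequence` spawn keys, so cohorts are
bitwise reproducible and independent of iteration order.

Two granularities: `simulate_cohort` renders full B-scan volumes
(pipeline validation; the fidelity suite uses 30 rendered eyes), and
`simulate_growth_table` draws measured √area trajectories directly
(statistical calibration at 200 simulated trials, where rasterising
every eye would add nothing). Simulated lesions are compact
disc-like foci: they do not reproduce the irregular outlines of real GA,
so absolute perimeter values (real lesions: ~24 mm mean at baseline) are
not matched — perimeter accuracy is instead validated against analytic
circles. Passing tests demonstrate correctness of the measurement and
inference machinery under the configured growth model, not performance
on real OCT, and nothing here validates the upstream segmentation.

## Problem sizes and numerical choices

Default raster 600×600 px (0.01 mm), 49 B-scans, visits 0/2/6/12/18
months. Calibration suites use 200 null trials at 30 eyes/arm and 50
effect trials at 60 eyes/arm (tabular), 30 rendered eyes for simulator
fidelity, and 1,000 random rasters against the brute-force set-algebra
oracle. Bisection-free area solving uses one sort of the distance field
per eye and a searchsorted threshold per visit. Degenerate inputs error
loudly: empty candidate lists, missing baselines, empty arm×visit cells
(named), rank-deficient predictor sets (collinear pair named), anisotropic
rasters passed to morphology, translations that leave the raster.
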