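# Methods

This note documents the models implemented in `radrisk`, the numerical and
design choices behind them, what the synthetic cohorts emulate, and the
limits of what the test suite can show about real clinical data.

## Dose model and plan summation

A treatment course is a fractionation scheme (n fractions of d Gy) plus a
per-organ voxel dose vector on a uniform grid. Courses with different
fractionation are made comparable through the linear-quadratic biologically
effective dose, BED = n·d·(1 + d/(α/β)), with α/β = 3 Gy for late-responding
tissue throughout the package (a parameter of every conversion function, so
other tissues can be modelled). The protracted-irradiation (incomplete
repair) correction is deliberately absent: the brachytherapy boost modelled
here is high-dose-rate, where that correction is negligible.

Voxels off prescription are handled by **proportional fractionation**: a
voxel at total dose D in an n-fraction course receives D/n per fraction —
every voxel is treated in all n fractions, with a locally scaled fraction
dose. This is the standard assumption and makes the fractionation-adjusted
quantities (BED, the Schneider α′·D product) exact per voxel. It also means
a simultaneously integrated boost needs no separate course: boost voxels of
a 28 × 1.8 Gy course that carry 28 × 2.14 Gy in total automatically get
2.14 Gy per fraction.

Multi-course plans are summed voxelwise in BED space and reported as EQD2
(the equivalent total dose delivered in 2-Gy fractions, "BED2"). A summed
distribution carries a sentinel scheme (`None`) meaning "2 Gy per fraction
in every voxel"; its BED is recovered exactly as D·(1 + 2/(α/β)), which
makes summation exactly associative and commutative. Physical-dose summation
is available behind a flag; the pipeline uses it for the plan dose
statistics (see below). Grids are assumed pre-aligned — image registration
is an input contract, not a feature.

**DVHs** are differential, over half-open bins [a, b) starting at 0 Gy, with
fractional volumes (percent only at the reporting layer). The bin dose is
the midpoint; the default width of 0.1 Gy keeps the binning error in
EUD/NTCP well below 0.1% at clinical dose levels. Two consequences worth
knowing: every DVH-derived dose is biased by at most half a bin width, and a
strictly zero-dose organ still lands in the first bin (midpoint 0.05 Gy), so
DVH-routed risk figures have a floor of the corresponding half-bin risk. The
pipeline therefore takes organ mean doses from the voxel vector directly
(exact), and uses the DVH only where the models genuinely need one. D_y% (the
minimum dose to the hottest y% of volume) is interpolated linearly on the
hottest-first cumulative curve over occupied bin midpoints and clamped to
the occupied dose range; V_x is the volume fraction in bins with midpoint
dose ≥ x.

## LKB normal tissue complication probability

EUD = (Σᵢ vᵢ·Dᵢ^(1/n))ⁿ over the differential DVH; n = 1 (parallel organ)
reduces exactly to the mean dose, n → 0 approaches the maximum dose (serial
organ). The generalized mean is evaluated in log space so that strongly
serial exponents (1/n large) do not overflow. Zero-dose bins contribute
exactly zero and are skipped, avoiding the 0^(1/n) edge case.

NTCP = Φ((EUD − D₅₀)/(m·D₅₀)) with Φ the standard normal CDF evaluated in
closed form via the complementary error function — mathematically identical
to the defining Gaussian integral but exact to machine precision and fast.
NTCP(D₅₀) = 0.5 exactly.

Parameters ship as a versioned YAML registry keyed (organ, endpoint), with
the two lung pneumonitis rows preloaded; the same rows are applied to the
ipsilateral and the whole lung, as is common practice when no whole-lung
refit is available. The DVHs entering the model are the EQD2-summed ones —
the biologically accumulated dose is the natural input for a late-toxicity
dose-response; this is a modelling choice, and the physical-dose pathway
remains available through `sum_courses(..., mode="physical")`.

## Schneider secondary-cancer risk

EAR(D, age_x, age_a) = δ·RED(D)·μ(age_x, age_a) per 10,000 person-years.
The age modifier μ = exp(γe·(age_x − 30) + γa·ln(age_a/70)) equals 1 at the
reference ages (exposure at 30, attained age 70). Out-of-field (below ~20%
of the prescription isodose) RED(D) = D: the linear no-threshold form on the
mean organ dose, which is how measured out-of-field doses enter. In-field,

    RED(D) = e^(−α′D)/(α′R) · [1 − 2R + R²·e^(+α′D) − (1−R)²·e^(−α′DR/(1−R))]

with α′ = α + β·(d_T/D_T)·D (so α′·D is exactly α·BED under proportional
fractionation), β derived as α/(α/β) with α/β = 3 Gy, and repopulation
capacity R ∈ [0, 1]. The sign of the R² exponential is the one consistent
with the low-dose limit RED → D (the model must degenerate to LNT there);
this limit is verified numerically in the tests. Near the boundary
(|R| or |1 − R| < 10⁻⁶) the analytically equivalent closed forms replace the
general bracket, which is numerically singular there: R → 0 gives the pure
cell-kill bell D·e^(−α′D), R → 1 the plateau (1 − e^(−α′D))/α′. RED(D) ≤ D
for all parameters.

For multi-course plans the exposure is accumulated as α′D = α·BED summed
over courses. On the EQD2 scale this is a constant effective
α′ = α·(1 + 2/(α/β)), which the organ-equivalent-dose routine applies when
given a summed (sentinel-scheme) DVH. This choice is self-consistent with
the linear-quadratic framework and reduces exactly to the single-course
formula for one course.

Organ routing mirrors the dose regimes: the ipsilateral lung (and optionally
the heart) is in-field and uses the full model on the summed DVH; the
contralateral lung and breast are out-of-field and use LNT on a measured (or
synthetic) mean organ dose. The penumbra boundary between the regimes is not
operationally sharp; the two routes are best read as lower and upper
anchors. EAR stays on the per-10,000-PY scale everywhere.

## Cardiac risk (Darby)

ERR of major coronary events = 0.074 per Gy × mean heart dose, linear and
without threshold, with cumulative risk = baseline·(1 + ERR) (clamped at 1
with a warning) and the exact inverse ERR = cumulative/baseline − 1. The
slope is calibrated on physical mean heart dose, so the pipeline feeds it
the physically summed Dmean, not the EQD2 value. ERR is a dimensionless
fraction internally; percent only in reports.

## TLD aggregation and photoneutrons

Mean organ dose = (mean(readings) − mean(background)) × n_fractions.
Background (dosimeters kept outside the treatment room) is averaged once and
subtracted from each reading, so per-dosimeter full-course doses can be
reported alongside the organ mean (with SD and range). Negative nets are
floored at zero — absorbed dose cannot be negative — with a warning when
background dominates. A single dosimeter lying barely in-field can inflate
the organ mean several-fold; `outlier_excluded_mean` recomputes the
aggregate over retained readings, and the pipeline reports both values
(exclusion is applied before risk conversion by default, since the inflated
value reflects dosimeter placement, not organ burden).

The photoneutron chain multiplies: 18-MV dose = fraction × prescription;
× a neutron organ-equivalent-dose coefficient (4 mSv per Gy); × an IMRT
fluence factor (3); ÷ a linac emission ratio (2.5). mSv and mGy are treated
as numerically equal — this is an order-of-magnitude argument whose default
inputs (20% of 60 Gy) end at ~58 mSv, about 1‰ of the prescription,
justifying the neglect of neutrons in the risk models.

## Synthetic cohorts

No clinical dose grids are available, so the generator emulates the **study
conditions**: four scenarios (3D-CRT + sequential 5 × 2 Gy boost,
3D-CRT + 2 × 6 Gy brachytherapy, IMRT + 2 × 6 Gy brachytherapy, IMRT + SiB
28 × 1.8/2.14 Gy) with default cohort sizes 10/8/10/10 (38 patients — the
3D-CRT + brachytherapy cohort is smaller because that technique was being
phased out during the study window the conditions emulate).

Realism is DVH-level, not spatial: voxel doses are exchangeable draws —
every downstream model consumes DVHs or mean doses, so geometry would add
cost without information. Each organ's course dose is a three-component
mixture: an in-field component normal around the prescription (±5%), a
penumbra component uniform between 20% and 80% of prescription, and an
exponential out-of-field tail. Component fractions vary per patient (normal
draws around configured means); the whole vector is then rescaled so the
organ Dmean equals a truncated-normal patient draw whose mean/SD are the
scenario calibration targets transcribed into `data/scenarios.yaml` (TPS
dose statistics for the summed plans; full-course TLD organ doses per breast
size). Calibration targets are data, not code — editable without touching
the generator. Brachytherapy boosts deposit only a small exponential tail in
the organs at risk (steep Ir-192 falloff); teletherapy boosts add a
proportionally scaled copy of the in-field pattern. Defaults: 5,000 voxels
per organ (binning error far below model differences, seconds to run),
0.125 cm³ voxel volume.

TLD readings are lognormal around the configured per-fraction organ dose
(CV 10%, mean-preserving) plus an ambient background of 0.2 mGy per plan;
three background dosimeters scatter around the ambient level alone. For the
large-breast ipsilateral-lung setup one "barely in-field" outlier reading
(12× the true dose) is injected by default, reproducing the qualitative
feature that motivates the outlier-exclusion path.

Randomness: numpy PCG64 seeded via `SeedSequence([seed, scenario, patient,
organ])`, so datasets are bit-reproducible and extensible without
reshuffling existing patients; the manifest records seed, generator version
and configuration hash.

**What passing tests do and do not show.** The generator reproduces
cohort-level mean-dose structure and DVH character, not patient anatomy:
correlations between organs within a patient, realistic spatial dose
gradients, breathing motion, and the anatomy-driven tails of real DVHs are
absent. Recovery tests therefore validate the computational chain
(summation, binning, model evaluation, statistics) under controlled
conditions — they do not validate the epidemiological models themselves, nor
predict absolute risks for any real patient.

## Statistics

Scenario groups are compared with a normality-gated unpaired test:
Shapiro–Wilk at α = 0.05 on each group (standard and appropriate at n ≈ 10);
if both pass, Welch's unequal-variance t-test, otherwise the Mann–Whitney U
test with tie-corrected normal approximation, two-sided throughout.
Constant groups cannot be tested for normality and fall to the Mann–Whitney
branch with a warning; two identical constant groups report p = 1. The
Mann–Whitney U is used rather than the signed-rank test because the cohorts
are independent. Raw pairwise p-values are reported to match the
small-study reporting convention; a Holm-corrected column is emitted as a
clearly labelled extension. Pooled technique comparisons (IMRT vs 3D-CRT,
brachytherapy vs teletherapy boost) use size-weighted means Σnᵢmᵢ/Σnᵢ,
equal to the mean of the concatenated values.

Summaries are boxplot-style: mean ± SD, min–max, quartiles, whiskers at
1.5 × IQR, outliers listed. Table cells round to one decimal (doses, %,
ERR) and to integers (EAR per 10,000 PY).

## Problem sizes

The default study is 38 patients × 4 organs × 5,000 voxels and runs in a few
seconds. The recovery checks in the test suite use a 200-patient cohort at
1,500 voxels per organ and a 2,000-replicate null simulation for the type-I
error of the gated test — sizes chosen so Monte-Carlo error is small against
the tolerances being checked while the whole suite stays fast on one CPU.

## Known limitations

* Registration, DICOM-RT parsing and dose calculation are out of scope;
  inputs are plain-text voxel vectors on pre-aligned grids.
* The LKB input scale (EQD2 vs physical summed dose) is a modelling choice;
  both pathways exist, the pipeline defaults to EQD2.
* Out-of-field EAR from only a few phantom setups per scenario carries
  measurement variation that is reported separately from patient-anatomy
  variation, not folded into one SD.
* No latency modelling for cardiac risk, no EAR→ERR baseline conversion
  beyond the single inverse worked example, no tumour-control or
  target-coverage endpoints.
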