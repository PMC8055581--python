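# Methods

This note documents the models implemented in `adipometry`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Prediction systems

All coefficients live in `src/adipometry/data/skinfold_coefficients.yaml`,
each entry annotated with its source; code is generic over the registry, so
correcting a transcription is a data edit, never a code change.

**Slaughter** (triceps + medial calf, linear): FP = a·Σ₂ + b with
(a, b) = (0.610, 5.1) for girls and (0.735, 1.0) for boys. Only the
triceps+calf variant is implemented; the triceps+subscapular quadratic
variant and its >35 mm correction are out of scope. Maturation-specific
intercepts for boys are not applied.

**Durnin & Rahaman** (adolescent coefficients): body density
D = c₀ − c₁·log₁₀(Σ₄) over triceps, biceps, subscapular and suprailiac,
with (c₀, c₁) = (1.1369, 0.0598) girls / (1.1533, 0.0643) boys. The
registry schema supports age bands should adult coefficients ever be
added; the shipped entries are the adolescent set matching this package's
target age range (13–17 y).

**Johnston**: same functional form, (1.1440, 0.0610) girls /
(1.1660, 0.0706) boys.

**Siri conversion**: FP = (4.95/D − 4.50)·100. Exact fixed points — D = 1.1
(lean tissue) gives 0 % and D = 0.9 (fat tissue) gives 100 % — are asserted
to 1e-9 and define the physiological density band (0.9, 1.1).

**Lohman** (age, sex, weight, triceps + suprailiac):
FP = b₀(sex) + b₁·Σ₂ + b₂·weight + b₃·age. This is the least certain
registry entry: the primary coefficient table could not be consulted, so
the shipped values were fixed once to place outputs in the range this
equation family produces for athletic adolescents (≈38 % girls, ≈34 %
boys — 12–15 points above the density-based systems, reproducing its
well-known overestimation on such cohorts). Users with access to the
primary source should override the registry; nothing else changes.

Out-of-range predictions (<0 or >100 %) are returned raw with a warning.
Agreement statistics must see the uncensored value; clamping would bias
the Bland–Altman estimates.

## Five-component fractionation

Constants are in `src/adipometry/data/phantom_constants.yaml`. Each
variable is z-scored against the Phantom reference human (stature
170.18 cm) with dimensional scaling (exponent 1 for folds/girths/breadths,
3 for mass); each component averages its variables' z-scores and
back-transforms through the phantom component mass, scaled by
(stature/170.18)³.

Partition shipped (a registry-level reading of the five-way method; a
different reading is a registry edit):

- *adipose*: six folds (triceps, subscapular, supraspinale, abdominal,
  front thigh, medial calf);
- *muscle*: fold-corrected girths (girth − π·fold/10) for arm, thigh,
  calf and chest, plus the uncorrected forearm girth;
- *bone*: head girth plus biacromial, biiliocristal, humerus and femur
  breadths;
- *residual*: waist girth plus anteroposterior and transverse chest
  breadths, scaled by stature like the other components;
- *skin*: body-mass z-score (a surface-area proxy; skin mass co-varies
  with body size).

Sitting height is part of the method's declared input set and is required
for a record to be fractionated, although the shipped partition does not
consume it directly.

The adiposity→fat-percentage conversion is exposed both as the explicit
five-step chain (adiposity → fat mass → lipid fraction
LF = 0.327 + 0.0124·%Adip → lipid mass → fat % of weight) for
auditability, and as the collapsed identity FP = %Adip·LF; tests assert
they agree to 1e-12, and that the chain is independent of body mass (it
cancels algebraically).

Negative component masses are flagged with a warning, never clamped; at
the generator's default settings the flag rate is zero (asserted across
seeds).

## Agreement statistics

**ICC.** The source study for this design family does not state its ICC
model, so the default is two-way, absolute agreement, single rater
(McGraw & Wong ICC(A,1)) — the form appropriate when a method must
reproduce the criterion's *values*, not merely rank subjects — with the
consistency form ICC(C,1) selectable. Confidence intervals use the
standard F-based formulas; negative estimates and negative lower bounds
are reported as computed (they are meaningful under absolute agreement
with a large offset). The implementation is validated two ways: against a
brute-force ANOVA-table oracle on random small vectors (1e-8) and against
`pingouin.intraclass_corr` (point estimates to 1e-10; CIs to pingouin's
printed precision).

**Classification.** poor < 0.40 ≤ moderate ≤ 0.75 < good/excellent. Both
boundary values fall to moderate, following the usual wording ("below
0.40", "over 0.75").

**Bland–Altman.** Differences are criterion − prediction, so a system that
overestimates fat shows a *negative* bias. SD uses n−1; limits of
agreement are bias ± 1.96·SD by exact identity (multiplier configurable
for sensitivity analyses). The per-subject (mean, difference) coordinates
are retained and exported so any plotting tool reproduces the agreement
plots.

**Reports.** Listwise exclusion per equation, never imputation; excluded
counts and absent strata (n < 3) are recorded as diagnostics on the
report. Descriptive summaries always emit both mean/SD and
median/quartiles; the normality-based display choice belongs to the
caller.

## Synthetic cohorts

The generator emulates a mixed-sex adolescent-athlete cohort: n = 101,
50.5 % female, ages uniform on 13–17. Per sex: stature normal (medians
160.5 / 168.3 cm, SD 6 / 9 cm), body mass log-normal moment-matched to
50.9 ± 8.6 kg (F) / 56.1 ± 13.8 kg (M) and correlated with stature (0.6
on the latent scale); sitting height = 0.52·stature + N(0, 1.5²).
Skinfolds are equicorrelated log-normal (ρ = 0.7, log-SD 0.30) with the
shared fold factor loading 0.65 on latent mass — heavier athletes carry
thicker folds, which is both realistic and necessary for the adiposity
ratio (adipose mass / body mass) to behave; folds are truncated to
[2, 75] mm to respect the caliper range. Girths and breadths are
allometric in mass and stature with small log-normal noise. Fold medians
were calibrated once so that each prediction system's cohort medians sit
where they are observed in athletic adolescents (e.g. female Durnin &
Rahaman ≈ 26 %, male ≈ 18 %, five-component adiposity ≈ 34 % F / 27 % M).

The criterion is built from one reference equation:
dexa_fp = FP_ref + β + N(0, σ²). This makes β and σ exactly the
Bland–Altman estimands for the reference equation; the other systems'
biases *emerge* from real between-equation differences on the same
measurements. `SyntheticTruth` records the exact noise-free estimand per
equation, so recovery tests assert against the true injected quantity.
σ defaults to 2.5 percentage points, chosen from DEXA test-retest
precision plus the extra variability of a measurement gap between
anthropometry and densitometry.

`paper_scenario` fixes reference = Durnin & Rahaman, β = +0.8, σ = 2.5.
Across seeds this yields mean biases of roughly +5.7 (Slaughter), +0.8
(Durnin & Rahaman), −14 (Lohman), +2.7 (Johnston) and +1.2
(five-component) points, with Lohman the only negative-bias system, Lohman
classified poor and Durnin & Rahaman good/excellent in essentially every
seed.

**What the synthetic experiments do not show.** The criterion is an
equation plus noise, not an independent body model: cross-method residuals
against this criterion are larger than they would be against real DEXA
(which correlates with all methods through true adiposity). In particular
the five-component system's ICC lands moderate (~0.5–0.65) here rather
than the good/excellent seen against real densitometry — a property of the
one-reference-equation criterion design, not of the fractionation code.
Passing recovery tests demonstrates that the pipeline estimates what was
injected; it cannot demonstrate field validity of any equation on real
athletes.

## Numerical and scale choices

- Acceptance-style checks run at sizes that keep the whole suite fast:
  ICC oracle equivalence on 500 vectors of 4–8 pairs; lipid-chain identity
  on 1 000 random adiposities; Bland–Altman recovery at n = 10⁴ (bias
  tolerance 3σ/√n, SD tolerance 5 %); the multi-equation scenario across
  50 seeds of n = 101.
- All randomness flows through `numpy.random.default_rng(seed)`; cohorts
  are bit-reproducible under a fixed (seed, config).
- CSV round-trips print 10 significant digits (well beyond caliper
  precision); report CSVs print 6 decimals for byte-stable reruns.
- Degenerate inputs: ICC raises on n < 3 or zero total variance; perfect
  agreement returns exactly 1.0 with a degenerate (1, 1) interval;
  Bland–Altman raises on n < 2; strata with n < 3 are omitted with a
  diagnostic rather than raising.

## Known limitations

- Lohman registry coefficients are provisional (see above).
- The Phantom constant set and five-way partition are transcriptions; no
  attempt is made to re-derive them, and the historical cadaver-validation
  correlation of the method is not reproducible here.
- No measurement-error (TEM) modelling, no maturation staging, no
  bioimpedance, and no proportional-bias (regression-based) Bland–Altman
  extension.
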