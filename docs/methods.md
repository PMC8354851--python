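# Methods

This note documents the models, rules and numerical choices behind
`achondro`, in the order data flow through the pipeline.

## Registry model

Five flat tables (subjects, anthropometry, surgeries, polysomnography,
imaging) keyed by an opaque `subject_id`. Ages are stored in months
internally, converted from days as days/30.4375; subject-level age at
last encounter is in years, matching how registry demographics are
reported. "Unknown" is a first-class category throughout — it is encoded
as an explicit enum value in memory and an empty string in CSV — because
the cohort tables analyse unknowns as their own row, not as missingness
to impute. Birth decade is derived from the birth date with boundaries
closed on the decade-start day (before 1 Jan 1980 / 1980s / 1990s /
2000s / 1 Jan 2010 onward). Serialization fixes row order (subject id,
then age or date), column order and number formatting, so writing the
same registry twice is byte-identical; this is what makes the round-trip
property tests exact.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions
under which every downstream stage is validated, with ground truth
available for parameter-recovery checks.

**Stature (cm).** For age t in months,

    median(t) = birth + a·τ·(1 − e^(−t/τ)) + U(t/12)

where the exponential term captures the rapid infancy rise (a in
cm/month at birth, τ = 8 months) and U integrates a piecewise-linear
childhood velocity u(y) (cm/year) that declines to exactly zero at the
plateau age. Defaults:

| sex | birth (cm) | SD birth→adult | a | velocity knots (years, cm/yr) |
|---|---|---|---|---|
| male | 47.90 | 3.18 → 5.6 | 1.50 | (0, 4.21), (14.40, 4.21), (19.37, 0) |
| female | 47.28 | 2.85 → 5.2 | 1.30 | (0, 6.60), (3, 6.60), (12.44, 1.9934), (18.44, 0) |

Birth moments are the published cohort values. The final velocity
segment is placed so that velocity passes 1 cm/year and reaches zero at
the reported milestone ages (males 18.19 → 19.37 y, females
15.43 → 18.44 y), and the knots are then solved so the median reaches a
typical adult achondroplasia stature (131 cm male, 124 cm female). The
infancy amplitude is set so the stature curves diverge from the
average-stature standard in the first months of life, as the cohort's
curves do.

**Head circumference (cm).** A saturating exponential
`c + A(1 − e^(−k t))` with birth values 37.1/36.4 cm (male/female,
published), asymptotes 56.5/55.0 cm and rates k = 0.1112/0.1088 per
month, which place 90% attainment of the plateau near 11 months.
Between-subject SD is held at the published birth SD (3.2/2.3 cm).

**Weight (kg).** Multiplicative log-normal around a monotone PCHIP
median through anchors rising from the published birth means
(3.41/3.32 kg) to typical adult weights (50/46 kg); the log-scale SD
grows linearly with age (CV ≈ 0.15 at birth → 0.22 at 18 y), producing
the right-skew that motivates segmented weight splines.

**Within-subject structure.** Each subject carries a persistent standard
normal effect b multiplying the age-dependent SD (log-scale for weight),
plus small per-visit measurement noise (0.5 cm stature, 0.3 cm OFC,
2% weight). Cross-sectional spread therefore matches the SD curves while
individual trajectories are internally consistent and non-decreasing in
expectation — without the persistent effect, iid noise of magnitude
2–5 cm would make individual "growth" wildly non-monotone and the QC
shrinkage rule meaningless.

**Everything the literature does not describe is a stand-in, flagged in
the registry provenance**: visit intensity (piecewise Poisson, 2.5/year
under 2 y, 1.2/year to 6 y, 1.0/year to 21 y — roughly annual dysplasia
clinic follow-up — then 0.15/year), follow-up truncation (a Beta(2.6,
1.4) fraction of attained age, reproducing the cohort's mix of active
and lost-to-follow-up subjects), surgery age distributions (triangular,
early childhood for airway/cranial procedures, adolescence onward for
spine and extremity), the preterm growth deficit (additive/multiplicative
deficit fading linearly to zero by 24 months), and sleep-study counts.
Categorical rates (sex, decades, gestation, inheritance, adoption,
surgical hazards, per-decade sleep-study uptake and severity, imaging
volume) default to the published cohort's observed proportions.

Determinism: the root seed expands into per-subject substreams
(`default_rng([seed, k])`), so subject k's records are invariant to the
cohort size — tests can subset reproducibly.

**Error injection** corrupts each anthropometry row independently with
at most one error: a unit swap (length/OFC recorded in inches, i.e.
value/2.54; weight recorded in pounds, value×2.2046), an exact duplicate
row, or a ±8 SD outlier (multiplicative e^(±1.2) for weight). The
returned ledger is the ground truth against which QC recall is measured.

## Cleaning and exclusions

Two separate layers, both conserving counts (every input point ends up
retained, flagged-retained or dropped, and the report proves it).

**Exclusion rules** (the cohort's stated rules): all points from
limb-lengthening, growth-hormone-treated or trial subjects are removed
(the whole subject, all ages — GH-deficient but untreated subjects are
*not* excluded); preterm subjects' points below 24 months are removed,
re-entering at exactly 24.0 months (boundary inclusive, reading "up to
2 years" as [0, 24)); unknown-gestation subjects are presumed term iff
they have at least one birth measurement (age ≤ 0.5 months) and every
available birth measurement lies within mean ± 2 SD of the sex-specific
achondroplasia birth reference — the conjunction over measures is a
design choice, since the combination rule for plural "birth parameters"
is not stated — otherwise they are treated like preterm subjects before
24 months. The rules are idempotent.

**QC layer.** The original study's cleaning algorithms live in an
unavailable supplement; this layer is a documented stand-in with every
threshold config-exposed. Rules: exact duplicates (same subject,
measure, age, value) collapsed to one; hard physiologic bounds
(length/height 20–220 cm, weight 0.3–250 kg, OFC 20–70 cm); within-
subject stature decreases > 2 cm between consecutive visits before 18 y;
and trajectory checks. A point's expected value is linearly
interpolated between its nearest within-subject neighbours (linearly
extrapolated from the two nearest at series edges; log scale for
weight). A point is suspect when its residual exceeds 4 residual-SD
(3 cm length, 2.5 cm OFC, 0.10 log-weight) *plus a curvature
allowance* — the worst-case linear-prediction error for a curve whose
second derivative is bounded by a per-measure envelope
`amp·e^(−t/τ) + floor` (growth curves bend hardest in infancy; without
the allowance, correct birth weights read as outliers when their nearest
neighbours are months away). A suspect whose value times 2.54 (length/
OFC) or 0.4536 (weight) falls back within 2 SD (+ allowance) of the
trajectory is flagged `unit_swap_suspect`; otherwise `implausible`. Two
passes are run: the second re-predicts with first-pass suspects masked,
so one corrupt point neither hides nor creates a neighbour's flag; where
masking leaves only distant neighbours (allowance dominating the
threshold), the first-pass verdict stands. Flagged points are never
silently deleted — dropping them for curve construction is a config
switch, default on.

On the noiseless clean limit no point is flagged (specificity 1), and on
5%-corrupted registries recall against the injection ledger exceeds 0.9;
the irreducible misses are corruptions at points whose nearest
within-subject neighbours are too distant for any trajectory test.

## Percentile curves

Empirical P5/P50/P95 at each grid age pool every value whose age falls
in a closed window: half-widths ±0.5 months on [0, 12], ±1 on (12, 36],
±3 on (36, 120], ±6 on (120, 216] months. The evaluation grid is monthly
to 36 months, quarterly to 120, semiannual to 216, so adjacent windows
overlap at most 50%. Quantiles are order statistics with linear
interpolation at rank 1 + (n−1)p (numpy's "linear"); windows with fewer
than `min_n` = 20 values yield gaps rather than estimates (the minimum
support is unstated in the source procedure; 20 keeps the binomial
noise of an empirical P5 below ~1 SD-equivalent). Repeated measures are
pooled regardless of subject — a documented limitation: subjects with
more visits weigh more, and no within-subject correlation is modelled.
At the first and last grid ages the window is one-sided, biasing the
estimate toward the data's interior by up to half a window width; tests
assert on interior ages for sharp tolerances.

Smoothing fits one cubic penalized smoothing spline per percentile level
(scipy `make_smoothing_spline`; the penalty chosen by generalized
cross-validation, or fixed via `lam` — 0 reproduces the empirical points
exactly). Non-crossing is enforced afterwards by sorting the three
levels at each grid age (an isotonic projection across levels); the
maximum deviation from the empirical input is reported in the curve
metadata. Weight uses separate splines on birth–3 y and 3–18 y (its
skewness grows with age, and a single penalty cannot serve both the
steep infancy rise and the adolescent tail), cross-faded linearly over
a ±3-month window around 36 months; per-segment curves are also
exposed and the seam gap is reported. Head-circumference curves run
birth through 5 years; stature and weight birth through 18 years.

Birth statistics use values at ages in [0, 0.5] months: mean, sample SD,
and a normal 95% CI (z = 1.96; n is in the hundreds, so t refinements
are immaterial). The difference from the reference is called significant
when the reference mean falls outside the CI — the comparison rule used
with the published birth moments.

## Reference standard

External references load from `reference.csv` (sex, measure, age,
LMS triple or direct p5/p50/p95 per row); LMS centiles are
`M(1 + L·S·z_p)^(1/L)` (L ≠ 0) or `M·e^(S·z_p)` (L = 0), with L, M, S
interpolated linearly in age. The bundled average-stature standard is a
synthetic WHO/CDC-shaped table (monotone interpolant through typical
medians, constant coefficient of variation, log-normal weight), anchored
at the published reference birth moments (length 49.9/49.1 cm, weight
3.3/3.2 kg, OFC 34.5/33.9 cm). It is a stand-in for the real tables, so
divergence milestones computed against it are demonstrations of the
method, not clinical values.

## Height velocity and milestones

Velocity estimates are difference quotients of two time-ordered
length/height values 6–18 months apart, in cm/year at the midpoint age.
Pairing is greedy and non-overlapping: each measurement pairs with the
earliest subsequent measurement in the eligible gap range and the scan
resumes from that measurement — a subject contributes independent,
non-overlapping intervals rather than O(n²) correlated pairs. Estimates
are binned with the same window scheme extended to 21 years (the
late-adolescent decline to zero would otherwise fall off-grid), and bins
under `min_n` are suppressed.

For threshold milestones the binned curve is first smoothed with a
count-weighted penalized spline restricted to ages ≥ 24 months —
infancy velocities fall an order of magnitude in two years, and a single
GCV penalty chosen against that segment would leave the adolescent tail,
where the milestones live, effectively unsmoothed. The 1 cm/year age is
the first crossing from above after the curve's maximum, linearly
interpolated (crossings during the infancy decline are not milestones).

The zero-velocity age needs different handling. Pairwise mean velocities
are non-negative by construction near growth cessation: stature does not
shrink, so once both measurements of a pair lie past the plateau their
difference quotient is pure noise centred at zero, and pairs straddling
the plateau are positive. The expected binned curve therefore approaches
zero from above and never crosses it — any literal crossing is a noise
artifact, arbitrarily placed. The package instead reports the zero
intercept of a count-weighted straight line fitted to the declining limb
(smoothed velocities between 0.3 and 2.0 cm/year, which lies inside the
final linear segment of decline for both sexes). On a linear decline
this is exact; on the synthetic cohorts it recovers the configured
plateau age to well within half a year. The grid-bounded crossing
operator is still provided (`velocity_threshold_age`) and is what the
closed-form tests exercise.

The divergence milestone is the smallest age after which the cohort P95
stays below the reference P5 for the remainder of a shared fine grid
(0.25-month steps, linear interpolation between grid points; age 0 when
the cohort is already below at birth). The head-circumference milestone
is the first age at which the median reaches 90% of its plateau, the
plateau being the mean of the median over the final year of the grid —
"90% of head circumference" is read against the curve's own asymptotic
level, the only denominator available from the curve itself. Milestones
print in years to two decimals for stature and months to one decimal
for head circumference.

## Summary tables

Six tables (demographics by vital status, birth-decade characteristics,
anthropometry counts by age band, surgical burden, sleep studies by
decade, imaging catalogue) in a long cell format with explicit
denominators. Percentages are rounded half-up to one decimal — the rule
verified against every reconcilable printed count/denominator pair.
Counting rules: surgical burden counts the five achondroplasia-related
categories with the full cohort as denominator; pressure-equalizing-tube
events without a recorded date are excluded from counting; "never" means
a confirmed-negative surgical history, "unknown" means no validated
history and no recorded events; a subject's obstructive-sleep-apnea
grade is the worst across all their studies; non-achondroplasia
surgeries are counted but never percentaged. Demographics are stratified
by vital status (total/living/deceased); an "active in clinical
follow-up" stratum would need a field the subject record does not carry
and is out of scope.

The `published_cohort` module transcribes the printed counts of a
1,374-subject multicenter cohort and reconstructs a registry from them,
so the summary engine's arithmetic can be regression-tested against the
printed percentages. Two pairs of printed marginals are mutually
inconsistent by small amounts (the surgical distinct-category
distribution vs the per-category counts, off by 5 subjects; the
sleep-study outcome rows vs the with-study total, off by 15); the
fixture matches the per-category and per-decade counts exactly and the
conflicting marginals as closely as arithmetic allows.

## Problem sizes and what the tests show

Unit tests run on 20–150-subject cohorts; oracle-equivalence checks use
100 independent 8-subject registries; parameter recovery uses three
fixed-seed cohorts of 500 subjects per sex followed to 24 years, where
the constructed median curves recover the generator's truth (stature
MAE < 1 cm, OFC < 0.5 cm, weight < 5% relative), the zero-velocity age
lands within 0.5 years of the configured plateau, 90% OFC attainment
within 0.5 months of the analytic age, and the divergence age within one
grid step of the analytic crossing. Passing these tests shows the
estimators are correct under the generator's assumptions — persistent
within-subject effects, Gaussian/log-normal noise, the stand-in visit
process. They do not establish performance under real-data features the
generator omits: informative visit timing (sicker children visit more),
measurement-protocol shifts across four decades and sites, secular
growth trends, within-family correlation, or surgical effects on growth
(head-circumference curves here include post-surgical measurements, as
the source cohort's did).
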