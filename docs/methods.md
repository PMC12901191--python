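# Methods

## Scope and data model

The package mirrors the numerical chain of a targeted GC–MS/MS
bioanalytical study: design the acquisition method on paper, confirm
analyte identity, validate the quantitative method, quantify unknowns,
profile brain pharmacokinetics, and score the behavioral endpoints the
exposure is meant to explain. The atoms of the calibration/validation
chain are *injection records* — one injection's per-transition retention
times and integrated areas (quantifier, two qualifiers, internal
standard) plus the analyte/IS area ratio. Pharmacokinetics consumes
*concentration–time tables* from destructive sampling (each animal
contributes exactly one observation); behavior consumes pre-scored bout
and arm-entry logs.

## Mass and method-design arithmetic

Atomic masses are embedded constants: nominal masses are the integer
mass of the most abundant isotope (C 12, H 1, O 16, Si 28, …);
monoisotopic masses use standard IUPAC values. One TMS substitution
replaces an active hydroxyl hydrogen with Si(CH₃)₃, a net composition
change of +C₃H₈Si; the derivative of licochalcone A (C21H22O4, 338.15 Da
monoisotopic) is therefore C27H38O4Si2 (482.23 Da), and icaritin
(C21H20O6) with three substitutions gives C30H44O6Si3, nominal parent
ion 584. Fragment m/z values are nominal-mass differences
(unit-resolution quadrupole scale): loss of CH₃ gives 467, loss of OCH₃
gives the base peak 451, and the p-trimethylsilyloxy-benzoyl acylium ion
C10H13O2Si⁺ gives 193.

Oven programs are an initial hold plus heating ramps with holds; the
duration is summed in exact rational arithmetic before any float
conversion, so the screening program (70 °C/1 min, 5 °C/min to 300 °C,
2 min) is exactly 49 min and the optimized program (200 °C/1 min,
30 °C/min to 280 °C, 2 °C/min to 300 °C, 2 min) is 47/3 = 15.667 min —
quoted as 15.6 min under truncation. Cooling ramps are rejected.

The Kováts index is implemented in its logarithmic form (base-10 logs of
raw retention times). On a temperature-programmed run the *linear* index
is the usual convention, but the logarithmic form is what this assay's
documentation uses, so it is the default and only form; the bracketing
requirement (tₙ ≤ tₓ < tₙ₊₁, consecutive carbon numbers) is enforced.
`ladder_from_index_pairs` inverts the two-point system so a ladder
consistent with published (RT, index) pairs can be reconstructed; that
ladder is a consistency construct, not measured data.

MRM transition selection ranks product ions by abundance at their best
collision energy: the top ion is the quantifier, the next two are
qualifiers carrying expected relative abundances (100·qualifier/
quantifier, the "100/x" convention). Abundance ties break toward the
lower product m/z (an arbitrary but fixed rule). Acquisition schedules
are half-open [start, end) time segments; each analyte's transitions are
active in the segment containing its retention time, and segments with
no expected analyte are assigned the latest-eluting analyte — the
quantification target is watched outside other analytes' windows, which
reproduces the 4–9.5 / 9.5–11 / 11–15.6 min layout for analyte RTs of
11.22 and 10.04 min with boundaries at 9.5 and 11 min.

## Peak processing

Traces are uniformly sampled intensity series. Noise is estimated
robustly (1.4826·MAD about the median), detection runs on a 5-point
moving-average copy against a baseline + k·σ threshold (k = 3 by
default; the smoothing suppresses single-sample excursions so a pure
noise trace almost never yields an apex), and apex retention times are
refined by parabolic interpolation of the top three raw samples (ties
resolve to the earlier time). Integration is trapezoidal above a straight
baseline joining the window endpoints, reported in counts·s. S/N is
baseline-corrected height divided by the SD of a linearly detrended,
peak-free flanking window — chosen over the peak-to-peak/2 alternative
for statistical stability; a zero-variance window flags an infinite S/N.
The classical 3:1 / 10:1 thresholds classify detectability. No
deconvolution of overlapping peaks and no saturation handling.

## Identity confirmation

Four criteria, each an auditable record: retention time within ±1% of
the same-batch reference standard (denominator always the reference);
each qualifier's relative abundance within ±20% *relative* of the
reference ratio (a relative window, which is what regulatory guidance
applies to ratios of this size — not absolute percentage points);
pre-run blank below 20% of the LLOQ analyte area and 5% of the mean IS
area; and the same limits applied to the post-run blank as a carry-over
check (no separate numeric limit is defined for carry-over, so the blank
limits are reused). The overall decision is the strict conjunction, so
loosening any tolerance can never turn a confirmed sample into an
unconfirmed one.

## Validation engine

Calibration is OLS of area ratio on concentration over six non-zero
levels (0.5–20 µg/mL). The *library default is unweighted*, matching the
single reported line y = 8.5133x + 1.7962; a 1/x² weighted mode exists,
and the *pipeline* uses it: under the generator's constant-CV response
noise, unweighted OLS mis-estimates the intercept badly enough to fail
the LLOQ ±20% back-calculation gate in roughly a third of simulated
assays, which is a regression-misspecification artifact rather than an
assay property. Gates: ≥75% of calibrators within ±15% of nominal and
the LLOQ within ±20%.

LOD = 3.3σ/S and LOQ = 10σ/S with σ the SD of intercepts and S the mean
slope over ≥3 independent assays; the 10/3.3 coupling is structural.
Intra-day precision is the within-day CV averaged across days; inter-day
precision is the CV of day means (the pooled-all-replicates CV is also
reported, since pooling conventions differ). Accuracy is
100·grand-mean/nominal; gates ±15%, ±20% where the level is the LLOQ
(here LQC = 0.5 µg/mL equals the lowest calibrator). Recovery is
100·mean(pre-extraction-spiked ratio)/mean(post-extraction-spiked
ratio); the matrix factor is mean matrix-spiked area over mean
solvent-spiked area per channel, and the IS-normalized factor
(analyte MF / IS MF) is gated to 0.8–1.2 with CV ≤ 15%. Quantification
inverts the line, flags BLQ/ALQ, and carries flagged values without
including them in group means. The homogenate↔tissue unit bridge is
explicit: µg/mL × 0.01 mL/mg (1 mL buffer per 100 mg brain) = µg/mg.
Reported tissue burdens can therefore sit far above the calibration span
expressed per mL; the pipeline surfaces this as a warning rather than
reconciling it silently. Stability studies and incurred-sample
reanalysis are out of scope.

## Non-compartmental pharmacokinetics

Destructive sampling is analyzed by naive pooling: per-time mean ± SD of
the composite profile. Cmax/Tmax are the observed maximum of the mean
profile (ties to the earlier time). λz comes from log-linear OLS on the
adjusted-R²-best suffix of ≥3 post-Tmax points (Cmax excluded); when a
late observed Tmax leaves fewer than three such points on the sparse
{0, 2, 4, 6, 8, 24} h grid, `nca` falls back to the last three points
including Cmax and records a warning. AUC is linear-trapezoidal by
default (lin-up/log-down optional), AUMC uses t·C trapezoids,
AUC₀₋∞ = AUC₀₋ₜ + C_last/λz, and an observed fraction below 0.8 raises a
high-extrapolation warning — the default synthetic study observes only
~60% of its exposure within 24 h, so Cl/F and Vz/F should be read with
that in mind. Units: concentrations µg/mg, times h, dose µg/kg, so
Cl/F = dose/AUC₀₋∞ lands directly in mg/(kg·h) and Vz/F = Cl_F/λz in
mg/kg. The t = 0 concentration is fixed at zero (extravascular dosing).
Compartmental and population modeling are non-goals.

A note on the terminal fit: on the noiseless default profile the last
three grid points (6, 8, 24 h) recover λz as 0.04009 rather than the
generating 0.0405 — a 1.0% bias from the absorption exponential still
contributing ~1% of the signal at 6–8 h. The derived half-life, 17.29 h,
is within 1.1% of ln 2/0.0405 = 17.11 h.

## Synthetic-data generators

The generators define the study conditions and carry their ground truth
alongside every output.

**Injection tables.** The expected area ratio of a sample at
concentration C is (8.5133·C + 1.7962), multiplied by the extraction
recovery (default 0.68, mid-range of the assay's 63–72%) for samples
that pass through extraction and by the matrix factors for matrix-based
samples (analyte channel 0.88, IS channel 1.00, so the IS-normalized
truth is 0.88 — mild suppression, inside the 0.8–1.2 gate). Noise is
multiplicative mean-one lognormal on the ratio (intra-assay CV 4%) times
a shared per-day lognormal factor (CV 8%), which makes inter-day
variability exceed intra-day as validation tables typically show. IS
areas (nominal 20 000 counts at 0.5 µg/mL) carry their own small (2%)
instrument noise that cancels from the ratio; blanks carry additive
baseline noise (SD 50 counts) only. Qualifier areas follow the reference
relative abundances 73% and 44% of the quantifier with 5% ratio noise;
retention times jitter by 0.02 min (SD) around 11.22/10.04 min. Roles:
blank, zero, calibrator, QC, pre-spike, post-spike, solvent, unknown;
calibrators/QCs/unknowns are treated as matrix-based pre-extraction
samples, so quantification against matrix calibrators is unbiased by
construction. By default only the E-isomer derivative peak is emitted;
an optional flag adds a minor early Z-isomer peak.

**Chromatograms.** Gaussian peaks (σ in seconds) on a flat baseline with
white noise, sampled with ≥12 points per narrowest σ.

**Pharmacokinetics.** One-compartment, first-order absorption:
C(t) = scale·(e^(−λz·t) − e^(−ka·t)) with ka = 0.8 h⁻¹ and
λz = 0.0405 h⁻¹, chosen so the continuous-time peak (3.93 h) falls on
the 4 h grid point and the half-life is ~17.1 h; scale = 95 µg/mg puts
the noiseless Cmax at 76.9 µg/mg. Each animal is sampled once
(destructive design, 5 animals per time at {0, 2, 4, 6, 8, 24} h) with a
mean-one lognormal per-animal scale (CV 15%, consistent with the
reported Cmax dispersion). The structural model is a modeling choice —
the assay itself is analyzed non-compartmentally — and ka ≤ λz
(flip-flop kinetics) is rejected rather than modeled.

**Behavior.** NOR bout durations are exponential with novel/familiar
means set so the expected discrimination ratio matches the configured
group mean (control 0.65, LPS 0.50, LPS+LCA 0.62, LCA 0.66 — chosen as
plausible effect patterns; the source figures print no group means).
Y-maze sequences follow a first-order process: after two distinct
entries the animal completes an alternation triplet with probability p
(0.70/0.55/0.68/0.71 by group) or returns to the arm visited two entries
ago; p = 1 yields perfect alternation and the expected score ≈ 100p.
Between-animal variability distributions are conventions of this
generator, not inferences about any real cohort.

**What passing tests do and do not show.** The generators reproduce the
response model, variance structure and design of the assay, not real
chromatographic artifacts (drift, saturation, co-eluting interferents,
EI isotope patterns) or any pharmacodynamic link between exposure and
behavior. Parameter-recovery results therefore demonstrate correctness
of the estimators under the stated model, not robustness to real-matrix
pathology.

## Behavioral scoring

The discrimination ratio is novel/(novel + familiar) exploration seconds
in the test session — scale- and bout-permutation-invariant by
construction. Spontaneous alternation counts length-3 windows of the
entry sequence containing three distinct arms over (entries − 2), ×100.
Consecutive duplicate arm symbols are collapsed with a warning
(re-entry into the occupied arm is not an entry); a strict mode rejects
them. Exclusions: <7 s total exploration in either NOR session, or <8
arm entries; exclusion is deterministic with per-animal reason codes.
Sessions with zero exploration are excluded, never scored. Inferential
statistics on group scores (ANOVA etc.) are out of scope; group
summaries report mean, SD, SEM and n.

## Numerical choices and degenerate inputs

Full precision is kept internally everywhere; tables render
concentrations and percentages to two decimals. Ties: earliest time for
Cmax/Tmax and apex samples, lowest product m/z for equal-abundance
transitions. Empty formulas weigh 0; a hold-only oven program has its
hold as duration; zero-variance noise windows flag infinite S/N; an
all-zero profile cannot yield Cmax. Determinism: every generator is a
pure function of (config, design, seed); the pipeline embeds the seed
and a config hash, and identical inputs give byte-identical JSON
reports.

## Known limitations

- The composite (naively pooled) profile yields one parameter set per
  study; per-animal SDs of NCA parameters are not derivable from a
  single pooled profile under destructive sampling.
- With the default 15% between-animal CV, the observed grid Tmax is 4 h
  in only ~60% of simulated studies: the generating profile is nearly
  flat between 4 h and 6 h (77 vs 74 µg/mg), so per-time means at
  n = 5 cannot reliably order the two. This is a property of the design,
  not an estimator defect — the noiseless Tmax is always 4 h.
- Pipeline-level validation verdicts fail in ~30% of simulated studies,
  driven by the sampling distribution of an inter-day CV estimated from
  three days against a 15% limit when the generating day-to-day CV is
  8%; this, too, is an honest operating characteristic.
- The Kováts logarithmic form is retained on a temperature-programmed
  separation for fidelity to the assay's documentation; indices should
  be compared only within this convention.
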