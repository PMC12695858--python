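# Methods

This note documents the models and procedures implemented in `tastesig`,
the assumptions behind them, and the design choices made where more than
one reasonable convention exists.

## Case-level data model and cleaning

Both supported dialects are normalized into three tables: one row per
report (demographics + case label), one row per reported drug (normalized
name, canonical role, therapy start date) and one row per reported event
(MedDRA PT code, onset date). Report-level counting is used throughout: a
report naming the target drug twice contributes one observation, and the
2×2 cells always sum to the number of cleaned reports.

Cleaning rules, in order:

1. **Deduplication.** FAERS assigns a version number to each case
   submission; only the highest version per case id is kept (exact ties
   resolved by ingestion order, last read wins). JADER has no versioning;
   exact duplicate rows after normalization are dropped instead.
2. **Exclusions.** Reports with blank or anomalous age, blank/unknown
   sex, no parseable therapy start date, or no parseable event date are
   removed. Each report is tallied under the *first* matching reason in
   that fixed order, so survivors + per-reason counts = input count
   exactly — the attrition-flowchart identity that the pipeline asserts.
3. **Age handling.** FAERS ages are converted to years through a unit
   table (years, decades, months, weeks, days, hours); values with
   unconvertible units, negative values, or values above 120 years count
   as *anomalous* rather than missing. JADER decade buckets ("60歳代")
   map to the decade midpoint (65). Conversion rather than exclusion of
   non-year units is standard FAERS practice.
4. **Exposure roles.** FAERS analyses are restricted to the
   primary-suspect (PS) drug; JADER, which has no PS/SS distinction, uses
   the "suspected drug" (被疑薬) role.
5. **Text normalization.** NFKC folding (full-width → half-width),
   whitespace collapse and case folding; drug names are matched exactly
   after normalization, and salt forms (e.g. "sunitinib malate") are
   deliberately distinct keys.

### Partial dates and time-to-onset

Dates are kept at their reported precision (year / year-month / full) and
intervals are exact proleptic-Gregorian day differences. For each case
report exposed to the drug under study, the onset interval runs from the
(earliest) therapy start to the earliest target-event onset, with:

* year-only precision on either side → record excluded;
* year-month precision → day imputed to 15 ("set to 15 days" is read as
  *day-of-month := 15*, so a year-month pair two months apart yields a
  61-day interval by calendar subtraction);
* onset before start → excluded;
* onset on the start day (identical y/m/d after imputation, including two
  year-month dates in the same month) → 0.5 days.

The 0.5-day convention puts probability mass at the minimum; no
left-truncation correction is applied.

## Disproportionality statistics

**ROR.** ROR = (N₁₁/N₁₀)/(N₀₁/N₀₀) with the log-scale Wald 95% CI using
z = 1.96. A zero in any cell makes the cross-ratio undefined; such tables
are returned flagged rather than raised, and the ≥ 5-case eligibility
gate keeps them out of screening. Signal criterion: CI lower bound > 1.

**BCPNN information component.** With N = N₊₊ and Dirichlet priors
γ₁₁ = 1, α₁ = β₁ = 1, α = β = 2, the joint-cell prior weight is

    γ = γ₁₁ (N+α)(N+β) / ((N₁₊+α₁)(N₊₁+β₁))

which makes the prior expectation of the IC null, and

    E(IC) = log₂ [(N₁₁+γ₁₁)(N+α)(N+β) / ((N+γ)(N₁₊+α₁)(N₊₁+β₁))].

The variance is the standard three-term closed form over the joint cell
and both margins,

    V(IC) = 1/ln²2 · [ (N−N₁₁+γ−γ₁₁)/((N₁₁+γ₁₁)(1+N+γ))
                     + (N−N₁₊+α−α₁)/((N₁₊+α₁)(1+N+α))
                     + (N−N₊₁+β−β₁)/((N₊₁+β₁)(1+N+β)) ],

and the credible bounds are E(IC) ± 2·√V — two posterior standard
deviations, not 1.96. Signal criterion: IC₀₂₅ > 0. These choices
reproduce published reference values at both count extremes (N₁₁ ≈ 4,000
and N₁₁ = 10) to 2 decimal places, which is the package's built-in
verification (`tastesig verify`).

An expected-count warning flag (N₁₊·N₊₁/N₊₊ < 5) is attached to results
but never used as a filter.

**Display rounding** is decimal half-up at 2 places (implemented with
`decimal`, since binary-float rounding misbehaves at .005 boundaries);
internal values keep full precision.

## Weibull time-to-onset

Per drug with ≥ 20 onset records, the two-parameter Weibull distribution
is fitted by the classical probability-plot method: sorted times receive
empirical-CDF plotting positions — mean rank i/(n+1) for n ≥ 30, Benard's
median-rank approximation (i−0.3)/(n+0.4) below — and an OLS line through
y = ln(−ln(1−F)) against x = ln t gives the shape β̂ (slope) and scale
exp(−intercept/slope). Ties (common after the 0.5-day convention) keep
distinct sequential ranks in stable order, so positions stay strictly
increasing; if all times are identical the fit is refused as
*indeterminate*.

Hazard classification from the 95% CI of β: upper bound < 1 → *early
failure* (decreasing hazard); lower bound > 1 → *wear-out failure*
(increasing); otherwise *random failure* (roughly constant).

**Confidence interval for β.** The textbook OLS slope standard error is
not valid here: plotting positions are deterministic functions of
dependent order statistics, so residuals carry almost none of the
sampling variability and the naive t-based interval is several times too
narrow (measured: at true β = 1, n = 500, it classified "random failure"
in only ~1/3 of replicates where a calibrated 95% interval yields ~95%).
The primary CI is therefore a seeded nonparametric bootstrap (percentile
interval over B = 200 resamples of the onset records, slope refitted per
resample), which restores near-nominal calibration while keeping the plot
slope as the point estimate. The naive interval remains available via
`ci_method="regression"`, and an MLE fit (`fit_weibull_mle`) is provided
as an independent cross-check diagnostic, not as the primary estimate.

Summary statistics (mean, median, IQR) are computed from the raw onset
days — the mean is arithmetic, not the fitted Weibull mean — with
quantiles by linear interpolation between order statistics.

## Adjusted reporting odds ratio

Per drug, each cleaned report is one observation of

    log-odds(case) = β₀ + β_D·D + β_A·A + β_G·G

with D the exposure indicator, A age in continuous years, and G an
indicator for female sex (male is the reference; the choice only flips
the sign of β_G). Age is modelled as a single continuous slope — one
coefficient per covariate in the printed model form. Fits are maximum
likelihood (statsmodels Logit, Newton, gradient tolerance 1e−8, ≤ 100
iterations); the adjusted ROR is exp(β_D) with a Wald 95% CI. The
drug-only submodel is algebraically identical to the closed-form 2×2 ROR,
asserted numerically to 1e−6 relative error in the tests.

Gates and diagnostics: the events-per-variable rule (EPV = 10, three
explanatory variables) restricts the model to drugs with ≥ 30 cases;
empty exposure×outcome cells (separation) refuse the fit with a named
diagnostic rather than reporting a divergent estimate; variance inflation
factors over (D, A, G), computed from auxiliary least-squares
regressions, are reported and warned about at VIF ≥ 2 but do not block
the fit.

## Synthetic SRS generator

The generator emulates the *structure* the pipeline assumes: one
primary-suspect drug per report sampled from a catalog; case status from
a logistic model combining a base reporting rate, a per-drug odds
multiplier, and optional age (per year, centred at 50) and sex effects —
giving the adjusted-ROR stage a recoverable confounding structure;
drug-specific Weibull onset intervals drawn by inverse-CDF; calendar
dates built from the sampled intervals and then degraded (year-month /
year-only precision, missing fields, anomalous ages, duplicate case
versions) with per-defect probabilities recorded in the ground truth.
One scenario seed expands into fixed per-component substreams, so output
files are byte-identical across runs with the same seed.

Default study conditions: 2% base reporting rate for the target event, a
four-drug catalog, age ~ N(55, 18²) truncated to [0, 100], 55% female —
typical magnitudes for taste-disorder reports in large SRS databases.

What it deliberately does **not** emulate: real FAERS/JADER marginal
distributions (drug mixes, reporting-year trends), multi-drug reports and
concomitant-medication confounding, free-text noise beyond
full-width/half-width variation, and record-linkage-style near-duplicate
cases. Passing tests therefore demonstrate correctness of the *pipeline
mechanics and estimators* under known generating conditions, not fidelity
of any particular real-world signal.

## Problem sizes used in the test suite

Monte-Carlo checks use sizes chosen to make sampling envelopes tight while
keeping the default suite quick: Weibull recovery uses 100 replicates of
n = 500 per true shape in {0.5, 0.9, 1.0, 1.5}; adjusted-ROR recovery uses
50 replicates of n = 200,000 reports with drug odds 3, age effect
0.02/yr, female effect 0.5; generator calibration checks use 10–20
replicates of 20,000–100,000 reports. Envelopes are the central 95% of
the replicate estimates; no tolerance is tuned to a specific seed.

## Known limitations

* Spontaneous reports carry no exposure denominators: RORs and ICs
  measure reporting disproportionality, not incidence or causality.
* The Weibull analysis ignores reporting censoring and assumes events
  can occur over unbounded time; with heavy mass at the 0.5-day floor the
  shape estimate describes the reported-interval distribution, not a
  clinical hazard in any strict sense.
* The adjusted model includes only age and sex; concomitant drugs and
  indications are out of scope by design.
* JADER decade-midpoint ages coarsen the age covariate; at SRS scale the
  effect on β_A is small but real.
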