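# Methods

This note documents the statistical model, the numerical and design
choices, what the synthetic-data generator does and does not emulate,
and the known limitations.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Counting model

The unit of analysis is the **deduplicated report**.  Deduplication
follows the FDA convention for spontaneous reports keyed by record id
(PRIMARYID analogue), case id (CASEID analogue) and receipt date
(FDA_DT analogue): among versions sharing a case id, keep the most
recent receipt date, breaking ties by the highest record id (numeric
comparison when ids are numeric, lexicographic otherwise; a residual
tie keeps the lexicographically last record so the operation is
deterministic and idempotent).  Unparseable receipt dates sort before
any parseable date, so a record with a bad date survives only when it
is the sole version of its case.

After deduplication, one report contributes **at most 1** to any
contingency cell: a drug repeated across role lines counts once, and a
report with several matching preferred terms is flagged once.  This
report-level counting is what makes published report-level totals
(database size, event margin, per-drug case counts) sufficient to
reconstruct full 2×2 tables, which the acceptance script exploits.

Partial dates are first-class: `YYYYMM` and `YYYY` values are retained
and sorted at reduced precision.  Interval arithmetic (time to onset,
therapy duration) requires at least month precision on both endpoints
and imputes day 15 for month-precision dates; year-only dates are
treated as missing for intervals.

## Disproportionality statistics

All four statistics are deterministic functions of the 2×2 cells and
are evaluated in log space, so they are stable at real-database scale
(N ~ 10⁷, d ≫ a).  Interval multipliers are the conventional printed
constants 1.96 (two-sided 95 %) and 1.64 (one-sided 95 %).

Choices where published practice is ambiguous:

- **χ² variant.** Pearson's statistic without Yates continuity
  correction.  Reconstruction of published rows (see
  `tests/test_acceptance.py`) reproduces printed χ² values within 0.2 %
  without correction, which fixes the variant empirically.
- **Zero cells.** No Haldane +0.5 correction by default: with the
  standard a ≥ 3 minimum-case filter, zero cells never reach scoring.
  The affected statistics are returned as NaN with `estimable=False`
  rather than silently corrected; a `continuity=True` option adds 0.5
  to every cell for exploratory use.
- **IC credibility bound.** The default (`method="bate"`) is the
  closed-form posterior expectation and variance of the
  confidence-propagation model with priors α₁ = β₁ = 1, α = β = 2,
  γ₁₁ = 1, giving IC025 = E(IC) − 2√V(IC).  Published result tables
  sometimes show IC intervals of exactly constant width around the
  point estimate; a `method="fixed_offset"` compatibility mode
  (default offset 1.67) reproduces that convention.  Both are labelled;
  the package does not guess which a given source used.
- **EBGM shrinkage.** The "MGPS" point estimate here is the
  relative reporting ratio a·N/((a+b)(a+c)) with a one-sided log-normal
  lower bound — the form printed in many applied screens — not the full
  DuMouchel gamma-Poisson mixture fitted by EM over the whole
  drug–event matrix.  Consequently IC = log₂(EBGM) holds exactly
  (tested to machine precision), and EBGM05 uses the symmetric
  four-cell variance.  True MGPS shrinkage is out of scope.
- **Monotonicity regime.** ROR and PRR are strictly increasing in *a*
  (b, c, d fixed) everywhere.  EBGM and IC are strictly increasing only
  in the sparse regime b, c ≥ a (provable from
  d ln EBGM/da = 1/a + 1/N − 1/(a+b) − 1/(a+c) and bounded margins);
  in dense tables where one drug dominates its margins the direction
  can reverse.  Spontaneous-report screens live deep in the sparse
  regime, and the property tests constrain to it.

## Signal criteria and strength

Defaults follow the common four-algorithm screen: ROR ≥ 3 with CI
lower bound > 1, PRR ≥ 3 with CI lower bound > 1, IC025 > 0, EBGM05 > 2
with a > 0, all four required (`combination="all"`; an any-k variant is
available).  Two documented ambiguities are exposed as configuration
rather than resolved silently:

- Some sources state the ROR/PRR inclusion rule as "a ≥ 3 and CI > 1"
  (a case threshold), others as a point threshold of 3.  Both are
  expressible (`min_cases`, `ror_point`/`prr_point`).
- Strength banding (weak ≤ 1.5 < medium ≤ 3 < strong) defaults to the
  IC025 field, its stated definition; the `SignalCriteria.ic_point_compat`
  preset bands on the IC point estimate instead, which is how some
  published tables are internally consistent.

Ranking is deterministic: chosen statistic descending, drug name
ascending on ties; unannotated drugs fall into class "other" with a
warning.

## Time to onset and covariate model

Onset is computed from the **earliest therapy start of a suspect drug
line** to the report's event date, one record per (flagged report,
suspect drug); negative or incomputable intervals are excluded and
tallied by reason.  Quartiles use linear interpolation between order
statistics (the mainstream statistical-software default).  Class
comparison is classical one-way fixed-effects ANOVA; the degenerate
all-constant case is reported as F = 0, p = 1.

The covariate model is a maximum-likelihood logistic regression
(Newton iterations, log-likelihood tolerance 1e-8, BFGS fallback on
singular Hessians) of the target-event flag on age (years, continuous;
missing filled with the cohort median plus an indicator), sex, country,
reporter, route, indication (each dummy-coded against its most frequent
level, with an explicit "(missing)" level), therapy duration, and 0/1
indicators for the requested drugs.  Wald intervals are exponentiated
to odds ratios.  Separation is detected (|coef| > 15 or exploding
standard errors) and the affected terms are flagged not estimable with
NaN intervals rather than reported as meaningless numbers.

## The synthetic generator

The generator emulates the structure the pipeline must survive, with
parameters chosen to match the reported demographics and onset profile
of a real drug-induced-cataract reporting cohort:

- age ~ N(63.85, 14.54²) years (truncated to [1, 115]), 67.59 % female,
  weight ~ N(74.72, 20.89²) kg;
- reporter mix 50 % physician / 4.7 % pharmacist / 18.3 % other health
  professional / 27 % consumer, so that after the default professional
  reporter filter the retained mix is ≈ 68.5 / 6.4 / 25.1 % — the
  proportions reported among professional reporters;
- per-class log-normal onset distributions with σ = 0.8 and means
  120.29 (ophthalmic), 128.9 (oncological), 196.26 (nervous system),
  325.35 (hormonal), 495.40 (other) days;
- a drug vocabulary with brand synonyms (verbatim names are randomly
  brands or generics, half upper-cased) and a toy narrow-SMQ event
  subset — synthetic stand-ins, not licensed terminology;
- injected drug–event pairs with configurable relative risk: the
  per-event probability is multiplied by the RR when the case is
  exposed, capped at 1 (so the realized relative reporting ratio
  compresses toward 1 as rr × background approaches the cap, and is
  additionally diluted below the configured RR when the drug's exposure
  probability is non-negligible, because exposed cases then inflate the
  event margin);
- duplicate case versions at a configurable rate: the superseded
  version shares the case id with a strictly earlier receipt date, a
  strictly smaller record id and a perturbed weight — exactly the
  configuration the dedup rule must resolve;
- dates as 8-digit integers with a configurable fraction truncated to
  6-digit partial dates.

Default scale is 20,000 cases with three pairs injected at RR = 10,
10 % duplicates, 5 % exposure and 1 % event background — small enough
to run in seconds, large enough for stable marginals.  Every case-level
latent variable (exposures, events, driver drug, true onset days,
reporter, version structure) is returned as ground truth and written as
a plain tabular sidecar.

What the generator does **not** emulate, hence what passing tests do
not show about real data: drug co-prescription correlation, country- or
time-varying reporting effects, indication-channelling bias, event
co-occurrence structure, free-text name misspellings (name matching is
exact after normalization), and true MGPS shrinkage behaviour on a
full drug–event matrix.  Detection-rate results on synthetic data are
statements about the generative model only.

## Problem sizes used in validation

The test suite validates at desk scale: 10,000-case extracts for
recount/dedup exactness, 100,000 cases for injected-signal recovery
(five pairs at RR = 10, all recovered, zero false positives among 20
null drugs), 10,000 simulated independence tables for interval
calibration (ROR 95 % CI excludes 1 in 5 % ± 1 %), n = 50,000 for
logistic parameter recovery (true OR 2.0), and 1,000 replicates for
ANOVA type-I error (5 % ± 1.5 %).  These sizes give comfortable
statistical resolution for the stated tolerances while keeping the
whole suite fast.

## Known limitations

- The published rows reproduced by the acceptance script are algebraic
  reconstructions from report-level totals, not a re-analysis of the
  raw source database; headline counts that depend on the full real
  extract (number of drugs screened, positive-signal census,
  real onset means) are out of reach by construction.
- The BCPNN IC025 of a given published table may follow either
  implemented convention; comparisons of lower bounds across sources
  should state which was used.
- Logistic odds ratios from spontaneous-report data quantify reporting
  associations, not causal risk; the model inherits every reporting
  bias of the database.
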