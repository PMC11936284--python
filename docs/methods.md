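# Methods

## Counting model

All disproportionality statistics operate on drug–event **pair** counts:
each distinct (report, PT) combination contributes one unit, so the
target-drug margin n1 = a+b is constant across PTs and the grand total N is
the pair count of the cleaned universe. Pair-level counting (rather than
report-level) is the convention whose Woolf variances are compatible with
published confidence intervals at FAERS scale: for a high-frequency term
with a = 415 out of roughly 1,150 target reports, report-level counting
would force 1/a + 1/b ≈ 0.0038, exceeding the total Woolf variance
(≈ 0.0030) implied by a printed CI of [15.70, 19.49] around 17.49 — only
pair-level counting admits a consistent table. SOC-level tables count
distinct (report, SOC) pairs, so a report with three PTs in one SOC
contributes once. Sex subgroups restrict the *entire* pair universe (case
and comparator arms) to the stratum; unknown-sex reports leave both arms.
Duplicate (report, PT) rows are collapsed before counting.

## Deduplication

One submission per case: the latest FDA_DT wins, ties go to the higher
PRIMARYID, and an unparseable FDA_DT loses to any dated submission. The
operation is idempotent and total. Age units DY/WK/MON/YR convert to years
by /365.25, /52.18, /12, ×1; ages ≥ 150 years are treated as missing.
Role filtering defaults to primary suspect (PS) only, with the role set
configurable for suspect-drug sensitivity analyses.

## The four algorithms

* **ROR / PRR.** Point estimates and log-scale 95% CIs from the standard
  delta-method variances. Any zero cell triggers a 0.5 continuity
  correction on all four cells for ROR (for PRR when a or c is zero),
  flagged in the output; χ² always uses the raw counts. χ² defaults to the
  Yates-corrected convention (plain available); the correction is clamped
  so |O−E| − 0.5 never crosses zero.
* **BCPNN.** Default variant is the moment approximation of the original
  information-component posterior with all marginal prior weights 1,
  marginal totals 2 and joint prior weight 1: IC025 = E(IC) − 2·sd(IC).
  This variant approaches log₂(O/E) for large expected counts (the deficit
  is ≈ log₂(E/(E+1))), matching how published IC values at FAERS scale
  track log₂(O/E). The later credibility-interval approximation
  (IC = log₂[(a+0.5)/(E+0.5)]) is a config switch.
* **MGPS.** The prior on the true relative reporting rate λ is a
  two-component gamma mixture (5 hyperparameters Q, α₁, β₁, α₂, β₂,
  shape/rate). The cell marginal is a negative-binomial mixture; the
  hyperparameters maximize the summed marginal log-likelihood via L-BFGS-B
  in log/logit space from the customary start (α₁=0.2, β₁=0.1, α₂=2, β₂=4,
  Q=1/3) plus 4 seeded jittered restarts, with a hard check that the
  optimum is at least as good as the start. The posterior per cell is again
  a two-gamma mixture; EBGM = exp E[ln λ | a] via digamma, and EB05 solves
  the posterior CDF = 0.05 by Brent root-finding (tolerance 1e-12). The
  prior is fitted unstratified; sex-stratum tables reuse the unstratified
  prior so strata remain comparable.
* **Signal.** A term is a signal when all four criteria hold: ROR lower CI
  > 1 with a ≥ 3; PRR ≥ 2 with χ² ≥ 4 and a ≥ 3; IC025 > 0; EB05 > 2. All
  thresholds are configurable.

## Inverting published rows

`invert_published_stats` recovers (b, c, d) from a printed (a, ROR point,
ROR 95% CI, χ²) triple. Given b, the ROR point and the Woolf variance
v = ((ln U − ln L)/3.92)² determine c and d in closed form; the remaining
unknown b is pinned by a bracketed 1-D root-find on χ². Two subtleties are
handled explicitly:

1. All three constraints are invariant under transposing b and c, so the
   system generically has a mirror pair of solutions. The b ≤ c branch is
   preferred (a target drug's margin is far below a reported event's
   comparator margin in a spontaneous-report database).
2. With inputs rounded to printed precision the χ² target can fall just
   outside the range attainable along the (ROR, Woolf)-exact family; the
   closest approach is then returned, and the relative χ² residual is
   reported and bounded by a 2% default tolerance. Exact inputs round-trip
   to better than 1e-9 relative error. Residual ties between χ²
   conventions resolve to the Yates default.

## Time to onset

TTO = EVENT_DT − earliest full START_DT of the target drug per report, in
whole days; partial/missing dates and negative intervals are excluded with
per-reason counts. Quantiles use the median-unbiased convention; the
histogram uses [0, 30] then (30, 60], … bins so day-0 events count as
first-month. The Weibull fit is unconditional maximum likelihood on
(ln α, ln β) (Nelder-Mead; analytic log-likelihood; zero days replaced by
0.5 since the support is t > 0), with 95% Wald CIs from the inverse
observed information (central-difference Hessian, step 1e-5)
back-transformed from the log scale. Classification: early failure when
the β CI lies entirely below 1, wear-out entirely above, random otherwise.
No censoring model is used — spontaneous reports record events, not
at-risk time.

## Descriptive tables

Percentages are half-up rounded to 2 decimals. The serious-outcome block's
denominator is the number of outcome *entries* (a report can carry several
outcome codes); every other block uses the report count. Aggregate shares
over several categories (e.g. age ≥ 65) are the sum of the rounded
per-category percentages, matching how such tables are quoted. Age bands:
<45, 45–64, 65–74, >74, unknown.

## Synthetic data generator

The generator emulates the composition of a real single-drug case series:
categorical margins for sex (48.44% male), age bands, serious outcomes
(51.61% of outcome entries deaths), reporter occupation, country (76.6%
US) and reporting year, onset times Weibull(shape 0.62, scale 95.51 days)
rounded to whole days, a configurable duplicate-submission rate, and a
configurable rate of truncated (YYYYMM/YYYY) or blank EVENT_DT/START_DT
values. FDA_DT stays full-precision so the planted duplicate count is an
exact ground truth for the deduplication stage. Reports carry 1 + Poisson(1)
drugs (the first is the primary suspect); 1% of comparator reports list the
target drug as a concomitant to exercise the role filter. PT occurrences
are independent Bernoulli draws per report — probability base_rate×λ
(capped at 1) under the target drug, base_rate otherwise — so each planted
cell count is exactly Binomial(n_target, min(1, base·λ)); a report with no
hit receives a filler term (PT0000) so every report has a reaction without
disturbing the per-PT truth. Base rates default to a Zipf-like 0.05/rank
profile. A single seeded generator drives everything; identical seeds give
byte-identical tables.

What the generator does **not** emulate: drug-name misspellings needing
NLP normalization, country-specific reporting lags, indication/report-source
tables, correlated PT co-occurrence, and secular reporting trends within a
year. Passing tests on synthetic data therefore validate the pipeline's
counting, deduplication, estimation and thresholding logic — not
robustness to real-world FAERS text noise.

## Validation scale and numerical choices

The test suite validates statistics against independent direct-formula
evaluations (1,000 random tables, 1e-10), EBGM/EB05 against adaptive
quadrature of the posterior (1e-6), prior recovery on 5,000 simulated
cells, Weibull CI coverage over 500 replicates of n = 240 (the published
TTO sample size), and planted-signal detection in a 10,000-report universe
with one tenfold-reporting PT (expected signal cell ≈ 200). On the prior
recovery check the fitted marginal log-likelihood is required to reach the
generating prior's level minus 2 units; by Wilks the ML fit *exceeds* the
generating value by ~χ²₅/2 (≈ 2.5 expected), so a two-sided band of the
same width would be systematically violated — the one-sided bound is the
meaningful optimizer-quality property. MGPS fitting below 20 cells and
Weibull fitting below 30 observations warn about weak identification.

## Known limitations

- The BCPNN moment approximation under-shoots log₂(O/E) by ≈ log₂(E/(E+1));
  at small expected counts the two variants disagree noticeably.
- The MGPS mixture likelihood is multi-modal under label switching; restarts
  mitigate but do not guarantee the global optimum.
- `invert_published_stats` assumes the printed CI is a Woolf interval and
  inherits the printed values' rounding error; its residual should always be
  inspected.
- No multiple-comparison adjustment is applied across PTs (matching standard
  practice for hypothesis-generating disproportionality screens).
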