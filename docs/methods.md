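# Methods

## Scope and data model

The package evaluates multi-class fundus-disease screeners on three
linked questions: how accurate is each model per disease class, do the
models differ statistically, and which screen-and-refer strategy yields
the greatest net benefit for a population. All computation runs on one of
two inputs: a **record table** (one row per image/subject:
`record_id,true_class,predicted_class,model_name`, classes drawn from the
declared diseases plus `normal`) or **confusion counts** (correct count
over a class denominator, the form in which screening reports print their
results). The published counts of the reference screening study ship in
`fundus_dca.reference` and are treated as data.

Diseases are mutually exclusive per record (single label), matching the
disjoint class denominators of the reference test set (287 AMD + 337 DR +
151 PM + 1115 normal = 1890).

## Synthetic cohort generator

`cohort.draw_true_classes` draws each subject's class independently from
the categorical distribution given by the per-disease prevalences, with
the residual mass (1 − Σπ_d, required strictly positive) on `normal`.
`cohort.apply_classifier` forward-simulates screening: a subject with
disease *d* is predicted *d* with probability sens_d, otherwise assigned
per the `miss_target` policy; a normal subject is predicted normal with
probability spec, otherwise assigned a disease per the
`false_positive_target` policy.

Policy choices, fixed and documented rather than inferred:

- **Missed cases go to `normal`.** Cross-disease confusions are not
  modelled, because the reference operating points report only per-class
  sensitivity and normal-fundus specificity — there is no information
  with which to calibrate an off-diagonal confusion structure. The policy
  token exists so a sensitivity analysis could swap the rule in one
  place.
- **False positives are assigned a disease uniformly at random.** No
  implemented statistic depends on *which* disease a misclassified
  normal receives (only any-disease vs normal enters the decision
  curves), but the draw is explicit and seeded so record tables are
  byte-reproducible.
- **Seeding.** Every random draw flows through a
  `numpy.random.Generator` constructed from an explicit integer seed; no
  global RNG state. Identical (spec, seed) gives byte-identical tables.

What the generator emulates: class proportions, per-class operating
points, sampling noise. What it does not: image-quality degradation,
intra-subject eye-level correlation, site effects, or any dependence of
sensitivity on disease severity. Passing tests therefore demonstrate the
statistical machinery is correct under the stated sampling model, not
that any screener performs as simulated on real populations.

## Accuracy metrics

Sensitivity and specificity are ratios of the defining counts; display
follows the field's table conventions — percentages rounded **half-up**
to 2 decimals, Youden's *J* to 4 decimals — while all downstream
computation uses the unrounded fractions. Half-up rounding is implemented
on the decimal representation (`decimal.Decimal`) because binary
`round()` is half-even.

Two counting rules for "correct" are provided: `exact_class` (default —
a disease image counts as detected only if assigned its own class, the
rule consistent with class-specific published sensitivities) and
`any_disease` (any disease label counts as a detection; the natural rule
for referral decisions). The default is a declared convention, not an
empirical claim about how the reference counts were produced.

**Youden's index** has two routes. `youden_index` computes
*J* = sens + spec − 1 from unrounded fractions. `youden_from_counts(...,
table_convention=True)` first rounds both percentages to 2 decimals and
then sums, which is the arithmetic the reference tables actually print;
the two routes agree to within 1e-4 by construction. One cell of the
reference DR-validation table is internally inconsistent (a specificity
of 1021/1115 printed as 91.56 where every consistent rounding rule gives
91.57), so its printed *J* of 0.5328 is one unit in the last digit below
the count-derived 0.5329; the package reports the count-derived value.

AUC is provided as a generic utility via the rank formulation
(equivalently, trapezoidal integration of the ROC with tie-averaging) and
is verified against an O(n²) pair-counting oracle. Wilson score intervals
for proportions are offered as an extension; the reference tables print
no interval estimates.

## Model comparison

Per class, the models form an r×2 table of (correct, incorrect) counts on
a shared denominator. The omnibus test is the **uncorrected Pearson χ²**
with df = r − 1. No continuity correction is applied at any table size:
the uncorrected statistic reproduces all thirteen published pairwise and
omnibus values to 2 decimals, and the Yates-corrected one does not.

**Exact tests.** Fisher's 2×2 exact test uses the two-sided
point-probability ("Irwin") rule: sum the hypergeometric probabilities of
all tables with the observed margins whose point probability does not
exceed the observed one (relative tie tolerance 1e-7). The
**Freeman–Halton** extension to r×2 enumerates the multivariate-
hypergeometric distribution over admissible tables; an enumeration guard
(default 10,000 admissible tables, counted by dynamic programming)
switches to a seeded Monte-Carlo estimate over multivariate-
hypergeometric draws (add-one estimator, default 100,000 resamples) when
enumeration would be too large. Both exact tests are verified against
brute-force enumeration oracles written independently of the
implementation's table generator.

**Test selection.** The exact test is chosen when any observed cell is 0
or any expected count is below 5, else Pearson χ². This rule is an
inference from the reference report's observed choices (the exact test
appears exactly where a zero cell occurs — the PM table, where the lead
model scored 151/151); it is explicit in `choose_method` and overridable
per call.

**Post-hoc procedure.** Pairwise 2×2 tests run only if the omnibus
rejects at α = 0.05 (standard post-hoc gating; the reference report does
not state whether it gated), each at the Bonferroni level
α′ = α/k with k = 3 for three models. A pairwise result is flagged
significant only below α′.

One published value is knowingly not reproduced: the AMD commercial-pair
entry "χ² = 0.61, p = 0.61". The statistic recomputes as 0.26 from
(176, 111) vs (170, 117) while the p-value recomputes as 0.61, so the
printed statistic appears to duplicate the p-value; the suite asserts the
p-value only.

## Decision curve analysis

Net benefit of a strategy at probability threshold p_t:

    NB(p_t) = TP/n − (p_t / (1 − p_t)) · FP/n

p_t is the disease risk at which referral and non-referral break even, so
p_t/(1−p_t) is the number of true positives one false positive is worth.
For a test with sensitivity s and specificity q in a population of
prevalence π, the closed form uses expected counts TP = nπs,
FP = n(1−π)(1−q), kept fractional (no rounding to whole persons);
treat-all is the (s, q) = (1, 0) special case, NB = π − (1−π)·p_t/(1−p_t),
crossing zero exactly at p_t = π; treat-none is identically zero. The
empirical route counts records: TP = screen-positive and truly carrying
the condition, FP = screen-positive and not, n = all records. Thresholds
are restricted to the open interval (0,1): the false-positive weight is
undefined at 1, and at 0 the net benefit reduces to the limit TP/n, which
is an annotation, not a grid point. The default grid is 1% steps over
1%–99%, matching the granularity at which dominance ranges are reported.

**Combined multi-disease screening.** The reference study plots combined
screening without stating its combination rule. The package's rule,
isolated in `combined_screening` so it can be swapped: with mutually
exclusive diseases, combined prevalence is Σπ_d; combined sensitivity is
the prevalence-weighted mean Σπ_d·s_d / Σπ_d (the probability a randomly
chosen diseased subject is flagged, given misses go to normal); combined
specificity is the normal-class specificity unchanged. Under the
generator's forward model this closed form is exactly the any-disease
empirical expectation, which is what the cross-check tests verify.

**Closed vs empirical cross-check.** On a simulated 100,000-subject
cohort the two routes must agree at every grid threshold within 4
propagated binomial standard deviations,
sd = sqrt[(p_TP(1−p_TP) + w²·p_FP(1−p_FP))/n] with w = p_t/(1−p_t) —
treating TP and FP as independent binomials, which is conservative enough
at these prevalences (their multinomial covariance is negative and
small).

**Dominance intervals** are maximal contiguous grid runs on which one
strategy's net benefit strictly exceeds every competitor's; grid points
where the maximum is tied contribute to no interval. Endpoints are
reported at grid resolution (a single-point run yields a degenerate
interval with equal endpoints).

**Prevalences.** The study built its hypothetical cohort from urban/rural
prevalence figures it cites but does not print, so its dominance ranges
(2–40% rural, 4–71% urban) cannot be exact targets. The shipped defaults
— urban AMD 3.1%, DR 2.4%, PM 1.1%; rural AMD 2.2%, DR 1.2%, PM 0.6% —
are illustrative round figures with urban above rural, chosen once so
that the qualitative findings (the lead model dominates over a broad
low-threshold range, wider and higher in the urban setting) are
exercised. Under them the lead model dominates combined screening on
roughly 1–44% (urban) and 1–32% (rural).

## Pipeline and reproducibility

`RunConfig` validates the whole configuration — cohort spec, per-model
operating points, analysis switches, grid — before any stage runs;
`run_pipeline` executes simulate → metrics → compare → dca, writes each
table as UTF-8 CSV whose first line embeds the seed and a SHA-256 prefix
of the effective config (output location excluded from the hash), and on
stage failure removes partial outputs and re-raises naming the stage.
Reruns with the same config and seed are byte-identical. Logging goes to
stderr; machine outputs are never interleaved with logs.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use the study's cohort
size of 100,000 subjects; each such check runs in a few seconds. The
pipeline tests use 20,000-subject cohorts, ample for their
near-operating-point assertions. Exact-test oracle comparisons use small
random tables (2×2 up to n ≈ 200; 3×2 within the 10,000-table enumeration
guard), where brute-force enumeration is itself exact. Statistical
tolerances are 4 binomial/propagated standard deviations for stochastic
recoveries, 1e-7 relative for exact-test tie handling, and 1e-9 relative
or better for closed-form identities.

## Known limitations

- No cost-effectiveness or health-economic modelling; net benefit is the
  terminal quantity.
- No bootstrap or analytic confidence bands for net benefit curves.
- No eye-level clustering: records are treated as independent.
- No multi-class AUC; the AUC utility is binary only.
- The Fisher-vs-χ² selection rule and the post-hoc gating are inferences
  from the reference report's observed practice, documented above, not
  its stated procedure.
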