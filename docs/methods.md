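# Methods

## Model and assumptions

A subject's true status is a binary variable `X`; each of `n` tests returns
`Y_i ∈ {0,1}` with sensitivity `TPR_i = Pr(Y_i=1 | X=1)` and specificity
`TNR_i = Pr(Y_i=0 | X=0)`.  Unless stated otherwise, test results are
assumed conditionally independent given `X` — the standard simplification
in the decision-making literature, and the only regime in which
manufacturer-reported per-test characteristics determine a protocol's
characteristics exactly.  Sensitivities and specificities are treated as
constant in time (no antibody-waning or stage-of-infection effects).

An aggregation rule is a Boolean function on the `2^n` ordered outcome
vectors.  The package fixes one canonical index for these vectors:
positive-first lexicographic order, so the all-positive vector is first
and the all-negative vector last, with the bijection `+ ↦ 1` to bit
tuples.  Truth-table strings in all I/O use this order.  Series and
parallel administration of the same rule have identical aggregate
characteristics, so no separate "series characteristics" computation
exists; administration order only affects test counts (economy module).

## Aggregate characteristics

`rule_characteristics` evaluates the sum-of-products expressions

    TPR_S = Σ_{j: S_j=+} Π_i [TPR_i or 1−TPR_i],
    TNR_S = Σ_{j: S_j=−} Π_i [TNR_i or 1−TNR_i],

accumulating terms in canonical order so results are bit-reproducible.
AND/OR use their product closed forms (`Π TPR_i`; `1 − Π(1−TPR_i)`), which
equal the truth-table evaluation to float round-off; the test suite pins
the two routes together and against a brute-force joint-distribution
oracle at 1e−12.

Boolean expressions use an infix dialect with `&`, `|`, `!`, parentheses,
and 1-based test indices (`(1&2)|3`), matching the conjunction/disjunction
notation used for such protocols with minimal parsing; a small
recursive-descent parser materializes the truth table, so arbitrary
expressions and explicit sign strings are interchangeable.

## ROC frontier

All `2^(2^n)` rules are enumerated as bitmasks over the canonical outcome
index and their (FPR, TPR) points computed vectorized.  Enumeration is
capped at `n = 4` (65,536 rules, well under a second); `n ≥ 5` would mean
at least 2^32 rules, so the operation refuses and points to the
named-family mode (AND, OR, every k-of-n, single projections, and
user-supplied expressions).  Coincident points are merged at 12 decimals
and all attaining rules reported, sorted by truth-table string — the first
is the deterministic representative.

The efficient set is the upper-left chain of the planar convex hull
(scipy's Qhull) between (0,0) and (1,1): hull vertices on or above the
chance diagonal, swept for dominance, with collinear interior points
pruned so the frontier is in strict convex position.  Degenerate clouds on
which a hull cannot be built (all points collinear, e.g. copies of a
chance-level test) fall back to the same dominance sweep over all points.
Only achievable deterministic rules are reported — no randomized
interpolation along frontier edges.

## Decision metrics and test economy

PPV and NPV follow the usual prevalence-weighted forms.  The crossover
prevalence solves PPV = NPV exactly:
`f*/(1−f*) = sqrt(TNR(1−TNR)/(TPR(1−TPR)))`; a grid scan in the tests
confirms the sign change at this value.  Degenerate 0/0 cases (e.g. PPV at
zero prevalence with a perfectly specific protocol) raise an explicit
undefined-value error rather than returning a conventional limit.

For two-test series administration, the second test is needed with
probability `f·TPR₁ + (1−f)(1−TNR₁)` (AND) or `f(1−TPR₁) + (1−f)·TNR₁`
(OR), giving parallel-to-series ratios `2/(1+·)` that always lie in
[1, 2].  The critical prevalence `f_c = (2·TNR₁−1)/(2(TPR₁+TNR₁−1))` marks
where the AND and OR series protocols exchange which saves more tests; it
is computed for any first test but only meaningful when `TNR₁ ≥ 1/2` and
the test has discriminatory power (`TPR+TNR > 1`), and the package flags —
but does not special-case — the reversed regime.

## Prevalence correction and severity

The measured positivity rate of a protocol at true prevalence `f` is
`f* = f·TPR_S + (1−f)(1−TNR_S)`; inverting it yields the generalized
Rogan–Gladen estimate `f̂ = (f* + TNR_S − 1)/(TPR_S + TNR_S − 1)`.  The raw
inverse can leave [0, 1] when the measured rate falls below the protocol's
false-positive floor (or above its sensitivity ceiling); records carry
both the raw and the clamped value with a flag, and severity ratios use
the clamped one — standard practice for this estimator.  A protocol with
`TPR_S + TNR_S = 1` carries no information and the inversion raises.

IFR and IHR divide cumulative fatality/hospitalization counts by `f̂·N`.
Population, counts, and strata are explicit inputs carried as opaque
labels; no temporal smoothing, sampling-bias adjustment, or excess-death
modeling is attempted.  Report output rounds percentages to one decimal;
internally everything is a unit-interval float and percent conversion
happens only at the I/O boundary.

## Uncertainty

Published `median (2.5%–97.5%)` summaries of rates are modelled as beta
distributions.  Shapes minimize the summed squared differences between the
beta CDF at the three summary values and the levels (0.025, 0.5, 0.975),
via Nelder–Mead (`scipy.optimize.fmin`) on log-shapes from a
method-of-moments start, with a coarse log-grid restart if the local
search stalls badly.  Summaries touching 0 or 1 (e.g. a specificity of
100% (98–100%)) have their targets clipped inward by 1e−4, since a proper
beta cannot put a quantile at an endpoint; zero-width intervals are
treated as fixed constants.  Note that many published asymmetric summaries
admit no exact beta match; the irreducible residual is reported on the
fitted shape.

`mc_propagate` samples each uncertain input independently (each test's TPR
and TNR are independent beta variables, and independent across tests — no
joint uncertainty model is available from per-test summaries), evaluates
the pipeline quantity vectorized, and reports empirical 2.5/50/97.5%
quantiles.  Draws where the quantity is undefined are discarded and
counted; exceeding 1% discards flags the summary.  The default sample
count is 10^5 and every run is seeded — identical seeds reproduce
summaries bit-for-bit.

Boole–Fréchet bounds give the best-possible (TPR, TNR) intervals for
AND/OR/majority protocols when only the marginal rates are known and
nothing about dependence: e.g. for AND,
`max(0, ΣTPR_i − (n−1)) ≤ TPR ≤ min_i TPR_i`.  The independence closed
forms always lie inside these intervals (property-tested).  Empirical
dependence factors `λ¹¹|¹ = Pr(Y_i=1,Y_j=1|X=1)/(Pr(Y_i=1|X=1)·Pr(Y_j=1|X=1))`
(and the both-negative analogue given X=0) are estimated per test pair on
pairwise-complete observations, with marginals computed on the same
subset so the matrices are symmetric by construction; pairs with no
complete data or a zero marginal are reported unavailable (NaN), never 0.
Both unweighted and count-weighted means are reported, since a summary
mean can reasonably weight pairs by sample size.  The factors are
descriptive diagnostics only — they never feed back into the aggregation
formulas, for which no dependent closed form exists.

## Synthetic cohorts

`simulate_cohort` draws `X ~ Bernoulli(f)` i.i.d. and, given X, each test
positive with its TPR (X=1) or FPR (X=0).  Optional dependence injection
couples consecutive disjoint test pairs via a chain factorization: the
second member is drawn conditional on the first so that the same-sign
joint probability equals `λ` times the product of marginals — both-positive
in the diseased class and both-negative in the healthy class — while
marginal rates are preserved exactly.  This makes the injected `λ`
directly recoverable as both `λ¹¹|¹` and `λ⁰⁰|⁰`, which is what the
estimator's parameter-recovery tests exercise.  Infeasible `λ` for the
given margins is rejected with the feasible range in the message.
Missingness is completely at random — the simplest mechanism sufficient to
exercise pairwise-complete estimation.

The generator emulates the statistical structure the closed forms assume
(Bernoulli outcomes conditional on status, at most pairwise dependence,
MCAR missingness).  It does not emulate covariate-driven heterogeneity in
test performance, time-varying characteristics, clustered sampling, or
informative missingness; passing recovery tests therefore validate the
estimators under the model's own assumptions, not robustness to violations
beyond pairwise dependence.

## Problem sizes and numerical choices

The deterministic worked examples are desk-scale (`n ≤ 3`, 256 rules) and
run in milliseconds.  Stochastic validation uses cohorts of 10^5–3·10^5
subjects — large enough that three binomial standard errors separate the
closed forms from plausible implementation errors — and fixed seeds
throughout, so every stochastic test is deterministic in practice.
Coincident ROC points merge at 12 decimals; oracle-equivalence tolerances
are 1e−12; probability sums are clipped to [0, 1] to absorb accumulation
round-off at the boundaries.

## Known limitations

- Exact characteristics require conditional independence; under dependence
  only bounds and diagnostics are provided, by design.
- Exhaustive frontier search is capped at `n = 4`; beyond that only named
  families are evaluated.
- Indeterminate/equivocal test results, monetary costs, test fatigue, and
  multiclass discrimination are out of scope.
- The beta-summary fit assumes the published interval is a central 95%
  interval of a unimodal [0, 1] quantity; heavily boundary-concentrated
  summaries are representable only approximately after clipping.
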