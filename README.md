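# testfuse

Tools for aggregating repeated binary diagnostic or screening tests.

Clinical and public-health testing often administers several imperfect
binary tests — each with its own sensitivity (true positive rate, TPR) and
specificity (true negative rate, TNR) — and combines the results with a
Boolean rule: *positive only if all tests are positive* (AND), *positive if
any test is positive* (OR), majority votes, or arbitrary truth tables.
`testfuse` computes the exact operating characteristics of any such
protocol, finds the efficient ones, and propagates the corrected error
rates into population-level prevalence and severity estimates.  It is aimed
at biostatisticians and epidemiologists designing multi-test protocols or
re-analyzing seroprevalence studies that used them.

## The model

Test results `Y_1, …, Y_n ∈ {0,1}` are assumed conditionally independent
given the true status `X ∈ {0,1}`.  An aggregation rule is an output
sequence `S` assigning `+` or `−` to each of the `2^n` ordered outcome
vectors (indexed positive-first: `(+,+), (+,−), (−,+), (−,−)` for `n = 2`).
Its aggregate sensitivity and specificity are sums of products:

    TPR_S = Σ_{j : S_j = +}  Π_i [ TPR_i if outcome j has + at i else 1 − TPR_i ]
    TNR_S = Σ_{j : S_j = −}  Π_i [ TNR_i if outcome j has − at i else 1 − TNR_i ]

On top of this primitive the package provides:

- **ROC frontier** — exhaustive enumeration of all `2^(2^n)` rules
  (`n ≤ 4`) and extraction of the efficient ones via a planar convex hull
  in (FPR, TPR) space;
- **Test economy** — expected test counts and parallel-to-series ratios for
  sequential AND/OR administration, including the critical prevalence
  `f_c = (2·TNR₁ − 1) / (2(TPR₁ + TNR₁ − 1))` where the cheaper mode flips;
- **PPV/NPV** and their prevalence crossover;
- **Generalized Rogan–Gladen correction** — inverts
  `f* = f·TPR_S + (1 − f)(1 − TNR_S)` to recover true prevalence from the
  apparent positivity rate of any aggregated protocol, feeding infection
  fatality/hospitalization ratios `IFR = D / (f̂·N)`, `IHR = H / (f̂·N)`;
- **Uncertainty** — beta distributions fitted to published
  `median (95% CI)` summaries and seeded Monte Carlo propagation;
  Boole–Fréchet bounds and empirical dependence factors `λ` quantify what
  conditional dependence could do to the closed forms;
- **Synthetic cohorts** — a seeded generator of subjects × tests binary
  panels, with optional pairwise dependence injection, used throughout the
  test suite.

## Worked example

Three rapid antigen tests with median sensitivities/specificities of
74.8%/99.7%, 68.1%/99.0% and 68.7%/100%:

```python
from testfuse import TestProfile, parse_rule, rule_characteristics, roc_frontier

panel = [
    TestProfile("abbott", 0.748, 0.997),
    TestProfile("innova", 0.681, 0.990),
    TestProfile("siemens", 0.687, 1.000),
]
agg = rule_characteristics(parse_rule("(1&2)|3", 3), panel)
print(f"TPR_S = {agg.tpr_s * 100:.1f}%, 1-TNR_S = {agg.fpr_s * 100:.4f}%")
for pt in roc_frontier(panel).points:
    print(f"fpr={pt.fpr:.6f}  tpr={pt.tpr:.6f}  rule={pt.representative}")
```

prints

```
TPR_S = 84.6%, 1-TNR_S = 0.0030%
fpr=0.000000  tpr=0.000000  rule=--------
fpr=0.000000  tpr=0.687000  rule=+-+-+-+-
fpr=0.000030  tpr=0.846438  rule=+++-+-+-
fpr=0.003000  tpr=0.921124  rule=+++++-+-
fpr=0.012970  tpr=0.974839  rule=+++++++-
fpr=1.000000  tpr=1.000000  rule=++++++++
```

The rule `(1&2)|3` — positive when the first two tests agree positive or
the third is positive — reaches 84.6% sensitivity at a 0.003% false
positive rate, far better than any single test; the frontier consists of
the trivial endpoints plus test 3 alone, `(1&2)|3`, `1|3`, and `1|2|3`.

Correcting a seroprevalence survey that combined two antibody assays
(83.1%/100% and 91.1%/100%) with an AND rule:

```python
from testfuse import and_characteristics, correct_prevalence, severity_ratio

protocol = and_characteristics([TestProfile("abbott_igg", 0.831, 1.0),
                                TestProfile("euroimmun", 0.911, 1.0)])
rec = correct_prevalence(0.019, protocol)          # measured 1.9% positive
print(f"corrected prevalence = {rec.corrected * 100:.1f}%")
print(f"IFR = {severity_ratio(59, rec.corrected, 249_614) * 100:.1f}%")
```

prints `corrected prevalence = 2.5%` and `IFR = 0.9%`: the AND protocol's
reduced sensitivity (75.7%) means the raw 1.9% positivity understates the
true prevalence, and the corrected denominator lowers the apparent
fatality ratio from 1.2% to 0.9%.

The same analyses are available from a shell via the `testfuse` command
(`aggregate`, `frontier`, `economy`, `prevalence`, `bounds`, `dependence`,
`simulate`; see `testfuse --help`).

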