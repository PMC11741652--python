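"""Synthetic cohort generator for binary test panels.

Generates per-subject true status ``X ~ Bernoulli(f)`` and, conditional on
X, per-test binary outcomes with the supplied sensitivities (X=1) and
false-positive rates (X=0).  Tests are conditionally independent unless a
pairwise dependence factor lambda is injected, in which case consecutive
disjoint test pairs (1,2), (3,4), ... are coupled via a chain
factorization: the second test of a pair is drawn conditional on the first
so that

    Pr(Y_i = y, Y_j = y | X = x) = lambda * Pr(Y_i = y | X) * Pr(Y_j = y | X)

with ``y = 1`` in the diseased class and ``y = 0`` in the healthy class.
Marginal rates are preserved exactly, so the injected lambda is recoverable
as the corresponding empirical dependence factor.  Missingness is applied
completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AggregateCharacteristics, AggregationRule, TestProfile

__all__ = ["CohortTable", "simulate_cohort", "empirical_characteristics"]


@dataclass(frozen=True)
class CohortTable:
    """A simulated or observed subjects-by-tests panel.

    ``data`` has a 0/1 ``status`` column (no missing values) and one
    column per test with values in {0, 1, NaN}.
    """

    data: pd.DataFrame
    prevalence: float
    profiles: tuple[TestProfile, ...]
    pairwise_lambda: Optional[float]
    missing_rate: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def test_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "status"]


def _feasible_lambda_range(p_first: float, p_second: float) -> tuple[float, float]:
    """Range of lambda for which the chain conditionals stay in [0, 1].

    Given margins p_i (first of the pair) and p_j (second), the coupled
    conditionals are ``Pr(Yj=y|Yi=y) = lambda * p_j`` and
    ``Pr(Yj=y|Yi!=y) = p_j * (1 - lambda * p_i) / (1 - p_i)``.
    """
    hi = np.inf
    if p_second > 0:
        hi = min(hi, 1.0 / p_second)
    if p_first > 0:
        hi = min(hi, 1.0 / p_first)
    lo = 0.0
    if p_first < 1.0 and p_first > 0 and p_second > 0:
        # need p_j*(1 - lam*p_i)/(1-p_i) <= 1  =>  lam >= (p_i+p_j-1)/(p_i*p_j)
        lo = max(lo, (p_first + p_second - 1.0) / (p_first * p_second))
    return lo, hi


def simulate_cohort(
    n_subjects: int,
    f: float,
    profiles: Sequence[TestProfile],
    pairwise_lambda: Optional[float] = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> CohortTable:
    """Simulate a cohort of subjects tested with every profile.

    Parameters
    ----------
    n_subjects
        Cohort size.
    f
        True prevalence; X is i.i.d. Bernoulli(f).
    profiles
        One :class:`TestProfile` per test; conditional on X, test i is
        positive with probability ``tpr_i`` (X=1) or ``1 - tnr_i`` (X=0).
    pairwise_lambda
        Optional positive dependence factor coupling consecutive test
        pairs; ``None`` (default) means conditional independence.  The
        injected value must keep the implied conditional probabilities in
        [0, 1] for every coupled pair, in both status classes.
    missing_rate
        Probability that any single result is masked, i.i.d.
    seed
        Seed; the same seed reproduces the identical table.
    """
    if n_subjects < 0:
        raise ValueError(f"n_subjects must be non-negative, got {n_subjects}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {f}")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"missing_rate must lie in [0, 1], got {missing_rate}")
    profiles = tuple(profiles)
    if not profiles:
        raise ValueError("need at least one test profile")
    n_tests = len(profiles)

    # per-class per-test positivity rates
    pos_rate = {
        1: np.array([p.tpr for p in profiles]),
        0: np.array([1.0 - p.tnr for p in profiles]),
    }

    if pairwise_lambda is not None:
        lam = float(pairwise_lambda)
        if lam <= 0:
            raise ValueError(f"pairwise_lambda must be positive, got {lam}")
        for i in range(0, n_tests - 1, 2):
            for cls in (1, 0):
                # the coupled event is both-positive in class 1,
                # both-negative in class 0
                p_i = pos_rate[cls][i] if cls == 1 else 1.0 - pos_rate[cls][i]
                p_j = pos_rate[cls][i + 1] if cls == 1 else 1.0 - pos_rate[cls][i + 1]
                lo, hi = _feasible_lambda_range(p_i, p_j)
                if not lo <= lam <= hi:
                    raise ValueError(
                        f"pairwise_lambda={lam} is infeasible for test pair "
                        f"({profiles[i].name}, {profiles[i + 1].name}) in "
                        f"class X={cls}: feasible range is "
                        f"[{lo:.4g}, {hi:.4g}]"
                    )

    rng = np.random.default_rng(seed)
    status = (rng.random(n_subjects) < f).astype(int)
    results = np.empty((n_subjects, n_tests), dtype=float)

    for cls in (1, 0):
        mask = status == cls
        m = int(mask.sum())
        if m == 0:
            continue
        rates = pos_rate[cls]
        draws = rng.random((m, n_tests))
        y = (draws < rates).astype(float)
        if pairwise_lambda is not None:
            lam = float(pairwise_lambda)
            # redo the second member of each coupled pair conditionally
            for i in range(0, n_tests - 1, 2):
                if cls == 1:
                    p_i, p_j = rates[i], rates[i + 1]
                    anchor = y[:, i] == 1.0
                else:
                    p_i, p_j = 1.0 - rates[i], 1.0 - rates[i + 1]
                    anchor = y[:, i] == 0.0
                cond_match = min(1.0, lam * p_j)
                cond_other = (
                    p_j * (1.0 - lam * p_i) / (1.0 - p_i) if p_i < 1.0 else 0.0
                )
                prob_match = np.where(anchor, cond_match, cond_other)
                u = rng.random(m)
                matched = u < prob_match
                if cls == 1:
                    y[:, i + 1] = matched.astype(float)
                else:
                    y[:, i + 1] = (~matched).astype(float)
        results[mask] = y

    if missing_rate > 0.0:
        miss = rng.random((n_subjects, n_tests)) < missing_rate
        results[miss] = np.nan

    columns = {p.name: results[:, i] for i, p in enumerate(profiles)}
    data = pd.DataFrame({"status": status, **columns})
    return CohortTable(
        data=data,
        prevalence=f,
        profiles=profiles,
        pairwise_lambda=pairwise_lambda,
        missing_rate=missing_rate,
        seed=seed,
    )


def empirical_characteristics(
    cohort: CohortTable, rule: AggregationRule
) -> AggregateCharacteristics:
    """Apply a rule per subject and count empirical (TPR_S, TNR_S).

    Rows with any missing result among the rule's n tests are dropped (and
    their count is implicit in the reduced denominators).  Raises
    ``ValueError`` when a status class has no complete rows.
    """
    n = rule.n
    test_cols = cohort.test_columns
    if len(test_cols) != n:
        raise ValueError(
            f"rule is over n={n} tests but the cohort has {len(test_cols)}"
        )
    values = cohort.data[test_cols].to_numpy(dtype=float)
    status = cohort.data["status"].to_numpy()
    complete = ~np.isnan(values).any(axis=1)
    values = values[complete].astype(int)
    status = status[complete]

    # canonical index: outcome (+,+,...,+) = all ones is index 0
    weights = 2 ** np.arange(n - 1, -1, -1)
    indices = (1 - values) @ weights
    positive_call = np.array([s == "+" for s in rule.outputs])[indices]

    n_pos = int((status == 1).sum())
    n_neg = int((status == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "empirical characteristics undefined: a status class has no "
            f"complete observations (X=1: {n_pos}, X=0: {n_neg})"
        )
    tpr_s = float(positive_call[status == 1].mean())
    tnr_s = float((~positive_call[status == 0]).mean())
    return AggregateCharacteristics(tpr_s=tpr_s, tnr_s=tnr_s, rule=rule)
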