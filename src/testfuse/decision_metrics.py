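"""Prevalence-dependent decision measures and series-testing economy.

PPV and NPV translate a protocol's (TPR, TNR) into post-test probabilities
at a given prevalence f.  The economy quantities compare parallel
administration (always 2N tests for two tests on N people) with series
administration, where the second test is given only when the first result
can change the aggregate call: after a positive first test for AND, after a
negative first test for OR.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence, Union

from .core import AggregateCharacteristics, TestProfile

__all__ = [
    "ppv",
    "npv",
    "ppv_npv_crossover",
    "ppv_ordering_holds",
    "npv_ordering_holds",
    "parallel_series_ratio",
    "expected_series_tests",
    "critical_prevalence",
]

Mode = Literal["and", "or"]
Characteristics = Union[AggregateCharacteristics, TestProfile]


def _tpr_tnr(agg: Characteristics) -> tuple[float, float]:
    if isinstance(agg, TestProfile):
        return agg.tpr, agg.tnr
    return agg.tpr_s, agg.tnr_s


def _check_mode(mode: str) -> str:
    mode = mode.lower()
    if mode not in ("and", "or"):
        raise ValueError(f"mode must be 'and' or 'or', got {mode!r}")
    return mode


def ppv(f: float, agg: Characteristics) -> float:
    """Positive predictive value ``f*TPR / (f*TPR + (1-f)*(1-TNR))``.

    Raises ``ZeroDivisionError`` when no positive calls can occur (for
    example ``f = 0`` with a perfectly specific protocol): the value is a
    0/0 indeterminate form, not 0.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {f}")
    tpr, tnr = _tpr_tnr(agg)
    denom = f * tpr + (1.0 - f) * (1.0 - tnr)
    if denom == 0.0:
        raise ZeroDivisionError(
            "PPV undefined: the protocol produces no positive calls at "
            f"prevalence {f} (tpr={tpr}, tnr={tnr})"
        )
    return f * tpr / denom


def npv(f: float, agg: Characteristics) -> float:
    """Negative predictive value ``(1-f)*TNR / ((1-f)*TNR + f*(1-TPR))``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {f}")
    tpr, tnr = _tpr_tnr(agg)
    denom = (1.0 - f) * tnr + f * (1.0 - tpr)
    if denom == 0.0:
        raise ZeroDivisionError(
            "NPV undefined: the protocol produces no negative calls at "
            f"prevalence {f} (tpr={tpr}, tnr={tnr})"
        )
    return (1.0 - f) * tnr / denom


def ppv_npv_crossover(agg: Characteristics) -> float:
    """Prevalence f* above which PPV >= NPV.

    Setting PPV = NPV and solving gives
    ``f*/(1-f*) = sqrt(TNR(1-TNR) / (TPR(1-TPR)))``, i.e.
    ``f* = sqrt(TNR(1-TNR)) / (sqrt(TNR(1-TNR)) + sqrt(TPR(1-TPR)))``.
    For a symmetric protocol (TPR = TNR) this is 1/2; with TNR = 1 it is 0
    (PPV dominates at every positive prevalence).  With both TPR and TNR in
    {0, 1} the expression is 0/0 and an error is raised.
    """
    tpr, tnr = _tpr_tnr(agg)
    num = math.sqrt(tnr * (1.0 - tnr))
    denom = num + math.sqrt(tpr * (1.0 - tpr))
    if denom == 0.0:
        raise ZeroDivisionError(
            "PPV/NPV crossover undefined for a protocol with both TPR and "
            f"TNR in {{0, 1}} (tpr={tpr}, tnr={tnr})"
        )
    return num / denom


def ppv_ordering_holds(p1: TestProfile, p2: TestProfile) -> bool:
    """Whether AND-PPV dominates OR-PPV for every prevalence.

    The condition is
    ``(TPR1+TPR2)/(TPR1*TPR2) <= (FPR1+FPR2)/(FPR1*FPR2)`` where
    ``FPR = 1-TNR``; it always holds when both tests have discriminatory
    power.  Degenerate zero products make a side infinite, which is
    handled by cross-multiplying.
    """
    t1, t2 = p1.tpr, p2.tpr
    e1, e2 = 1.0 - p1.tnr, 1.0 - p2.tnr
    # (t1+t2)/(t1*t2) <= (e1+e2)/(e1*e2)  <=>  (t1+t2)*e1*e2 <= (e1+e2)*t1*t2
    return (t1 + t2) * e1 * e2 <= (e1 + e2) * t1 * t2


def npv_ordering_holds(p1: TestProfile, p2: TestProfile) -> bool:
    """Whether OR-NPV dominates AND-NPV for every prevalence (mirrored)."""
    s1, s2 = p1.tnr, p2.tnr
    m1, m2 = 1.0 - p1.tpr, 1.0 - p2.tpr
    return (s1 + s2) * m1 * m2 <= (m1 + m2) * s1 * s2


def parallel_series_ratio(f: float, first: TestProfile, mode: Mode) -> float:
    """Ratio of parallel to series test counts for a two-test protocol.

    AND: ``2 / (1 + f*TPR1 + (1-f)*(1-TNR1))``;
    OR:  ``2 / (1 + f*(1-TPR1) + (1-f)*TNR1)``.  Both lie in [1, 2].
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {f}")
    mode = _check_mode(mode)
    if mode == "and":
        second_prob = f * first.tpr + (1.0 - f) * (1.0 - first.tnr)
    else:
        second_prob = f * (1.0 - first.tpr) + (1.0 - f) * first.tnr
    return 2.0 / (1.0 + second_prob)


def expected_series_tests(
    N: int, f: float, first: TestProfile, mode: Mode
) -> float:
    """Expected number of tests to cover N people with series administration.

    AND: ``N * (1 + f*TPR1 + (1-f)*(1-TNR1))``;
    OR:  ``N * (1 + f*(1-TPR1) + (1-f)*TNR1)``.
    """
    if N < 0:
        raise ValueError(f"population size must be non-negative, got {N}")
    return 2.0 * N / parallel_series_ratio(f, first, mode)


def critical_prevalence(first: TestProfile) -> float:
    """Prevalence f_c where AND- and OR-series test savings cross.

    ``f_c = (2*TNR1 - 1) / (2*(TPR1 + TNR1 - 1))``.  Below f_c the AND
    series protocol uses fewer tests; above it the OR series does.  The
    quantity is meaningful when ``TNR1 >= 1/2`` and the first test has
    discriminatory power; it is still computed (but not special-cased)
    otherwise.  Undefined when ``TPR1 + TNR1 = 1``.
    """
    denom = 2.0 * (first.tpr + first.tnr - 1.0)
    if denom == 0.0:
        raise ZeroDivisionError(
            "critical prevalence undefined: the first test has no "
            f"discriminatory power (tpr={first.tpr}, tnr={first.tnr})"
        )
    return (2.0 * first.tnr - 1.0) / denom
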