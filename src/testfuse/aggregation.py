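"""Aggregated sensitivity and specificity of Boolean test-combination rules.

Under conditional independence of test results given true status, the
sensitivity of a rule with output sequence S over the canonical outcomes is
a sum of products: for each outcome vector mapped to "+", multiply
``tpr_i`` where the vector shows a positive for test i and ``1 - tpr_i``
where it shows a negative, then sum over those vectors.  Specificity is the
mirrored sum over the vectors mapped to "-", using ``tnr_i`` for negatives
and ``1 - tnr_i`` for positives.

Named families (AND, OR, majority, k-of-n, single-test projection) are thin
constructors over the same machinery, with closed forms used where they
exist (products for AND/OR).
"""

from __future__ import annotations

import math
import re
from typing import Callable, Sequence

from .core import (
    AggregateCharacteristics,
    AggregationRule,
    OutcomeVector,
    TestProfile,
    canonical_outcomes,
)

__all__ = [
    "parse_rule",
    "rule_characteristics",
    "and_rule",
    "or_rule",
    "k_of_n_rule",
    "projection_rule",
    "expression_rule",
    "and_characteristics",
    "or_characteristics",
    "k_of_n_characteristics",
    "majority_characteristics",
]


# ---------------------------------------------------------------------------
# Rule constructors
# ---------------------------------------------------------------------------

def _rule_from_predicate(n: int, positive: Callable[[OutcomeVector], bool]) -> AggregationRule:
    outputs = tuple(
        "+" if positive(v) else "-" for v in canonical_outcomes(n)
    )
    return AggregationRule(n=n, outputs=outputs)


def and_rule(n: int) -> AggregationRule:
    """Positive iff every test is positive (conjunctive positivity)."""
    return _rule_from_predicate(n, lambda v: all(v.bits))


def or_rule(n: int) -> AggregationRule:
    """Positive iff any test is positive (disjunctive positivity)."""
    return _rule_from_predicate(n, lambda v: any(v.bits))


def k_of_n_rule(n: int, k: int) -> AggregationRule:
    """Positive iff at least k of the n tests are positive."""
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n={n}, got k={k}")
    return _rule_from_predicate(n, lambda v: sum(v.bits) >= k)


def majority_rule(n: int) -> AggregationRule:
    """Positive iff more than half the tests are positive; odd n only."""
    if n % 2 == 0:
        raise ValueError(f"majority aggregation requires odd n, got n={n}")
    return k_of_n_rule(n, (n + 1) // 2)


def projection_rule(n: int, index: int) -> AggregationRule:
    """The rule that just reports test ``index`` (1-based)."""
    if not 1 <= index <= n:
        raise ValueError(f"test index must be in 1..{n}, got {index}")
    return _rule_from_predicate(n, lambda v: bool(v.bits[index - 1]))


# ---------------------------------------------------------------------------
# Boolean-expression parsing
#
# Dialect: 1-based test identifiers, infix & (AND), | (OR), prefix ! (NOT),
# parentheses.  Precedence ! > & > |.  Whitespace ignored.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\d+|[&|!()])")


def _tokenize(expr: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            raise ValueError(
                f"malformed Boolean expression {expr!r}: unexpected character "
                f"at position {pos} ({expr[pos]!r})"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _parse_expression(tokens: list[str], n: int) -> Callable[[tuple[int, ...]], bool]:
    """Recursive-descent parse; returns an evaluator over bit tuples."""
    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else None

    def take(expected=None):
        nonlocal idx
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise ValueError(
                f"malformed Boolean expression: expected {expected or 'a token'}, "
                f"got {tok!r}"
            )
        idx += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() == "|":
            take("|")
            rhs = parse_and()
            node = (lambda a, b: lambda bits: a(bits) or b(bits))(node, rhs)
        return node

    def parse_and():
        node = parse_not()
        while peek() == "&":
            take("&")
            rhs = parse_not()
            node = (lambda a, b: lambda bits: a(bits) and b(bits))(node, rhs)
        return node

    def parse_not():
        if peek() == "!":
            take("!")
            inner = parse_not()
            return lambda bits: not inner(bits)
        return parse_atom()

    def parse_atom():
        tok = peek()
        if tok == "(":
            take("(")
            node = parse_or()
            take(")")
            return node
        if tok is not None and tok.isdigit():
            take()
            i = int(tok)
            if not 1 <= i <= n:
                raise ValueError(
                    f"expression references test {i}, but only tests 1..{n} exist"
                )
            return lambda bits, i=i: bool(bits[i - 1])
        raise ValueError(f"malformed Boolean expression: unexpected token {tok!r}")

    evaluator = parse_or()
    if idx != len(tokens):
        raise ValueError(
            f"malformed Boolean expression: trailing tokens {tokens[idx:]!r}"
        )
    return evaluator


def expression_rule(expr: str, n: int) -> AggregationRule:
    """Materialize a Boolean expression over tests 1..n as an output sequence."""
    evaluator = _parse_expression(_tokenize(expr), n)
    return _rule_from_predicate(n, lambda v: evaluator(v.bits))


_NAMED = {"AND": and_rule, "OR": or_rule, "MAJORITY": majority_rule}


def parse_rule(spec: str, n: int) -> AggregationRule:
    """Parse a rule specification into a materialized output sequence.

    Accepted forms:

    - named rules: ``AND``, ``OR``, ``MAJORITY`` (odd n), ``K_OF_N:k``,
      ``PROJECTION:i`` (case-insensitive);
    - a truth-table sign string of length ``2**n`` over ``{+, -}``
      (canonical positive-first order), e.g. ``"+---"``;
    - a Boolean expression over 1-based test identifiers with ``&``, ``|``,
      ``!`` and parentheses, e.g. ``"(1&2)|3"``.
    """
    spec = spec.strip()
    upper = spec.upper()
    if upper in _NAMED:
        return _NAMED[upper](n)
    for prefix, builder in (("K_OF_N", k_of_n_rule), ("PROJECTION", projection_rule)):
        if upper.startswith(prefix + ":"):
            try:
                arg = int(spec.split(":", 1)[1])
            except ValueError:
                raise ValueError(f"{prefix} parameter must be an integer: {spec!r}")
            return builder(n, arg)
    normalized = spec.replace("−", "-").replace("–", "-")
    if set(normalized) <= {"+", "-"}:
        if len(normalized) != 2**n:
            raise ValueError(
                f"truth-table string must have length 2**{n} = {2**n}, "
                f"got {len(normalized)} ({spec!r})"
            )
        return AggregationRule.from_string(normalized, n)
    return expression_rule(spec, n)


# ---------------------------------------------------------------------------
# Characteristics
# ---------------------------------------------------------------------------

def rule_characteristics(
    rule: AggregationRule, profiles: Sequence[TestProfile]
) -> AggregateCharacteristics:
    """Exact (TPR_S, TNR_S) of a rule under conditional independence.

    Sums are accumulated in canonical outcome order so that results are
    bit-reproducible across runs.
    """
    if len(profiles) != rule.n:
        raise ValueError(
            f"rule is over n={rule.n} tests but {len(profiles)} profiles given"
        )
    tprs = [p.tpr for p in profiles]
    tnrs = [p.tnr for p in profiles]
    tpr_s = 0.0
    tnr_s = 0.0
    for vec, out in zip(canonical_outcomes(rule.n), rule.outputs):
        if out == "+":
            prod = 1.0
            for bit, tpr in zip(vec.bits, tprs):
                prod *= tpr if bit else (1.0 - tpr)
            tpr_s += prod
        else:
            prod = 1.0
            for bit, tnr in zip(vec.bits, tnrs):
                prod *= (1.0 - tnr) if bit else tnr
            tnr_s += prod
    # clip away accumulation noise at the boundaries
    tpr_s = min(1.0, max(0.0, tpr_s))
    tnr_s = min(1.0, max(0.0, tnr_s))
    return AggregateCharacteristics(tpr_s=tpr_s, tnr_s=tnr_s, rule=rule)


def and_characteristics(profiles: Sequence[TestProfile]) -> AggregateCharacteristics:
    """Closed-form AND aggregation: ``tpr = prod tpr_i``, ``fpr = prod fpr_i``."""
    if not profiles:
        raise ValueError("need at least one test profile")
    tpr = math.prod(p.tpr for p in profiles)
    tnr = 1.0 - math.prod(1.0 - p.tnr for p in profiles)
    return AggregateCharacteristics(tpr_s=tpr, tnr_s=tnr, rule=and_rule(len(profiles)))


def or_characteristics(profiles: Sequence[TestProfile]) -> AggregateCharacteristics:
    """Closed-form OR aggregation: ``1-tpr = prod (1-tpr_i)``, ``tnr = prod tnr_i``."""
    if not profiles:
        raise ValueError("need at least one test profile")
    tpr = 1.0 - math.prod(1.0 - p.tpr for p in profiles)
    tnr = math.prod(p.tnr for p in profiles)
    return AggregateCharacteristics(tpr_s=tpr, tnr_s=tnr, rule=or_rule(len(profiles)))


def k_of_n_characteristics(
    profiles: Sequence[TestProfile], k: int
) -> AggregateCharacteristics:
    """Characteristics of the "at least k of n positive" rule."""
    rule = k_of_n_rule(len(profiles), k)
    return rule_characteristics(rule, profiles)


def majority_characteristics(
    profiles: Sequence[TestProfile],
) -> AggregateCharacteristics:
    """Characteristics of the majority rule (odd n)."""
    rule = majority_rule(len(profiles))
    return rule_characteristics(rule, profiles)
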