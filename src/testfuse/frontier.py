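"""Exhaustive rule enumeration and the efficient ROC frontier.

With n tests there are ``2**n`` outcome vectors and ``2**(2**n)`` Boolean
aggregation rules.  Each rule maps to one (FPR, TPR) point; the efficient
protocols are the vertices of the upper-left convex hull of this point
cloud between (0, 0) (the constant-negative rule) and (1, 1) (the
constant-positive rule).

Exhaustive enumeration is allowed up to ``n = 4`` (65,536 rules).  For
larger n the double-exponential blow-up makes enumeration intractable; use
the named-family search instead (AND, OR, all k-of-n, projections, and any
user-supplied expressions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .core import (
    MAX_ENUMERATION_N,
    AggregateCharacteristics,
    AggregationRule,
    TestProfile,
    canonical_outcomes,
    has_discriminatory_power,
)
from .aggregation import (
    and_rule,
    expression_rule,
    k_of_n_rule,
    or_rule,
    projection_rule,
    rule_characteristics,
)

__all__ = ["ROCPoint", "ROCFrontier", "enumerate_rules", "roc_frontier"]

# coincident (fpr, tpr) points are merged at this resolution
_POINT_DECIMALS = 12


@dataclass(frozen=True)
class ROCPoint:
    """One efficient (FPR, TPR) point and every rule attaining it."""

    fpr: float
    tpr: float
    rules: tuple[AggregationRule, ...]

    @property
    def representative(self) -> AggregationRule:
        """First attaining rule under the canonical truth-table ordering."""
        return self.rules[0]


@dataclass(frozen=True)
class ROCFrontier:
    """Efficient frontier points ordered by increasing FPR."""

    points: tuple[ROCPoint, ...]
    n: int
    profile_names: tuple[str, ...]
    non_discriminatory: tuple[str, ...] = field(default_factory=tuple)

    def __iter__(self) -> Iterator[ROCPoint]:
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


def enumerate_rules(n: int) -> Iterator[AggregationRule]:
    """Yield all ``2**(2**n)`` aggregation rules for n tests.

    Rules are yielded in increasing bitmask order of their output sequence
    (all-negative first, all-positive last), each over the canonical
    outcome order.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"need at least one test, got n={n}")
    if n > MAX_ENUMERATION_N:
        raise ValueError(
            f"exhaustive enumeration for n={n} means 2**{2**n} rules; "
            f"the cap is n={MAX_ENUMERATION_N}.  Use the named-family mode "
            "(AND, OR, k-of-n, projections, expressions) for larger n."
        )
    r = 2**n
    for mask in range(2**r):
        yield AggregationRule.from_mask(mask, n)


def _all_points(profiles: Sequence[TestProfile]) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) of every rule, vectorized over all 2**(2**n) bitmasks.

    Returns ``(points, masks)`` where ``points[k]`` is the (fpr, tpr) of the
    rule with bitmask ``masks[k]``.
    """
    n = len(profiles)
    r = 2**n
    outcome_bits = np.array([v.bits for v in canonical_outcomes(n)])  # (r, n)
    tprs = np.array([p.tpr for p in profiles])
    tnrs = np.array([p.tnr for p in profiles])
    # per-outcome joint probabilities given X=1 and X=0
    p_pos = np.prod(np.where(outcome_bits == 1, tprs, 1.0 - tprs), axis=1)  # (r,)
    p_neg = np.prod(np.where(outcome_bits == 1, 1.0 - tnrs, tnrs), axis=1)  # (r,)
    masks = np.arange(2**r, dtype=np.uint64)
    # rule_bits[k, j] = 1 if rule k maps outcome j to "+"
    shifts = (r - 1 - np.arange(r)).astype(np.uint64)
    rule_bits = (masks[:, None] >> shifts[None, :]) & np.uint64(1)  # (m, r)
    tpr_s = rule_bits @ p_pos
    fpr_s = rule_bits @ p_neg
    points = np.column_stack([fpr_s, tpr_s])
    return points, masks


def _upper_left_chain(unique_pts: np.ndarray) -> np.ndarray:
    """Indices into ``unique_pts`` of the efficient hull chain.

    Primary path uses a planar convex hull; degenerate clouds (all points
    collinear) fall back to a direct dominance scan with a collinearity
    prune, which needs no hull machinery.
    """
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(unique_pts)
        candidates = hull.vertices
    except (QhullError, ValueError):
        candidates = np.arange(len(unique_pts))
    pts = unique_pts[candidates]
    # keep only points on or above the chance diagonal
    above = pts[:, 1] >= pts[:, 0] - 1e-15
    candidates = candidates[above]
    pts = pts[above]
    # dominance sweep: sort by (fpr asc, tpr desc), keep strictly improving tpr
    order = np.lexsort((-pts[:, 1], pts[:, 0]))
    keep = []
    best_tpr = -np.inf
    for i in order:
        if pts[i, 1] > best_tpr:
            keep.append(i)
            best_tpr = pts[i, 1]
    chain = candidates[keep]
    # endpoints (0,0) and (1,1) are always achievable and always part of
    # the frontier even when dominated along their vertical/horizontal edge
    for corner in ((0.0, 0.0), (1.0, 1.0)):
        match = np.where(
            (np.abs(unique_pts[:, 0] - corner[0]) < 1e-12)
            & (np.abs(unique_pts[:, 1] - corner[1]) < 1e-12)
        )[0]
        if len(match) and match[0] not in chain:
            chain = np.append(chain, match[0])
    # prune collinear interior points so the chain is in strict convex position
    order = np.lexsort((unique_pts[chain][:, 1], unique_pts[chain][:, 0]))
    chain = chain[order]
    pruned = list(chain[:1])
    for idx in chain[1:]:
        while len(pruned) >= 2:
            a = unique_pts[pruned[-2]]
            b = unique_pts[pruned[-1]]
            c = unique_pts[idx]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross >= -1e-15:  # b lies on or below segment a-c: not a vertex
                pruned.pop()
            else:
                break
        pruned.append(idx)
    return np.array(pruned)


def roc_frontier(profiles: Sequence[TestProfile]) -> ROCFrontier:
    """Enumerate every rule and return the efficient ROC frontier.

    Every returned point lists all rules attaining it, sorted by
    truth-table string; points are ordered by increasing FPR and include
    the trivial endpoints (0, 0) and (1, 1).
    """
    n = len(profiles)
    if not 1 <= n <= MAX_ENUMERATION_N:
        raise ValueError(
            f"roc_frontier enumerates all rules and supports 1 <= n <= "
            f"{MAX_ENUMERATION_N}; got n={n}"
        )
    points, masks = _all_points(profiles)
    rounded = np.round(points, _POINT_DECIMALS)
    unique_pts, inverse = np.unique(rounded, axis=0, return_inverse=True)
    chain = _upper_left_chain(unique_pts)

    frontier_points = []
    for idx in chain:
        attaining_masks = masks[inverse == idx]
        rules = sorted(
            (AggregationRule.from_mask(int(m), n) for m in attaining_masks),
            key=lambda rl: rl.as_string(),
        )
        fpr, tpr = unique_pts[idx]
        frontier_points.append(
            ROCPoint(fpr=float(fpr), tpr=float(tpr), rules=tuple(rules))
        )
    frontier_points.sort(key=lambda p: (p.fpr, p.tpr))
    flagged = tuple(
        p.name for p in profiles if not has_discriminatory_power(p)
    )
    return ROCFrontier(
        points=tuple(frontier_points),
        n=n,
        profile_names=tuple(p.name for p in profiles),
        non_discriminatory=flagged,
    )


def named_family_points(
    profiles: Sequence[TestProfile],
    expressions: Sequence[str] = (),
) -> list[tuple[str, AggregateCharacteristics]]:
    """Characteristics of the named rule families, for n beyond the cap.

    Covers AND, OR, every k-of-n threshold, every single-test projection,
    and any user-supplied Boolean expressions.
    """
    n = len(profiles)
    named: list[tuple[str, AggregationRule]] = [
        ("AND", and_rule(n)),
        ("OR", or_rule(n)),
    ]
    named += [(f"K_OF_N:{k}", k_of_n_rule(n, k)) for k in range(2, n)]
    named += [(f"PROJECTION:{i}", projection_rule(n, i)) for i in range(1, n + 1)]
    named += [(expr, expression_rule(expr, n)) for expr in expressions]
    return [(name, rule_characteristics(rule, profiles)) for name, rule in named]
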