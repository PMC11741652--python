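"""Domain types and canonical conventions for binary-test aggregation.

A diagnostic or screening test is summarised by its sensitivity (true
positive rate, TPR) and specificity (true negative rate, TNR).  A protocol
that administers ``n`` such tests and maps each ordered outcome vector to a
single binary call is an *aggregation rule*: a Boolean function on the
``2**n`` outcome vectors.

Canonical outcome order
-----------------------
All rule representations in this package index the ``2**n`` outcome vectors
in positive-first lexicographic order: the all-positive vector comes first
and the all-negative vector last.  For two tests the order is

    (+,+), (+,-), (-,+), (-,-)

Under the bijection ``+ -> 1``, ``- -> 0`` this is ``itertools.product``
over ``(1, 0)`` — bit tuples enumerated from all-ones down to all-zeros.
Truth-table strings such as ``"+---"`` (the two-test AND rule) use this
order everywhere in the package's I/O.

Probabilities are carried as unit-interval floats internally; percent
formatting happens only at the I/O boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "MAX_ENUMERATION_N",
    "TestProfile",
    "OutcomeVector",
    "AggregationRule",
    "AggregateCharacteristics",
    "ProbabilityInterval",
    "canonical_outcomes",
    "has_discriminatory_power",
    "read_profiles",
    "write_profiles",
]

#: Largest number of tests for which exhaustive rule enumeration is allowed.
#: With n tests there are 2**(2**n) rules; n = 4 gives 65,536 (fast),
#: n = 5 would give 2**32 (intractable).
MAX_ENUMERATION_N = 4

POSITIVE = "+"
NEGATIVE = "-"
_SIGNS = (POSITIVE, NEGATIVE)
# unicode minus variants accepted on input
_SIGN_ALIASES = {"+": "+", "-": "-", "−": "-", "–": "-"}


def _check_probability(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_ci(
    ci: Optional[Tuple[float, float]], point: float, name: str
) -> Optional[Tuple[float, float]]:
    if ci is None:
        return None
    lo, hi = (float(ci[0]), float(ci[1]))
    _check_probability(lo, f"{name} CI lower bound")
    _check_probability(hi, f"{name} CI upper bound")
    if not lo <= point <= hi:
        raise ValueError(
            f"{name} CI ({lo}, {hi}) must bracket the point value {point}"
        )
    return (lo, hi)


@dataclass(frozen=True)
class TestProfile:
    """One test's sensitivity/specificity, with optional 95% CIs.

    Parameters
    ----------
    name
        Label used in reports and Boolean expressions.
    tpr
        Sensitivity (true positive rate), in [0, 1].
    tnr
        Specificity (true negative rate), in [0, 1].
    tpr_ci, tnr_ci
        Optional ``(lo, hi)`` 95% confidence bounds bracketing the point
        values.
    """

    name: str
    tpr: float
    tnr: float
    tpr_ci: Optional[Tuple[float, float]] = None
    tnr_ci: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tpr", _check_probability(self.tpr, "tpr"))
        object.__setattr__(self, "tnr", _check_probability(self.tnr, "tnr"))
        object.__setattr__(self, "tpr_ci", _check_ci(self.tpr_ci, self.tpr, "tpr"))
        object.__setattr__(self, "tnr_ci", _check_ci(self.tnr_ci, self.tnr, "tnr"))

    @property
    def fpr(self) -> float:
        """False positive rate, ``1 - tnr``."""
        return 1.0 - self.tnr


# not a pytest collectable despite the Test* name
TestProfile.__test__ = False


def has_discriminatory_power(profile: TestProfile) -> bool:
    """True iff the test beats a random classifier: ``tpr + tnr > 1``.

    A test with ``tpr + tnr == 1`` sits on the ROC diagonal and carries no
    information about the true status; such tests are permitted everywhere
    but flagged by the CLI.
    """
    return profile.tpr + profile.tnr > 1.0


@dataclass(frozen=True)
class OutcomeVector:
    """An ordered vector of n per-test signs, e.g. ``(+, -, +)``."""

    signs: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.signs:
            raise ValueError("OutcomeVector needs at least one sign")
        normalized = tuple(_SIGN_ALIASES.get(s, s) for s in self.signs)
        for s in normalized:
            if s not in _SIGNS:
                raise ValueError(f"outcome signs must be '+' or '-', got {s!r}")
        object.__setattr__(self, "signs", normalized)

    def __len__(self) -> int:
        return len(self.signs)

    @property
    def bits(self) -> Tuple[int, ...]:
        """0/1 view under the canonical bijection ``+ -> 1``."""
        return tuple(1 if s == POSITIVE else 0 for s in self.signs)

    def __str__(self) -> str:
        return "(" + ",".join(self.signs) + ")"


def canonical_outcomes(n: int) -> list[OutcomeVector]:
    """All ``2**n`` outcome vectors in positive-first lexicographic order.

    The all-positive vector is first and the all-negative last; this order
    is THE canonical index of :class:`AggregationRule` outputs throughout
    the package.

    Raises
    ------
    ValueError
        If ``n < 1`` or ``n > MAX_ENUMERATION_N + 1`` (outcome enumeration
        itself is cheap, but a cap guards against typos; rule enumeration
        has the stricter cap).
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"need at least one test, got n={n}")
    if n > 20:
        raise ValueError(
            f"n={n} would enumerate 2**{n} outcome vectors; this is almost "
            "certainly a mistake"
        )
    return [
        OutcomeVector(signs) for signs in itertools.product(_SIGNS, repeat=n)
    ]


@dataclass(frozen=True)
class AggregationRule:
    """A Boolean aggregation rule as an output sequence over canonical order.

    ``outputs[j]`` is the aggregate call (``'+'`` or ``'-'``) assigned to
    the j-th canonical outcome vector of ``canonical_outcomes(n)``.
    """

    n: int
    outputs: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one test, got n={self.n}")
        normalized = tuple(_SIGN_ALIASES.get(s, s) for s in self.outputs)
        if len(normalized) != 2**self.n:
            raise ValueError(
                f"output sequence must have length 2**{self.n} = {2**self.n}, "
                f"got {len(normalized)}"
            )
        for s in normalized:
            if s not in _SIGNS:
                raise ValueError(f"outputs must be '+' or '-', got {s!r}")
        object.__setattr__(self, "outputs", normalized)

    @classmethod
    def from_string(cls, s: str, n: int) -> "AggregationRule":
        """Build from a truth-table sign string like ``"+---"``."""
        return cls(n=n, outputs=tuple(s))

    @classmethod
    def from_mask(cls, mask: int, n: int) -> "AggregationRule":
        """Build from an integer bitmask; bit ``r-1-j`` maps outcome j to +."""
        r = 2**n
        outputs = tuple(
            POSITIVE if (mask >> (r - 1 - j)) & 1 else NEGATIVE for j in range(r)
        )
        return cls(n=n, outputs=outputs)

    def as_string(self) -> str:
        return "".join(self.outputs)

    def complement(self) -> "AggregationRule":
        """Rule with every output sign flipped."""
        flipped = tuple(POSITIVE if s == NEGATIVE else NEGATIVE for s in self.outputs)
        return AggregationRule(n=self.n, outputs=flipped)

    def __str__(self) -> str:
        return self.as_string()


@dataclass(frozen=True)
class AggregateCharacteristics:
    """The (TPR_S, TNR_S) pair of an aggregated protocol."""

    tpr_s: float
    tnr_s: float
    rule: Optional[AggregationRule] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tpr_s", _check_probability(self.tpr_s, "tpr_s"))
        object.__setattr__(self, "tnr_s", _check_probability(self.tnr_s, "tnr_s"))

    @property
    def fpr_s(self) -> float:
        return 1.0 - self.tnr_s


@dataclass(frozen=True)
class ProbabilityInterval:
    """A closed probability interval ``[lo, hi]`` within [0, 1]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        _check_probability(self.lo, "lo")
        _check_probability(self.hi, "hi")
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper {self.hi}")

    def __contains__(self, value: float) -> bool:
        return self.lo <= value <= self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo


# ---------------------------------------------------------------------------
# Profile table I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["name", "tpr", "tpr_lo", "tpr_hi", "tnr", "tnr_lo", "tnr_hi"]


def _maybe_pair(lo, hi) -> Optional[Tuple[float, float]]:
    if pd.isna(lo) or pd.isna(hi):
        return None
    return (float(lo), float(hi))


def read_profiles(path_or_buf, percent: bool = False) -> list[TestProfile]:
    """Read a test-profile table from delimited text.

    The table has header ``name,tpr,tpr_lo,tpr_hi,tnr,tnr_lo,tnr_hi``; CI
    columns may be empty.  Values are proportions in [0, 1] unless
    ``percent=True``, in which case every numeric column is divided by 100.
    The scale is never guessed from magnitudes.
    """
    df = pd.read_csv(path_or_buf, comment="#")
    missing = [c for c in ("name", "tpr", "tnr") if c not in df.columns]
    if missing:
        raise ValueError(f"profile table is missing required columns: {missing}")
    for col in PROFILE_COLUMNS[1:]:
        if col not in df.columns:
            df[col] = float("nan")
    scale = 0.01 if percent else 1.0
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            TestProfile(
                name=str(row["name"]),
                tpr=float(row["tpr"]) * scale,
                tnr=float(row["tnr"]) * scale,
                tpr_ci=_maybe_pair(row["tpr_lo"] * scale, row["tpr_hi"] * scale),
                tnr_ci=_maybe_pair(row["tnr_lo"] * scale, row["tnr_hi"] * scale),
            )
        )
    if not profiles:
        raise ValueError("profile table contains no rows")
    return profiles


def write_profiles(
    profiles: Sequence[TestProfile], path_or_buf, percent: bool = False
) -> None:
    """Write profiles back to the delimited-text format of :func:`read_profiles`."""
    scale = 100.0 if percent else 1.0
    rows = []
    for p in profiles:
        tpr_ci = p.tpr_ci or (float("nan"), float("nan"))
        tnr_ci = p.tnr_ci or (float("nan"), float("nan"))
        rows.append(
            {
                "name": p.name,
                "tpr": p.tpr * scale,
                "tpr_lo": tpr_ci[0] * scale,
                "tpr_hi": tpr_ci[1] * scale,
                "tnr": p.tnr * scale,
                "tnr_lo": tnr_ci[0] * scale,
                "tnr_hi": tnr_ci[1] * scale,
            }
        )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path_or_buf, index=False)
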