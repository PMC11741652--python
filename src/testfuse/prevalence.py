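"""Misclassification-corrected prevalence and outbreak-severity ratios.

A protocol with aggregate sensitivity TPR_S and specificity TNR_S turns a
true prevalence f into an expected measured (apparent) positivity rate

    f* = f * TPR_S + (1 - f) * (1 - TNR_S).

Inverting this relation gives a generalized Rogan-Gladen estimate

    f_hat = (f* + TNR_S - 1) / (TPR_S + TNR_S - 1),

valid for any Boolean aggregation protocol, not just a single test.  The
raw inverse can land outside [0, 1] (for example when the measured rate
falls below the protocol's false-positive floor); records carry both the
raw and the clamped value, and severity ratios use the clamped one.

Severity ratios divide a cumulative event count (fatalities D or
hospitalizations H) by the estimated number of infections ``f_hat * N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

from .core import AggregateCharacteristics

__all__ = [
    "PrevalenceRecord",
    "measured_from_true",
    "correct_prevalence",
    "severity_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrevalenceRecord:
    """A measured prevalence and its error-corrected estimate for one stratum."""

    stratum: str
    measured: float
    corrected: float          # clamped into [0, 1]
    corrected_raw: float      # unclamped Rogan-Gladen inverse
    clamped: bool
    measured_ci: Optional[Tuple[float, float]] = None
    corrected_ci: Optional[Tuple[float, float]] = None


def measured_from_true(f: float, agg: AggregateCharacteristics) -> float:
    """Expected apparent positivity rate of a protocol at true prevalence f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {f}")
    return f * agg.tpr_s + (1.0 - f) * (1.0 - agg.tnr_s)


def correct_prevalence(
    measured: float,
    agg: AggregateCharacteristics,
    stratum: str = "all",
    measured_ci: Optional[Tuple[float, float]] = None,
) -> PrevalenceRecord:
    """Generalized Rogan-Gladen correction of a measured prevalence.

    Raises ``ZeroDivisionError`` when ``TPR_S + TNR_S = 1`` (the protocol
    is non-informative and the relation cannot be inverted).  A raw
    estimate outside [0, 1] is clamped, with the raw value retained and a
    warning logged.
    """
    if not 0.0 <= measured <= 1.0:
        raise ValueError(f"measured prevalence must lie in [0, 1], got {measured}")
    denom = agg.tpr_s + agg.tnr_s - 1.0
    if denom == 0.0:
        raise ZeroDivisionError(
            "prevalence correction undefined: protocol has no discriminatory "
            f"power (tpr_s={agg.tpr_s}, tnr_s={agg.tnr_s})"
        )
    raw = (measured + agg.tnr_s - 1.0) / denom
    clamped_value = min(1.0, max(0.0, raw))
    clamped = clamped_value != raw
    if clamped:
        logger.warning(
            "corrected prevalence %.6g for stratum %r falls outside [0, 1]; "
            "clamped to %.6g",
            raw,
            stratum,
            clamped_value,
        )
    return PrevalenceRecord(
        stratum=stratum,
        measured=measured,
        corrected=clamped_value,
        corrected_raw=raw,
        clamped=clamped,
        measured_ci=measured_ci,
    )


def severity_ratio(count: int, corrected: float, population: int) -> float:
    """Event count divided by estimated infections: ``count / (f_hat * N)``.

    ``corrected`` is the (clamped) error-corrected prevalence; ``count`` is
    a cumulative number of fatalities (IFR) or hospitalizations (IHR).
    """
    if count < 0:
        raise ValueError(f"event count must be non-negative, got {count}")
    if population <= 0:
        raise ZeroDivisionError(
            f"severity ratio undefined for population {population}"
        )
    if corrected <= 0.0:
        raise ZeroDivisionError(
            "severity ratio undefined: estimated prevalence is zero"
        )
    return count / (corrected * population)
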