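"""Uncertainty quantification: beta fits, Monte Carlo CIs, dependence bounds.

Sensitivities, specificities, and prevalences live on [0, 1], so published
``median (2.5%-97.5%)`` summaries are modelled as beta distributions.  The
shapes are found by minimizing the sum of squared differences between the
beta CDF evaluated at the three summary values and the target quantile
levels (0.025, 0.5, 0.975).  Fitted distributions are then sampled
independently to propagate uncertainty through any deterministic pipeline
quantity.

Two dependence tools complement the conditional-independence closed forms:

* Boole-Frechet bounds — best possible intervals for AND/OR/majority
  characteristics given only the marginal TPRs/TNRs, with no assumption on
  the joint distribution of test results;
* empirical dependence factors — ratios of joint to product-of-marginal
  conditional frequencies, lambda = 1 under conditional independence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ProbabilityInterval, TestProfile

__all__ = [
    "BetaShape",
    "CredibleSummary",
    "DependenceFactors",
    "fit_beta",
    "mc_propagate",
    "frechet_bounds",
    "dependence_factors",
]

#: Quantile levels a (median, lo, hi) summary pins down.
QUANTILE_LEVELS = (0.025, 0.5, 0.975)

#: Quantile targets touching 0 or 1 are clipped into [EPS, 1-EPS] before
#: fitting; a proper beta cannot place a quantile exactly at an endpoint.
ENDPOINT_EPS = 1e-4

DEFAULT_N_SAMPLES = 100_000


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters (alpha, beta) of a fitted beta distribution."""

    alpha: float
    beta: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    def quantiles(self, levels: Sequence[float] = QUANTILE_LEVELS) -> np.ndarray:
        return stats.beta.ppf(levels, self.alpha, self.beta)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class CredibleSummary:
    """Empirical median and central 95% interval of a Monte Carlo sample."""

    median: float
    lo: float
    hi: float
    n_samples: int
    seed: int
    n_discarded: int = 0
    flagged: bool = False

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class DependenceFactors:
    """Pairwise dependence diagnostics for a cohort of binary test results.

    ``lambda_pp.loc[i, j]`` estimates
    ``Pr(Yi=1, Yj=1 | X=1) / (Pr(Yi=1|X=1) * Pr(Yj=1|X=1))`` and
    ``lambda_nn`` the analogous both-negative factor given ``X=0``.
    Entries are NaN where no pairwise-complete observations (or a zero
    marginal) make the ratio unavailable.  Matrices are symmetric; the
    diagonal is excluded by default (NaN).
    """

    lambda_pp: pd.DataFrame
    lambda_nn: pd.DataFrame
    counts_pos: pd.DataFrame
    counts_neg: pd.DataFrame

    def mean_factors(self, weighted: bool = False) -> Tuple[float, float]:
        """Off-diagonal means of (lambda_pp, lambda_nn).

        With ``weighted=True`` each pair is weighted by its
        pairwise-complete observation count.
        """
        out = []
        for mat, counts in (
            (self.lambda_pp, self.counts_pos),
            (self.lambda_nn, self.counts_neg),
        ):
            vals = mat.to_numpy(dtype=float)
            w = counts.to_numpy(dtype=float)
            iu = np.triu_indices_from(vals, k=1)
            v, cw = vals[iu], w[iu]
            ok = ~np.isnan(v)
            if not ok.any():
                out.append(float("nan"))
            elif weighted:
                out.append(float(np.average(v[ok], weights=cw[ok])))
            else:
                out.append(float(np.mean(v[ok])))
        return out[0], out[1]


# ---------------------------------------------------------------------------
# Beta fitting
# ---------------------------------------------------------------------------

def _moment_guess(median: float, lo: float, hi: float) -> Tuple[float, float]:
    """Method-of-moments initial shapes from (median, CI width)."""
    mean = median
    sd = max((hi - lo) / 3.92, 1e-3)
    var = min(sd**2, mean * (1 - mean) * 0.999)
    nu = mean * (1 - mean) / var - 1.0
    return max(mean * nu, 1e-2), max((1 - mean) * nu, 1e-2)


def fit_beta(median: float, lo: float, hi: float) -> BetaShape:
    """Fit beta shapes to a ``median (lo-hi)`` 95% summary.

    Minimizes ``sum_q (CDF(target_q; alpha, beta) - level_q)**2`` over the
    levels (0.025, 0.5, 0.975) with a derivative-free simplex search from a
    method-of-moments start; a coarse log-grid restart is used if the local
    search stalls.  Targets touching 0 or 1 are clipped inward by 1e-4.
    """
    if not 0.0 <= lo <= median <= hi <= 1.0:
        raise ValueError(
            f"need 0 <= lo <= median <= hi <= 1, got ({lo}, {median}, {hi})"
        )
    if hi <= lo:
        raise ValueError(
            f"degenerate zero-width interval ({lo}, {hi}): treat the value "
            "as a fixed constant instead of fitting a distribution"
        )
    targets = np.clip([lo, median, hi], ENDPOINT_EPS, 1.0 - ENDPOINT_EPS)
    levels = np.array([QUANTILE_LEVELS[0], QUANTILE_LEVELS[1], QUANTILE_LEVELS[2]])

    def objective(log_shapes: np.ndarray) -> float:
        a, b = np.exp(log_shapes)
        cdf = stats.beta.cdf(targets, a, b)
        return float(np.sum((cdf - levels) ** 2))

    med_clipped = float(np.clip(median, ENDPOINT_EPS, 1 - ENDPOINT_EPS))
    x0 = np.log(_moment_guess(med_clipped, targets[0], targets[2]))
    best_x = optimize.fmin(objective, x0, xtol=1e-8, ftol=1e-12, disp=False)
    best_val = objective(best_x)
    if best_val > 1e-3:
        # coarse log-grid restart; only reached when the local search stalls
        # badly (most asymmetric summaries leave a small irreducible residual)
        grid = np.log(np.logspace(-1, 3, 9))
        for la in grid:
            for lb in grid:
                x = optimize.fmin(
                    objective, [la, lb], xtol=1e-8, ftol=1e-12, disp=False
                )
                val = objective(x)
                if val < best_val:
                    best_x, best_val = x, val
                if best_val <= 1e-10:
                    break
            if best_val <= 1e-10:
                break
    alpha, beta = np.exp(best_x)
    return BetaShape(alpha=float(alpha), beta=float(beta), residual=best_val)


# ---------------------------------------------------------------------------
# Monte Carlo propagation
# ---------------------------------------------------------------------------

UncertainInput = Union[float, Tuple[float, float, float], BetaShape]


def mc_propagate(
    quantity: Callable[..., np.ndarray],
    inputs: Sequence[UncertainInput],
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    flag_discard_fraction: float = 0.01,
) -> CredibleSummary:
    """Propagate beta-distributed input uncertainty through a pipeline quantity.

    Parameters
    ----------
    quantity
        Deterministic function of the inputs.  Called once with one numpy
        array per input (each of length ``n_samples``) and must evaluate
        elementwise; draws where it returns NaN/inf are discarded.
    inputs
        Each entry is a plain float (fixed constant), a ``(median, lo, hi)``
        summary to fit, or a pre-fitted :class:`BetaShape`.
    n_samples
        Number of Monte Carlo draws (>= 1000).
    seed
        Seed for the random generator; identical seeds give bit-identical
        summaries.

    Returns the empirical 2.5%/50%/97.5% quantiles of the valid draws.  If
    more than ``flag_discard_fraction`` of draws are discarded the summary
    is flagged.
    """
    if n_samples < 1000:
        raise ValueError(f"n_samples must be at least 1000, got {n_samples}")
    rng = np.random.default_rng(seed)
    columns = []
    for inp in inputs:
        if isinstance(inp, BetaShape):
            columns.append(inp.sample(n_samples, rng))
        elif isinstance(inp, tuple):
            shape = fit_beta(*inp)
            columns.append(shape.sample(n_samples, rng))
        else:
            columns.append(np.full(n_samples, float(inp)))
    with np.errstate(all="ignore"):
        values = np.asarray(quantity(*columns), dtype=float)
    if values.shape != (n_samples,):
        values = np.broadcast_to(values, (n_samples,)).copy()
    valid = np.isfinite(values)
    n_discarded = int(n_samples - valid.sum())
    if valid.sum() == 0:
        raise ValueError("every Monte Carlo draw produced an undefined value")
    lo, median, hi = np.quantile(values[valid], QUANTILE_LEVELS)
    return CredibleSummary(
        median=float(median),
        lo=float(lo),
        hi=float(hi),
        n_samples=n_samples,
        seed=seed,
        n_discarded=n_discarded,
        flagged=n_discarded > flag_discard_fraction * n_samples,
    )


# ---------------------------------------------------------------------------
# Boole-Frechet bounds
# ---------------------------------------------------------------------------

RuleFamily = Literal["and", "or", "majority"]


def frechet_bounds(
    profiles: Sequence[TestProfile], rule_family: RuleFamily
) -> Tuple[ProbabilityInterval, ProbabilityInterval]:
    """Best-possible (TPR, TNR) intervals without any independence assumption.

    AND:      TPR in [max(0, sum TPR_i - (n-1)), min_i TPR_i],
              TNR in [max_i TNR_i, min(1, sum TNR_i)];
    OR:       TPR in [max_i TPR_i, min(1, sum TPR_i)],
              TNR in [max(0, sum TNR_i - (n-1)), min_i TNR_i];
    majority: both coordinates in [max(0, sum - (n-1)), min(1, sum)]
              (odd n only), containing the AND and OR bounds.
    """
    if not profiles:
        raise ValueError("need at least one test profile")
    family = rule_family.lower()
    n = len(profiles)
    tprs = [p.tpr for p in profiles]
    tnrs = [p.tnr for p in profiles]
    if family == "and":
        tpr_iv = ProbabilityInterval(max(0.0, sum(tprs) - (n - 1)), min(tprs))
        tnr_iv = ProbabilityInterval(max(tnrs), min(1.0, sum(tnrs)))
    elif family == "or":
        tpr_iv = ProbabilityInterval(max(tprs), min(1.0, sum(tprs)))
        tnr_iv = ProbabilityInterval(max(0.0, sum(tnrs) - (n - 1)), min(tnrs))
    elif family == "majority":
        if n % 2 == 0:
            raise ValueError(f"majority bounds require odd n, got n={n}")
        tpr_iv = ProbabilityInterval(
            max(0.0, sum(tprs) - (n - 1)), min(1.0, sum(tprs))
        )
        tnr_iv = ProbabilityInterval(
            max(0.0, sum(tnrs) - (n - 1)), min(1.0, sum(tnrs))
        )
    else:
        raise ValueError(
            f"rule_family must be 'and', 'or' or 'majority', got {rule_family!r}"
        )
    return tpr_iv, tnr_iv


# ---------------------------------------------------------------------------
# Empirical dependence factors
# ---------------------------------------------------------------------------

def dependence_factors(
    cohort: pd.DataFrame, status_column: str = "status"
) -> DependenceFactors:
    """Estimate pairwise dependence factors from a subjects-by-tests table.

    ``cohort`` has one row per subject, a 0/1 ``status`` column (true
    condition X) and one 0/1 column per test; missing results are NaN.
    For each unordered test pair (i, j):

    * ``lambda_pp`` uses subjects with X=1 and both results observed:
      empirical ``Pr(Yi=1, Yj=1) / (Pr(Yi=1) * Pr(Yj=1))``;
    * ``lambda_nn`` likewise from X=0 subjects and both-negative
      frequencies.

    Marginals are computed on the same pairwise-complete subset, so the
    matrices are symmetric by construction.  Pairs with no complete
    observations, or a zero marginal frequency, are NaN (unavailable),
    never 0.
    """
    if status_column not in cohort.columns:
        raise ValueError(f"cohort table has no {status_column!r} column")
    test_cols = [c for c in cohort.columns if c != status_column]
    if len(test_cols) < 2:
        raise ValueError("need at least two test columns to estimate dependence")
    status = cohort[status_column].to_numpy()
    if np.isnan(status.astype(float)).any():
        raise ValueError("status column must have no missing values")

    k = len(test_cols)
    shape = (k, k)
    lam_pp = np.full(shape, np.nan)
    lam_nn = np.full(shape, np.nan)
    cnt_pos = np.zeros(shape, dtype=int)
    cnt_neg = np.zeros(shape, dtype=int)
    data = cohort[test_cols].to_numpy(dtype=float)

    for cls, lam, cnt, want in (
        (1, lam_pp, cnt_pos, 1.0),
        (0, lam_nn, cnt_neg, 0.0),
    ):
        sub = data[status == cls]
        for i in range(k):
            for j in range(i + 1, k):
                pair = sub[:, [i, j]]
                complete = ~np.isnan(pair).any(axis=1)
                m = int(complete.sum())
                cnt[i, j] = cnt[j, i] = m
                if m == 0:
                    continue
                yi, yj = pair[complete, 0], pair[complete, 1]
                p_i = np.mean(yi == want)
                p_j = np.mean(yj == want)
                if p_i == 0.0 or p_j == 0.0:
                    continue
                joint = np.mean((yi == want) & (yj == want))
                lam[i, j] = lam[j, i] = joint / (p_i * p_j)

    idx = pd.Index(test_cols)
    return DependenceFactors(
        lambda_pp=pd.DataFrame(lam_pp, index=idx, columns=idx),
        lambda_nn=pd.DataFrame(lam_nn, index=idx, columns=idx),
        counts_pos=pd.DataFrame(cnt_pos, index=idx, columns=idx),
        counts_neg=pd.DataFrame(cnt_neg, index=idx, columns=idx),
    )
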