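"""Beta fitting, Monte Carlo propagation, Frechet bounds, dependence factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from testfuse import (
    TestProfile,
    and_characteristics,
    dependence_factors,
    fit_beta,
    frechet_bounds,
    majority_characteristics,
    mc_propagate,
    or_characteristics,
)

from conftest import random_profiles


class TestFitBeta:
    def test_symmetric_summary_gives_symmetric_shapes(self):
        shape = fit_beta(0.5, 0.3, 0.7)
        assert shape.alpha == pytest.approx(shape.beta, abs=1e-3)

    @pytest.mark.parametrize("alpha,beta", [(2.0, 5.0), (0.8, 0.8), (40.0, 120.0)])
    def test_round_trip_recovers_known_shapes(self, alpha, beta):
        lo, med, hi = stats.beta.ppf([0.025, 0.5, 0.975], alpha, beta)
        fitted = fit_beta(med, lo, hi)
        assert fitted.alpha == pytest.approx(alpha, rel=0.01)
        assert fitted.beta == pytest.approx(beta, rel=0.01)

    def test_antigen_sensitivity_summary_reproduced(self):
        # Abbott Panbio sensitivity 74.8% (67.6-80.8%)
        shape = fit_beta(0.748, 0.676, 0.808)
        q = shape.quantiles()
        assert np.allclose(q, [0.676, 0.748, 0.808], atol=0.005)

    def test_boundary_touching_summary_is_clipped_not_rejected(self):
        # Siemens specificity 100% (98.0-100%)
        shape = fit_beta(1.0, 0.98, 1.0)
        assert shape.alpha > 0 and shape.beta > 0
        assert shape.quantiles()[0] >= 0.97

    @pytest.mark.parametrize(
        "median,lo,hi", [(0.5, 0.6, 0.7), (0.5, 0.5, 0.5), (0.5, 0.4, 1.1)]
    )
    def test_invalid_summaries_rejected(self, median, lo, hi):
        with pytest.raises(ValueError):
            fit_beta(median, lo, hi)


class TestMCPropagate:
    def test_identical_seeds_reproduce_bit_for_bit(self):
        args = dict(
            quantity=lambda a, b: a * b,
            inputs=[(0.8, 0.7, 0.9), (0.9, 0.85, 0.95)],
            n_samples=5000,
            seed=42,
        )
        assert mc_propagate(**args) == mc_propagate(**args)

    def test_constant_inputs_have_zero_width(self):
        s = mc_propagate(lambda a, b: a + b, [0.25, 0.5], n_samples=2000, seed=0)
        assert s.median == pytest.approx(0.75)
        assert s.width == 0.0
        assert s.n_discarded == 0

    def test_undefined_draws_are_discarded_and_flagged(self):
        # quantity undefined on roughly half the draws
        s = mc_propagate(
            lambda a: np.where(a > 0.5, a, np.nan),
            [(0.5, 0.3, 0.7)],
            n_samples=2000,
            seed=1,
        )
        assert s.n_discarded > 0
        assert s.flagged

    def test_interval_brackets_the_deterministic_estimate(self, antibody_panel):
        # corrected population prevalence with measured 1.9% (0.8-3.7%) and
        # the two antibody sensitivities uncertain
        agg = and_characteristics(antibody_panel)
        point = (0.019 + agg.tnr_s - 1) / (agg.tpr_s + agg.tnr_s - 1)

        def corrected(m, s1, s2):
            return m / (s1 * s2)

        summary = mc_propagate(
            corrected,
            [(0.019, 0.008, 0.037), (0.831, 0.754, 0.99), (0.911, 0.807, 0.961)],
            n_samples=20_000,
            seed=3,
        )
        assert summary.lo < point < summary.hi
        # published interval (1.1-5.0%) is a plausibility reference only
        assert 0.005 < summary.lo < point
        assert point < summary.hi < 0.10

    def test_intervals_shrink_with_more_samples(self):
        inputs = [(0.7, 0.6, 0.8)]
        wide = mc_propagate(lambda a: a, inputs, n_samples=1000, seed=9)
        narrow = mc_propagate(lambda a: a, inputs, n_samples=100_000, seed=9)
        mc_se = wide.width / np.sqrt(1000)
        assert narrow.width <= wide.width + 3 * mc_se

    def test_tiny_sample_count_rejected(self):
        with pytest.raises(ValueError):
            mc_propagate(lambda a: a, [(0.5, 0.4, 0.6)], n_samples=10, seed=0)


class TestFrechetBounds:
    def test_single_test_collapses_to_point(self):
        p = TestProfile("t", 0.8, 0.9)
        tpr_iv, tnr_iv = frechet_bounds([p], "and")
        assert (tpr_iv.lo, tpr_iv.hi) == (0.8, 0.8)
        assert (tnr_iv.lo, tnr_iv.hi) == (0.9, 0.9)

    def test_two_test_and_bounds_are_extremal_couplings(self):
        # margins 0.9 and 0.8: comonotone coupling attains min = 0.8,
        # countermonotone attains max(0, 0.9 + 0.8 - 1) = 0.7
        pair = [TestProfile("a", 0.9, 0.99), TestProfile("b", 0.8, 0.98)]
        tpr_iv, _ = frechet_bounds(pair, "and")
        assert tpr_iv.lo == pytest.approx(0.7)
        assert tpr_iv.hi == pytest.approx(0.8)

    @pytest.mark.parametrize("n", [2, 3])
    def test_independence_closed_forms_lie_inside_bounds(self, n):
        rng = np.random.default_rng(500 + n)
        for _ in range(1000):
            profiles = random_profiles(rng, n)
            a = and_characteristics(profiles)
            o = or_characteristics(profiles)
            and_tpr, and_tnr = frechet_bounds(profiles, "and")
            or_tpr, or_tnr = frechet_bounds(profiles, "or")
            assert a.tpr_s in and_tpr and a.tnr_s in and_tnr
            assert o.tpr_s in or_tpr and o.tnr_s in or_tnr

    def test_majority_bounds_contain_closed_form_and_union_span(self):
        rng = np.random.default_rng(501)
        for _ in range(200):
            profiles = random_profiles(rng, 3)
            m = majority_characteristics(profiles)
            maj_tpr, maj_tnr = frechet_bounds(profiles, "majority")
            and_tpr, _ = frechet_bounds(profiles, "and")
            or_tpr, _ = frechet_bounds(profiles, "or")
            assert m.tpr_s in maj_tpr and m.tnr_s in maj_tnr
            assert maj_tpr.lo <= and_tpr.lo and maj_tpr.hi >= or_tpr.hi

    def test_majority_requires_odd_n(self):
        with pytest.raises(ValueError, match="odd"):
            frechet_bounds([TestProfile("a", 0.9, 0.9)] * 2, "majority")


class TestDependenceFactors:
    def test_hand_counted_contingency_oracle(self):
        # 100 diseased subjects: 40 both-positive, marginals 50 and 60
        yi = np.zeros(100)
        yj = np.zeros(100)
        yi[:50] = 1
        yj[:40] = 1
        yj[50:70] = 1
        cohort = pd.DataFrame({"status": 1, "a": yi, "b": yj})
        # add healthy subjects so the X=0 class exists
        healthy = pd.DataFrame({"status": 0, "a": [0, 0, 1, 0], "b": [0, 1, 0, 0]})
        factors = dependence_factors(pd.concat([cohort, healthy], ignore_index=True))
        assert factors.lambda_pp.loc["a", "b"] == pytest.approx(0.40 / (0.5 * 0.6))
        assert factors.counts_pos.loc["a", "b"] == 100

    def test_duplicated_test_gives_reciprocal_sensitivity(self):
        rng = np.random.default_rng(8)
        x = np.ones(20_000, dtype=int)
        y = (rng.random(20_000) < 0.7).astype(float)
        cohort = pd.DataFrame(
            {"status": np.r_[x, np.zeros(1000, dtype=int)],
             "a": np.r_[y, (rng.random(1000) < 0.05).astype(float)],
             "b": np.r_[y, (rng.random(1000) < 0.05).astype(float)]}
        )
        # columns a and b are identical for diseased subjects
        factors = dependence_factors(cohort)
        tpr_hat = cohort.loc[cohort.status == 1, "a"].mean()
        assert factors.lambda_pp.loc["a", "b"] == pytest.approx(1 / tpr_hat)

    def test_symmetry_and_excluded_diagonal(self):
        rng = np.random.default_rng(15)
        cohort = pd.DataFrame(
            {
                "status": rng.integers(0, 2, 2000),
                "a": (rng.random(2000) < 0.5).astype(float),
                "b": (rng.random(2000) < 0.5).astype(float),
                "c": (rng.random(2000) < 0.5).astype(float),
            }
        )
        factors = dependence_factors(cohort)
        pp = factors.lambda_pp
        assert np.allclose(pp.to_numpy(), pp.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(pp.to_numpy())).all()

    def test_unobservable_pairs_are_nan_not_zero(self):
        cohort = pd.DataFrame(
            {
                "status": [1, 1, 0, 0],
                "a": [1.0, 0.0, 0.0, 1.0],
                "b": [np.nan, np.nan, np.nan, np.nan],
            }
        )
        factors = dependence_factors(cohort)
        assert np.isnan(factors.lambda_pp.loc["a", "b"])
        assert factors.counts_pos.loc["a", "b"] == 0

    def test_weighted_and_unweighted_means(self):
        rng = np.random.default_rng(21)
        cohort = pd.DataFrame(
            {
                "status": np.ones(5000, dtype=int),
                "a": (rng.random(5000) < 0.6).astype(float),
                "b": (rng.random(5000) < 0.6).astype(float),
                "c": (rng.random(5000) < 0.6).astype(float),
            }
        )
        cohort.loc[:10, "status"] = 0
        factors = dependence_factors(cohort)
        mean_pp, _ = factors.mean_factors(weighted=False)
        wmean_pp, _ = factors.mean_factors(weighted=True)
        assert mean_pp == pytest.approx(1.0, abs=0.1)
        assert wmean_pp == pytest.approx(mean_pp, abs=0.05)

    def test_requires_status_and_two_tests(self):
        with pytest.raises(ValueError):
            dependence_factors(pd.DataFrame({"a": [1], "b": [0]}))
        with pytest.raises(ValueError):
            dependence_factors(pd.DataFrame({"status": [1], "a": [1.0]}))
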