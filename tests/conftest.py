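"""Shared fixtures: published test panels and a brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

from testfuse import TestProfile


@pytest.fixture
def antigen_panel():
    """Three SARS-CoV-2 antigen tests (median sensitivity/specificity with
    95% CIs): Abbott Panbio, Innova, Siemens CLINITEST."""
    return [
        TestProfile("abbott", 0.748, 0.997, (0.676, 0.808), (0.996, 0.998)),
        TestProfile("innova", 0.681, 0.990, (0.472, 0.836), (0.985, 0.993)),
        TestProfile("siemens", 0.687, 1.000, (0.480, 0.838), (0.980, 1.000)),
    ]


@pytest.fixture
def antibody_panel():
    """The two Norrbotten serosurvey assays, combined with AND:
    Abbott SARS-CoV-2 IgG and Euroimmun anti-SARS-CoV-2 ELISA (IgG)."""
    return [
        TestProfile("abbott_igg", 0.831, 1.000, (0.754, 1.000), None),
        TestProfile("euroimmun", 0.911, 1.000, (0.807, 0.961), (0.965, 1.000)),
    ]


def random_profiles(rng: np.random.Generator, n: int, lo=0.05, hi=0.99):
    """n random test profiles with rates uniform in [lo, hi]."""
    return [
        TestProfile(f"t{i}", float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        for i in range(n)
    ]


def oracle_characteristics(rule, profiles):
    """Brute-force joint-distribution oracle for aggregate (TPR_S, TNR_S).

    Enumerates every joint outcome as a bit tuple, multiplies the
    conditional Bernoulli probabilities given each true status, looks the
    aggregate call up by recomputing the canonical index from the bits,
    and sums per class.  Independent of the package's sum-of-products
    accumulation path.
    """
    n = len(profiles)
    tpr_s = 0.0
    tnr_s = 0.0
    for bits in itertools.product((0, 1), repeat=n):
        p_given_pos = math.prod(
            p.tpr if b else 1.0 - p.tpr for b, p in zip(bits, profiles)
        )
        p_given_neg = math.prod(
            (1.0 - p.tnr) if b else p.tnr for b, p in zip(bits, profiles)
        )
        j = sum((1 - b) << (n - 1 - i) for i, b in enumerate(bits))
        if rule.outputs[j] == "+":
            tpr_s += p_given_pos
        else:
            tnr_s += p_given_neg
    return tpr_s, tnr_s
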