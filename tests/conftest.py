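"""Shared fixtures: small synthetic cohorts and independent test oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from liquidmrd import io as io_mod
from liquidmrd.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 21-patient simulated cohort mirroring the study size."""
    return simulate_cohort(CohortConfig(n_patients=21, seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """A 200-patient cohort for model-machinery and recovery checks."""
    return simulate_cohort(CohortConfig(n_patients=200, seed=11))


@pytest.fixture(scope="session")
def large_pipeline(tmp_path_factory, large_cohort):
    """Full pipeline run over the 200-patient cohort; returns output paths."""
    root = tmp_path_factory.mktemp("large")
    paths = io_mod.write_cohort(large_cohort, root / "input")
    config = io_mod.RunConfig(
        well_table=paths["wells"],
        sample_sheet=paths["sample_sheet"],
        spikein_table=paths["spikein"],
        output_dir=root / "out",
        seed=11,
    )
    return io_mod.run_pipeline(config)


def brute_force_auc(scores, outcomes) -> float:
    """Concordance over all case-control pairs, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    cases, controls = scores[y == 1], scores[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def exhaustive_permutation_p(scores, outcomes, midp: bool = False) -> float:
    """Two-sided permutation p for H0: AUC = 0.5, by exhaustive relabeling.

    With ``midp`` the observed deviation contributes half its probability
    mass (the mid-p correction for discrete permutation distributions).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n, npos = len(y), int(y.sum())
    obs = abs(brute_force_auc(scores, y) - 0.5)
    devs = []
    for combo in combinations(range(n), npos):
        lab = np.zeros(n, dtype=int)
        lab[list(combo)] = 1
        devs.append(abs(brute_force_auc(scores, lab) - 0.5))
    devs = np.asarray(devs)
    if midp:
        gt = float((devs > obs + 1e-12).mean())
        eq = float((np.abs(devs - obs) <= 1e-12).mean())
        return gt + 0.5 * eq
    return float((devs >= obs - 1e-12).mean())


def clopper_pearson_bisect(k: int, n: int, alpha: float = 0.05):
    """Exact binomial CI by bisection of the binomial tail probabilities."""
    from scipy.stats import binom

    def bisect(f, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            above = f(mid) > target
            if above == increasing:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    # lower bound: P(X >= k | p) = alpha/2, increasing in p
    # upper bound: P(X <= k | p) = alpha/2, decreasing in p
    lo = (
        0.0
        if k == 0
        else bisect(lambda p: 1.0 - binom.cdf(k - 1, n, p), alpha / 2, True)
    )
    hi = (
        1.0
        if k == n
        else bisect(lambda p: binom.cdf(k, n, p), alpha / 2, False)
    )
    return lo, hi
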