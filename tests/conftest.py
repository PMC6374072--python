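"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's computational paths:
group decisions are brute-forced over all 2^N vote vectors, and
optimal thresholds are found by dense grid search over expected cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from quorumpool import DecisionEcology, expected_cost, rates_at_threshold
from quorumpool.experiments import figure3_panel


# ---------------------------------------------------------------- oracles

def enumerate_choose_plus(v: float, n: int, q: float, tie_policy: str = "coin_flip") -> float:
    """P(group chooses '+') by summing over all 2^n vote vectors.

    Each vector with k '+'-votes has probability v^k (1-v)^(n-k); the
    group chooses '+' when k > q*n, with integer ties resolved per
    policy.  Exponential in n — keep n <= 12.
    """
    t = q * n
    tie = round(t) if abs(t - round(t)) < 1e-9 else None
    total = 0.0
    for mask in range(2**n):
        k = bin(mask).count("1")
        prob = v**k * (1.0 - v) ** (n - k)
        if k > t + 1e-9:
            total += prob
        elif tie is not None and k == tie and tie_policy == "coin_flip":
            total += 0.5 * prob
    return total


def enumerate_group_accuracy(a_plus: float, a_minus: float, p: float,
                             n: int, q: float, tie_policy: str = "coin_flip") -> float:
    """Overall group accuracy by brute-force enumeration in both states."""
    acc_plus = enumerate_choose_plus(a_plus, n, q, tie_policy)
    acc_minus = 1.0 - enumerate_choose_plus(1.0 - a_minus, n, q, tie_policy)
    return p * acc_plus + (1.0 - p) * acc_minus


def grid_search_threshold(eco: DecisionEcology, n_grid: int = 10_000):
    """Cost-minimising threshold by dense search over [mu- - 6s, mu+ + 6s].

    Returns (best_threshold, best_cost).  The grid cost is evaluated
    through the same closed-form rate/cost functions but never through
    the closed-form threshold, keeping the check independent.
    """
    from scipy.stats import norm

    xs = np.linspace(eco.mu_minus - 6 * eco.sigma, eco.mu_plus + 6 * eco.sigma, n_grid)
    a_plus = norm.sf((xs - eco.mu_plus) / eco.sigma)
    a_minus = norm.cdf((xs - eco.mu_minus) / eco.sigma)
    cost = eco.p * ((1 - a_plus) * eco.c_fn + a_plus * eco.c_tp) + (1 - eco.p) * (
        (1 - a_minus) * eco.c_fp + a_minus * eco.c_tn
    )
    i = int(np.argmin(cost))
    return float(xs[i]), float(cost[i])


def random_ecology(rng: np.random.Generator) -> DecisionEcology:
    """A random valid decision scenario.

    Ranges keep the optimal threshold within ~20 cue standard
    deviations of the means so tail probabilities stay well clear of
    floating-point underflow.
    """
    mu_minus = rng.uniform(-2.0, 2.0)
    return DecisionEcology(
        mu_minus=mu_minus,
        mu_plus=mu_minus + rng.uniform(0.8, 2.5),
        sigma=rng.uniform(0.6, 1.2),
        p=rng.uniform(0.05, 0.95),
        c_tp=rng.uniform(0.0, 1.0),
        c_tn=rng.uniform(0.0, 1.0),
        c_fp=rng.uniform(1.5, 6.0),
        c_fn=rng.uniform(1.5, 6.0),
    )


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def panel_points():
    """Optimal operating points for the six reference ecologies."""
    from quorumpool import optimal_operating_point

    out = {}
    for panel in "abcdef":
        spec = figure3_panel(panel)
        out[panel] = (spec, optimal_operating_point(spec.ecology))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260913)
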