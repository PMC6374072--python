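"""Individual signal detection: optimal threshold and operating point.

A lone decision-maker observes a scalar cue drawn from one of two
equal-variance normal distributions, N(mu_minus, sigma^2) in state "-"
and N(mu_plus, sigma^2) in state "+".  State "+" holds with prior
probability ``p``; the four decision outcomes carry costs (lower is
better).  The cost-minimising rule is a threshold rule: decide "+"
exactly when the cue exceeds a criterion x*, where x* follows in closed
form from the likelihood-ratio criterion beta.

The resulting state-wise accuracies

    a_plus  = P(cue > x* | state +)   (true positive rate)
    a_minus = P(cue <= x* | state -)  (true negative rate)

are the individual-level inputs to every group-level computation in
this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import EcologyError

__all__ = [
    "DecisionEcology",
    "OperatingPoint",
    "lr_criterion",
    "optimal_threshold",
    "rates_at_threshold",
    "optimal_operating_point",
    "roc_curve",
    "expected_accuracy",
    "expected_cost",
]


@dataclass(frozen=True)
class DecisionEcology:
    """One binary decision scenario: cue distributions, prior and costs.

    Parameters
    ----------
    mu_minus, mu_plus : float
        Cue means in state "-" and state "+"; ``mu_plus > mu_minus`` is
        required.  If your problem has the means the other way round,
        relabel the states rather than feeding an inverted ecology.
    sigma : float
        Common cue standard deviation, > 0.
    p : float
        Prior probability of state "+", strictly inside (0, 1).
    c_tp, c_tn, c_fp, c_fn : float
        Costs of true positive, true negative, false positive and false
        negative (lower = better).  Errors must be strictly costlier
        than the correct outcome in the same state: ``c_fn > c_tp`` and
        ``c_fp > c_tn``.  Payoff matrices should be negated by the
        caller.
    """

    mu_minus: float
    mu_plus: float
    sigma: float
    p: float
    c_tp: float
    c_tn: float
    c_fp: float
    c_fn: float

    def __post_init__(self) -> None:
        if not self.mu_plus > self.mu_minus:
            raise EcologyError(
                f"mu_plus ({self.mu_plus}) must exceed mu_minus "
                f"({self.mu_minus}); if your '+' state has the lower cue "
                "mean, relabel the states instead of inverting the means"
            )
        if not self.sigma > 0:
            raise EcologyError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 < self.p < 1.0:
            raise EcologyError(f"p must lie strictly in (0, 1), got {self.p}")
        if not self.c_fn > self.c_tp:
            raise EcologyError(
                f"degenerate costs: c_fn ({self.c_fn}) must exceed c_tp "
                f"({self.c_tp})"
            )
        if not self.c_fp > self.c_tn:
            raise EcologyError(
                f"degenerate costs: c_fp ({self.c_fp}) must exceed c_tn "
                f"({self.c_tn})"
            )


@dataclass(frozen=True)
class OperatingPoint:
    """A decision threshold with its state-wise accuracies.

    ``a_plus`` is the true positive rate, ``a_minus`` the true negative
    rate; the false positive rate is ``1 - a_minus``.  ``threshold`` may
    be NaN for points specified directly by their rates rather than
    derived from a cue model.
    """

    threshold: float
    a_plus: float
    a_minus: float

    def __post_init__(self) -> None:
        for name in ("a_plus", "a_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise EcologyError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_rates(cls, a_plus: float, a_minus: float) -> "OperatingPoint":
        """Build a point from accuracies alone (no cue threshold)."""
        return cls(threshold=math.nan, a_plus=a_plus, a_minus=a_minus)

    @property
    def fpr(self) -> float:
        return 1.0 - self.a_minus

    @property
    def tpr(self) -> float:
        return self.a_plus


def lr_criterion(eco: DecisionEcology) -> float:
    """Cost/prior-weighted likelihood-ratio criterion.

    beta = [(1 - p)(c_fp - c_tn)] / [p (c_fn - c_tp)]

    Deciding "+" whenever the likelihood ratio f_+(x)/f_-(x) exceeds
    beta minimises expected cost.  beta = 1 in the fully symmetric case
    (p = 1/2 and equal error-cost differences).
    """
    return ((1.0 - eco.p) * (eco.c_fp - eco.c_tn)) / (eco.p * (eco.c_fn - eco.c_tp))


def optimal_threshold(eco: DecisionEcology) -> float:
    """Cost-minimising cue criterion x*.

    For equal-variance Gaussians the likelihood ratio is monotone in the
    cue, so the beta-criterion maps to a single threshold:

        x* = (mu_plus + mu_minus)/2 + sigma^2 ln(beta) / (mu_plus - mu_minus)
    """
    beta = lr_criterion(eco)
    midpoint = 0.5 * (eco.mu_plus + eco.mu_minus)
    return midpoint + eco.sigma**2 * math.log(beta) / (eco.mu_plus - eco.mu_minus)


def rates_at_threshold(eco: DecisionEcology, x: float) -> OperatingPoint:
    """State-wise accuracies of the rule "decide '+' iff cue > x".

    a_plus = 1 - Phi((x - mu_plus)/sigma), a_minus = Phi((x - mu_minus)/sigma),
    with Phi the standard normal CDF.
    """
    a_plus = norm.sf((x - eco.mu_plus) / eco.sigma)
    a_minus = norm.cdf((x - eco.mu_minus) / eco.sigma)
    return OperatingPoint(threshold=float(x), a_plus=float(a_plus), a_minus=float(a_minus))


def optimal_operating_point(eco: DecisionEcology) -> OperatingPoint:
    """Operating point of the cost-minimising threshold rule."""
    return rates_at_threshold(eco, optimal_threshold(eco))


def roc_curve(eco: DecisionEcology, n_points: int = 201) -> np.ndarray:
    """ROC curve from a monotone threshold sweep.

    Thresholds are linearly spaced on [mu_minus - 6 sigma, mu_plus + 6 sigma],
    which pins the endpoints to within 1e-9 of (0, 0) and (1, 1); the
    exact limiting points are appended.  Returns a structured view as a
    float array of shape (n_points + 2, 3) with columns
    (threshold, fpr, tpr), ordered by increasing FPR.
    """
    if n_points < 2:
        raise EcologyError(f"n_points must be >= 2, got {n_points}")
    lo = eco.mu_minus - 6.0 * eco.sigma
    hi = eco.mu_plus + 6.0 * eco.sigma
    thresholds = np.linspace(hi, lo, n_points)  # FPR increasing
    fpr = norm.sf((thresholds - eco.mu_minus) / eco.sigma)
    tpr = norm.sf((thresholds - eco.mu_plus) / eco.sigma)
    out = np.column_stack([
        np.concatenate([[np.inf], thresholds, [-np.inf]]),
        np.concatenate([[0.0], fpr, [1.0]]),
        np.concatenate([[0.0], tpr, [1.0]]),
    ])
    return out


def expected_accuracy(p: float, point: OperatingPoint) -> float:
    """Expected individual accuracy a = p a_plus + (1 - p) a_minus.

    This is the single accuracy the classic jury-theorem model ascribes
    to each voter; the prior drops out exactly when a_plus = a_minus.
    """
    if not 0.0 <= p <= 1.0:
        raise EcologyError(f"p must lie in [0, 1], got {p}")
    return p * point.a_plus + (1.0 - p) * point.a_minus


def expected_cost(eco: DecisionEcology, point: OperatingPoint) -> float:
    """Expected cost of operating the given point in the given ecology."""
    plus = point.a_plus * eco.c_tp + (1.0 - point.a_plus) * eco.c_fn
    minus = point.a_minus * eco.c_tn + (1.0 - point.a_minus) * eco.c_fp
    return eco.p * plus + (1.0 - eco.p) * minus
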