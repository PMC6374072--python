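"""Group accuracy under quorum voting.

N voters observe the same true state of the world and vote
independently; each votes correctly with probability ``a_plus`` in
state "+" and ``a_minus`` in state "-" (conditional independence given
the state).  The group chooses "+" when the number of "+"-votes
strictly exceeds ``q * N``; an exact tie (only possible when ``q * N``
is an integer) is resolved by the rule's tie policy.

Group accuracy is available three ways: exactly via binomial tails,
by Monte Carlo simulation, and in the large-N limit.  The limit is
driven by the law of large numbers: the "+"-vote fraction converges to
``a_plus`` in state "+" and to ``1 - a_minus`` in state "-", so any
quorum strictly between these two rates separates the states perfectly
as N grows — the open interval ``(1 - a_minus, a_plus)`` is exactly the
set of asymptotically perfect quorums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Optional

import numpy as np
from scipy.stats import binom

from .exceptions import BelowChanceError, BoundaryQuorumError, ValidationError
from .sdt import DecisionEcology, OperatingPoint, expected_accuracy, optimal_operating_point

__all__ = [
    "GroupRule",
    "GroupAccuracyResult",
    "AsymptoticAccuracy",
    "p_choose_plus",
    "group_accuracy_exact",
    "group_accuracy_sim",
    "group_accuracy_sim_cues",
    "majority_accuracy_condorcet",
    "asymptotic_group_accuracy",
    "quorum_bounds",
    "recommend_quorum",
]

TiePolicy = Literal["coin_flip", "choose_minus"]

# q*N is treated as attaining an integer tie count when within this
# absolute tolerance of one; floating q like 0.035 times N=5001 must
# not spuriously register as a tie.
_TIE_ATOL = 1e-9


@dataclass(frozen=True)
class GroupRule:
    """Quorum voting rule: group size ``n``, quorum fraction ``q``.

    The group decides "+" iff (# of "+"-votes) > q*n strictly.
    ``tie_policy`` applies only when q*n is an integer and the count
    hits it exactly: ``coin_flip`` decides "+" with probability 1/2
    (half the tie mass in exact computation), ``choose_minus`` always
    decides "-".  q = 1/2 with odd n reproduces textbook majority.
    """

    n: int
    q: float = 0.5
    tie_policy: TiePolicy = "coin_flip"

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValidationError(f"group size n must be a positive integer, got {self.n}")
        if not 0.0 <= self.q < 1.0:
            raise ValidationError(f"quorum q must lie in [0, 1), got {self.q}")
        if self.tie_policy not in ("coin_flip", "choose_minus"):
            raise ValidationError(f"unknown tie_policy {self.tie_policy!r}")

    @property
    def tie_count(self) -> Optional[int]:
        """The integer vote count that ties, or None when no tie is possible."""
        t = self.q * self.n
        k = round(t)
        return int(k) if abs(t - k) < _TIE_ATOL else None


@dataclass(frozen=True)
class GroupAccuracyResult:
    """Group accuracy overall and per state of the world.

    ``accuracy = p * acc_plus + (1 - p) * acc_minus`` by construction;
    ``std_error`` and ``n_reps``/``seed`` are populated only for
    simulated results.
    """

    accuracy: float
    acc_plus: float
    acc_minus: float
    p: float
    method: Literal["exact", "simulated", "asymptotic"]
    n_reps: Optional[int] = None
    std_error: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "acc_plus", "acc_minus"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValidationError(f"{name} out of [0, 1]: {v}")
        recomposed = self.p * self.acc_plus + (1.0 - self.p) * self.acc_minus
        if abs(recomposed - self.accuracy) > 1e-9:
            raise ValidationError(
                f"inconsistent result: accuracy {self.accuracy} != "
                f"p*acc_plus + (1-p)*acc_minus = {recomposed}"
            )


class AsymptoticAccuracy(NamedTuple):
    """Large-N limit of group accuracy, with the per-state outcomes."""

    accuracy: float
    plus_correct: bool   # does the group decide "+" a.s. in state "+"?
    minus_correct: bool  # does the group decide "-" a.s. in state "-"?


def p_choose_plus(vote_plus_prob: float, rule: GroupRule) -> float:
    """P(group chooses "+") when each voter votes "+" independently
    with probability ``vote_plus_prob``.

    With K ~ Binomial(n, v) this is P(K > q n), plus half the tie mass
    P(K = q n) under the coin-flip policy when q n is an integer.
    """
    if not 0.0 <= vote_plus_prob <= 1.0:
        raise ValidationError(f"vote probability out of [0, 1]: {vote_plus_prob}")
    v, n = vote_plus_prob, rule.n
    k_tie = rule.tie_count
    if k_tie is not None:
        prob = binom.sf(k_tie, n, v)
        if rule.tie_policy == "coin_flip":
            prob += 0.5 * binom.pmf(k_tie, n, v)
    else:
        # strict "K > q n" with fractional q n: K >= ceil(q n)
        prob = binom.sf(math.ceil(rule.q * n) - 1, n, v)
    return float(min(1.0, max(0.0, prob)))


def group_accuracy_exact(point: OperatingPoint, p: float, rule: GroupRule) -> GroupAccuracyResult:
    """Exact group accuracy via binomial tails.

    In state "+" each voter votes "+" with probability ``a_plus`` and
    the group is correct when it chooses "+"; in state "-" each votes
    "+" with probability ``1 - a_minus`` and the group is correct when
    it does not.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    acc_plus = p_choose_plus(point.a_plus, rule)
    acc_minus = 1.0 - p_choose_plus(1.0 - point.a_minus, rule)
    return GroupAccuracyResult(
        accuracy=p * acc_plus + (1.0 - p) * acc_minus,
        acc_plus=acc_plus,
        acc_minus=acc_minus,
        p=p,
        method="exact",
    )


def group_accuracy_sim(
    point: OperatingPoint,
    p: float,
    rule: GroupRule,
    n_reps: int = 10_000,
    seed: int = 0,
) -> GroupAccuracyResult:
    """Monte Carlo group accuracy.

    Each replicate draws the true state (Bernoulli p), the "+"-vote
    count directly from the state-conditional binomial, applies the
    quorum rule (ties resolved per policy, coin flips drawn from the
    same generator), and scores correctness.  ``std_error`` is the
    binomial standard error of the overall accuracy estimate.
    Identical seeds give identical results.
    """
    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    rng = np.random.default_rng(seed)
    state_plus = rng.random(n_reps) < p
    v = np.where(state_plus, point.a_plus, 1.0 - point.a_minus)
    k = rng.binomial(rule.n, v)
    t = rule.q * rule.n
    choose_plus = k > t
    k_tie = rule.tie_count
    if k_tie is not None and rule.tie_policy == "coin_flip":
        ties = k == k_tie
        choose_plus = choose_plus | (ties & (rng.random(n_reps) < 0.5))
    correct = choose_plus == state_plus

    acc = float(correct.mean())
    n_plus = int(state_plus.sum())
    # conditional means; an empty state cell (possible at small n_reps)
    # reports the unconditional estimate to keep the decomposition exact
    if 0 < n_plus < n_reps:
        acc_plus = float(correct[state_plus].mean())
        acc_minus = float(correct[~state_plus].mean())
        p_hat = n_plus / n_reps
    else:
        acc_plus = acc_minus = acc
        p_hat = p
    return GroupAccuracyResult(
        accuracy=acc,
        acc_plus=acc_plus,
        acc_minus=acc_minus,
        p=p_hat,
        method="simulated",
        n_reps=n_reps,
        std_error=float(np.sqrt(acc * (1.0 - acc) / n_reps)),
        seed=seed,
    )


def group_accuracy_sim_cues(
    eco: DecisionEcology,
    rule: GroupRule,
    n_reps: int = 10_000,
    seed: int = 0,
) -> GroupAccuracyResult:
    """Cue-level Monte Carlo cross-check.

    Instead of drawing vote correctness from (a_plus, a_minus), each
    replicate draws N Gaussian cues from the state's distribution and
    each voter applies the optimal threshold.  Equivalent in law to
    :func:`group_accuracy_sim` at the optimal operating point; slower,
    kept as an independent sanity path.
    """
    from .sdt import optimal_threshold  # local to avoid cycles in docs

    if n_reps < 1:
        raise ValidationError(f"n_reps must be >= 1, got {n_reps}")
    x_star = optimal_threshold(eco)
    rng = np.random.default_rng(seed)
    state_plus = rng.random(n_reps) < eco.p
    mu = np.where(state_plus, eco.mu_plus, eco.mu_minus)
    cues = rng.normal(loc=mu[:, None], scale=eco.sigma, size=(n_reps, rule.n))
    k = (cues > x_star).sum(axis=1)
    t = rule.q * rule.n
    choose_plus = k > t
    k_tie = rule.tie_count
    if k_tie is not None and rule.tie_policy == "coin_flip":
        ties = k == k_tie
        choose_plus = choose_plus | (ties & (rng.random(n_reps) < 0.5))
    correct = choose_plus == state_plus
    acc = float(correct.mean())
    n_plus = int(state_plus.sum())
    if 0 < n_plus < n_reps:
        acc_plus = float(correct[state_plus].mean())
        acc_minus = float(correct[~state_plus].mean())
        p_hat = n_plus / n_reps
    else:
        acc_plus = acc_minus = acc
        p_hat = eco.p
    return GroupAccuracyResult(
        accuracy=acc,
        acc_plus=acc_plus,
        acc_minus=acc_minus,
        p=p_hat,
        method="simulated",
        n_reps=n_reps,
        std_error=float(np.sqrt(acc * (1.0 - acc) / n_reps)),
        seed=seed,
    )


def majority_accuracy_condorcet(
    a: float, n: int, tie_policy: TiePolicy = "coin_flip"
) -> float:
    """Classic single-accuracy majority-rule group accuracy.

    Each of n voters is correct independently with probability a; the
    group is correct when a strict majority is.  Identical to the
    two-accuracy model with a_plus = a_minus = a and q = 1/2: when only
    one error type exists, which state holds is irrelevant.  Above
    a = 1/2 this grows to 1 with n; below, it decays to 0.
    """
    if not 0.0 <= a <= 1.0:
        raise ValidationError(f"accuracy a must lie in [0, 1], got {a}")
    return p_choose_plus(a, GroupRule(n=n, q=0.5, tie_policy=tie_policy))


def asymptotic_group_accuracy(
    point: OperatingPoint, p: float, q: float
) -> AsymptoticAccuracy:
    """Large-N limit of group accuracy under quorum q.

    By the law of large numbers the "+"-vote fraction converges to
    a_plus in state "+" and to 1 - a_minus in state "-", so

        limit = p * 1{a_plus > q} + (1 - p) * 1{1 - a_minus < q}.

    Any q strictly inside (1 - a_minus, a_plus) gives limit 1.  For
    q = 1/2 the mixed-sign cases give p (when a_plus > 1/2 > a_minus)
    or 1 - p (when a_plus < 1/2 < a_minus): the group becomes certain
    to pick one action, and is then right exactly as often as that
    action's state occurs.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    if math.isclose(q, point.a_plus, abs_tol=1e-12) or math.isclose(
        q, 1.0 - point.a_minus, abs_tol=1e-12
    ):
        raise BoundaryQuorumError(
            f"quorum q={q} coincides with a vote-fraction limit "
            f"(a_plus={point.a_plus}, 1-a_minus={1.0 - point.a_minus}); "
            "the asymptotic accuracy is undefined at the boundary"
        )
    plus_correct = point.a_plus > q
    minus_correct = (1.0 - point.a_minus) < q
    accuracy = p * plus_correct + (1.0 - p) * minus_correct
    return AsymptoticAccuracy(accuracy=accuracy, plus_correct=plus_correct, minus_correct=minus_correct)


def quorum_bounds(point: OperatingPoint) -> tuple[float, float]:
    """Open interval (1 - a_minus, a_plus) of asymptotically perfect quorums.

    Defined only above the chance diagonal (a_plus > 1 - a_minus);
    on or below it, the interval is empty and the decision-maker should
    invert their decisions instead.
    """
    lower, upper = 1.0 - point.a_minus, point.a_plus
    if not upper > lower:
        raise BelowChanceError(
            f"operating point (a_plus={point.a_plus}, a_minus={point.a_minus}) "
            "is on or below the chance diagonal; no quorum interval exists — "
            "invert the decisions and retry"
        )
    return (lower, upper)


def recommend_quorum(point: OperatingPoint) -> tuple[float, str]:
    """Midpoint of the quorum interval and its relation to majority rule.

    Returns ``(q, label)`` with label ``sub_majority`` when the whole
    interval lies below 1/2, ``super_majority`` when wholly above, and
    ``majority_compatible`` when 1/2 lies inside (simple majority
    already drives group accuracy to 1).  The midpoint is a robust
    within-interval choice; optimising q per group size is deliberately
    out of scope.
    """
    lower, upper = quorum_bounds(point)
    q = 0.5 * (lower + upper)
    if upper <= 0.5:
        label = "sub_majority"
    elif lower >= 0.5:
        label = "super_majority"
    else:
        label = "majority_compatible"
    return q, label


def optimal_group_accuracy_exact(
    eco: DecisionEcology, rule: GroupRule
) -> GroupAccuracyResult:
    """Convenience: exact group accuracy for SDT-optimal individuals."""
    point = optimal_operating_point(eco)
    return group_accuracy_exact(point, eco.p, rule)


def individual_accuracy(eco: DecisionEcology) -> float:
    """Convenience: expected accuracy of one SDT-optimal individual."""
    return expected_accuracy(eco.p, optimal_operating_point(eco))
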