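"""Condorcet predictive errors and error-region maps.

The classic jury theorem ascribes a single accuracy ``a`` to each voter
and predicts that majority-group accuracy converges to 1 when a > 1/2
and to 0 when a < 1/2.  With two state-wise accuracies (a_plus,
a_minus) those predictions fail in three characteristic ways whenever
the two accuracies straddle 1/2:

* **Error Ia** — prediction "to 1" (a > 1/2) but the majority group
  actually converges to p (if a_plus > 1/2 > a_minus) or 1 - p (the
  mirror case), not to 1.
* **Error Ib** — Ia, and additionally the limit falls below the
  individual accuracy: groups end up *worse* than individuals.
* **Error II** — prediction "to 0" (a < 1/2) but the group converges to
  the same positive limit, not to 0.

A fourth case ("prediction to 0 but groups beat individuals") is
algebraically impossible: when a < 1/2 the mixed-sign limit always lies
below a.  :func:`no_error_iib_search` probes this claim numerically.

:func:`region_map` sweeps a grid of priors p and cost ratios
C_FP / C_FN (with C_TP = C_TN = 0, C_FN = 1), optimises the individual
at each cell via signal detection, classifies, and marks where a
requested error type occurs — the map of decision scenarios in which
majority voting misleads.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.stats import norm

from .exceptions import ValidationError
from .group import asymptotic_group_accuracy
from .sdt import DecisionEcology, OperatingPoint, expected_accuracy, optimal_operating_point

__all__ = [
    "ErrorClass",
    "ErrorRegionMap",
    "condorcet_prediction",
    "classify_scenario",
    "no_error_iib_search",
    "region_map",
]

#: equality tolerance for classification boundaries (a_plus = 1/2 etc.);
#: measure-zero set, reported as BOUNDARY rather than silently binned
BOUNDARY_TOL = 1e-12


class ErrorClass(enum.Enum):
    NONE = "none"
    ERROR_IA = "error_ia"
    ERROR_IB = "error_ib"
    ERROR_II = "error_ii"
    BOUNDARY = "boundary"
    BELOW_CHANCE = "below_chance"


def condorcet_prediction(a: float, tol: float = BOUNDARY_TOL) -> str:
    """The classic prediction for majority groups of accuracy-a voters:
    ``to_one`` if a > 1/2, ``to_zero`` if a < 1/2, ``indeterminate`` at
    a = 1/2 (within tol)."""
    if not 0.0 <= a <= 1.0:
        raise ValidationError(f"accuracy a must lie in [0, 1], got {a}")
    if abs(a - 0.5) <= tol:
        return "indeterminate"
    return "to_one" if a > 0.5 else "to_zero"


@dataclass(frozen=True)
class ScenarioVerdict:
    """Full classification of one (operating point, prior) scenario."""

    error_class: ErrorClass
    prediction: str          # Condorcet's prediction: to_one / to_zero / indeterminate
    actual_limit: float      # true majority-rule (q = 1/2) large-N limit; NaN on a boundary
    individual_accuracy: float


def classify_scenario(
    point: OperatingPoint, p: float, tol: float = BOUNDARY_TOL
) -> ScenarioVerdict:
    """Classify a decision scenario into the Condorcet error taxonomy.

    Order of tests (most to least structural): below-chance points,
    then the no-error region (both accuracies above 1/2), then — in the
    mixed-sign region — Error II (individual accuracy below 1/2),
    Error Ib (limit below individual accuracy) and finally Error Ia.
    Any defining inequality that is an equality within ``tol`` yields
    BOUNDARY.  The reported class is the most specific: Ib implies Ia's
    conditions.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p must lie strictly in (0, 1), got {p}")
    a_p, a_m = point.a_plus, point.a_minus
    a = expected_accuracy(p, point)
    margin = a_p - (1.0 - a_m)  # above-chance margin

    if abs(margin) <= tol:
        return ScenarioVerdict(ErrorClass.BOUNDARY, condorcet_prediction(a), float("nan"), a)
    if margin < 0:
        return ScenarioVerdict(
            ErrorClass.BELOW_CHANCE,
            condorcet_prediction(a),
            asymptotic_group_accuracy(point, p, 0.5).accuracy if _off_half(point, tol) else float("nan"),
            a,
        )
    if abs(a_p - 0.5) <= tol or abs(a_m - 0.5) <= tol:
        return ScenarioVerdict(ErrorClass.BOUNDARY, condorcet_prediction(a), float("nan"), a)

    limit = asymptotic_group_accuracy(point, p, 0.5).accuracy

    if a_p > 0.5 and a_m > 0.5:
        return ScenarioVerdict(ErrorClass.NONE, condorcet_prediction(a), limit, a)

    # mixed-sign region: majority voting is suboptimal and Condorcet errs
    if abs(a - 0.5) <= tol:
        return ScenarioVerdict(ErrorClass.BOUNDARY, "indeterminate", limit, a)
    if a < 0.5:
        return ScenarioVerdict(ErrorClass.ERROR_II, "to_zero", limit, a)
    if abs(limit - a) <= tol:
        return ScenarioVerdict(ErrorClass.BOUNDARY, "to_one", limit, a)
    if limit < a:
        return ScenarioVerdict(ErrorClass.ERROR_IB, "to_one", limit, a)
    return ScenarioVerdict(ErrorClass.ERROR_IA, "to_one", limit, a)


def _off_half(point: OperatingPoint, tol: float) -> bool:
    return abs(point.a_plus - 0.5) > tol and abs(1.0 - point.a_minus - 0.5) > tol


def no_error_iib_search(n_samples: int, seed: int = 0) -> np.ndarray:
    """Search for the impossible "Error IIb": prediction "to 0" yet
    groups beating individuals.

    Draws random (a_plus, a_minus, p) above the chance diagonal with
    mixed-sign accuracies, and returns the rows (shape (k, 3)) where
    the Error II conditions hold (expected individual accuracy < 1/2)
    AND the majority-rule limit exceeds that individual accuracy.  The
    two requirements are algebraically incompatible, so the returned
    array is empty for every seed.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    a_p = rng.uniform(0.0, 1.0, n_samples)
    a_m = rng.uniform(0.0, 1.0, n_samples)
    p = rng.uniform(0.0, 1.0, n_samples)
    above_chance = a_p > 1.0 - a_m
    mixed = ((a_p > 0.5) & (a_m < 0.5)) | ((a_p < 0.5) & (a_m > 0.5))
    a = p * a_p + (1.0 - p) * a_m
    limit = np.where(a_p > 0.5, p, 1.0 - p)
    offending = above_chance & mixed & (a < 0.5) & (limit > a)
    return np.column_stack([a_p, a_m, p])[offending]


@dataclass(frozen=True)
class ErrorRegionMap:
    """Grid over (prior p, cost ratio C_FP/C_FN) of error-type occurrence.

    ``cells`` holds the full :class:`ErrorClass` per grid cell
    (shape |p_grid| x |ratio_grid|, p varying along rows); ``marked``
    is the boolean mask of cells where the requested error type
    (``which``) applies.  ``a_plus``/``a_minus`` store the optimal
    operating point per cell.
    """

    p_grid: np.ndarray
    ratio_grid: np.ndarray
    cells: np.ndarray          # dtype=object array of ErrorClass
    marked: np.ndarray         # bool
    a_plus: np.ndarray
    a_minus: np.ndarray
    which: Literal["ia", "ib", "ii", "any"]
    template: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.p_grid), len(self.ratio_grid))
        for name in ("cells", "marked", "a_plus", "a_minus"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")

    def to_frame(self):
        """Long-format table with columns p, ratio, a_plus, a_minus, error_class, marked."""
        import pandas as pd

        pp, rr = np.meshgrid(self.p_grid, self.ratio_grid, indexing="ij")
        return pd.DataFrame(
            {
                "p": pp.ravel(),
                "ratio": rr.ravel(),
                "a_plus": self.a_plus.ravel(),
                "a_minus": self.a_minus.ravel(),
                "error_class": [c.value for c in self.cells.ravel()],
                "marked": self.marked.ravel(),
            }
        )


_WHICH_TO_CLASSES = {
    "ia": {ErrorClass.ERROR_IA, ErrorClass.ERROR_IB},  # Ib refines Ia
    "ib": {ErrorClass.ERROR_IB},
    "ii": {ErrorClass.ERROR_II},
    "any": {ErrorClass.ERROR_IA, ErrorClass.ERROR_IB, ErrorClass.ERROR_II},
}


def default_p_grid(n: int = 201) -> np.ndarray:
    """Linear prior grid on (0.005, 0.995)."""
    return np.linspace(0.005, 0.995, n)


def default_ratio_grid(n: int = 201) -> np.ndarray:
    """Log-spaced cost-ratio grid on [1e-2, 1e2]; ratios above one make
    a false positive worse than a false negative, below one the reverse."""
    return np.logspace(-2, 2, n)


def region_map(
    template: dict | None = None,
    p_grid: np.ndarray | None = None,
    ratio_grid: np.ndarray | None = None,
    which: Literal["ia", "ib", "ii", "any"] = "any",
) -> ErrorRegionMap:
    """Classify every (p, ratio) cell of a grid of decision scenarios.

    Each cell builds the ecology (mu_minus, mu_plus, sigma from
    ``template``, default 0/1/1; c_fp = ratio, c_fn = 1,
    c_tp = c_tn = 0), computes the optimal operating point in closed
    form, and classifies it.  Vectorised over the whole grid; a sampled
    agreement test against the scalar :func:`classify_scenario` guards
    the vectorised path.
    """
    if which not in _WHICH_TO_CLASSES:
        raise ValidationError(f"unknown error map kind {which!r}")
    template = dict(template or {})
    mu_minus = template.setdefault("mu_minus", 0.0)
    mu_plus = template.setdefault("mu_plus", 1.0)
    sigma = template.setdefault("sigma", 1.0)
    template.setdefault("c_tp", 0.0)
    template.setdefault("c_tn", 0.0)
    template.setdefault("c_fn", 1.0)
    if not mu_plus > mu_minus or not sigma > 0:
        raise ValidationError("template must satisfy mu_plus > mu_minus and sigma > 0")
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    ratio_grid = default_ratio_grid() if ratio_grid is None else np.asarray(ratio_grid, dtype=float)
    for name, g in (("p_grid", p_grid), ("ratio_grid", ratio_grid)):
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValidationError(f"{name} must be non-empty and strictly increasing")
    if np.any((p_grid <= 0) | (p_grid >= 1)):
        raise ValidationError("priors must lie strictly in (0, 1)")
    if np.any(ratio_grid <= 0):
        raise ValidationError("cost ratios must be positive")

    pp, rr = np.meshgrid(p_grid, ratio_grid, indexing="ij")
    beta = (1.0 - pp) * rr / pp  # c_fp = ratio, c_fn = 1, c_tp = c_tn = 0
    x_star = 0.5 * (mu_plus + mu_minus) + sigma**2 * np.log(beta) / (mu_plus - mu_minus)
    a_plus = norm.sf((x_star - mu_plus) / sigma)
    a_minus = norm.cdf((x_star - mu_minus) / sigma)
    cells = _classify_grid(a_plus, a_minus, pp)

    marked = np.isin(
        np.vectorize(lambda c: c.value)(cells),
        [c.value for c in _WHICH_TO_CLASSES[which]],
    )
    return ErrorRegionMap(
        p_grid=p_grid,
        ratio_grid=ratio_grid,
        cells=cells,
        marked=marked,
        a_plus=a_plus,
        a_minus=a_minus,
        which=which,
        template=template,
    )


def _classify_grid(a_p: np.ndarray, a_m: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised mirror of :func:`classify_scenario` over arrays."""
    tol = BOUNDARY_TOL
    a = p * a_p + (1.0 - p) * a_m
    limit = np.where(a_p > 0.5, p, 1.0 - p)
    margin = a_p - (1.0 - a_m)

    out = np.full(a_p.shape, ErrorClass.NONE, dtype=object)
    boundary = (
        (np.abs(margin) <= tol)
        | (np.abs(a_p - 0.5) <= tol)
        | (np.abs(a_m - 0.5) <= tol)
    )
    below = (margin < -tol) & ~boundary
    mixed = ~boundary & ~below & (((a_p > 0.5) & (a_m < 0.5)) | ((a_p < 0.5) & (a_m > 0.5)))
    boundary_mixed = mixed & ((np.abs(a - 0.5) <= tol) | (np.abs(limit - a) <= tol))
    err_ii = mixed & ~boundary_mixed & (a < 0.5)
    err_ib = mixed & ~boundary_mixed & (a > 0.5) & (limit < a)
    err_ia = mixed & ~boundary_mixed & (a > 0.5) & (limit > a)

    out[boundary | boundary_mixed] = ErrorClass.BOUNDARY
    out[below] = ErrorClass.BELOW_CHANCE
    out[err_ii] = ErrorClass.ERROR_II
    out[err_ib] = ErrorClass.ERROR_IB
    out[err_ia] = ErrorClass.ERROR_IA
    return out
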