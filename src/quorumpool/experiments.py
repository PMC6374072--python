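"""End-to-end numerical experiments.

Reproduces, from printed parameters alone, the two families of results
this package exists for:

* accuracy-versus-group-size curves for six reference decision
  ecologies (three majority-rule failures and their quorum
  remediations), exactly and by simulation;
* the four (prior x cost-ratio) error-region maps showing where
  majority-based reasoning fails.

All six reference panels share the cue model mu_minus = 0,
mu_plus = sigma = 1 and costs C_TP = C_TN = 0, C_FN = 1, varying only
C_FP, the prior p and the quorum q:

====== ===== ==== ======= ==========================================
panel  C_FP   p     q      behaviour
====== ===== ==== ======= ==========================================
a       4    0.9   0.5    Error Ia: limit p = 0.9, above individual
b       4    0.9   0.7    super-majority remediation, limit 1
c       1    0.7   0.5    Error Ib: limit p = 0.7, below individual
d       1    0.7   0.75   super-majority remediation, limit 1
e      10    0.7   0.5    Error II: limit 1 - p = 0.3
f      10    0.7   0.035  sub-majority remediation, limit 1
====== ===== ==== ======= ==========================================
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .condorcet import default_p_grid, default_ratio_grid, region_map
from .exceptions import ValidationError
from .group import (
    GroupRule,
    asymptotic_group_accuracy,
    group_accuracy_exact,
    group_accuracy_sim,
)
from .sdt import DecisionEcology, expected_accuracy, optimal_operating_point

__all__ = [
    "ExperimentSpec",
    "PANELS",
    "figure3_panel",
    "accuracy_curve",
    "figure2_maps",
    "default_n_values",
]

#: default group-size grid: odd sizes so q = 1/2 never ties
def default_n_values(n_max: int = 501) -> list[int]:
    return list(range(1, n_max + 1, 2))


@dataclass(frozen=True)
class ExperimentSpec:
    """One accuracy-versus-group-size experiment."""

    ecology: DecisionEcology
    q: float
    n_values: Sequence[int] = field(default_factory=default_n_values)
    method: Literal["exact", "sim", "both"] = "both"
    n_reps: int = 10_000
    seed: int = 0
    tie_policy: str = "coin_flip"

    def __post_init__(self) -> None:
        ns = list(self.n_values)
        if not ns or any(n < 1 for n in ns) or any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValidationError("n_values must be non-empty, strictly increasing, all >= 1")
        if self.method not in ("exact", "sim", "both"):
            raise ValidationError(f"unknown method {self.method!r}")

    @property
    def reference_lines(self) -> dict[str, float]:
        """Individual accuracy and the majority-rule large-N limit —
        the horizontal guide lines of the reference panels."""
        point = optimal_operating_point(self.ecology)
        return {
            "individual_accuracy": expected_accuracy(self.ecology.p, point),
            "asymptotic_limit": asymptotic_group_accuracy(point, self.ecology.p, self.q).accuracy,
        }


# printed parameters of the six reference panels
PANELS: dict[str, dict[str, float]] = {
    "a": {"c_fp": 4.0, "p": 0.9, "q": 0.5},
    "b": {"c_fp": 4.0, "p": 0.9, "q": 0.7},
    "c": {"c_fp": 1.0, "p": 0.7, "q": 0.5},
    "d": {"c_fp": 1.0, "p": 0.7, "q": 0.75},
    "e": {"c_fp": 10.0, "p": 0.7, "q": 0.5},
    "f": {"c_fp": 10.0, "p": 0.7, "q": 0.035},
}


def figure3_panel(
    panel: str,
    n_values: Sequence[int] | None = None,
    method: Literal["exact", "sim", "both"] = "both",
    n_reps: int = 10_000,
    seed: int = 0,
) -> ExperimentSpec:
    """The experiment spec for reference panel a–f (see module table)."""
    try:
        params = PANELS[panel]
    except KeyError:
        raise ValidationError(
            f"unknown panel {panel!r}; expected one of {sorted(PANELS)}"
        ) from None
    eco = DecisionEcology(
        mu_minus=0.0,
        mu_plus=1.0,
        sigma=1.0,
        p=params["p"],
        c_tp=0.0,
        c_tn=0.0,
        c_fp=params["c_fp"],
        c_fn=1.0,
    )
    kwargs: dict = {"method": method, "n_reps": n_reps, "seed": seed}
    if n_values is not None:
        kwargs["n_values"] = list(n_values)
    return ExperimentSpec(ecology=eco, q=params["q"], **kwargs)


def accuracy_curve(spec: ExperimentSpec) -> pd.DataFrame:
    """Group accuracy at every group size in the spec.

    Returns one row per N with exact and/or simulated accuracies,
    per-state accuracies, the simulation standard error, and the two
    reference lines repeated per row (convenient for plotting layers).
    Deterministic given the seed: replicate streams are derived per N
    from the spec seed.
    """
    point = optimal_operating_point(spec.ecology)
    p = spec.ecology.p
    refs = spec.reference_lines
    rows = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(list(spec.n_values)))]
    for n, child in zip(spec.n_values, child_seeds):
        rule = GroupRule(n=int(n), q=spec.q, tie_policy=spec.tie_policy)  # type: ignore[arg-type]
        row: dict = {"n": int(n), "q": spec.q, "p": p,
                     "a_plus": point.a_plus, "a_minus": point.a_minus}
        if spec.method in ("exact", "both"):
            ex = group_accuracy_exact(point, p, rule)
            row.update(accuracy=ex.accuracy, acc_plus=ex.acc_plus, acc_minus=ex.acc_minus)
        if spec.method in ("sim", "both"):
            sim = group_accuracy_sim(point, p, rule, n_reps=spec.n_reps, seed=child)
            row.update(
                sim_accuracy=sim.accuracy,
                sim_acc_plus=sim.acc_plus,
                sim_acc_minus=sim.acc_minus,
                std_error=sim.std_error,
                seed=child,
            )
        row.update(refs)
        rows.append(row)
    return pd.DataFrame(rows)


def figure2_maps(
    out_dir: str | Path,
    p_grid: np.ndarray | None = None,
    ratio_grid: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write the four error-region maps (ia, ib, ii, any) as long-format
    CSVs plus a JSON metadata sidecar recording grids, template and
    version.  Returns the paths written, keyed by map kind."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_grid = default_p_grid() if p_grid is None else np.asarray(p_grid, dtype=float)
    ratio_grid = default_ratio_grid() if ratio_grid is None else np.asarray(ratio_grid, dtype=float)
    paths: dict[str, Path] = {}
    template: dict = {}
    for which in ("ia", "ib", "ii", "any"):
        m = region_map(p_grid=p_grid, ratio_grid=ratio_grid, which=which)  # type: ignore[arg-type]
        template = m.template
        path = out_dir / f"error_map_{which}.csv"
        m.to_frame().to_csv(path, index=False, float_format="%.12g")
        paths[which] = path
    meta = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "template": template,
        "p_grid": {"min": float(p_grid[0]), "max": float(p_grid[-1]), "n": int(p_grid.size), "scale": "linear"},
        "ratio_grid": {"min": float(ratio_grid[0]), "max": float(ratio_grid[-1]), "n": int(ratio_grid.size), "scale": "log"},
        "columns": ["p", "ratio", "a_plus", "a_minus", "error_class", "marked"],
    }
    meta_path = out_dir / "error_maps_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["meta"] = meta_path
    return paths
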