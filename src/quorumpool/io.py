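"""Configuration parsing and result serialization.

Ecology parameters come from CLI flags or a plain-text YAML/JSON config
with exactly the keys mu_minus, mu_plus, sigma, p, c_tp, c_tn, c_fp,
c_fn.  Results are written as JSON (deterministic key order, floats at
12 significant digits) or CSV; round-tripping a written result yields
an equal structure.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .exceptions import ValidationError
from .group import GroupAccuracyResult
from .sdt import DecisionEcology

__all__ = [
    "ECOLOGY_KEYS",
    "ecology_from_mapping",
    "load_ecology",
    "result_to_dict",
    "write_result",
    "roc_to_csv",
]

ECOLOGY_KEYS = ("mu_minus", "mu_plus", "sigma", "p", "c_tp", "c_tn", "c_fp", "c_fn")

#: CSV column order for group-accuracy records
GROUP_CSV_COLUMNS = [
    "n", "q", "p", "a_plus", "a_minus",
    "method", "accuracy", "acc_plus", "acc_minus", "std_error", "seed",
]


def _fmt(x: Any) -> Any:
    """Floats to 12 significant digits (round-trip stable)."""
    if isinstance(x, float):
        if math.isnan(x):
            return None
        return float(f"{x:.12g}")
    return x


def ecology_from_mapping(params: Mapping[str, Any]) -> DecisionEcology:
    """Build a validated ecology from a key-value mapping.

    Unknown keys and missing keys are both errors, named precisely so a
    typo in a config file surfaces as the offending field.
    """
    unknown = set(params) - set(ECOLOGY_KEYS)
    if unknown:
        raise ValidationError(
            f"unknown ecology key(s): {sorted(unknown)}; expected exactly {list(ECOLOGY_KEYS)}"
        )
    missing = set(ECOLOGY_KEYS) - set(params)
    if missing:
        raise ValidationError(f"missing ecology key(s): {sorted(missing)}")
    values = {}
    for k in ECOLOGY_KEYS:
        try:
            values[k] = float(params[k])
        except (TypeError, ValueError):
            raise ValidationError(f"ecology key {k!r} must be numeric, got {params[k]!r}") from None
    return DecisionEcology(**values)


def load_ecology(path: str | Path) -> DecisionEcology:
    """Read an ecology from a YAML (or JSON — a YAML subset) file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ValidationError(f"config {path} must be a key-value mapping, got {type(raw).__name__}")
    return ecology_from_mapping(raw)


def result_to_dict(result: Any) -> dict:
    """Serializable dict of a result dataclass with stable float formatting."""
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        d = dataclasses.asdict(result)
    elif isinstance(result, Mapping):
        d = dict(result)
    elif hasattr(result, "_asdict"):  # NamedTuple
        d = result._asdict()
    else:
        raise ValidationError(f"cannot serialize result of type {type(result).__name__}")
    return {k: _fmt(v) for k, v in d.items()}


def write_result(result: Any, path: str | Path, format: str = "json") -> Path:
    """Write a result (dataclass / mapping / DataFrame) to JSON or CSV.

    JSON objects use deterministic key order; group-accuracy CSV rows
    follow the documented column order and append to an existing file
    (writing the header only once).
    """
    path = Path(path)
    if format == "json":
        if isinstance(result, pd.DataFrame):
            payload = result.to_dict(orient="records")
            payload = [{k: _fmt(v) for k, v in row.items()} for row in payload]
        else:
            payload = result_to_dict(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        if isinstance(result, pd.DataFrame):
            df = result
        elif isinstance(result, GroupAccuracyResult):
            df = pd.DataFrame([result_to_dict(result)])
        else:
            df = pd.DataFrame([result_to_dict(result)])
        if isinstance(result, GroupAccuracyResult):
            for col in GROUP_CSV_COLUMNS:
                if col not in df.columns:
                    df[col] = None
            df = df[[c for c in GROUP_CSV_COLUMNS if c in df.columns]]
        header = not path.exists()
        df.to_csv(path, mode="a" if not header else "w", header=header,
                  index=False, float_format="%.12g")
    else:
        raise ValidationError(f"unknown output format {format!r}")
    return path


def roc_to_csv(curve, path: str | Path) -> Path:
    """Write an ROC sweep (threshold, fpr, tpr) array to CSV."""
    path = Path(path)
    pd.DataFrame(curve, columns=["threshold", "fpr", "tpr"]).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path
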