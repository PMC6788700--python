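"""Delimited-text input/output and config parsing.

CSV is the canonical dialect (TSV via ``sep``). Variable cells that are
blank or non-numeric are parsed as missing and counted; the target
column must parse strictly to 0/1. Threshold sets round-trip through a
flat CSV whose columns are
``variable, side, cut, direction, z, n_out, p_out, p_iqr, n_iqr, p25, p75``
plus a rounded ``cut_display``; floats are written at full precision so
the round trip is exact. A companion rules file renders each threshold
as one plain-English sentence.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import BaselineStats, ThresholdResult, ThresholdSet, UfaConfig
from .dataset import DataError, Dataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "threshold_set_to_frame",
    "threshold_set_from_frame",
    "write_threshold_report",
    "read_threshold_report",
    "load_config",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "variable", "side", "cut", "direction", "z",
    "n_out", "p_out", "p_iqr", "n_iqr", "p25", "p75", "cut_display",
]


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path, target: str, sep: Optional[str] = None,
    continuous_target: bool = False,
) -> Dataset:
    """Read a delimited table with a header row into a Dataset.

    Non-numeric or empty cells in variable columns become missing (the
    number of coerced cells is logged); a target cell that is not 0 or 1
    is an error, not a missing value.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    raw = pd.read_csv(path, sep=_sep_for(path, sep), float_precision="round_trip")
    if raw.shape[0] == 0:
        raise DataError("input has zero data rows")
    if target not in raw.columns:
        raise DataError(f"target column {target!r} not in header")
    yraw = pd.to_numeric(raw[target], errors="coerce")
    if yraw.isna().any():
        bad = raw[target][yraw.isna()].iloc[0]
        raise DataError(f"target value {bad!r} is not numeric")
    X = raw.drop(columns=[target])
    coerced = 0
    for name in X.columns:
        before = X[name].notna().sum()
        X[name] = pd.to_numeric(X[name], errors="coerce")
        coerced += int(before - X[name].notna().sum())
    if coerced:
        logger.warning("%d non-numeric variable cell(s) treated as missing", coerced)
    return Dataset(X, yraw, continuous_target=continuous_target)


def write_dataset(dataset: Dataset, path, target: str = "y",
                  sep: Optional[str] = None) -> None:
    path = Path(path)
    dataset.to_frame(target).to_csv(path, sep=_sep_for(path, sep), index=False)


def threshold_set_to_frame(thresholds: ThresholdSet) -> pd.DataFrame:
    rows = []
    for t in thresholds:
        rows.append({
            "variable": t.variable, "side": t.side, "cut": t.cut,
            "direction": t.direction, "z": t.z, "n_out": t.n_out,
            "p_out": t.p_out, "p_iqr": t.baseline.p_iqr,
            "n_iqr": t.baseline.n_iqr, "p25": t.baseline.p25,
            "p75": t.baseline.p75, "cut_display": float(f"{t.cut:.4g}"),
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def threshold_set_from_frame(
    frame: pd.DataFrame, config: Optional[UfaConfig] = None
) -> ThresholdSet:
    config = config or UfaConfig()
    results = []
    for _, r in frame.iterrows():
        results.append(ThresholdResult(
            variable=str(r["variable"]), cut=float(r["cut"]),
            side=str(r["side"]), direction=str(r["direction"]),
            z=float(r["z"]), n_out=int(r["n_out"]), p_out=float(r["p_out"]),
            baseline=BaselineStats(
                p25=float(r["p25"]), p75=float(r["p75"]),
                n_iqr=int(r["n_iqr"]), p_iqr=float(r["p_iqr"]),
            ),
            significant=True,
        ))
    return ThresholdSet(thresholds=tuple(results), config=config)


def write_threshold_report(
    thresholds: ThresholdSet, path, rules_path=None, outcome: str = "Y"
) -> None:
    """Write the threshold CSV and, optionally, the plain-English rules file."""
    path = Path(path)
    # %.17g round-trips IEEE doubles exactly through text
    threshold_set_to_frame(thresholds).to_csv(
        path, index=False, float_format="%.17g"
    )
    if rules_path is not None:
        lines = [t.rule_text(outcome) for t in thresholds]
        Path(rules_path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_threshold_report(path, config: Optional[UfaConfig] = None) -> ThresholdSet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    return threshold_set_from_frame(frame, config)


def load_config(path) -> UfaConfig:
    """Build a UfaConfig from a YAML/key-value file.

    Recognised keys mirror the UfaConfig fields; unknown keys are an
    error so typos do not silently fall back to defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"no such config file: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a key-value mapping")
    valid = {f.name for f in dc_fields(UfaConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "sides" in data:
        data["sides"] = tuple(data["sides"])
    return UfaConfig(**data)
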