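"""File formats: field CSV, grid CSV, trained-model JSON, YAML configs.

Field CSV layout: ``patient_id,eye,loc_1..loc_M`` with sensitivities in dB
(one decimal).  Values outside [0, 40] are clamped with a warning; missing
values are rejected.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import DB_MAX, DB_MIN, GridSpec, LocationSequence, PopulationMatrix
from .sors import SorsModel

__all__ = [
    "read_fields_csv",
    "write_fields_csv",
    "write_grid_csv",
    "grid_hash",
    "save_model",
    "load_model",
    "load_yaml_config",
]


class FieldsCsvError(ValueError):
    """Malformed field CSV (header, column count, or cell contents)."""


def _loc_columns(M: int):
    return [f"loc_{i}" for i in range(1, M + 1)]


def write_fields_csv(X: PopulationMatrix, path, eyes=None) -> None:
    cols = _loc_columns(X.M)
    df = pd.DataFrame(np.round(X.X.T, 1), columns=cols)
    df.insert(0, "patient_id", X.patient_ids)
    df.insert(1, "eye", eyes if eyes is not None else ["right"] * X.N)
    df.to_csv(path, index=False, float_format="%.1f")


def read_fields_csv(path, expected_M: int = 54) -> PopulationMatrix:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FieldsCsvError(f"cannot parse {path}: {exc}") from exc
    cols = _loc_columns(expected_M)
    expected = ["patient_id", "eye"] + cols
    if list(df.columns) != expected:
        raise FieldsCsvError(
            f"bad header: expected patient_id,eye,loc_1..loc_{expected_M}, "
            f"got {len(df.columns)} columns")
    values = df[cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FieldsCsvError("non-numeric sensitivity cell")
    if np.isnan(values).any():
        raise FieldsCsvError("missing sensitivity values are not allowed")
    if (values < DB_MIN).any() or (values > DB_MAX).any():
        warnings.warn("field values outside [0, 40] dB clamped", UserWarning,
                      stacklevel=2)
        values = np.clip(values, DB_MIN, DB_MAX)
    return PopulationMatrix(X=values.T, patient_ids=df["patient_id"].astype(str).tolist())


def write_grid_csv(grid: GridSpec, path) -> None:
    rows = [{"index": i + 1, "x_deg": x, "y_deg": y,
             "is_blind_spot": int(i in grid.blind_spot_indices)}
            for i, (x, y) in enumerate(grid.locations)]
    pd.DataFrame(rows).to_csv(path, index=False)


def grid_hash(grid: GridSpec) -> str:
    payload = json.dumps({"locations": list(grid.locations),
                          "blind_spot": list(grid.blind_spot_indices)})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_model(model: SorsModel, path, grid: GridSpec = None,
               trained_on: str = "") -> None:
    doc = {
        "sequence": list(model.sequence.indices),
        "bases": [D.tolist() for D in model.bases],
        "training_errors": model.training_errors.tolist(),
        "grid_hash": grid_hash(grid) if grid is not None else None,
        "trained_on": trained_on,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> SorsModel:
    doc = json.loads(Path(path).read_text())
    return SorsModel(
        sequence=LocationSequence(tuple(doc["sequence"])),
        bases=[np.asarray(D, dtype=float) for D in doc["bases"]],
        training_errors=np.asarray(doc["training_errors"], dtype=float),
    )


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return doc
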