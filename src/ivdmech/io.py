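"""File I/O: indentation CSVs, TIFF images, JSON sidecars, result tables.

Indent curves are delimited text with columns ``time_s``,
``displacement_um``, ``force_uN`` (the instrument-export convention) plus a
JSON sidecar carrying tip radius, Poisson's ratio and specimen metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .models import IndentationRecord

__all__ = [
    "SchemaError",
    "DataError",
    "read_indent_csv",
    "write_indent_csv",
    "read_image",
    "write_image",
    "fits_to_frame",
]

CURVE_COLUMNS = ("time_s", "displacement_um", "force_uN")


class SchemaError(ValueError):
    """A file is missing a required column or metadata key."""


class DataError(ValueError):
    """A file parsed but its contents violate an invariant."""


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_indent_csv(path: str | Path, sidecar: str | Path | None = None) -> IndentationRecord:
    """Read one indentation curve with optional metadata sidecar.

    Raises
    ------
    SchemaError
        If a required column is missing (the error names the column).
    DataError
        If the time column is not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in CURVE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path.name}: time_s must be strictly increasing")

    meta: dict[str, Any] = {}
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    return IndentationRecord(
        t=t,
        h=df["displacement_um"].to_numpy(dtype=float),
        P=df["force_uN"].to_numpy(dtype=float),
        tip_radius=float(meta.get("tip_radius_um", 42.0)),
        poisson_ratio=float(meta.get("poisson_ratio", 0.5)),
        spring_constant=meta.get("spring_constant_N_per_m", 0.48),
        metadata=meta.get("metadata", {}),
    )


def write_indent_csv(
    record: IndentationRecord, path: str | Path, with_sidecar: bool = True
) -> Path:
    """Write one curve as CSV plus a JSON sidecar with metadata/ground truth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": record.t, "displacement_um": record.h, "force_uN": record.P}
    ).to_csv(path, index=False)
    if with_sidecar:
        sidecar = {
            "tip_radius_um": record.tip_radius,
            "poisson_ratio": record.poisson_ratio,
            "spring_constant_N_per_m": record.spring_constant,
            "metadata": _jsonable(record.metadata),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-page or stacked grayscale TIFF."""
    return np.asarray(tifffile.imread(str(path)))


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale image (or stack) as TIFF; floats are kept as float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)
    return path


def fits_to_frame(records_and_fits) -> pd.DataFrame:
    """Tabulate (record, SLSFit) pairs into a per-indent fit table."""
    rows = []
    for record, fit in records_and_fits:
        md = record.metadata
        rows.append(
            {
                "group": md.get("group"),
                "specimen": md.get("specimen"),
                "structure": md.get("structure"),
                "level": md.get("level"),
                "stage": md.get("stage"),
                "E0_kPa": fit.params.E0,
                "E1_kPa": fit.params.E1,
                "tau1_s": fit.params.tau1,
                "E_ins_kPa": fit.E_ins,
                "E_eq_kPa": fit.E_eq,
                "f": fit.f,
                "rmse_uN": fit.rmse,
                "r_squared": fit.r_squared,
                "converged": fit.converged,
                "at_bounds": fit.at_bounds,
            }
        )
    return pd.DataFrame(rows)
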