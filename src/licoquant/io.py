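"""CSV/JSON input and output with schema checks.

Injection tables, concentration-time tables and reports round-trip
losslessly for all numeric fields (pandas writes shortest-round-trip
float representations). Missing required columns fail fast naming the
column; unknown extra columns are preserved with a warning; malformed
numeric cells report the offending row.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import pandas as pd

from .nca import ConcTimeTable

__all__ = [
    "INJECTION_COLUMNS",
    "read_injection_table",
    "write_injection_table",
    "read_conc_time_table",
    "write_conc_time_table",
    "write_json_report",
    "read_chromatograms_csv",
    "read_chromatograms_mzml",
]

INJECTION_COLUMNS = (
    "sample_id", "role", "day", "nominal",
    "rt_analyte", "rt_is",
    "area_quant", "area_qual1", "area_qual2", "area_is", "area_ratio",
)
_NUMERIC = (
    "day", "nominal", "rt_analyte", "rt_is",
    "area_quant", "area_qual1", "area_qual2", "area_is", "area_ratio",
)


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-base
            raise ValueError(
                f"{path}: malformed numeric value in column {col!r} at line {row}"
            )
        df[col] = coerced
    return df


def read_injection_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INJECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in INJECTION_COLUMNS]
    if extra:
        warnings.warn(f"{path}: preserving unknown columns {extra}", stacklevel=2)
    df = _check_numeric(df, _NUMERIC, path)
    df["day"] = df["day"].astype(int)
    return df


def write_injection_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_conc_time_table(
    path: str | Path, dose_ug_per_kg: float = 20_000.0
) -> ConcTimeTable:
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ("animal", "time_h", "conc") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df = _check_numeric(df, ("time_h", "conc"), path)
    truth = None
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    return ConcTimeTable(data=df, dose_ug_per_kg=dose_ug_per_kg, truth=truth)


def write_conc_time_table(table: ConcTimeTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index=False)
    if table.truth is not None:
        path.with_suffix(".truth.json").write_text(
            json.dumps(table.truth, indent=2, sort_keys=True)
        )


def write_json_report(report: dict[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_chromatograms_csv(path: str | Path):
    """Read traces from CSV columns (transition, time_min, intensity)."""
    from .peaks import Chromatogram

    df = pd.read_csv(path)
    missing = [c for c in ("transition", "time_min", "intensity") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    out = {}
    for tr, sub in df.groupby("transition"):
        sub = sub.sort_values("time_min")
        out[str(tr)] = Chromatogram(
            transition=str(tr),
            time=sub["time_min"].to_numpy(dtype=float),
            intensity=sub["intensity"].to_numpy(dtype=float),
        )
    return out


def read_chromatograms_mzml(path: str | Path):
    """Extract chromatogram arrays from an mzML file (needs pyteomics)."""
    from pyteomics import mzml as _mzml  # lazy optional dependency

    from .peaks import Chromatogram

    out = {}
    with _mzml.read(str(path)) as reader:
        for entry in reader.iterfind("chromatogram"):
            cid = entry.get("id", f"chrom{len(out)}")
            t = entry["time array"]
            y = entry["intensity array"]
            out[cid] = Chromatogram(transition=cid, time=t, intensity=y)
    return out
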