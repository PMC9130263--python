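"""Delimited-table readers/writers with schema checks."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_table",
    "read_bud_records",
    "read_growth",
    "read_peak_areas",
]

BUD_RECORD_COLUMNS = {"cell_id", "condition", "window", "replicate"}
GROWTH_COLUMNS = {"time_h", "replicate", "measured_cd"}
PEAK_AREA_COLUMNS = {"sample_id", "condition", "time_h", "replicate",
                     "metabolite", "area"}


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)
    return path


def _read(path: str | Path, required: set[str], what: str,
          sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{what} {path}: missing required column(s) {sorted(missing)}"
        )
    return df


def read_bud_records(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Bud-record table; needs site_1.. letters or angle_1.. degrees."""
    df = _read(path, BUD_RECORD_COLUMNS, "bud-record table", sep)
    has_sites = any(c in df.columns for c in ("site_1", "site_2"))
    has_angles = any(c in df.columns for c in ("angle_1", "angle_2"))
    if not (has_sites or has_angles):
        raise ValueError(
            f"bud-record table {path}: needs site_1..site_3 or angle_1..angle_3"
        )
    for c in ("site_1", "site_2", "site_3"):
        if c in df.columns:
            df[c] = df[c].fillna("").astype(str).str.strip().str.upper()
            df.loc[df[c] == "NAN", c] = ""
    return df


def read_growth(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    return _read(path, GROWTH_COLUMNS, "growth table", sep)


def read_peak_areas(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    df = _read(path, PEAK_AREA_COLUMNS, "peak-area table", sep)
    if "sample_role" not in df.columns:
        df["sample_role"] = "culture"
    return df
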