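"""Readers and writers for per-cell feature tables, plate maps and results.

All files are plain CSV (comma-separated, ``.`` decimal, UTF-8, mandatory
header).  Well labels are normalised to zero-padded row-letter + column
form (``A01``) on read so that joins between tables are exact.  Hit tables
can additionally be written as JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "normalize_well_label",
    "read_cell_features",
    "read_platemap",
    "read_profiles",
    "write_profiles",
    "read_nuclei_counts",
    "write_nuclei_counts",
    "write_hit_table",
    "write_platemap",
]

CELL_KEY_COLUMNS = ("plate", "well", "site", "cell_id")
PLATEMAP_COLUMNS = ("plate", "well", "compound", "concentration", "role")

_WELL_RE = re.compile(r"^([A-Za-z]{1,2})(\d{1,2})$")


def normalize_well_label(label: str) -> str:
    """Normalise a well label to ``A01`` form; raises on malformed labels."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"malformed well label: {label!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


@dataclass
class ValidationReport:
    """Plain-text-loggable record of what a reader fixed or flagged."""

    source: str
    n_rows: int = 0
    n_features: int = 0
    coerced_cells: int = 0
    messages: list[str] = field(default_factory=list)

    def log(self, msg: str) -> None:
        self.messages.append(msg)

    def to_text(self) -> str:
        head = (
            f"source: {self.source}\nrows: {self.n_rows}\nfeatures: {self.n_features}\n"
            f"non-numeric feature cells coerced to missing: {self.coerced_cells}\n"
        )
        return head + "".join(f"- {m}\n" for m in self.messages)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")


def read_cell_features(
    path: str | Path,
    key_columns: tuple[str, ...] = CELL_KEY_COLUMNS,
    cell_line: str | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a per-cell feature CSV.

    Key columns are validated (a hard error lists any that are missing);
    every remaining column is treated as a feature.  Non-numeric feature
    cells become missing values and are counted in the returned report.
    """
    df = pd.read_csv(path)
    report = ValidationReport(source=str(path))
    required = list(key_columns)
    if cell_line is None and "cell_line" in df.columns:
        required = ["cell_line"] + required
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cell feature table {path} is missing key columns: {missing}")
    feature_cols = [c for c in df.columns if c not in required]
    if not feature_cols:
        raise ValueError(f"cell feature table {path} has no feature columns")
    for col in feature_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            report.coerced_cells += int((coerced.isna() & df[col].notna()).sum())
            df[col] = coerced
    df["well"] = df["well"].map(normalize_well_label)
    if cell_line is not None:
        df.insert(0, "cell_line", cell_line)
    dup = df.duplicated(subset=required)
    if dup.any():
        raise ValueError(f"duplicate {tuple(required)} keys in {path} ({int(dup.sum())} rows)")
    report.n_rows = len(df)
    report.n_features = len(feature_cols)
    return df, report


def read_platemap(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate map CSV.

    Every plate must carry at least one vehicle-control (DMSO) well, since
    normalization is impossible without one; duplicate (plate, well) rows
    are a hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path} is missing columns: {missing}")
    df["well"] = df["well"].map(normalize_well_label)
    return validate_platemap(df, source=str(path))


def validate_platemap(df: pd.DataFrame, source: str = "<platemap>") -> pd.DataFrame:
    keys = ["cell_line", "plate", "well"] if "cell_line" in df.columns else ["plate", "well"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate {tuple(keys)} rows in {source}")
    bad_role = ~df["role"].isin(["treatment", "vehicle_control"])
    if bad_role.any():
        raise ValueError(f"unknown role values in {source}: {sorted(df.loc[bad_role, 'role'].unique())}")
    mislabelled = (df["role"] == "vehicle_control") & (df["compound"] != "DMSO")
    if mislabelled.any():
        raise ValueError(f"vehicle_control rows must have compound == 'DMSO' in {source}")
    for plate, grp in df.groupby("plate"):
        if not (grp["role"] == "vehicle_control").any():
            raise ValueError(f"plate {plate} has no DMSO (vehicle_control) wells; normalization impossible")
    return df


def write_platemap(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write image- or well-level profiles to CSV (lossless for finite values)."""
    profiles.to_csv(path, index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "well" in df.columns:
        df["well"] = df["well"].map(normalize_well_label)
    return df


def write_nuclei_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def read_nuclei_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["plate", "well", "nuclei_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"nuclei count table {path} is missing columns: {missing}")
    df["well"] = df["well"].map(normalize_well_label)
    return df


def write_hit_table(table: pd.DataFrame, path: str | Path, as_json: bool = False) -> None:
    """Write a hit table as CSV, or JSON (records orientation) when requested."""
    path = Path(path)
    if as_json or path.suffix.lower() == ".json":
        records = table.replace({np.nan: None}).to_dict(orient="records")
        path.write_text(json.dumps(records, indent=2), encoding="utf-8")
    else:
        table.to_csv(path, index=False)
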