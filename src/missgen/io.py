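"""Readers and writers for data tables and variable-type sidecars."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .structure import DataMatrix

_NA_DEFAULT = ("", "NA", "NaN", "nan")


def read_types(path: str | Path) -> dict[str, str]:
    """Two-column TSV sidecar (var_id, type) with type in {continuous, binary}."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("types sidecar needs columns (var_id, type)")
    frame.columns = ["var_id", "type", *frame.columns[2:]]
    types = dict(zip(frame["var_id"], frame["type"]))
    bad = set(types.values()) - {"continuous", "binary"}
    if bad:
        raise ValueError(f"unknown variable types in sidecar: {sorted(bad)}")
    return types


def read_data(
    table_path: str | Path,
    types_path: str | Path,
    missing_values=_NA_DEFAULT,
    index_col: str | int | None = None,
) -> DataMatrix:
    """Load a subjects-by-variables table (TSV/CSV/Parquet) plus its type sidecar."""
    path = Path(table_path)
    if path.suffix in (".parquet", ".pq"):
        frame = pd.read_parquet(path)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        frame = pd.read_csv(
            path, sep=sep, na_values=list(missing_values), keep_default_na=True,
            index_col=index_col,
        )
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.idxmax()] if hasattr(bad, "idxmax") else "?"
                raise ValueError(
                    f"non-numeric cell in column {col!r} (first at row {bad.idxmax()})"
                )
            frame[col] = coerced
    types = read_types(types_path)
    missing_decl = set(frame.columns) - set(types)
    if missing_decl:
        raise ValueError(f"no type declared for variables: {sorted(missing_decl)[:5]} ...")
    if frame.index.name is None and not isinstance(frame.index, pd.RangeIndex):
        pass
    frame.index = [str(i) for i in frame.index]
    return DataMatrix.from_frame(frame, types)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
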