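"""Tab-separated record-table round-tripping and run manifests.

The record schema (versioned in a ``#`` header) is the package's
exchange format: one row per stored frame, with the columns
time, replica_id, replicate_index, pH, window_id, z_nm, state,
bias_kJmol, equilibration_flag (plus optional analysis columns such as
insertion_A appended by the geometry calculators).  Lines starting with
``#`` carry provenance metadata and survive a round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd

from .engine import RECORD_COLUMNS

SCHEMA_VERSION = "1"

_DTYPES = {
    "time": float,
    "replica_id": str,
    "replicate_index": int,
    "pH": float,
    "window_id": str,
    "z_nm": float,
    "state": str,
    "bias_kJmol": float,
    "equilibration_flag": bool,
}


def write_records(records: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a record table as TSV with ``#`` provenance header lines."""
    path = Path(path)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing mandatory columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# titramem-records schema={SCHEMA_VERSION}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        records.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _read_header(path: Path) -> tuple[dict, int]:
    meta = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_comment


def read_records(
    path, chunksize: Optional[int] = None
) -> Union[tuple[pd.DataFrame, dict], Iterator[pd.DataFrame]]:
    """Read a record table (TSV).  With ``chunksize`` an iterator of
    DataFrames is returned (bounded memory in frame count); otherwise
    (table, metadata)."""
    path = Path(path)
    meta, n_comment = _read_header(path)

    def _finish(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s): {missing}")
        for col, dtype in _DTYPES.items():
            if col in ("window_id", "replica_id", "state"):
                df[col] = df[col].fillna("").astype(str)
                continue
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
                lineno = (bad.index[0] + n_comment + 2) if len(bad) else "?"
                raise ValueError(
                    f"{path}: column {col!r} has a type mismatch near line {lineno}"
                ) from exc
        return df

    reader = pd.read_csv(
        path,
        sep="\t",
        skiprows=n_comment,
        chunksize=chunksize,
        true_values=["True"],
        false_values=["False"],
    )
    if chunksize is not None:
        return (_finish(chunk.reset_index(drop=True)) for chunk in reader)
    return _finish(reader), meta


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(manifest), indent=2, sort_keys=True) + "\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
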