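"""Cohort and report file I/O.

CSV dialect: comma-separated, one header row, UTF-8, empty field =
missing.  Floats are serialized at 17 significant digits so round
trips are bit faithful.  Cohort files carry a JSON sidecar with the
generating spec and seed when simulated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import ROISchema

FLOAT_FORMAT = "%.17g"


def write_cohort(cohort: pd.DataFrame, path, spec=None) -> None:
    """Write a cohort CSV (+ JSON sidecar with the simulation spec)."""
    path = Path(path)
    cohort.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if spec is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"spec": spec.to_dict()}, indent=1,
                                      default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def read_cohort(path, schema: ROISchema) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the ROI schema.

    Mandatory columns: ``subject_id`` and every schema ROI.  Unknown
    columns are preserved as passthrough covariates.  Raises on missing
    mandatory columns, duplicate subject ids, or ragged rows (the parse
    error names the offending line).
    """
    try:
        df = pd.read_csv(path, on_bad_lines="error",
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in ["subject_id", *schema.names] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks mandatory columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values: {sorted(set(dup))}")
    return df


def write_matrix(values: np.ndarray, path, labels=None) -> None:
    """Write a square matrix as CSV with row/column labels."""
    n = values.shape[0]
    labels = labels if labels is not None else [f"S{i}" for i in range(n)]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, float_format=FLOAT_FORMAT)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_report(out_dir, objects: dict) -> dict:
    """Write a dict of name -> (DataFrame | str | dict) into out_dir.

    DataFrames become CSV, strings become text files, dicts become
    JSON.  Returns the file inventory with content hashes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory = {}
    for name, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        elif isinstance(obj, str):
            suffix = ".newick" if name.endswith("dendrogram") else ".txt"
            p = out_dir / f"{name}{suffix}"
            p.write_text(obj)
        elif isinstance(obj, dict):
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, default=_jsonable))
        else:
            raise TypeError(f"cannot write object of type {type(obj)} for {name}")
        inventory[name] = {"path": str(p), "sha256": file_sha256(p)}
    return inventory
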