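"""Validated table readers, result writers, and run manifests.

All delimited text is tab-separated UTF-8 with a mandatory header row and
``.`` decimals; lengths are μm and times hours throughout (no unit
inference).  Readers are tolerant of extra columns (warning) but strict
about missing or non-numeric required ones, reporting the offending
row/column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_results", "run_manifest"]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: required column -> dtype kind ("num" or "str") per named schema
SCHEMAS: dict[str, dict[str, str]] = {
    "labeling": {
        "population": "str",
        "time_h": "num",
        "fraction_labeled": "num",
        "sd": "num",
    },
    "sections": {
        "replicate": "str",
        "section": "str",
        "ap_position_um": "num",
        "n_pcna": "num",
        "n_mitotic": "num",
        "section_thickness_um": "num",
    },
    "geometry": {"replicate": "str", "mean_cell_length_um": "num"},
    "spindles": {
        "cell_id": "str",
        **{c: "num" for c in (
            "ax", "ay", "az", "bx", "by", "bz",
            "cx", "cy", "cz", "dx", "dy", "dz",
        )},
        "ap_position_um": "num",
    },
    "cleavage": {
        "cell_id": "str",
        "group": "str",
        **{c: "num" for c in ("sx1", "sy1", "sx2", "sy2", "apx1", "apy1", "apx2", "apy2")},
    },
}

#: recognised but not required columns, validated when present
OPTIONAL_COLS: dict[str, dict[str, str]] = {
    "labeling": {"n_animals": "num"},
    "sections": {},
    "geometry": {},
    "spindles": {"group": "str", "day": "num"},
    "cleavage": {},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV and validate it against a named schema.

    Missing required columns raise :class:`SchemaError` naming the
    column; non-numeric cells in numeric columns raise it with the 1-based
    data row and column name.  Unknown extra columns pass with a warning.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    optional = OPTIONAL_COLS.get(schema, {})
    extra = [c for c in df.columns if c not in spec and c not in optional]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {extra}", stacklevel=2)
    known = dict(spec)
    known.update({c: k for c, k in optional.items() if c in df.columns})
    for col, kind in known.items():
        if kind != "num":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}, data row {row}"
            )
        df[col] = converted
    return df


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "to_dict") and not isinstance(obj, (pd.DataFrame, pd.Series)):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return _to_jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _to_jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def write_results(
    result: Any, path: str | Path, fmt: str | None = None, force: bool = False
) -> Path:
    """Write a result object to JSON, or a DataFrame to TSV.

    Refuses to overwrite an existing file unless ``force``.  JSON writes
    use ``repr``-exact floats so a read-back reproduces every numeric
    field.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (--force) to overwrite")
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "json"
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        if not isinstance(result, pd.DataFrame):
            raise TypeError("tsv output requires a DataFrame")
        result.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(_to_jsonable(result), indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def run_manifest(config: Mapping[str, Any], seed: int | None) -> dict:
    """Reproducibility manifest: package version, canonical config hash,
    seed, and the fully materialized configuration."""
    from . import __version__

    materialized = _to_jsonable(dict(config))
    blob = json.dumps(materialized, sort_keys=True).encode()
    return {
        "package": "axoregen",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": materialized,
    }
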