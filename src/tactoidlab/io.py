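"""Shared table readers/writers, config handling and provenance records.

Tables are CSV or TSV (delimiter auto-detected); units are carried in the
column names (``*_um``, ``*_nm``, ``*_s``).  Every CLI run drops a JSON
provenance sidecar (config, seed, package version) beside its outputs so a
result can always be traced back to the exact invocation.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "read_table",
    "write_results",
    "write_provenance",
    "load_config",
]


class SchemaError(ValueError):
    """A table is missing required columns or contains non-numeric cells."""


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    numeric: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV table and validate it against a simple schema.

    The delimiter (comma or tab) is detected from the header line.
    ``required`` names the columns that must exist; ``numeric`` the columns
    (default: the required ones) that must parse as numbers — a failure
    reports the 1-based data row of the first offending cell.  Lines
    starting with ``#`` are treated as comments (used for trace metadata).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line
                break
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: empty input file")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric if numeric is not None else required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}, data row {row}"
            )
        df[col] = coerced
    return df


def write_results(
    records: pd.DataFrame | list[dict[str, Any]],
    path: str | Path,
    force: bool = False,
) -> Path:
    """Write records as CSV with deterministic column order and floats at
    6 significant digits; refuses to overwrite unless ``force``.

    Numbers round-trip through :func:`read_table` losslessly at that
    precision.  An empty record list yields a header-only file.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (--force) to overwrite")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def write_provenance(
    out_path: str | Path, config: dict[str, Any], seed: int | None = None
) -> Path:
    """Drop ``<out>.provenance.json`` recording config, seed and version."""
    from tactoidlab import __version__

    out_path = Path(out_path)
    side = out_path.with_suffix(out_path.suffix + ".provenance.json")
    payload = {
        "tool": "tactoidlab",
        "version": __version__,
        "seed": seed,
        "config": config,
        "argv": sys.argv,
    }
    side.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return side


def load_config(path: str | Path | None, overrides: dict[str, Any]) -> dict[str, Any]:
    """Merge a YAML config file with CLI overrides (CLI wins); unknown keys
    in the file are rejected so typos surface."""
    import yaml

    merged = dict(overrides)
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        if not isinstance(file_cfg, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(file_cfg) - set(overrides)
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        for key, val in file_cfg.items():
            if merged.get(key) is None:
                merged[key] = val
    return merged
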