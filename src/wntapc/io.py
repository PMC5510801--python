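"""Tabular and JSON serialization with reproducibility metadata."""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .config import RunConfig, config_hash

__all__ = ["write_results", "read_results", "run_metadata"]


def run_metadata(config: RunConfig | None = None, seed: int | None = None) -> dict[str, Any]:
    """Metadata block echoed into every output: version, seed, config hash."""
    meta: dict[str, Any] = {"package": "wntapc", "version": __version__}
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["effective_config"] = config.effective_dict()
        meta["seed"] = config.seed if seed is None else seed
    elif seed is not None:
        meta["seed"] = seed
    return meta


def _as_records(records) -> list[dict[str, Any]]:
    if isinstance(records, pd.DataFrame):
        return records.to_dict(orient="records")
    out = []
    for r in records:
        if dataclasses.is_dataclass(r) and not isinstance(r, type):
            out.append(dataclasses.asdict(r))
        elif isinstance(r, Mapping):
            out.append(dict(r))
        else:
            raise TypeError(f"cannot serialize record of type {type(r).__name__}")
    keys = {tuple(sorted(r)) for r in out}
    if len(keys) > 1:
        raise ValueError("records are not homogeneous: differing field sets")
    return out


def write_results(
    records: Sequence[Any] | pd.DataFrame,
    format: str,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Write homogeneous records as CSV (RFC-4180, full precision) or JSON.

    CSV floats use the shortest round-tripping repr; JSON output wraps the
    records with the metadata block and round-trips bit-exactly through
    :func:`read_results`.
    """
    rows = _as_records(records)
    path = Path(path)
    if format == "csv":
        if not rows:
            path.write_text("")
            return
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]), quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        payload = {"metadata": dict(metadata or {}), "records": rows}
        path.write_text(json.dumps(payload, indent=1, allow_nan=True))
    else:
        raise ValueError(f"unknown output format {format!r}; expected 'csv' or 'json'")


def read_results(path: str | Path) -> tuple[list[dict[str, Any]], dict[str, Any]]:
    """Inverse of :func:`write_results`; returns (records, metadata)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return payload["records"], payload.get("metadata", {})
    records = []
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            parsed: dict[str, Any] = {}
            for k, v in row.items():
                try:
                    parsed[k] = int(v)
                except ValueError:
                    try:
                        parsed[k] = float(v)
                    except ValueError:
                        parsed[k] = v
            records.append(parsed)
    return records, {}
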