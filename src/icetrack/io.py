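"""Table readers/writers with a documented column registry, plus the run
manifest used for reproducibility checks.

All tables are CSV (comma-separated, header row, no index column); every
table kind has a registered set of mandatory columns with units. Writing a
table also writes a ``<name>.meta.json`` sidecar holding the column units
and a SHA-256 checksum; reading validates the schema and flags unit
mismatches (e.g. a file recorded in nm where the registry expects um).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["TABLE_SCHEMAS", "SchemaError", "write_table", "read_table",
           "RunManifest"]


class SchemaError(ValueError):
    """A table violates its registered schema."""


# kind -> {column: unit}; '-' marks unitless columns
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "cells": {
        "cell_id": "-", "frame": "frame", "mother_id": "-",
        "length_um": "um", "width_um": "um", "x_um": "um", "y_um": "um",
        "angle_rad": "rad", "echerry": "au", "is_recipient": "-",
    },
    "foci": {
        "cell_id": "-", "frame": "frame", "channel": "-",
        "axial_um": "um", "transverse_um": "um", "score": "1-7",
        "intensity": "1-7",
    },
    "lineage": {
        "cell_id": "-", "birth_frame": "frame", "death_frame": "frame",
        "mother_id": "-", "fate": "-", "offspring_final": "-",
    },
    "classes": {
        "cell_id": "-", "echerry": "au", "class": "-", "qq_residual": "log-au",
    },
    "distribution": {
        "focus_count": "-", "cells": "-",
    },
    "pairs": {
        "cell_id": "-", "length_um": "um", "ploidy_class": "-",
        "distance_nm": "nm", "same_half": "-",
    },
    "events": {
        "donor_id": "-", "recipient_id": "-", "focus_frame": "frame",
        "echerry_frame": "frame", "donor_max_foci": "-", "status": "-",
    },
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_table(df: pd.DataFrame, path, kind: str) -> str:
    """Write a registered table kind with its metadata sidecar.

    Returns the SHA-256 checksum of the written CSV.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table missing column(s): {missing}")
    path = Path(path)
    df.to_csv(path, index=False)
    checksum = _sha256(path)
    sidecar = {"kind": kind, "units": schema, "sha256": checksum,
               "n_rows": int(len(df))}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=1))
    return checksum


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and schema-validate a registered table kind.

    Raises :class:`SchemaError` naming missing columns, and on unit
    mismatches between the sidecar metadata and the registry.
    """
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path)
    schema = TABLE_SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table {path.name} missing mandatory column(s): {missing}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        recorded = meta.get("units", {})
        for col, unit in recorded.items():
            if col in schema and unit != schema[col]:
                raise SchemaError(
                    f"unit mismatch in {path.name}, column {col!r}: "
                    f"file says {unit!r}, registry expects {schema[col]!r}")
    return df


@dataclasses.dataclass
class RunManifest:
    """Snapshot of a pipeline run: config, seeds, versions, checksums."""

    config: dict
    seed: int
    stage_seeds: dict
    checksums: dict = dataclasses.field(default_factory=dict)
    versions: dict = dataclasses.field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self):
        if not self.versions:
            import numpy
            import scipy

            from . import __version__
            self.versions = {"icetrack": __version__,
                             "numpy": numpy.__version__,
                             "scipy": scipy.__version__,
                             "pandas": pd.__version__,
                             "python": platform.python_version()}
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def record(self, name: str, checksum: str) -> None:
        self.checksums[name] = checksum

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
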