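"""Shared I/O: TIFF field stacks, CSV event tables, YAML configs, manifests.

Field stacks are written as multi-page 32-bit-float TIFFs with a JSON
sidecar carrying grid spacing and physical units (units are never inferred
from the data).  All writers are atomic (write to a temporary file in the
same directory, then rename), so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_field_stack",
    "write_field_stack",
    "read_events",
    "write_table",
    "load_config",
    "RunManifest",
    "write_manifest",
]

EVENT_COLUMNS = ["frame", "x", "y", "type"]


def _atomic_path(path: Path):
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    return Path(tmp)


def write_field_stack(field: np.ndarray, path: str | Path, **metadata: Any) -> None:
    """Write frames (or one frame) of a scalar/vector field as a float32
    multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    arr = np.asarray(field, dtype=np.float32)
    tmp = _atomic_path(path)
    try:
        tifffile.imwrite(tmp, arr)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)
    meta = {"shape": list(arr.shape), "dtype": "float32", **metadata}
    side = path.with_suffix(path.suffix + ".json")
    tmp = _atomic_path(side)
    tmp.write_text(json.dumps(meta, indent=1, default=str))
    os.replace(tmp, side)


def read_field_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF field stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    arr = tifffile.imread(path)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return np.asarray(arr), meta


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Atomically write a DataFrame as CSV with a fixed column order."""
    path = Path(path)
    tmp = _atomic_path(path)
    try:
        rows.to_csv(tmp, index=False)
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an extrusion-event catalog (frame, x, y, type[, id]) and
    validate it."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event catalog {path}: missing column(s) {missing}")
    if (df[["x", "y"]] < 0).any().any():
        bad = df.index[(df[["x", "y"]] < 0).any(axis=1)][0]
        raise ValueError(f"event catalog {path}: negative coordinate at row {bad}")
    if (df["frame"] < 0).any():
        raise ValueError(f"event catalog {path}: negative frame index")
    return df


def load_config(path: str | Path, required: dict[str, list[str]] | None = None) -> dict:
    """Load a YAML config and check for required keys.

    ``required`` maps section name -> list of keys; a missing key raises an
    error naming both the key and its section.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ValueError(f"config {path}: malformed YAML ({e})") from e
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    for section, keys in (required or {}).items():
        if section not in cfg:
            raise ValueError(f"config {path}: missing section '{section}'")
        for k in keys:
            if k not in cfg[section]:
                raise ValueError(f"config {path}: missing key '{k}' in section '{section}'")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    package_version: str = ""

    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    from . import __version__

    path = Path(path)
    manifest.package_version = manifest.package_version or __version__
    payload = asdict(manifest)
    payload["config_hash"] = manifest.config_hash()
    for group in ("inputs", "outputs"):
        payload[group] = {
            k: (_digest(Path(v)) if Path(v).exists() else v)
            for k, v in payload[group].items()
        }
    tmp = _atomic_path(path)
    tmp.write_text(json.dumps(payload, indent=1, default=str))
    os.replace(tmp, path)
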