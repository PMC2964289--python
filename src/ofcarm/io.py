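"""Result serialization: CSV tables, JSON run manifests, checksums."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig, config_to_dict

__all__ = ["write_results", "verify_manifest", "read_results"]

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            digest.update(block)
    return digest.hexdigest()


def write_results(
    records: Dict[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int,
    config: Optional[ExperimentConfig] = None,
    extra: Optional[dict] = None,
) -> dict:
    """Write per-table CSVs plus a manifest that fully determines a re-run.

    The manifest snapshots the configuration, seed and library versions and
    records a sha256 checksum per output file, so identical (config, seed)
    runs are verifiable bit-for-bit and tampered tables are detectable.
    """
    if not records:
        raise ValueError("no result tables to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = {}
    for name, frame in records.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        inventory[path.name] = _sha256(path)
    manifest = {
        "seed": int(seed),
        "config": config_to_dict(config) if config is not None else None,
        "created": datetime.now(timezone.utc).isoformat(),
        "versions": {
            "ofcarm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "files": inventory,
    }
    if extra:
        manifest["extra"] = extra
    with open(out / MANIFEST_NAME, "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every listed file; False if any checksum mismatches."""
    out = Path(out_dir)
    with open(out / MANIFEST_NAME, "r", encoding="utf-8") as handle:
        manifest = json.load(handle)
    for name, digest in manifest["files"].items():
        path = out / name
        if not path.exists() or _sha256(path) != digest:
            return False
    return True


def read_results(out_dir: str | Path) -> Dict[str, pd.DataFrame]:
    """Load every CSV listed in a result directory's manifest."""
    out = Path(out_dir)
    with open(out / MANIFEST_NAME, "r", encoding="utf-8") as handle:
        manifest = json.load(handle)
    return {Path(name).stem: pd.read_csv(out / name)
            for name in manifest["files"]}
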