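"""Plain-text output: TSV tables, JSON summaries, run manifests, config files."""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np

from . import __version__

__all__ = ["write_tsv", "write_json", "read_config", "run_manifest", "ensure_outdir"]


def ensure_outdir(path: str | Path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_tsv(df, path: str | Path) -> Path:
    """UTF-8, tab-delimited, header row."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
    return path


def read_config(path: str | Path) -> dict:
    """Flat key/value config (YAML); returns {} for an empty file."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping of parameter names to values")
    return cfg


def run_manifest(parameters: dict, seed: int | None, started: float) -> dict:
    """Reproducibility record written next to every CLI output."""
    return {
        "package": "genostore",
        "version": __version__,
        "seed": seed,
        "parameters": _jsonable(parameters),
        "python": platform.python_version(),
        "runtime_seconds": round(time.time() - started, 3),
        "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
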