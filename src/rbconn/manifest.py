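"""Run manifests: every CLI output directory records what produced it.

A manifest carries the command, a hash of its configuration, SHA-256 hashes
of the input files, the method and penalty, the seed, the package version and
a timestamp — enough to rerun the command and reproduce its outputs
bit for bit (for deterministic commands).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__

MANIFEST_NAME = "manifest.json"


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir, command: str, config: dict, inputs=(), **extra) -> Path:
    """Write the single manifest of an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "config_hash": _config_hash(config),
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        **extra,
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def read_manifest(out_dir) -> dict:
    return json.loads((Path(out_dir) / MANIFEST_NAME).read_text())
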