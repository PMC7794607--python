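"""Run manifests: a JSON record that makes every output re-derivable.

Each artifact-producing CLI command writes exactly one manifest next to
its outputs, recording the command, a hash of the effective configuration,
the seed, input and output paths, the package version and a timestamp.
Re-running the command with the recorded configuration and seed
reproduces stochastic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunManifest", "config_hash", "write_manifest"]


def config_hash(config) -> str:
    """SHA-256 of a canonical JSON rendering of a configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    inputs: tuple = ()
    outputs: tuple = ()
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_manifest(
    command: str,
    config,
    seed: int | None,
    inputs,
    outputs,
    directory,
    name: str = "manifest.json",
) -> Path:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config),
        seed=seed,
        inputs=tuple(str(p) for p in inputs),
        outputs=tuple(str(p) for p in outputs),
        version=__version__,
    )
    path = Path(directory) / name
    path.write_text(manifest.to_json() + "\n")
    return path
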