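"""Report writers and run manifests.

CSV dialect: comma-separated, header row, "." decimal, floats at 17
significant digits so every written trajectory round-trips bit-for-bit
through the package's own reader.  Every CLI run also writes a JSON
RunManifest recording the command, resolved arguments, config hash, seed and
package version; re-running a deterministic manifest reproduces its outputs
bit-for-bit.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .engine import Trajectory


def format_float(x: float) -> str:
    """Render a float at 17 significant digits (round-trip exact)."""
    return format(float(x), ".17g")


def write_trajectory_csv(path, traj: Trajectory, columns: list[str]) -> None:
    """Write a trajectory as CSV with time column ``t`` plus state columns."""
    if len(columns) != traj.states.shape[1]:
        raise ValueError("one column name per state component required")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", *columns])
        for t, row in zip(traj.times, traj.states):
            writer.writerow([format_float(t), *(format_float(v) for v in row)])


def read_trajectory_csv(path) -> tuple[list[str], Trajectory]:
    """Read a trajectory CSV back; returns (state column names, Trajectory)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [[float(v) for v in row] for row in reader]
    data = np.array(rows)
    return header[1:], Trajectory(data[:, 0], data[:, 1:])


def write_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(obj) -> str:
    """Stable SHA-256 hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    model: str
    invocation: dict  # resolved arguments, sufficient to re-run
    seed: int | None
    outputs: list[str]
    version: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @property
    def hash(self) -> str:
        return config_hash(self.invocation)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "model": self.model,
            "invocation": self.invocation,
            "config_hash": self.hash,
            "seed": self.seed,
            "outputs": list(self.outputs),
            "version": self.version,
            "timestamp": self.timestamp,
        }


def write_manifest(path, manifest: RunManifest) -> None:
    write_json(path, manifest.to_dict())


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def manifest_path_for(out_path) -> Path:
    out = Path(out_path)
    return out.with_suffix(out.suffix + ".manifest.json")
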