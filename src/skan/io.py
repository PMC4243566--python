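"""File formats, configuration, and run manifests.

Spike events travel as plain CSV with header ``time,channel`` (one event
per row, non-negative integers); labels as ``onset,pattern_id``.  Both
round-trip bit-exactly.  Configurations are flat YAML keyed by the model's
parameter names.  Every CLI run writes a JSON manifest (config snapshot,
master seed, package version, timestamps, output inventory with SHA-256
digests) sufficient to reproduce its outputs bit-exactly.
"""
from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .stimulus import StimulusStream

__all__ = [
    "read_events", "write_events", "read_labels", "write_labels",
    "load_config", "dump_config", "RunManifest", "write_manifest",
]


class EventFormatError(ValueError):
    """Malformed spike-event CSV."""


def _validate_int_frame(df: pd.DataFrame, cols: tuple, path) -> pd.DataFrame:
    if list(df.columns) != list(cols):
        raise EventFormatError(f"{path}: expected header {','.join(cols)}, "
                               f"got {','.join(map(str, df.columns))}")
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise EventFormatError(
                f"{path}: row {row + 1}: field {col!r} = {df[col].iloc[row]!r} "
                "is not a non-negative integer")
        df[col] = numeric.astype(np.int64)
    return df


def read_events(path, T: Optional[int] = None,
                n_channels: Optional[int] = None) -> StimulusStream:
    """Read a ``time,channel`` CSV into a stream (events sorted by time).
    ``T`` and ``n_channels`` may be supplied when known; otherwise the
    channel count is inferred and the period left unset."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _validate_int_frame(df, ("time", "channel"), path)
    events = df.to_numpy(dtype=np.int64).reshape(-1, 2)
    order = np.lexsort((events[:, 1], events[:, 0]))
    events = events[order]
    n_ch = n_channels if n_channels is not None else (
        int(events[:, 1].max()) + 1 if events.size else 1)
    duration = int(events[:, 0].max()) + 1 if events.size else 0
    if T is not None and duration:
        duration = ((duration + T - 1) // T) * T
    return StimulusStream(events, np.zeros(0, dtype=np.int64),
                          np.zeros(0, dtype=np.int64), T, max(duration, 1), n_ch)


def write_events(stream: StimulusStream, path) -> None:
    pd.DataFrame(stream.events, columns=["time", "channel"]).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    """Read an ``onset,pattern_id`` CSV into an ``(n, 2)`` int64 array."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _validate_int_frame(df, ("onset", "pattern_id"), path)
    return df.to_numpy(dtype=np.int64).reshape(-1, 2)


def write_labels(stream: StimulusStream, path) -> None:
    pd.DataFrame(stream.labels, columns=["onset", "pattern_id"]).to_csv(path, index=False)


def load_config(path) -> dict:
    """Flat YAML config; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of parameter names to values")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    command: str
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def write_manifest(out_dir, command: str, config: dict, seed: int,
                   started: _dt.datetime, output_files: list) -> Path:
    from . import __version__
    out_dir = Path(out_dir)
    manifest = RunManifest(
        command=command,
        config=config,
        seed=int(seed),
        version=__version__,
        started=started.isoformat(timespec="seconds"),
        finished=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        outputs={Path(f).name: _sha256(Path(f)) for f in output_files},
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json())
    return path
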