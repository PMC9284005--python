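"""Reading and writing recordings, metadata sidecars, and dataset manifests.

Storage layout is deliberately plain-text:

* signal file — headered CSV, one row per sample, columns ``t_s, ch1..chC``;
* metadata sidecar — ``<name>.json`` next to the CSV with ``fs_hz``,
  ``subject_id``, ``label``, ``channel_names``, ``trial_index``;
* manifest — TSV with columns ``path  subject  label  trial  fs_hz``.

Times are seconds from trial start; sample index ``i`` corresponds to
``t = i / fs_hz`` and all sample ranges are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

#: Movement classes, in canonical label-index order.
CLASSES = ("standing", "sitting", "walking")


class SignalFormatError(ValueError):
    """A signal file, sidecar, or manifest violates the storage contract."""


@dataclass
class RawRecording:
    """One trial's ``C x T`` signal matrix plus acquisition metadata.

    ``signal`` is in arbitrary signal units; rows are channels (muscles),
    columns are time samples at ``fs_hz``.
    """

    signal: np.ndarray
    fs_hz: int
    subject_id: str
    label: str
    channel_names: Sequence[str] = field(default_factory=list)
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValueError(f"signal must be a C x T matrix with C,T >= 1, got shape {self.signal.shape}")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"channel_names length {len(self.channel_names)} != channel count {self.signal.shape[0]}"
            )
        self.channel_names = list(self.channel_names)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, **kwargs) -> "RawRecording":
        return replace(self, **kwargs)


@dataclass
class DatasetManifest:
    """Ordered index of recording files belonging to one dataset."""

    entries: list[dict]

    def __post_init__(self) -> None:
        paths = [e["path"] for e in self.entries]
        if len(set(paths)) != len(paths):
            raise SignalFormatError("manifest contains duplicate paths")
        fs = {int(e["fs_hz"]) for e in self.entries}
        if len(fs) > 1:
            raise SignalFormatError(f"manifest mixes sampling rates {sorted(fs)}; all fs_hz must be equal")

    def __len__(self) -> int:
        return len(self.entries)


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".json")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write one recording as a CSV signal file plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.fs_hz
    table = np.column_stack([t, rec.signal.T])
    header = ",".join(["t_s"] + [f"ch{i + 1}" for i in range(rec.n_channels)])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt="%.10g")
    meta = {
        "fs_hz": int(rec.fs_hz),
        "subject_id": rec.subject_id,
        "label": rec.label,
        "channel_names": list(rec.channel_names),
        "trial_index": int(rec.trial_index),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_recording(path: str | Path) -> RawRecording:
    """Read a CSV + JSON sidecar pair back into a :class:`RawRecording`."""
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"signal file not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SignalFormatError(f"missing metadata sidecar for {path}: expected {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise SignalFormatError(f"malformed JSON sidecar {sidecar}: {exc}") from exc
    for key in ("fs_hz", "subject_id", "label", "channel_names", "trial_index"):
        if key not in meta:
            raise SignalFormatError(f"sidecar {sidecar} missing field {key!r}")
    with open(path) as fh:
        header = fh.readline().strip()
        has_data = bool(fh.readline().strip())
    if not header.startswith("t_s"):
        raise SignalFormatError(f"malformed header in {path}: expected leading 't_s' column, got {header!r}")
    if not has_data:
        raise SignalFormatError(f"empty signal file: {path}")
    try:
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise SignalFormatError(f"malformed signal file {path}: {exc}") from exc
    if table.size == 0:
        raise SignalFormatError(f"empty signal file: {path}")
    n_cols = table.shape[1] - 1
    if n_cols != len(meta["channel_names"]):
        raise SignalFormatError(
            f"{path}: {n_cols} data columns but sidecar declares "
            f"{len(meta['channel_names'])} channels"
        )
    return RawRecording(
        signal=table[:, 1:].T,
        fs_hz=int(meta["fs_hz"]),
        subject_id=str(meta["subject_id"]),
        label=str(meta["label"]),
        channel_names=list(meta["channel_names"]),
        trial_index=int(meta["trial_index"]),
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["path\tsubject\tlabel\ttrial\tfs_hz"]
    for e in manifest.entries:
        lines.append(f"{e['path']}\t{e['subject_id']}\t{e['label']}\t{e['trial_index']}\t{e['fs_hz']}")
    path.write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise SignalFormatError(f"manifest not found: {path}")
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["path", "subject", "label", "trial", "fs_hz"]:
            raise SignalFormatError(f"malformed manifest header in {path}: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise SignalFormatError(f"malformed manifest row in {path}: {line!r}")
            entries.append(
                {
                    "path": parts[0],
                    "subject_id": parts[1],
                    "label": parts[2],
                    "trial_index": int(parts[3]),
                    "fs_hz": int(parts[4]),
                }
            )
    return DatasetManifest(entries=entries)


def load_dataset(manifest_path: str | Path) -> list[RawRecording]:
    """Load every recording listed in a manifest, in manifest order."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    recs = []
    for e in manifest.entries:
        p = Path(e["path"])
        if not p.is_absolute():
            p = root / p
        if not p.exists():
            raise SignalFormatError(f"manifest {manifest_path} references missing file: {p}")
        rec = read_recording(p)
        if rec.fs_hz != int(e["fs_hz"]):
            raise SignalFormatError(f"{p}: sidecar fs_hz {rec.fs_hz} != manifest fs_hz {e['fs_hz']}")
        recs.append(rec)
    return recs
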