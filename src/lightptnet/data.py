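"""In-memory containers for windowed inertial data and the cached on-disk form.

A :class:`WindowedDataset` is the package's canonical container: an array of
fixed-length multichannel windows ``[n, T, C]`` with integer class labels,
per-window subject identifiers and an ordered class-name list.  A
:class:`RawStream` is an unsegmented per-subject recording with a label per
timestep; :func:`lightptnet.preprocess.sliding_window` turns streams into
windows.

Datasets cache to disk as a ``.npz`` of arrays plus a JSON sidecar holding
class names and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RawStream", "WindowedDataset", "save_dataset", "load_dataset"]


@dataclass
class RawStream:
    """One contiguous recording from one subject.

    channels: [N, C] raw sensor values (m/s^2 or rad/s); labels: length-N
    per-timestep activity strings; sampling_rate in Hz.
    """

    subject_id: str
    channels: np.ndarray
    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.channels.ndim != 2 or self.channels.shape[1] < 1:
            raise ValueError("channels must be [N, C] with C >= 1")
        if len(self.labels) != len(self.channels):
            raise ValueError("labels must align 1:1 with timesteps")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]


@dataclass
class WindowedDataset:
    """Segmented windows [n, T, C], integer labels, subject ids, class names."""

    windows: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    class_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=str)
        self.class_names = list(self.class_names)
        if self.windows.ndim != 3:
            raise ValueError("windows must be a [n, T, C] array")
        n = len(self.windows)
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels and subjects must have one entry/window")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels must lie in [0, n_classes)")
        if not np.isfinite(self.windows).all():
            raise ValueError("windows contain non-finite values")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def T(self) -> int:
        return self.windows.shape[1]

    @property
    def C(self) -> int:
        return self.windows.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subject_ids(self) -> list[str]:
        """Unique subjects in order of first appearance."""
        seen = dict.fromkeys(self.subjects.tolist())
        return list(seen)

    def select(self, index) -> "WindowedDataset":
        return WindowedDataset(self.windows[index], self.labels[index],
                               self.subjects[index], self.class_names,
                               dict(self.provenance))

    def one_hot_labels(self) -> np.ndarray:
        eye = np.eye(self.n_classes, dtype=np.float32)
        return eye[self.labels]


def save_dataset(ds: WindowedDataset, path) -> Path:
    """Write ``path.npz`` (arrays) and ``path.json`` (class names, provenance)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), windows=ds.windows, labels=ds.labels,
             subjects=ds.subjects)
    sidecar = {"class_names": ds.class_names, "provenance": ds.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_dataset(path) -> WindowedDataset:
    path = Path(path)
    npz = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    if not npz.exists():
        raise FileNotFoundError(f"missing dataset file {npz}")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing dataset sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with np.load(npz) as arrs:
        return WindowedDataset(arrs["windows"], arrs["labels"],
                               arrs["subjects"], meta["class_names"],
                               meta.get("provenance", {}))
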