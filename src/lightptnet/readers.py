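"""Readers for the three public smartphone-HAR dataset dialects.

* UCI HAR — pre-segmented fixed-width text files: nine "Inertial Signals"
  channel files per partition (one 128-column row per window), plus
  ``y_*.txt`` labels and ``subject_*.txt`` subject ids.
* WISDM v1 — one raw comma-separated stream
  (``user,activity,timestamp,x,y,z;``), segmented downstream with a
  sliding window.
* UniMiB SHAR — mat-file with the AF-17 adapted arrays: ``acc_data``
  rows of 3*151 values (the three axes concatenated) and ``acc_labels``
  ``[n, 3]`` (activity id, subject id, trial id).

Class-name order is frozen to the order the datasets' descriptions list
them in; labels are stored as integer indices into that order.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import scipy.io

from .data import RawStream, WindowedDataset

__all__ = [
    "UCIHAR_CLASSES",
    "WISDM_CLASSES",
    "UNIMIB_AF17_CLASSES",
    "UCIHAR_CHANNELS",
    "read_ucihar",
    "read_wisdm",
    "read_unimib",
    "write_wisdm_text",
]


class FormatError(ValueError):
    """Raised when a dataset file violates its dialect."""


UCIHAR_CLASSES = ["Walking", "Upstairs", "Downstairs",
                  "Sitting", "Standing", "Laying"]
WISDM_CLASSES = ["Jogging", "Walking", "Upstairs",
                 "Downstairs", "Sitting", "Standing"]
UNIMIB_AF17_CLASSES = [
    "StandingUpFS", "StandingUpFL", "Walking", "Running", "GoingUpS",
    "Jumping", "GoingDownS", "LyingDownFS", "SittingDown", "FallingForw",
    "FallingRight", "FallingBack", "HittingObstacle", "FallingwithPS",
    "FallingBackSC", "Syncope", "FallingLeft",
]

# channel order: total acceleration, body acceleration, gyroscope; x, y, z each
UCIHAR_CHANNELS = [
    "total_acc_x", "total_acc_y", "total_acc_z",
    "body_acc_x", "body_acc_y", "body_acc_z",
    "body_gyro_x", "body_gyro_y", "body_gyro_z",
]


def _load_text_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing UCI HAR file {path}")
    return np.loadtxt(path, ndmin=2)


def read_ucihar(root_path, partitions=("train", "test")) -> WindowedDataset:
    """Read the pre-segmented UCI HAR layout into windows [n, 128, 9].

    Channels are stacked in the order total-acc xyz, body-acc xyz, gyro xyz;
    the shipped label ids 1..6 map onto :data:`UCIHAR_CLASSES` in order.
    """
    root = Path(root_path)
    parts = []
    for part in partitions:
        chans = []
        for name in UCIHAR_CHANNELS:
            f = root / part / "Inertial Signals" / f"{name}_{part}.txt"
            chans.append(_load_text_matrix(f))
        rows = {c.shape[0] for c in chans}
        if len(rows) != 1:
            raise FormatError(
                f"channel files of partition {part!r} have unequal row "
                f"counts: {sorted(rows)}")
        windows = np.stack(chans, axis=2)  # [n, 128, 9]
        y = _load_text_matrix(root / part / f"y_{part}.txt").ravel().astype(int)
        subj = _load_text_matrix(
            root / part / f"subject_{part}.txt").ravel().astype(int)
        if not (len(y) == len(subj) == len(windows)):
            raise FormatError(
                f"partition {part!r}: {len(windows)} windows but {len(y)} "
                f"labels and {len(subj)} subject ids")
        if y.min() < 1 or y.max() > len(UCIHAR_CLASSES):
            raise FormatError(f"labels outside 1..{len(UCIHAR_CLASSES)}")
        parts.append((windows, y - 1, subj.astype(str)))
    windows = np.concatenate([p[0] for p in parts])
    labels = np.concatenate([p[1] for p in parts])
    subjects = np.concatenate([p[2] for p in parts])
    keep = np.isfinite(windows).all(axis=(1, 2))
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} windows with "
                      "non-finite samples")
    return WindowedDataset(windows[keep], labels[keep], subjects[keep],
                           UCIHAR_CLASSES,
                           provenance={"source": "ucihar", "root": str(root)})


def read_wisdm(file_path, sampling_rate: float = 20.0) -> list[RawStream]:
    """Parse the WISDM v1 raw text dialect into per-(subject, activity) streams.

    Records are ``user,activity,timestamp,x,y,z`` optionally terminated by
    ``;``; several records may share a physical line.  Malformed or null
    rows are dropped and counted in a warning.  Rows are grouped by user
    (file order preserved within a user) and split at activity changes.
    """
    path = Path(file_path)
    if not path.exists():
        raise FileNotFoundError(f"missing WISDM file {path}")
    text = path.read_text()
    rows_by_user: dict[str, list[tuple[str, float, float, float]]] = {}
    dropped = 0
    n_rows = 0
    for record in text.replace("\n", ";").split(";"):
        record = record.strip()
        if not record:
            continue
        n_rows += 1
        fields = [f.strip() for f in record.split(",")]
        if len(fields) != 6 or any(f == "" for f in fields):
            dropped += 1
            continue
        user, activity, _ts, xs, ys, zs = fields
        if activity not in WISDM_CLASSES:
            raise FormatError(
                f"unknown activity {activity!r}; valid labels: "
                f"{', '.join(WISDM_CLASSES)}")
        try:
            xyz = (float(xs), float(ys), float(zs))
        except ValueError:
            dropped += 1
            continue
        if not all(np.isfinite(v) for v in xyz):
            dropped += 1
            continue
        rows_by_user.setdefault(user, []).append((activity, *xyz))
    if n_rows == 0:
        raise FormatError(f"no parseable records in {path}")
    if dropped:
        warnings.warn(f"dropped {dropped} malformed/null WISDM rows "
                      f"out of {n_rows}")
    streams = []
    for user, rows in rows_by_user.items():
        start = 0
        for i in range(1, len(rows) + 1):
            if i == len(rows) or rows[i][0] != rows[start][0]:
                seg = rows[start:i]
                streams.append(RawStream(
                    subject_id=user,
                    channels=np.array([r[1:] for r in seg]),
                    labels=np.array([r[0] for r in seg]),
                    sampling_rate=sampling_rate))
                start = i
    return streams


def write_wisdm_text(streams: list[RawStream], path,
                     sampling_rate: float = 20.0) -> Path:
    """Emit streams in the WISDM raw dialect (used to test the reader
    end-to-end against generated data)."""
    path = Path(path)
    lines = []
    for s in streams:
        t0 = 0
        for i in range(len(s)):
            ts = int((t0 + i) / sampling_rate * 1e9)
            x, y, z = s.channels[i]
            lines.append(f"{s.subject_id},{s.labels[i]},{ts},"
                         f"{x:.6g},{y:.6g},{z:.6g};")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_unimib(mat_path, subset: str = "AF-17") -> WindowedDataset:
    """Read the UniMiB SHAR AF-17 mat-file into windows [n, 151, 3].

    Only the 17-class AF-17 set (daily activities plus falls) is supported;
    the other released subsets raise an explicit error.
    """
    if subset != "AF-17":
        raise ValueError(
            f"unsupported UniMiB subset {subset!r}: only 'AF-17' is "
            "supported (A-9, AF-2 and F-8 are out of scope)")
    path = Path(mat_path)
    if not path.exists():
        raise FileNotFoundError(f"missing UniMiB mat-file {path}")
    mat = scipy.io.loadmat(path)
    if "acc_data" not in mat or "acc_labels" not in mat:
        raise FormatError(
            f"{path} lacks 'acc_data'/'acc_labels' arrays")
    data = np.asarray(mat["acc_data"], dtype=np.float64)
    labels = np.asarray(mat["acc_labels"])
    T = 151
    if data.ndim != 2 or data.shape[1] != 3 * T:
        raise FormatError(
            f"acc_data must be [n, {3 * T}] (three axes of {T} samples "
            f"concatenated), got {data.shape}")
    if labels.shape[0] != data.shape[0] or labels.shape[1] < 2:
        raise FormatError("acc_labels must be [n, >=2] (class, subject, ...)")
    windows = data.reshape(-1, 3, T).transpose(0, 2, 1)  # [n, 151, 3]
    y = labels[:, 0].astype(int)
    if y.min() < 1 or y.max() > len(UNIMIB_AF17_CLASSES):
        raise FormatError(
            f"class ids outside 1..{len(UNIMIB_AF17_CLASSES)}")
    subjects = labels[:, 1].astype(int).astype(str)
    keep = np.isfinite(windows).all(axis=(1, 2))
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} windows with "
                      "non-finite samples")
    return WindowedDataset(windows[keep], y[keep] - 1, subjects[keep],
                           UNIMIB_AF17_CLASSES,
                           provenance={"source": "unimib", "subset": subset})
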