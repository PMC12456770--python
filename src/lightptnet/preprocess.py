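"""Segmentation, min-max normalisation and subject-independent splitting."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import RawStream, WindowedDataset

__all__ = [
    "sliding_window",
    "windows_from_streams",
    "Normalizer",
    "fit_normalizer",
    "apply_normalizer",
    "SplitSpec",
    "subject_split",
    "subject_holdout_spec",
]


def sliding_window(stream: RawStream, size: int, step: int,
                   class_names: list[str] | None = None) -> WindowedDataset:
    """Cut a single-activity stream into windows of ``size`` samples every
    ``step`` samples; the trailing partial window is discarded.

    A stream shorter than ``size`` yields zero windows with a warning.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if not 1 <= step <= size:
        raise ValueError("require 1 <= step <= size")
    labels = np.unique(stream.labels)
    if len(labels) != 1:
        raise ValueError(
            f"stream must carry a single activity label, found {labels}")
    label = str(labels[0])
    if class_names is None:
        class_names = [label]
    if label not in class_names:
        raise ValueError(f"label {label!r} not in class_names {class_names}")
    n = (len(stream) - size) // step + 1 if len(stream) >= size else 0
    if n == 0:
        warnings.warn(
            f"stream of length {len(stream)} shorter than window size {size};"
            " produced 0 windows")
        windows = np.empty((0, size, stream.n_channels))
    else:
        idx = np.arange(n)[:, None] * step + np.arange(size)[None, :]
        windows = stream.channels[idx]
    k = class_names.index(label)
    return WindowedDataset(
        windows, np.full(n, k, dtype=np.int64),
        np.full(n, stream.subject_id, dtype=object).astype(str),
        class_names,
        provenance={"segmentation": {"size": size, "step": step}})


def windows_from_streams(streams: list[RawStream], size: int, step: int,
                         class_names: list[str]) -> WindowedDataset:
    """Segment every stream and concatenate into one dataset."""
    parts = [sliding_window(s, size, step, class_names) for s in streams]
    parts = [p for p in parts if len(p)]
    if not parts:
        raise ValueError("no stream produced any window")
    return WindowedDataset(
        np.concatenate([p.windows for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.subjects for p in parts]),
        class_names,
        provenance={"segmentation": {"size": size, "step": step}})


@dataclass
class Normalizer:
    """Per-channel min-max scaler to [0, 1], fitted on the training set only.

    Channels that are constant on the fitting set map to 0; values outside
    the fitted range (e.g. on a test set) are NOT clipped.
    """

    min: np.ndarray
    max: np.ndarray

    def transform(self, ds: WindowedDataset) -> WindowedDataset:
        span = self.max - self.min
        safe = np.where(span > 0, span, 1.0)
        scaled = (ds.windows - self.min) / safe
        scaled[..., span == 0] = 0.0
        return WindowedDataset(scaled, ds.labels, ds.subjects, ds.class_names,
                               dict(ds.provenance, normalized=True))


def fit_normalizer(train: WindowedDataset) -> Normalizer:
    """Per-channel min/max over all training windows and timesteps."""
    return Normalizer(min=train.windows.min(axis=(0, 1)),
                      max=train.windows.max(axis=(0, 1)))


def apply_normalizer(norm: Normalizer, ds: WindowedDataset) -> WindowedDataset:
    return norm.transform(ds)


@dataclass
class SplitSpec:
    """Subject-independent split: disjoint train/test subject sets and a
    seeded window-level validation fraction drawn from the training windows."""

    train_subjects: list[str]
    test_subjects: list[str]
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.train_subjects = [str(s) for s in self.train_subjects]
        self.test_subjects = [str(s) for s in self.test_subjects]
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(
                f"train and test subjects overlap: {sorted(overlap)}")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


def subject_holdout_spec(ds: WindowedDataset, n_train_subjects: int,
                         val_fraction: float = 0.2, seed: int = 0,
                         shuffle: bool = False) -> SplitSpec:
    """Build a :class:`SplitSpec` holding out all but the first
    ``n_train_subjects`` subjects (native order), or a seeded random draw
    when ``shuffle`` is set (as used for WISDM's 26/10 protocol)."""
    subjects = ds.subject_ids()
    if not 0 < n_train_subjects < len(subjects):
        raise ValueError(
            f"n_train_subjects must be in (0, {len(subjects)})")
    if shuffle:
        order = np.random.default_rng(seed).permutation(len(subjects))
        subjects = [subjects[i] for i in order]
    return SplitSpec(train_subjects=subjects[:n_train_subjects],
                     test_subjects=subjects[n_train_subjects:],
                     val_fraction=val_fraction, seed=seed)


def subject_split(ds: WindowedDataset, spec: SplitSpec):
    """(train, val, test): test holds exactly the test subjects' windows;
    val is a seeded random ``val_fraction`` of the training windows."""
    present = set(ds.subject_ids())
    missing = (set(spec.train_subjects) | set(spec.test_subjects)) - present
    if missing:
        raise ValueError(f"subjects not present in dataset: {sorted(missing)}")
    train_mask = np.isin(ds.subjects, spec.train_subjects)
    test_mask = np.isin(ds.subjects, spec.test_subjects)
    train_idx = np.flatnonzero(train_mask)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(train_idx))
    n_val = int(round(spec.val_fraction * len(train_idx)))
    val_idx = np.sort(train_idx[perm[:n_val]])
    tr_idx = np.sort(train_idx[perm[n_val:]])
    return (ds.select(tr_idx), ds.select(val_idx),
            ds.select(np.flatnonzero(test_mask)))
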