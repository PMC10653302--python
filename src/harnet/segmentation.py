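"""Segmentation of labeled multichannel sensor recordings into windows.

A recording is a ``C × N`` matrix of sensor samples (e.g., 3-axial
acceleration plus 3-axial angular velocity at 50 Hz) with one activity
label per sample. Classification operates on fixed-length overlapping
windows cut from the recording; this module provides the windowing,
per-channel standardisation, class weighting for imbalanced data, and
stratified k-fold splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter1d
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RawRecording",
    "Window",
    "WindowSet",
    "FoldSplit",
    "sliding_window",
    "standardize",
    "class_weights",
    "stratified_kfold",
    "read_recording_csv",
    "save_windows",
    "load_windows",
]


@dataclass
class RawRecording:
    """A C-channel, length-N sensor time series with per-sample labels."""

    values: np.ndarray          # [C, N]
    sample_rate: float          # Hz
    labels: np.ndarray          # int [N]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        C, N = self.values.shape
        if N < 1 or C < 1:
            raise ValueError("recording must have at least one channel and one sample")
        if self.labels.shape != (N,):
            raise ValueError(f"labels length {self.labels.shape} != number of samples {N}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative class indices")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(C)]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Window:
    """One fixed-length segment: the model's classification unit."""

    values: np.ndarray      # [C, L]
    label: int
    source_offset: int      # 0-based start index in the recording


@dataclass
class WindowSet:
    """An ordered collection of equally sized labeled windows."""

    values: np.ndarray      # [W, C, L]
    labels: np.ndarray      # int [W]
    offsets: np.ndarray     # int [W]
    num_classes: int
    sample_rate: float = 50.0
    window_length: int = 0
    overlap: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be [windows, channels, samples]")
        if not self.window_length:
            self.window_length = self.values.shape[2]

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Window:
        return Window(self.values[i], int(self.labels[i]), int(self.offsets[i]))

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)

    def subset(self, indices) -> "WindowSet":
        indices = np.asarray(indices)
        return WindowSet(self.values[indices], self.labels[indices],
                         self.offsets[indices], self.num_classes,
                         self.sample_rate, self.window_length, self.overlap)


@dataclass
class FoldSplit:
    """Fold index per window, stratified by class."""

    fold_assignments: np.ndarray    # int [W] in [0, F)
    n_folds: int

    def train_test_indices(self, fold: int):
        test = np.flatnonzero(self.fold_assignments == fold)
        train = np.flatnonzero(self.fold_assignments != fold)
        return train, test


def sliding_window(recording: RawRecording, length: int, overlap: float,
                   pure_only: bool = False, num_classes: int | None = None) -> WindowSet:
    """Cut a recording into fixed-length windows with fractional overlap.

    Windows are half-open ``[offset, offset + length)`` starting at
    0, stride, 2·stride, … with ``stride = round(length · (1 − overlap))``;
    trailing samples that do not fill a window are discarded. Each
    window's label is the majority per-sample label, ties broken by the
    lowest class index; ``pure_only`` drops windows whose samples carry
    more than one label.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    N = recording.n_samples
    if length > N:
        raise ValueError("recording shorter than window")
    if not np.all(np.isfinite(recording.values)):
        raise ValueError("invalid signal values: non-finite samples present")
    stride = int(round(length * (1.0 - overlap)))
    if stride < 1:
        raise ValueError("overlap too high: stride would be zero")
    n_windows = (N - length) // stride + 1
    offsets = np.arange(n_windows) * stride

    value_view = sliding_window_view(recording.values, length, axis=1)  # [C, N-L+1, L]
    values = value_view[:, offsets, :].transpose(1, 0, 2).copy()        # [W, C, L]
    label_view = sliding_window_view(recording.labels, length)[offsets]  # [W, L]

    K = num_classes if num_classes is not None else int(recording.labels.max()) + 1
    counts = np.stack([np.bincount(row, minlength=K) for row in label_view])
    labels = counts.argmax(axis=1)  # argmax returns the lowest index on ties

    if pure_only:
        pure = (counts > 0).sum(axis=1) == 1
        values, labels, offsets = values[pure], labels[pure], offsets[pure]

    return WindowSet(values, labels, offsets, K, recording.sample_rate,
                     length, overlap)


def standardize(recording: RawRecording, smooth_window: int | None = None) -> RawRecording:
    """Per-channel z-score standardisation (population SD), labels unchanged.

    Channels with zero variance become all-zeros. An optional moving-average
    smoother (``smooth_window`` samples, centered) is applied before
    standardising; it is off by default.
    """
    if recording.n_samples < 2:
        raise ValueError("standardize requires at least 2 samples")
    values = recording.values
    if smooth_window is not None and smooth_window > 1:
        values = uniform_filter1d(values, smooth_window, axis=1, mode="nearest")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return RawRecording(out, recording.sample_rate, recording.labels.copy(),
                        list(recording.channel_names))


def class_weights(window_set_or_counts) -> np.ndarray:
    """Inverse-frequency class weights: ``w_k = total / (K · count_k)``.

    The count-weighted mean of the weights is exactly 1, so the weighted
    cross-entropy keeps the scale of the unweighted loss.
    """
    counts = (window_set_or_counts.class_counts
              if isinstance(window_set_or_counts, WindowSet)
              else np.asarray(window_set_or_counts))
    counts = counts.astype(float)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"empty class: classes {empty} have no windows")
    K = len(counts)
    return counts.sum() / (K * counts)


def stratified_kfold(window_set: WindowSet, folds: int, seed: int) -> FoldSplit:
    """Stratified fold assignment: each fold preserves class proportions
    to within one window per class."""
    if folds < 2:
        raise ValueError("folds must be at least 2")
    counts = window_set.class_counts
    present = counts[counts > 0]
    if np.any(present < folds):
        raise ValueError("class too small to stratify: every class needs "
                         f"at least {folds} windows (counts: {counts.tolist()})")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments = np.empty(len(window_set), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(window_set.values[:, 0, 0],
                                                   window_set.labels)):
        assignments[test_idx] = fold
    return FoldSplit(assignments, folds)


# -- I/O ----------------------------------------------------------------------


def read_recording_csv(path, channel_columns, label_column, sample_rate: float,
                       delimiter: str | None = ",") -> RawRecording:
    """Read a delimited recording: one row per sample, channel columns plus an
    integer label column. Columns may be names or 0-based indices.
    ``delimiter=None`` splits on whitespace (UCI-HAR-style text files)."""
    kwargs = {"sep": delimiter} if delimiter is not None else {"sep": r"\s+"}
    by_index = all(isinstance(c, int) for c in list(channel_columns) + [label_column])
    df = pd.read_csv(path, header=None if by_index else 0, **kwargs)
    cols = df.iloc[:, list(channel_columns)] if by_index else df[list(channel_columns)]
    label = df.iloc[:, label_column] if by_index else df[label_column]
    names = [str(c) for c in channel_columns]
    return RawRecording(cols.to_numpy(dtype=float).T, sample_rate,
                        label.to_numpy(dtype=int), names)


def save_windows(path, window_set: WindowSet):
    """Write a WindowSet to a single HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=window_set.values)
        f.create_dataset("labels", data=window_set.labels)
        f.create_dataset("offsets", data=window_set.offsets)
        f.attrs["num_classes"] = window_set.num_classes
        f.attrs["sample_rate"] = window_set.sample_rate
        f.attrs["window_length"] = window_set.window_length
        f.attrs["overlap"] = window_set.overlap


def load_windows(path) -> WindowSet:
    import h5py

    with h5py.File(path, "r") as f:
        return WindowSet(f["values"][:], f["labels"][:], f["offsets"][:],
                         int(f.attrs["num_classes"]), float(f.attrs["sample_rate"]),
                         int(f.attrs["window_length"]), float(f.attrs["overlap"]))
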