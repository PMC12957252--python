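"""Dataset container, sliding windows, normalization and file I/O.

The in-memory unit is a :class:`FeatureDataset`: one record per subject,
each holding windowed differential-entropy (DE) feature tensors of shape
``(T, C, B)`` — T time steps, C electrode channels, B frequency bands —
with one emotion label per window.  All file-format knowledge lives here.

On disk the container is a single HDF5 file, one group per subject::

    /meta                      attrs: schema, T, C, B, n_classes
    /subject_<id>/features     float array (n_samples, T, C, B)
    /subject_<id>/labels       int array  (n_samples,)

An optional importer for per-subject MAT files with precomputed DE
features (the layout the SEED distribution uses) is provided as an
adapter; the pipeline itself only ever sees :class:`FeatureDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py

__all__ = [
    "SubjectRecord",
    "FeatureDataset",
    "Normalizer",
    "sliding_windows",
    "save",
    "load",
    "normalize",
    "import_mat_subject",
]

_SCHEMA = "dspmcf-container-v1"


class FormatError(ValueError):
    """Raised when a container file violates the documented schema."""


@dataclass
class SubjectRecord:
    """All windowed samples of one subject."""

    subject_id: int
    features: np.ndarray  # (n_samples, T, C, B)
    labels: np.ndarray  # (n_samples,) int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 4:
            raise FormatError("features must be (n_samples, T, C, B)")
        if len(self.labels) != len(self.features):
            raise FormatError("labels and features length mismatch")
        if len(self.features) == 0:
            raise FormatError("subject record must be nonempty")

    @property
    def n_samples(self) -> int:
        return len(self.features)


@dataclass
class FeatureDataset:
    """Multi-subject collection with uniform tensor shapes.

    ``coords`` optionally carries the (C, 3) electrode positions the data
    was generated (or recorded) with, so the spatial graph downstream is
    built on the same geometry; ``templates`` carries ground-truth class
    templates for synthetic data.
    """

    subjects: list[SubjectRecord]
    n_classes: int
    templates: np.ndarray | None = field(default=None, repr=False)
    coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.subjects:
            raise FormatError("dataset must contain at least one subject")
        shapes = {s.features.shape[1:] for s in self.subjects}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent sample shapes across subjects: {shapes}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise FormatError("subject IDs must be unique")
        for s in self.subjects:
            if s.labels.min() < 0 or s.labels.max() >= self.n_classes:
                raise FormatError("labels out of range [0, n_classes)")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def window_length(self) -> int:
        return self.subjects[0].features.shape[1]

    @property
    def n_channels(self) -> int:
        return self.subjects[0].features.shape[2]

    @property
    def n_bands(self) -> int:
        return self.subjects[0].features.shape[3]

    def subset(self, subject_ids: list[int]) -> "FeatureDataset":
        keep = [s for s in self.subjects if s.subject_id in set(subject_ids)]
        return FeatureDataset(keep, self.n_classes, templates=self.templates, coords=self.coords)


def sliding_windows(series: np.ndarray, T: int, stride: int = 1) -> np.ndarray:
    """Cut a (L, C, B) feature series into overlapping (T, C, B) windows.

    Returns ``floor((L - T) / stride) + 1`` contiguous windows; windows
    overlap whenever ``stride < T``.
    """
    series = np.asarray(series)
    L = series.shape[0]
    if T < 1 or stride < 1:
        raise ValueError("T and stride must be >= 1")
    if L < T:
        raise ValueError(f"series length {L} shorter than window {T}")
    n = (L - T) // stride + 1
    return np.stack([series[i * stride : i * stride + T] for i in range(n)])


# ---------------------------------------------------------------------------
# normalization


@dataclass
class Normalizer:
    """Per-feature z-score statistics fitted on source subjects only.

    One mean/sd per (channel, band) position, pooled over samples and time
    steps of the *fitting* subjects.  The same statistics are reused for the
    held-out target subject, so no target data ever influences the fit.
    """

    mean: np.ndarray  # (C, B)
    sd: np.ndarray  # (C, B)

    @staticmethod
    def fit(ds: FeatureDataset, eps: float = 1e-6) -> "Normalizer":
        stacked = np.concatenate([s.features for s in ds.subjects])  # (n, T, C, B)
        mean = stacked.mean(axis=(0, 1))
        sd = stacked.std(axis=(0, 1))
        return Normalizer(mean=mean, sd=np.maximum(sd, eps))

    def transform(self, ds: FeatureDataset) -> FeatureDataset:
        subs = [
            SubjectRecord(s.subject_id, (s.features - self.mean) / self.sd, s.labels.copy())
            for s in ds.subjects
        ]
        return FeatureDataset(subs, ds.n_classes, templates=ds.templates, coords=ds.coords)


def normalize(ds: FeatureDataset, mode: str = "zscore") -> tuple[FeatureDataset, Normalizer | None]:
    """Normalize a dataset; ``mode`` is ``"zscore"`` or ``"none"``."""
    if mode == "none":
        return ds, None
    if mode != "zscore":
        raise ValueError(f"unknown normalization mode: {mode}")
    norm = Normalizer.fit(ds)
    return norm.transform(ds), norm


# ---------------------------------------------------------------------------
# container I/O


def save(ds: FeatureDataset, path) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema"] = _SCHEMA
        meta.attrs["T"] = ds.window_length
        meta.attrs["C"] = ds.n_channels
        meta.attrs["B"] = ds.n_bands
        meta.attrs["n_classes"] = ds.n_classes
        if ds.templates is not None:
            meta.create_dataset("templates", data=ds.templates)
        if ds.coords is not None:
            meta.create_dataset("coords", data=ds.coords)
        for s in ds.subjects:
            g = f.create_group(f"subject_{s.subject_id}")
            g.create_dataset("features", data=s.features)
            g.create_dataset("labels", data=s.labels)


def load(path) -> FeatureDataset:
    with h5py.File(path, "r") as f:
        if "meta" not in f or f["meta"].attrs.get("schema") != _SCHEMA:
            raise FormatError(f"unknown schema in {path}")
        meta = f["meta"]
        n_classes = int(meta.attrs["n_classes"])
        templates = meta["templates"][...] if "templates" in meta else None
        coords = meta["coords"][...] if "coords" in meta else None
        subjects = []
        for key in sorted(k for k in f.keys() if k.startswith("subject_")):
            g = f[key]
            if "labels" not in g or "features" not in g:
                raise FormatError(f"group {key} missing features or labels")
            subjects.append(
                SubjectRecord(
                    subject_id=int(key.split("_", 1)[1]),
                    features=g["features"][...],
                    labels=g["labels"][...],
                )
            )
    subjects.sort(key=lambda s: s.subject_id)
    return FeatureDataset(subjects, n_classes, templates=templates, coords=coords)


def import_mat_subject(path, de_key: str, label_vector: np.ndarray, T: int, stride: int = 1):
    """Adapter for one subject's MAT file of precomputed DE features.

    ``de_key`` selects a (C, L, B) array in the MAT file; it is transposed
    to (L, C, B), windowed, and each window inherits the trial's label from
    ``label_vector``.  Requires :mod:`scipy`.
    """
    from scipy.io import loadmat

    mat = loadmat(path)
    arrays, labels = [], []
    for trial_idx, lab in enumerate(label_vector, start=1):
        arr = mat[f"{de_key}{trial_idx}"]  # (C, L, B)
        series = np.transpose(arr, (1, 0, 2))
        wins = sliding_windows(series, T, stride)
        arrays.append(wins)
        labels.append(np.full(len(wins), lab))
    return np.concatenate(arrays), np.concatenate(labels)
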