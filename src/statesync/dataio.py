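"""Containers and I/O for multi-subject ROI time series.

The central object is :class:`SubjectTimeSeries`, a TR-by-voxel matrix for a
single subject, and :class:`Dataset`, an ordered collection of such matrices
sharing shape and sampling metadata.  Voxel series can be extracted from 4D
NIfTI volumes through an :class:`ROIMask`, and whole datasets round-trip
losslessly through a versioned HDF5 container.

Conventions fixed project-wide:

* z-scoring uses the population standard deviation (divide by ``T``, not
  ``T - 1``); Pearson correlations are unaffected by the choice, but fixing
  one convention keeps intermediate matrices bit-comparable across modules.
* voxel order follows linear C-order of the mask indices;
* the time axis is a 0-based TR index internally; user-facing reports also
  carry seconds (``index * tr_seconds``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SubjectTimeSeries",
    "Dataset",
    "ROIMask",
    "load_roi_timeseries",
    "zscore_within_subject",
    "store_dataset",
    "load_dataset",
]

_SCHEMA_VERSION = 1


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time series: ``data[t, v]`` is voxel ``v`` at TR ``t``."""

    subject_id: str
    data: np.ndarray  # (T, V)
    tr_seconds: float = 2.0
    roi_name: str = "roi"
    voxel_ids: np.ndarray | None = None
    zscored: bool = False
    constant_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (T, V); got shape {self.data.shape}")
        T, V = self.data.shape
        if T < 2:
            raise ValueError(f"need at least 2 TRs, got T={T}")
        if V < 1:
            raise ValueError("need at least 1 voxel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(V)
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape != (V,):
                raise ValueError(
                    f"voxel_ids length {self.voxel_ids.shape} does not match V={V}"
                )
        self.constant_voxels = np.asarray(self.constant_voxels, dtype=int)
        if self.zscored:
            self._check_zscored()

    def _check_zscored(self) -> None:
        live = np.setdiff1d(np.arange(self.n_voxels), self.constant_voxels)
        cols = self.data[:, live]
        if cols.size == 0:
            return
        if np.max(np.abs(cols.mean(axis=0))) > 1e-8:
            raise ValueError("zscored flag set but column means deviate from 0")
        if np.max(np.abs(cols.std(axis=0) - 1.0)) > 1e-6:
            raise ValueError("zscored flag set but column SDs deviate from 1")

    @property
    def n_trs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def times_seconds(self) -> np.ndarray:
        return np.arange(self.n_trs) * self.tr_seconds


@dataclass
class Dataset:
    """An ordered multi-subject collection with homogeneous shape and metadata."""

    subjects: list[SubjectTimeSeries]
    study_label: str = "study"

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise ValueError("Dataset requires at least one subject")
        first = self.subjects[0]
        for sts in self.subjects[1:]:
            for attr in ("n_trs", "n_voxels", "tr_seconds", "roi_name"):
                a, b = getattr(first, attr), getattr(sts, attr)
                if a != b:
                    raise ValueError(
                        f"subject {sts.subject_id!r} mismatches {first.subject_id!r} "
                        f"on {attr}: {b!r} != {a!r}"
                    )
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in Dataset")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_trs(self) -> int:
        return self.subjects[0].n_trs

    @property
    def n_voxels(self) -> int:
        return self.subjects[0].n_voxels

    @property
    def tr_seconds(self) -> float:
        return self.subjects[0].tr_seconds

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def stacked(self) -> np.ndarray:
        """Row-concatenate all subjects into an ``(N * T, V)`` matrix."""
        return np.vstack([s.data for s in self.subjects])


@dataclass
class ROIMask:
    """A set of voxels, as linear C-order indices into a 3-D volume."""

    volume_shape: tuple[int, int, int]
    voxel_indices: np.ndarray
    parcel_id: int = 0

    def __post_init__(self) -> None:
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if len(self.volume_shape) != 3:
            raise ValueError("volume_shape must have 3 entries")
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        if self.voxel_indices.size == 0:
            raise ValueError("empty ROI mask")
        n_vox = int(np.prod(self.volume_shape))
        bad = self.voxel_indices[(self.voxel_indices < 0) | (self.voxel_indices >= n_vox)]
        if bad.size:
            raise IndexError(
                f"mask index {int(bad[0])} out of bounds for volume of {n_vox} voxels"
            )
        if np.unique(self.voxel_indices).size != self.voxel_indices.size:
            raise ValueError("mask indices must be unique")

    @classmethod
    def from_volume(cls, mask_volume: np.ndarray, parcel_id: int = 0) -> "ROIMask":
        """Build a mask from a 3-D indicator (or label) volume.

        Nonzero voxels are included when ``parcel_id`` is 0; otherwise voxels
        equal to ``parcel_id``.
        """
        mask_volume = np.asarray(mask_volume)
        if mask_volume.ndim != 3:
            raise ValueError("mask volume must be 3-D")
        if parcel_id:
            flat = np.flatnonzero(mask_volume.ravel(order="C") == parcel_id)
        else:
            flat = np.flatnonzero(mask_volume.ravel(order="C"))
        return cls(volume_shape=mask_volume.shape, voxel_indices=flat, parcel_id=parcel_id)


def load_roi_timeseries(
    volume_path, mask: ROIMask, tr_seconds: float, subject_id: str = "subject",
    roi_name: str | None = None,
) -> SubjectTimeSeries:
    """Extract a ``T x V`` ROI matrix from a 4-D NIfTI volume.

    Voxel columns follow the linear C-order of ``mask.voxel_indices``.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    if tuple(data.shape[:3]) != mask.volume_shape:
        raise ValueError(
            f"volume spatial shape {tuple(data.shape[:3])} does not match "
            f"mask volume_shape {mask.volume_shape}"
        )
    T = data.shape[3]
    flat = data.reshape(-1, T, order="C")  # (X*Y*Z, T)
    roi = flat[mask.voxel_indices, :].T  # (T, V)
    return SubjectTimeSeries(
        subject_id=subject_id,
        data=np.ascontiguousarray(roi, dtype=np.float64),
        tr_seconds=tr_seconds,
        roi_name=roi_name or f"parcel_{mask.parcel_id}",
        voxel_ids=mask.voxel_indices.copy(),
    )


def zscore_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize with population SD; constant columns map to 0.

    Returns ``(zscored, constant_column_indices)``.
    """
    data = np.asarray(data, dtype=np.float64)
    mean = data.mean(axis=0)
    sd = data.std(axis=0)  # population convention (ddof=0)
    constant = np.flatnonzero(sd == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (data - mean) / safe_sd
    z[:, constant] = 0.0
    return z, constant


def zscore_within_subject(sts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Standardize each voxel series within the subject (population SD).

    Constant voxels are set to 0 and recorded in ``constant_voxels``.
    Idempotent, and leaves pairwise column correlations unchanged.
    """
    z, constant = zscore_matrix(sts.data)
    return replace(sts, data=z, zscored=True, constant_voxels=constant)


def store_dataset(ds: Dataset, path) -> None:
    """Persist a dataset to an HDF5 container (lossless round trip)."""
    with h5py.File(str(path), "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["study_label"] = ds.study_label
        f.attrs["subject_order"] = [s.subject_id for s in ds.subjects]
        grp = f.create_group("subjects")
        for sts in ds.subjects:
            g = grp.create_group(sts.subject_id)
            g.create_dataset("data", data=sts.data, track_times=False)
            g.create_dataset("voxel_ids", data=np.asarray(sts.voxel_ids), track_times=False)
            g.create_dataset(
                "constant_voxels", data=np.asarray(sts.constant_voxels), track_times=False
            )
            g.attrs["tr_seconds"] = sts.tr_seconds
            g.attrs["roi_name"] = sts.roi_name
            g.attrs["zscored"] = bool(sts.zscored)


def load_dataset(path) -> Dataset:
    """Load a dataset written by :func:`store_dataset`."""
    with h5py.File(str(path), "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported dataset schema version {version}; "
                f"this build reads version {_SCHEMA_VERSION}"
            )
        order = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["subject_order"]
        ]
        subjects = []
        for sid in order:
            g = f["subjects"][sid]
            subjects.append(
                SubjectTimeSeries(
                    subject_id=sid,
                    data=g["data"][()],
                    tr_seconds=float(g.attrs["tr_seconds"]),
                    roi_name=str(g.attrs["roi_name"]),
                    voxel_ids=g["voxel_ids"][()],
                    zscored=bool(g.attrs["zscored"]),
                    constant_voxels=g["constant_voxels"][()],
                )
            )
        label = f.attrs["study_label"]
        label = label.decode() if isinstance(label, bytes) else str(label)
    return Dataset(subjects=subjects, study_label=label)
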