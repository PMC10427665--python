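"""Label-volume, manifest and feature-table I/O plus cohort splitting.

Label volumes are NIfTI-1 images whose voxel values are integer region
labels (0 = background).  Cohort manifests are TSV files with one row per
scan session.  Feature tables are CSV files with identifier columns
followed by ``RV:<region>`` / ``SVR:<region>`` feature columns.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "CohortManifest",
    "SplitAssignment",
    "read_label_volume",
    "write_label_volume",
    "read_feature_table",
    "write_feature_table",
    "read_manifest",
    "write_manifest",
    "split_cohort",
]

#: Default plausibility window for postmenstrual age at scan, in weeks.
DEFAULT_PMA_WINDOW = (20.0, 60.0)

MANIFEST_COLUMNS = [
    "subject_id",
    "session_id",
    "pma_weeks",
    "birth_ga_weeks",
    "sex",
    "volume_path",
]

_SEXES = {"female", "male", "unknown"}


@dataclass
class LabelVolume:
    """A 3D voxel grid of non-negative integer region labels.

    Parameters
    ----------
    voxels
        3D integer array; 0 is reserved for background.
    spacing
        Voxel size ``(dx, dy, dz)`` in mm.  Metadata only: all features
        derived from a :class:`LabelVolume` are voxel-count based.
    affine
        Optional 4x4 voxel-to-world matrix, preserved on write.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {vox.ndim}D")
        if any(s < 1 for s in vox.shape):
            raise ValueError(f"every dimension must be >= 1, got shape {vox.shape}")
        if not np.issubdtype(vox.dtype, np.integer):
            rounded = np.rint(vox)
            if not np.allclose(vox, rounded, atol=1e-6, rtol=0):
                raise ValueError("non-integer labels in volume")
            vox = rounded.astype(np.int32)
        if vox.min() < 0:
            raise ValueError("labels must be >= 0")
        self.voxels = vox
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have 3 entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def region_ids(self) -> list[int]:
        """Sorted distinct nonzero labels present in the volume."""
        ids = np.unique(self.voxels)
        return [int(i) for i in ids if i != 0]


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a NIfTI label volume.

    A trailing singleton 4th dimension is squeezed away.  Voxel values
    within 1e-6 of an integer are rounded; anything else is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(voxels=data, spacing=spacing, affine=np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a :class:`LabelVolume` as NIfTI-1 (.nii or .nii.gz)."""
    affine = vol.affine
    if affine is None:
        affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.int32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort manifests and splits
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """One row per scan session: ids, PMA at scan, sex, volume path."""

    rows: pd.DataFrame
    pma_window: tuple[float, float] = DEFAULT_PMA_WINDOW

    def __post_init__(self) -> None:
        df = self.rows.copy()
        missing = [c for c in ("subject_id", "session_id", "pma_weeks") if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if "birth_ga_weeks" not in df.columns:
            df["birth_ga_weeks"] = np.nan
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        if "volume_path" not in df.columns:
            df["volume_path"] = ""
        df["subject_id"] = df["subject_id"].astype(str)
        df["session_id"] = df["session_id"].astype(str)
        df["pma_weeks"] = df["pma_weeks"].astype(float)
        df["volume_path"] = df["volume_path"].fillna("").astype(str)
        df = df[MANIFEST_COLUMNS].reset_index(drop=True)

        dup = df.duplicated(subset=["subject_id", "session_id"])
        if dup.any():
            raise ValueError("duplicate subject_id+session_id in manifest")
        bad_sex = set(df["sex"]) - _SEXES
        if bad_sex:
            raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
        lo, hi = self.pma_window
        if ((df["pma_weeks"] < lo) | (df["pma_weeks"] > hi)).any():
            raise ValueError(f"pma_weeks outside plausible window [{lo}, {hi}]")
        self.rows = df

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def subject_ids(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        return list(dict.fromkeys(self.rows["subject_id"]))


def read_manifest(path: str | os.PathLike, pma_window=DEFAULT_PMA_WINDOW) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "session_id": str})
    return CohortManifest(rows=df, pma_window=pma_window)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    manifest.rows.to_csv(path, sep="\t", index=False)


@dataclass
class SplitAssignment:
    """Partition of manifest rows into train/validation/test.

    All sessions of one subject land in the same partition.
    """

    labels: dict[tuple[str, str], str]
    seed: int
    fractions: tuple[float, float, float]

    PARTITIONS = ("train", "validation", "test")

    def partition_of(self, subject_id: str, session_id: str) -> str:
        return self.labels[(str(subject_id), str(session_id))]

    def sessions(self, partition: str) -> list[tuple[str, str]]:
        if partition not in self.PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return [k for k, v in self.labels.items() if v == partition]

    def counts(self) -> dict[str, int]:
        out = {p: 0 for p in self.PARTITIONS}
        for v in self.labels.values():
            out[v] += 1
        return out

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "fractions": list(self.fractions),
            "assignment": [
                {"subject_id": s, "session_id": ses, "partition": p}
                for (s, ses), p in self.labels.items()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SplitAssignment":
        payload = json.loads(Path(path).read_text())
        labels = {
            (row["subject_id"], row["session_id"]): row["partition"]
            for row in payload["assignment"]
        }
        return cls(labels=labels, seed=int(payload["seed"]), fractions=tuple(payload["fractions"]))


def _target_sizes(n_sessions: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    f_train, f_val, _ = fractions
    n_train = math.floor(f_train * n_sessions)
    n_val = math.floor(f_val * n_sessions + 0.5)  # round half up
    n_test = n_sessions - n_train - n_val
    return n_train, n_val, n_test


def split_cohort(
    manifest: CohortManifest,
    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
) -> SplitAssignment:
    """Split a cohort into train/validation/test at the subject level.

    Session-count targets are ``floor(f_train*N)``, ``round(f_val*N)`` and
    the remainder, where N is the number of sessions.  Subjects are
    shuffled by a seeded generator and assigned whole (all their sessions
    together) to the partition with the largest remaining need, so the
    targets are met as closely as subject grouping allows; for
    single-session cohorts they are met exactly.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must have 3 entries")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    df = manifest.rows
    n_sessions = len(df)
    targets = _target_sizes(n_sessions, fractions)

    subjects = manifest.subject_ids
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    sessions_by_subject = df.groupby("subject_id", sort=False).groups

    need = list(targets)
    labels: dict[tuple[str, str], str] = {}
    for idx in order:
        subj = subjects[idx]
        row_idx = sessions_by_subject[subj]
        size = len(row_idx)
        # prefer a partition that can absorb the whole subject; fall back to
        # the one with the largest remaining need (ties -> train, val, test)
        candidates = [p for p in range(3) if need[p] >= size]
        pool = candidates if candidates else range(3)
        part = max(pool, key=lambda p: (need[p], -p))
        need[part] -= size
        name = SplitAssignment.PARTITIONS[part]
        for i in row_idx:
            labels[(df.at[i, "subject_id"], df.at[i, "session_id"])] = name

    return SplitAssignment(labels=labels, seed=int(seed), fractions=fractions)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

ID_COLUMNS = ("subject_id", "session_id", "pma_weeks")


def write_feature_table(table, path: str | os.PathLike) -> None:
    """Write a FeatureTable as CSV.

    Columns: subject_id, session_id, pma_weeks, then one column per
    feature.  Floats are printed with 10 significant digits so that
    read(write(t)) equals t within 1e-9.
    """
    names = list(table.feature_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ID_COLUMNS) + names)
        for i, (subj, ses) in enumerate(table.subjects):
            row = [subj, ses, f"{table.ages[i]:.10g}"]
            row += [f"{v:.10g}" for v in table.values[i]]
            writer.writerow(row)


def read_feature_table(path: str | os.PathLike):
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    from .age_model import FeatureTable

    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        raise ValueError("duplicate column names in feature table")
    if tuple(header[:3]) != ID_COLUMNS:
        raise ValueError(f"feature table must start with columns {ID_COLUMNS}")
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    names = header[3:]
    values = df[names].to_numpy(dtype=float) if names else np.empty((len(df), 0))
    return FeatureTable(
        subjects=list(zip(df["subject_id"], df["session_id"])),
        feature_names=names,
        values=values,
        ages=df["pma_weeks"].to_numpy(dtype=float),
    )
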