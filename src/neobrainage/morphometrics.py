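"""Per-region morphometry from label volumes.

Two features per region:

* RV (relational volume): the region's voxel count divided by the total
  voxel count of all nonzero-labelled structures — a head-size-invariant
  volume fraction.
* SVR (surface-to-volume ratio): the number of the region's surface
  voxels (voxels with at least one differing-label neighbor) divided by
  its voxel count — a cheap gyrification proxy.

Both are computed from raw voxel counts; voxel spacing is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._regions import DEFAULT_REGION_IDS, region_name
from .io_core import LabelVolume

__all__ = [
    "RegionMorphometry",
    "region_volumes",
    "surface_voxel_count",
    "relational_volume",
    "surface_to_volume_ratio",
    "extract_features",
    "dice_coefficient",
    "mean_dice",
]

# face / edge / corner neighbor offsets
_OFFSETS_6 = [
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_18 = [o for o in _OFFSETS_26 if abs(o[0]) + abs(o[1]) + abs(o[2]) <= 2]

_CONNECTIVITY = {6: _OFFSETS_6, 18: _OFFSETS_18, 26: _OFFSETS_26}


@dataclass(frozen=True)
class RegionMorphometry:
    """Morphometric record for one region of one volume."""

    region_id: int
    region_name: str
    voxel_count: int
    surface_voxel_count: int
    rv: float
    svr: float
    absent: bool = False


def region_volumes(vol: LabelVolume) -> dict[int, int]:
    """Voxel count per nonzero label; empty dict for all-background."""
    labels, counts = np.unique(vol.voxels, return_counts=True)
    return {int(l): int(c) for l, c in zip(labels, counts) if l != 0}


def _surface_mask(voxels: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Boolean mask of voxels with >= 1 differing-label neighbor.

    Out-of-bounds neighbors are treated as background (label 0), so
    nonzero voxels on the volume border are surface voxels.
    """
    try:
        offsets = _CONNECTIVITY[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    padded = np.pad(voxels, 1, mode="constant", constant_values=0)
    surf = np.zeros(voxels.shape, dtype=bool)
    nx, ny, nz = voxels.shape
    for dx, dy, dz in offsets:
        neighbor = padded[1 + dx : 1 + dx + nx, 1 + dy : 1 + dy + ny, 1 + dz : 1 + dz + nz]
        surf |= neighbor != voxels
    return surf


def surface_voxel_count(vol: LabelVolume, region_id: int, connectivity: int = 6) -> int:
    """Count the region's voxels having a differing-label neighbor."""
    if region_id == 0:
        raise ValueError("region_id 0 is background, not a structure")
    surf = _surface_mask(vol.voxels, connectivity)
    return int(np.count_nonzero(surf & (vol.voxels == region_id)))


def relational_volume(volumes: Mapping[int, int], region_id: int) -> float:
    """Region voxel count over the summed count of all nonzero regions."""
    total = sum(volumes.values())
    if total <= 0:
        raise ValueError("no structures present")
    return volumes.get(int(region_id), 0) / total


def surface_to_volume_ratio(surface: int, voxel_count: int) -> float:
    """``surface / voxel_count``; 0.0 for an absent (zero-voxel) region."""
    if voxel_count < 0:
        raise ValueError("voxel_count must be >= 0")
    if surface > voxel_count:
        raise ValueError("surface count cannot exceed voxel count")
    if voxel_count == 0:
        return 0.0
    return surface / voxel_count


def extract_features(
    vol: LabelVolume,
    expected_regions: Sequence[int] | None = None,
    connectivity: int = 6,
) -> list[RegionMorphometry]:
    """One :class:`RegionMorphometry` per expected region, in scheme order.

    Regions absent from the volume get zero counts, rv = svr = 0 and the
    ``absent`` flag.  The RV denominator sums over all nonzero labels
    actually present in the volume (not just the expected ones).
    """
    if expected_regions is None:
        expected_regions = DEFAULT_REGION_IDS
    expected_regions = [int(r) for r in expected_regions]
    if not expected_regions:
        raise ValueError("expected_regions must be non-empty")
    if any(r <= 0 for r in expected_regions):
        raise ValueError("region ids must be positive")

    volumes = region_volumes(vol)
    total = sum(volumes.values())
    surf = _surface_mask(vol.voxels, connectivity)
    surf_labels = vol.voxels[surf]
    max_label = int(vol.voxels.max()) if vol.voxels.size else 0
    surf_counts = np.bincount(surf_labels.ravel(), minlength=max_label + 1)

    out = []
    for rid in expected_regions:
        count = volumes.get(rid, 0)
        if count == 0:
            out.append(
                RegionMorphometry(rid, region_name(rid), 0, 0, 0.0, 0.0, absent=True)
            )
            continue
        s = int(surf_counts[rid]) if rid < len(surf_counts) else 0
        out.append(
            RegionMorphometry(
                region_id=rid,
                region_name=region_name(rid),
                voxel_count=count,
                surface_voxel_count=s,
                rv=count / total,
                svr=s / count,
            )
        )
    return out


def extract_cohort_features(
    manifest,
    expected_regions: Sequence[int] | None = None,
    connectivity: int = 6,
):
    """Extract an RV/SVR feature table for every session in a manifest.

    Columns are ``RV:<region>`` for each expected region followed by
    ``SVR:<region>``; ages come from the manifest's ``pma_weeks``.
    """
    from .age_model import FeatureTable
    from .io_core import read_label_volume

    if expected_regions is None:
        expected_regions = DEFAULT_REGION_IDS
    subjects, rows = [], []
    for rec in manifest.rows.itertuples(index=False):
        vol = read_label_volume(rec.volume_path)
        morphs = extract_features(vol, expected_regions, connectivity)
        rows.append([m.rv for m in morphs] + [m.svr for m in morphs])
        subjects.append((rec.subject_id, rec.session_id))
    names = [f"RV:{region_name(r)}" for r in expected_regions] + [
        f"SVR:{region_name(r)}" for r in expected_regions
    ]
    return FeatureTable(
        subjects=subjects,
        feature_names=names,
        values=np.asarray(rows, dtype=float),
        ages=manifest.rows["pma_weeks"].to_numpy(dtype=float),
    )


def dice_coefficient(pred: LabelVolume, truth: LabelVolume, region_id: int) -> float:
    """Dice overlap of one region: 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    a = pred.voxels == region_id
    b = truth.voxels == region_id
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def mean_dice(pred: LabelVolume, truth: LabelVolume, regions: Iterable[int]) -> float:
    """Average per-region Dice over the given region list."""
    regions = list(regions)
    if not regions:
        raise ValueError("regions must be non-empty")
    return float(np.mean([dice_coefficient(pred, truth, r) for r in regions]))
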