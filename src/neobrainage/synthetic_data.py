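"""Synthetic inputs with known, age-dependent structure.

Two generators make every downstream stage testable without real data:

* :func:`generate_phantom` — voxel-level label phantoms: an ellipsoidal
  "brain" partitioned into regions by a weighted Voronoi tessellation.
  Region volume shares follow a softmax in age, and designated
  "cortical" regions get a boundary corrugation whose amplitude grows
  with age, raising their surface-voxel count.
* :func:`simulate_feature_table` — tabular cohorts with a planted linear
  age signal and a known noise floor, for regression and PFI tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._regions import region_name
from .age_model import FeatureTable
from .io_core import CohortManifest, LabelVolume, write_label_volume, write_manifest

__all__ = [
    "PhantomSpec",
    "SyntheticCohort",
    "default_phantom_spec",
    "generate_phantom",
    "generate_cohort",
    "simulate_feature_table",
]

AGE_PIVOT = 37.0   # center of the modelled scan-age range
AGE_MIN = 29.0     # folding amplitude is measured from this age
_FOLD_WAVELENGTH = 6.0  # voxels


@dataclass
class PhantomSpec:
    """Parameters of one label-volume phantom.

    ``growth_coefs[r]`` is the per-week log-share growth of region r+1;
    ``fold_coefs[r]`` the per-week boundary-corrugation amplitude (in
    voxels) of region r+1.  Geometry (centroids, base shares, fold
    phases) depends only on ``seed``, so the same seed at two ages yields
    the same anatomy at two developmental stages.
    """

    age_weeks: float = 37.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    n_regions: int = 87
    growth_coefs: np.ndarray | None = None
    fold_coefs: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3D")
        if not 0.0 <= self.noise_sd < 1.0:
            raise ValueError("noise_sd is a fraction of boundary voxels in [0, 1)")
        if self.growth_coefs is None:
            self.growth_coefs = np.zeros(self.n_regions)
        if self.fold_coefs is None:
            self.fold_coefs = np.zeros(self.n_regions)
        self.growth_coefs = np.asarray(self.growth_coefs, dtype=float)
        self.fold_coefs = np.asarray(self.fold_coefs, dtype=float)
        if self.growth_coefs.shape != (self.n_regions,):
            raise ValueError("growth_coefs must have one entry per region")
        if self.fold_coefs.shape != (self.n_regions,):
            raise ValueError("fold_coefs must have one entry per region")


def default_phantom_spec(
    age_weeks: float = 37.0,
    n_regions: int = 87,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
) -> PhantomSpec:
    """A template with a planted trend: regions 1-5 grow, 6-10 shrink
    (log-share +-0.02/week) and regions 11-15 fold with age (0.12
    voxels/week)."""
    growth = np.zeros(n_regions)
    fold = np.zeros(n_regions)
    growth[0 : min(5, n_regions)] = 0.02
    growth[5 : min(10, n_regions)] = -0.02
    fold[10 : min(15, n_regions)] = 0.12
    return PhantomSpec(
        age_weeks=age_weeks,
        grid_shape=tuple(grid_shape),
        n_regions=n_regions,
        growth_coefs=growth,
        fold_coefs=fold,
        seed=seed,
    )


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def generate_phantom(spec: PhantomSpec) -> LabelVolume:
    """Build one deterministic label phantom from a :class:`PhantomSpec`.

    An ellipsoidal mask is partitioned into ``n_regions`` by assigning
    each voxel to the nearest of ``n_regions`` seeded centroids under a
    share-weighted distance, so region volumes track
    ``softmax(base + growth_coef * (age - 37))``.  Regions with a nonzero
    fold coefficient have their distance field corrugated by a sinusoid
    of amplitude ``fold_coef * (age - 29)`` voxels, which wiggles their
    boundary and raises their surface count with age.  Finally a fraction
    ``noise_sd`` of boundary voxels is flipped to the label of a random
    face neighbor.

    Raises ``ValueError`` if any region ends up empty (grid too small).
    """
    rng = np.random.default_rng(spec.seed)
    shape = np.asarray(spec.grid_shape)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape

    # geometry draws: depend only on seed, never on age
    n = spec.n_regions
    directions = rng.normal(size=(n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rng.uniform(0, 1, size=n) ** (1 / 3)
    centroids = center + directions * radii[:, None] * (0.8 * semi)
    base_logits = rng.normal(0.0, 0.3, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=(n, 3))

    shares = _softmax(base_logits + spec.growth_coefs * (spec.age_weeks - AGE_PIVOT))
    scale = shares ** (1 / 3)  # radius-like weight per region

    grid = np.indices(spec.grid_shape, dtype=float)
    coords = grid.reshape(3, -1).T
    inside = (((coords - center) / semi) ** 2).sum(axis=1) <= 1.0
    pts = coords[inside]
    if not inside.any():
        raise ValueError("grid too small: empty ellipsoid mask")

    omega = 2 * np.pi / _FOLD_WAVELENGTH
    amplitudes = spec.fold_coefs * max(spec.age_weeks - AGE_MIN, 0.0)
    best_d = np.full(len(pts), np.inf)
    best_r = np.zeros(len(pts), dtype=np.int32)
    for r in range(n):
        d = np.linalg.norm(pts - centroids[r], axis=1)
        if amplitudes[r] != 0.0:
            corr = (
                np.sin(omega * pts[:, 0] + phases[r, 0])
                * np.sin(omega * pts[:, 1] + phases[r, 1])
                * np.sin(omega * pts[:, 2] + phases[r, 2])
            )
            d = d - amplitudes[r] * corr
        d = d / scale[r]
        better = d < best_d
        best_d[better] = d[better]
        best_r[better] = r + 1

    labels = np.zeros(int(np.prod(spec.grid_shape)), dtype=np.int32)
    labels[inside] = best_r
    labels = labels.reshape(spec.grid_shape)

    if spec.noise_sd > 0:
        labels = _flip_boundary_voxels(labels, spec)

    present = np.unique(labels)
    missing = set(range(1, n + 1)) - set(int(v) for v in present)
    if missing:
        raise ValueError(f"grid too small: regions {sorted(missing)} are empty")

    return LabelVolume(voxels=labels, spacing=(0.5, 0.5, 0.5))


def _flip_boundary_voxels(labels: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    from .morphometrics import _surface_mask

    nseed = spec.noise_seed
    if nseed is None:
        nseed = int(round(spec.age_weeks * 1e6)) % (2**31)
    rng = np.random.default_rng([spec.seed, nseed])

    surf = _surface_mask(labels, connectivity=6) & (labels > 0)
    idx = np.argwhere(surf)
    n_flip = int(round(spec.noise_sd * len(idx)))
    if n_flip == 0:
        return labels
    chosen = idx[rng.choice(len(idx), size=n_flip, replace=False)]
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    picks = offsets[rng.integers(0, 6, size=n_flip)]
    neighbors = chosen + picks
    out = labels.copy()
    shape = np.asarray(labels.shape)
    for (x, y, z), (nx, ny, nz) in zip(chosen, neighbors):
        if (0 <= nx < shape[0]) and (0 <= ny < shape[1]) and (0 <= nz < shape[2]):
            out[x, y, z] = labels[nx, ny, nz]
        else:
            out[x, y, z] = 0
    return out


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to build it."""

    manifest: CohortManifest
    truth: dict


def generate_cohort(
    n: int,
    age_range: tuple[float, float] = (29.0, 45.0),
    template: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike = ".",
) -> SyntheticCohort:
    """Generate ``n`` phantoms with uniform ages, write volumes + manifest.

    All subjects share the template's geometry seed (same "atlas"), so
    cross-subject feature variation reflects age and boundary noise only.
    Volumes are written as uncompressed NIfTI under ``out_dir`` and a
    manifest TSV as ``out_dir/manifest.tsv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age_range must satisfy lo < hi")
    if template is None:
        template = default_phantom_spec(seed=seed)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["female", "male"], size=n)

    rows = []
    for i in range(n):
        spec = replace(template, age_weeks=float(ages[i]), noise_seed=i)
        vol = generate_phantom(spec)
        sid = f"sub-{i:03d}"
        path = out_dir / f"{sid}_ses-1_labels.nii"
        write_label_volume(vol, path)
        rows.append(
            {
                "subject_id": sid,
                "session_id": "ses-1",
                "pma_weeks": float(ages[i]),
                "birth_ga_weeks": float(np.nan),
                "sex": str(sexes[i]),
                "volume_path": str(path),
            }
        )
    manifest = CohortManifest(rows=pd.DataFrame(rows))
    write_manifest(manifest, out_dir / "manifest.tsv")

    growing = np.argsort(-np.abs(template.growth_coefs))[:5] + 1
    truth = {
        "ages": ages.tolist(),
        "growth_coefs": template.growth_coefs.tolist(),
        "fold_coefs": template.fold_coefs.tolist(),
        "informative_regions": sorted(
            int(r + 1)
            for r in range(template.n_regions)
            if template.growth_coefs[r] != 0 or template.fold_coefs[r] != 0
        ),
        "top_growth_regions": [int(r) for r in growing],
        "seed": int(seed),
    }
    return SyntheticCohort(manifest=manifest, truth=truth)


def simulate_feature_table(
    n: int,
    n_regions: int = 87,
    informative: Sequence[int] | None = None,
    beta: float | Sequence[float] = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FeatureTable, dict]:
    """Tabular cohort with a planted linear age signal.

    Ages are Uniform(29, 45).  A shared age perturbation
    ``eps ~ N(0, noise_sd)`` (weeks) drives every informative feature, so
    no regressor can beat an MAE of ``noise_sd * sqrt(2/pi)`` — the
    returned truth dict records this floor.  RV columns are Dirichlet
    rows whose concentration for informative regions shifts linearly
    with the perturbed age; informative SVR columns are
    ``0.5 + beta * (age_perturbed - 37)`` plus a small independent
    jitter; the remaining SVR columns are pure noise.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if informative is None:
        informative = list(range(1, min(10, n_regions) + 1))
    informative = sorted(int(r) for r in informative)
    if not informative:
        raise ValueError("informative region set is empty")
    if any(r < 1 or r > n_regions for r in informative):
        raise ValueError(f"informative regions must be within 1..{n_regions}")

    betas = np.broadcast_to(np.asarray(beta, dtype=float), (len(informative),)).copy()

    rng = np.random.default_rng(seed)
    ages = rng.uniform(29.0, 45.0, size=n)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    z_obs = ages + eps

    names_rv = [f"RV:{region_name(r)}" for r in range(1, n_regions + 1)]
    names_svr = [f"SVR:{region_name(r)}" for r in range(1, n_regions + 1)]

    # RV rows: Dirichlet with age-shifted concentration on informative regions
    alpha = np.full((n, n_regions), 10.0)
    info_idx = np.asarray(informative) - 1
    alpha[:, info_idx] = np.maximum(10.0 + 0.5 * (z_obs[:, None] - AGE_PIVOT), 0.5)
    rv = np.empty((n, n_regions))
    for i in range(n):
        rv[i] = rng.dirichlet(alpha[i])

    svr = rng.normal(0.5, 0.05, size=(n, n_regions))
    for j, (r, b) in enumerate(zip(info_idx, betas)):
        jitter = rng.normal(0.0, 0.1 * abs(b) * noise_sd, size=n) if noise_sd > 0 else 0.0
        svr[:, r] = 0.5 + b * (z_obs - AGE_PIVOT) + jitter

    table = FeatureTable(
        subjects=[(f"sim-{i:03d}", "ses-1") for i in range(n)],
        feature_names=names_rv + names_svr,
        values=np.hstack([rv, svr]),
        ages=ages,
    )
    truth = {
        "informative_regions": informative,
        "informative_features": [names_rv[r] for r in info_idx]
        + [names_svr[r] for r in info_idx],
        "beta": betas.tolist(),
        "noise_sd": float(noise_sd),
        "noise_floor_mae": float(noise_sd * math.sqrt(2.0 / math.pi)),
        "observed_ages": z_obs.tolist(),
        "seed": int(seed),
    }
    return table, truth
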