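"""Permutation feature importance (PFI) per feature family.

Importance of a feature is the drop in a fitted model's score when that
feature's column is randomly shuffled (others intact), averaged over
repeats.  For the region-level report, two models are trained on the RV
and SVR feature families separately and their importances are rescaled to
[0, 1] by division by the family maximum.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .age_model import FeatureTable, FittedAgeModel, evaluate, fit_age_model, predict_age

__all__ = [
    "ImportanceEntry",
    "ImportanceReport",
    "permutation_importance",
    "family_importance",
    "rescale_importance",
]

FAMILIES = ("RV", "SVR")


@dataclass(frozen=True)
class ImportanceEntry:
    family: str
    region_name: str
    feature_name: str
    raw_importance: float
    importance_sd: float
    scaled_importance: float


@dataclass
class ImportanceReport:
    entries: list[ImportanceEntry]
    repeats: int
    scorer: str
    seed: int

    def sorted_entries(self) -> list[ImportanceEntry]:
        return sorted(self.entries, key=lambda e: -e.raw_importance)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "repeats": self.repeats,
            "scorer": self.scorer,
            "seed": self.seed,
            "entries": [
                {
                    "family": e.family,
                    "region_name": e.region_name,
                    "feature_name": e.feature_name,
                    "raw_importance": e.raw_importance,
                    "importance_sd": e.importance_sd,
                    "scaled_importance": e.scaled_importance,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ImportanceReport":
        p = json.loads(Path(path).read_text())
        entries = [ImportanceEntry(**e) for e in p["entries"]]
        return cls(entries=entries, repeats=int(p["repeats"]), scorer=p["scorer"], seed=int(p["seed"]))

    def to_csv(self, path: str | os.PathLike) -> None:
        """Tidy CSV (family, region, raw, sd, scaled) for plotting."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["family", "region_name", "feature_name", "raw", "sd", "scaled"])
            for e in self.sorted_entries():
                w.writerow(
                    [e.family, e.region_name, e.feature_name,
                     f"{e.raw_importance:.10g}", f"{e.importance_sd:.10g}",
                     f"{e.scaled_importance:.10g}"]
                )


def _score(model: FittedAgeModel, values: np.ndarray, ages: np.ndarray, scorer: str) -> float:
    preds = model.predict(values)
    if scorer == "r2_cod":
        sst = float(((ages - ages.mean()) ** 2).sum())
        return 1.0 - float(((preds - ages) ** 2).sum()) / sst
    if scorer == "neg_mae":
        return -float(np.mean(np.abs(preds - ages)))
    raise ValueError(f"unknown scorer {scorer!r}")


def permutation_importance(
    model: FittedAgeModel,
    table: FeatureTable,
    repeats: int = 30,
    seed: int = 0,
    scorer: str = "r2_cod",
) -> tuple[np.ndarray, np.ndarray]:
    """Raw PFI and Monte-Carlo sd per selected feature.

    importance_j = baseline score - mean over repeats of the score after
    shuffling column j; shuffles come from the seeded generator and the
    baseline is computed once on the supplied rows.
    """
    if table.n_rows < 5:
        raise ValueError("need at least 5 rows for permutation importance")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    missing = [n for n in model.selected_features if n not in table.feature_names]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")

    x = table.select_columns(model.selected_features).values.copy()
    ages = table.ages
    baseline = _score(model, x, ages, scorer)

    rng = np.random.default_rng(seed)
    p = x.shape[1]
    raw = np.empty(p)
    sd = np.empty(p)
    for j in range(p):
        drops = np.empty(repeats)
        original = x[:, j].copy()
        for r in range(repeats):
            x[:, j] = original[rng.permutation(len(original))]
            drops[r] = baseline - _score(model, x, ages, scorer)
        x[:, j] = original
        raw[j] = drops.mean()
        sd[j] = drops.std(ddof=1) if repeats > 1 else 0.0
    return raw, sd


def rescale_importance(raw: Sequence[float]) -> np.ndarray:
    """Clip negatives to 0 and divide by the maximum raw importance.

    All-non-positive input maps to all zeros.  Ranking among non-negative
    values is preserved and the operation is idempotent.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("importance list is empty")
    m = raw.max()
    if m <= 0:
        return np.zeros_like(raw)
    return np.maximum(raw, 0.0) / m


def family_importance(
    table: FeatureTable,
    family: str,
    repeats: int = 30,
    seed: int = 0,
    train_idx: Sequence[int] | None = None,
    eval_idx: Sequence[int] | None = None,
    scorer: str = "r2_cod",
    k_select: int | None = None,
) -> ImportanceReport:
    """Region-level PFI report for one feature family (RV or SVR).

    Restricts the table to the family's columns, fits a Bayesian ridge
    model on training rows, and runs PFI on held-out rows.  When no
    train/eval row indices are given, a seeded 75/25 shuffle split is
    used.  No top-k selection is applied within the family unless
    ``k_select`` is set.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    prefix = family + ":"
    names = [n for n in table.feature_names if n.startswith(prefix)]
    if len(names) < 2:
        raise ValueError(f"table has {len(names)} {family} features; need >= 2")
    fam_table = table.select_columns(names)

    rng = np.random.default_rng(seed)
    if train_idx is None or eval_idx is None:
        order = rng.permutation(fam_table.n_rows)
        n_train = int(round(0.75 * fam_table.n_rows))
        train_idx = order[:n_train]
        eval_idx = order[n_train:]
    train = fam_table.select_rows(train_idx)
    heldout = fam_table.select_rows(eval_idx)

    if k_select is not None:
        from .age_model import select_features

        selected = select_features(train, k=k_select)
    else:
        selected = names
    model = fit_age_model(train, selected, regressor_kind="bayesian_ridge", seed=seed)
    raw, sd = permutation_importance(
        model, heldout, repeats=repeats, seed=seed, scorer=scorer
    )
    scaled = rescale_importance(raw)

    entries = [
        ImportanceEntry(
            family=family,
            region_name=name[len(prefix):],
            feature_name=name,
            raw_importance=float(raw[j]),
            importance_sd=float(sd[j]),
            scaled_importance=float(scaled[j]),
        )
        for j, name in enumerate(model.selected_features)
    ]
    return ImportanceReport(entries=entries, repeats=int(repeats), scorer=scorer, seed=int(seed))
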