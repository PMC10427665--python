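# neobrainage

Interpretable brain-age estimation for neonatal MRI, downstream of
segmentation. Given 3D integer label volumes (e.g., an 87-region
DRAW-EM-style parcellation), the package:

1. extracts two cheap morphometric features per region —
   **relational volume** (RV: region voxels / all structure voxels) and
   **surface-to-volume ratio** (SVR: differing-neighbor surface voxels /
   region voxels, a gyrification proxy);
2. selects the features most correlated (absolute Pearson) with
   postmenstrual age (PMA) on the training rows;
3. regresses PMA at scan with Bayesian ridge (Kernel Ridge, ElasticNet,
   Gradient Boosting, SVM and MLP regressors are pluggable);
4. reports per-region **permutation feature importance** for the RV and
   SVR families separately, rescaled to [0, 1].

No real cohort is required: `neobrainage.synthetic_data` generates label
phantoms whose regional volumes and surface complexity depend on a known
age, and tabular cohorts with a planted linear age signal and a known
noise floor, so the whole pipeline is testable offline.

## CLI

```sh
# synthetic phantoms (NIfTI label volumes + manifest.tsv + truth.json)
neobrainage simulate --mode phantoms --n 20 --regions 87 --seed 0 --out cohort/

# RV/SVR feature table from a manifest of label volumes
neobrainage extract --manifest cohort/manifest.tsv --connectivity 6 --out features.csv

# subject-level train/validation/test split (defaults 0.60/0.15/0.25)
neobrainage split --manifest cohort/manifest.tsv --seed 0 --out split.json

# feature selection + Bayesian ridge fit; model saved as portable JSON
neobrainage fit --features features.csv --split split.json --k 100 \
    --regressor bayesian_ridge --seed 0 --out model.json

# predictions for new rows
neobrainage predict --model model.json --features features.csv --out preds.csv

# per-region permutation importance per family
neobrainage importance --features features.csv --split split.json \
    --family both --repeats 30 --seed 0 --out importance.json --csv importance.csv
```

The same operations are available as a Python API
(`neobrainage.extract_features`, `select_features`, `fit_age_model`,
`predict_age`, `evaluate`, `family_importance`, ...).

## Conventions

* Feature columns are named `RV:<region name>` and `SVR:<region name>`;
  the packaged default scheme has 87 regions (174 features). Unknown
  label ids fall back to `region_<id>`.
* Surface voxels use 6-connectivity by default (18/26 available);
  out-of-bounds neighbors count as background, so border voxels are
  surface voxels. All features are computed from voxel counts — voxel
  spacing is metadata only.
* `evaluate()` reports `r2` as the *squared Pearson correlation*
  (shift-invariant) plus `r2_cod` (coefficient of determination), MAE,
  RMSE and per-age-interval MAE.
* Splits are subject-level: all sessions of one subject share a
  partition. For a 558-scan single-session cohort at 0.60/0.15/0.25 the
  sizes are 334/84/140.

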