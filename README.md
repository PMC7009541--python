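# neonorm

Voxelwise normative modelling of multi-channel volumetric images with
multi-output Gaussian processes, plus patch-based anomaly scoring and
deviation-map fingerprinting.

For every voxel inside a brain mask, a five-output GP (two intensity
contrasts + three displacement components) is regressed on age-at-scan
(PMA), age-at-birth (GA) and sex, using an intrinsic co-regionalization
model: a shared linear + squared-exponential + white kernel coupled across
outputs by a low-rank-plus-diagonal mixing matrix. The fitted atlas yields:

- **growth-chart predictions** — expected image (mean and sd) at arbitrary
  covariates, with 5-fold every-fifth-subject cross-validation and MAE
  accuracy maps in units of the input-data SD;
- **deviation maps** — per-subject, per-channel Z volumes computed strictly
  out-of-fold;
- **zeta anomaly maps** — for each voxel, the distance from the subject's
  27-voxel deviation patch to the nearest of k=8 k-means clusters built from
  a reference set of other subjects' patches (neighbourhood context without
  smoothing);
- **lesion detection evaluation** — per-subject ROC/AUC for the sample
  Z-score, model Z-score and zeta score, compared with Friedman + post hoc
  Wilcoxon tests and Spearman age-dependence checks;
- **fingerprinting** — re-identification of individuals across timepoints by
  ranking spatial correlations of deviation maps;
- **global shape model** — per-subject affines decomposed into stretch and
  shear, each element fitted by a single-output GP, and rendering of
  template-space predictions into native space through the predicted affine
  and displacement fields.

A fully synthetic cohort generator (`neonorm.synthetic_cohort`) produces
5-channel volumes with known growth curves (baseline + linear + logistic +
prematurity terms), stable subject-specific deviation fields, correlated
cross-channel noise, planted spherical lesions and follow-up timepoints, so
the entire pipeline is testable without any imaging data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the release criteria (GP closed-form
oracles, Z calibration at n=200, trend/prematurity recovery, detection
ordering with planted 4-SD lesions, fingerprint identification vs chance,
affine round-trips, rank-statistic oracles). The full suite takes roughly
15 minutes on one CPU; everything else finishes in ~2 minutes.

## Command line

```bash
neonorm simulate --n 20 --grid 8,8,8 --seed 1 --lesions 5 --out work/cohort
neonorm fit      --cohort work/cohort --out work/atlas
neonorm predict  --atlas work/atlas --pma 41 --ga 30 --sex 0 --out work/pred
neonorm deviate  --atlas work/atlas --cohort work/cohort --out work/dev
neonorm zeta     --deviations work/dev --mask work/cohort/mask.nii --out work/zeta
neonorm evaluate --cohort work/cohort --atlas work/atlas --lesions work/cohort \
                 --out work/eval
neonorm fingerprint --followup-deviations work/dev2 \
                    --candidate-deviations work/dev \
                    --mask work/cohort/mask.nii --out work/fp
```

Volumes are NIfTI-1 (one file per subject per channel; 4-D channel stacks
are also read), covariates a CSV (`subject_id,pma_weeks,ga_weeks,sex
[,timepoint]`), atlases JSON. Every output directory carries a config
snapshot with a content hash; `evaluate` refuses to mix artifacts from
different configs without `--force`.

## Package layout

| module | contents |
| --- | --- |
| `neonorm.gp_kernels` | kernels, ICM covariance, Kronecker-factorized LML + analytic gradients, hyperparameter optimization, predictive distributions |
| `neonorm.normative_model` | fold assignment, per-voxel atlas fitting, deviation/MAE maps, image prediction, intensity normalization |
| `neonorm.synthetic_cohort` | covariate sampling, growth-curve ground truth, cohort/lesion/follow-up generators |
| `neonorm.shape_model` | affine stretch/shear decomposition, per-element GP fits, native-space rendering |
| `neonorm.anomaly_zeta` | patch extraction, per-voxel k-means references, zeta scoring (centroid and kNN variants) |
| `neonorm.evaluation` | ROC/AUC, sample Z-score, Friedman/Wilcoxon comparisons, age-dependence, fingerprinting, interval similarity |
| `neonorm.io_cli` | NIfTI/CSV/JSON I/O, run configuration + hashing, the `neonorm` CLI |
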