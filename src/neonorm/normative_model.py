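"""Per-voxel normative atlas: 5-fold cross-validated MOGP fitting over a
masked grid, out-of-fold deviation Z-maps, MAE accuracy maps, image
prediction at arbitrary covariates and prediction-median intensity
normalization."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import gp_kernels as gpk
from .synthetic_cohort import Cohort, CovariateRow, N_CHANNELS, design_matrix

__all__ = [
    "FoldAssignment",
    "NormativeAtlas",
    "DeviationMap",
    "AtlasFitError",
    "ExtrapolationError",
    "NormalizationError",
    "assign_folds",
    "fit_atlas",
    "predict_image",
    "deviation_map",
    "subject_deviation",
    "mae_map",
    "normalize_intensity",
]

log = logging.getLogger(__name__)

SD_FLOOR_FRACTION = 1e-6  # predicted-sd floor, as a fraction of channel data SD
EXTRAPOLATION_WARN_WEEKS = 2.0
EXTRAPOLATION_REFUSE_WEEKS = 6.0


class AtlasFitError(RuntimeError):
    """More than the tolerated fraction of voxels failed to fit."""


class ExtrapolationError(ValueError):
    """Requested covariates too far outside the training PMA range."""


class NormalizationError(RuntimeError):
    """Intensity normalization is undefined (zero ROI median)."""


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic every-k-th assignment in enrolment order."""

    subject_ids: tuple
    n_folds: int

    def fold_of(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id) % self.n_folds

    def fold_members(self, fold: int):
        return [s for i, s in enumerate(self.subject_ids) if i % self.n_folds == fold]

    def training_ids(self, fold: int):
        return [s for i, s in enumerate(self.subject_ids) if i % self.n_folds != fold]

    def as_dict(self) -> dict:
        return {s: i % self.n_folds for i, s in enumerate(self.subject_ids)}


def assign_folds(ordered_subject_ids, n_folds: int = 5) -> FoldAssignment:
    """Subject at ordinal position p goes to fold p mod n_folds (order matters)."""
    ids = tuple(ordered_subject_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    return FoldAssignment(ids, int(n_folds))


@dataclass
class DeviationMap:
    """Per-subject, per-channel Z volume (a normative probability map)."""

    z: np.ndarray  # (5, X, Y, Z); zero outside mask
    subject_id: str
    covariates: CovariateRow
    flagged_voxels: int = 0


@dataclass
class NormativeAtlas:
    """Grid of per-voxel MOGP fits (one per CV fold) plus accuracy maps."""

    mask: np.ndarray  # (X, Y, Z) bool — possibly reduced by degeneracy exclusion
    voxels: np.ndarray  # (V, 3) int coordinates of fitted voxels
    folds: FoldAssignment
    fits: list  # fits[fold][v] -> MOGPFit or None (flagged)
    config: dict
    data_sd: np.ndarray  # (V, 5) per-voxel/channel cohort SD
    pma_range: tuple
    final_fits: list | None = None  # all-data refit per voxel, optional
    mae: np.ndarray | None = None  # (5, X, Y, Z) normalized MAE
    flagged: np.ndarray | None = None  # (V,) bool

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def n_folds(self) -> int:
        return self.folds.n_folds

    def _check_covariates(self, cov: CovariateRow):
        lo, hi = self.pma_range
        over = max(lo - cov.pma_weeks, cov.pma_weeks - hi)
        if over > EXTRAPOLATION_REFUSE_WEEKS:
            raise ExtrapolationError(
                f"PMA {cov.pma_weeks} is {over:.1f} weeks outside training range "
                f"[{lo:.1f}, {hi:.1f}] (limit {EXTRAPOLATION_REFUSE_WEEKS})"
            )
        if over > EXTRAPOLATION_WARN_WEEKS:
            warnings.warn(
                f"PMA {cov.pma_weeks} extrapolates {over:.1f} weeks beyond the "
                f"training range [{lo:.1f}, {hi:.1f}]",
                stacklevel=3,
            )

    # -- serialization ------------------------------------------------------

    def to_json(self, path):
        doc = {
            "mask_shape": list(self.mask.shape),
            "mask_voxels": np.argwhere(self.mask).tolist(),
            "voxels": self.voxels.tolist(),
            "subject_ids": list(self.folds.subject_ids),
            "n_folds": self.folds.n_folds,
            "config": self.config,
            "data_sd": self.data_sd.tolist(),
            "pma_range": list(self.pma_range),
            "fits": [
                [None if f is None else f.to_dict() for f in fold_fits]
                for fold_fits in self.fits
            ],
            "final_fits": None
            if self.final_fits is None
            else [None if f is None else f.to_dict() for f in self.final_fits],
            "mae": None if self.mae is None else self.mae.tolist(),
            "flagged": None if self.flagged is None else self.flagged.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "NormativeAtlas":
        with open(path) as fh:
            doc = json.load(fh)
        mask = np.zeros(tuple(doc["mask_shape"]), dtype=bool)
        mv = np.array(doc["mask_voxels"], dtype=int)
        if len(mv):
            mask[tuple(mv.T)] = True
        return cls(
            mask=mask,
            voxels=np.array(doc["voxels"], dtype=int),
            folds=FoldAssignment(tuple(doc["subject_ids"]), doc["n_folds"]),
            fits=[
                [None if f is None else gpk.MOGPFit.from_dict(f) for f in fold_fits]
                for fold_fits in doc["fits"]
            ],
            config=doc["config"],
            data_sd=np.array(doc["data_sd"], dtype=float),
            pma_range=tuple(doc["pma_range"]),
            final_fits=None
            if doc["final_fits"] is None
            else [None if f is None else gpk.MOGPFit.from_dict(f) for f in doc["final_fits"]],
            mae=None if doc["mae"] is None else np.array(doc["mae"], dtype=float),
            flagged=None if doc["flagged"] is None else np.array(doc["flagged"], dtype=bool),
        )


DEFAULT_CONFIG = {
    "n_folds": 5,
    "rank": 2,
    "noise_mode": "coupled",
    "n_restarts": 1,
    "maxiter": 100,
    "ard": False,
    "seed": 0,
    "fit_final": False,
    "max_failure_fraction": 0.05,
    "compute_mae": True,
}


def fit_atlas(cohort: Cohort, config: dict | None = None) -> NormativeAtlas:
    """Fit one MOGP per masked voxel per training fold.

    Voxels are fitted independently (order-invariant), degenerate voxels
    (constant across the cohort in any channel) are excluded from the mask
    with a logged count, and per-voxel optimization failures are flagged as
    NaN; a run-level error is raised when more than
    ``max_failure_fraction`` of voxels fail.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if cohort.n_subjects < 10:
        raise ValueError("need at least 10 subjects to fit an atlas")
    if not cohort.mask.any():
        raise ValueError("empty mask")

    folds = assign_folds(cohort.subject_ids, cfg["n_folds"])
    X_all = design_matrix(cohort.covariates)
    pma = X_all[:, 0]

    mask = cohort.mask.copy()
    vox_all = np.argwhere(mask)
    Yv = cohort.images[:, :, vox_all[:, 0], vox_all[:, 1], vox_all[:, 2]]  # (n, 5, V)
    sd = Yv.std(axis=0)  # (5, V)
    degenerate = (sd <= 0).any(axis=0)
    if degenerate.any():
        log.info("excluding %d degenerate (constant) voxels from mask", degenerate.sum())
        mask[tuple(vox_all[degenerate].T)] = False
        vox_all = vox_all[~degenerate]
        Yv = Yv[:, :, ~degenerate]
        sd = sd[:, ~degenerate]
    V = len(vox_all)
    if V == 0:
        raise ValueError("all mask voxels are degenerate")

    fold_index = np.arange(cohort.n_subjects) % cfg["n_folds"]
    fits = [[None] * V for _ in range(cfg["n_folds"])]
    flagged = np.zeros(V, dtype=bool)
    failures = 0

    for f in range(cfg["n_folds"]):
        train = fold_index != f
        Xtr = X_all[train]
        for v in range(V):
            Ytr = Yv[train, :, v]
            try:
                fits[f][v] = gpk.optimize_hyperparameters(
                    Xtr,
                    Ytr,
                    n_restarts=cfg["n_restarts"],
                    seed=cfg["seed"] + f,
                    rank=cfg["rank"],
                    noise_mode=cfg["noise_mode"],
                    ard=cfg["ard"],
                    maxiter=cfg["maxiter"],
                )
            except (gpk.NumericalError, gpk.OptimizationError) as exc:
                log.warning("voxel %s fold %d failed: %s", vox_all[v], f, exc)
                flagged[v] = True
                failures += 1

    frac = failures / (V * cfg["n_folds"])
    if frac > cfg["max_failure_fraction"]:
        raise AtlasFitError(
            f"{failures} voxel-fold fits failed ({frac:.1%} > "
            f"{cfg['max_failure_fraction']:.0%} tolerated)"
        )

    final_fits = None
    if cfg["fit_final"]:
        final_fits = [None] * V
        for v in range(V):
            try:
                final_fits[v] = gpk.optimize_hyperparameters(
                    X_all,
                    Yv[:, :, v],
                    n_restarts=cfg["n_restarts"],
                    seed=cfg["seed"],
                    rank=cfg["rank"],
                    noise_mode=cfg["noise_mode"],
                    ard=cfg["ard"],
                    maxiter=cfg["maxiter"],
                )
            except (gpk.NumericalError, gpk.OptimizationError):
                flagged[v] = True

    atlas = NormativeAtlas(
        mask=mask,
        voxels=vox_all,
        folds=folds,
        fits=fits,
        config=cfg,
        data_sd=sd.T,  # (V, 5)
        pma_range=(float(pma.min()), float(pma.max())),
        final_fits=final_fits,
        flagged=flagged,
    )
    if cfg["compute_mae"]:
        atlas.mae = mae_map(atlas, cohort)
    return atlas


def _predict_voxels(atlas, fits, cov: CovariateRow, include_noise: bool):
    """Stack per-voxel predictions into (V, 5) mean and sd arrays."""
    x = cov.design()[None, :]
    V = atlas.n_voxels
    mean = np.full((V, N_CHANNELS), np.nan)
    sd = np.full((V, N_CHANNELS), np.nan)
    for v in range(V):
        fit = fits[v]
        if fit is None:
            continue
        mu, var = gpk.predict(fit, x, include_noise=include_noise)
        mean[v] = mu[0]
        sd[v] = np.sqrt(var[0])
    return mean, sd


def predict_image(
    atlas: NormativeAtlas,
    covariates: CovariateRow,
    include_noise: bool = False,
    fold: int | None = None,
):
    """Predicted (mean, sd) 5-channel volumes at arbitrary covariates.

    Uses the all-data refit when available, a specific fold when ``fold``
    is given, and otherwise averages the per-fold predictions (variances
    averaged accordingly).  NaN outside the mask and at flagged voxels.
    """
    atlas._check_covariates(covariates)
    if fold is not None:
        mean_v, sd_v = _predict_voxels(atlas, atlas.fits[fold], covariates, include_noise)
    elif atlas.final_fits is not None:
        mean_v, sd_v = _predict_voxels(atlas, atlas.final_fits, covariates, include_noise)
    else:
        means, variances = [], []
        for f in range(atlas.n_folds):
            m, s = _predict_voxels(atlas, atlas.fits[f], covariates, include_noise)
            means.append(m)
            variances.append(s**2)
        mean_v = np.mean(means, axis=0)
        sd_v = np.sqrt(np.mean(variances, axis=0))

    shape = (N_CHANNELS,) + atlas.mask.shape
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    ix = tuple(atlas.voxels.T)
    for c in range(N_CHANNELS):
        mean[c][ix] = mean_v[:, c]
        sd[c][ix] = sd_v[:, c]
    return mean, sd


def deviation_map(
    observed,
    predicted_mean,
    predicted_sd,
    subject_id: str = "",
    covariates: CovariateRow | None = None,
    mask=None,
    data_sd=None,
) -> DeviationMap:
    """Z = (observed − predicted mean) / predicted sd, per channel and voxel.

    The predicted sd is floored at ``SD_FLOOR_FRACTION`` of the channel data
    SD (or of the channel's own sd scale when data_sd is not given); floored
    voxels are counted in ``flagged_voxels``.
    """
    observed = np.asarray(observed, dtype=float)
    predicted_mean = np.asarray(predicted_mean, dtype=float)
    predicted_sd = np.asarray(predicted_sd, dtype=float)
    if mask is None:
        mask = np.isfinite(predicted_sd).all(axis=0)
    if data_sd is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data_sd = np.nanmax(predicted_sd.reshape(observed.shape[0], -1), axis=1)
    floor = SD_FLOOR_FRACTION * np.asarray(data_sd, dtype=float)
    floor = np.where(np.isfinite(floor) & (floor > 0), floor, SD_FLOOR_FRACTION)

    z = np.zeros_like(observed)
    flagged = 0
    for c in range(observed.shape[0]):
        sd_c = predicted_sd[c]
        low = mask & np.isfinite(sd_c) & (sd_c < floor[c])
        flagged += int(low.sum())
        sd_eff = np.where(sd_c >= floor[c], sd_c, floor[c])
        with np.errstate(invalid="ignore"):
            zc = (observed[c] - predicted_mean[c]) / sd_eff
        z[c] = np.where(mask, zc, 0.0)
    if flagged:
        log.warning("deviation_map: floored predicted sd at %d voxels", flagged)
    z[:, ~mask] = 0.0
    return DeviationMap(z=z, subject_id=subject_id, covariates=covariates, flagged_voxels=flagged)


def subject_deviation(
    atlas: NormativeAtlas,
    cohort: Cohort,
    subject_id: str,
    fold: int | None = None,
) -> DeviationMap:
    """Out-of-fold deviation map for one subject.

    The fold is the subject's own assignment when it appears in the atlas'
    enrolment list (so its training data never contained it); unseen
    subjects (e.g. follow-up scans) must pass ``fold`` explicitly or have
    their first-timepoint assignment looked up by id.
    """
    si = cohort.index_of(subject_id)
    cov = cohort.covariates[si]
    if fold is None:
        if subject_id not in atlas.folds.subject_ids:
            raise KeyError(
                f"{subject_id} was not in the fitted cohort; pass fold= explicitly"
            )
        fold = atlas.folds.fold_of(subject_id)
    mean, sd = predict_image(atlas, cov, include_noise=True, fold=fold)
    return deviation_map(
        cohort.images[si],
        mean,
        sd,
        subject_id=subject_id,
        covariates=cov,
        mask=atlas.mask,
        data_sd=atlas.data_sd.max(axis=0),
    )


def mae_map(atlas: NormativeAtlas, cohort: Cohort) -> np.ndarray:
    """Out-of-fold mean absolute error per voxel/channel, in units of that
    voxel/channel's cohort SD.  NaN (with a QC log entry) at zero-SD voxels."""
    X = design_matrix(cohort.covariates)
    ids = cohort.subject_ids
    ix = tuple(atlas.voxels.T)
    obs = cohort.images[:, :, ix[0], ix[1], ix[2]]  # (n, 5, V)

    abs_err = np.zeros((cohort.n_subjects, N_CHANNELS, atlas.n_voxels))
    for s, sid in enumerate(ids):
        fold = atlas.folds.fold_of(sid)
        mean_v, _ = _predict_voxels(
            atlas, atlas.fits[fold], cohort.covariates[s], include_noise=False
        )
        abs_err[s] = np.abs(obs[s] - mean_v.T)

    mae_v = abs_err.mean(axis=0)  # (5, V)
    sd_v = atlas.data_sd.T  # (5, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(sd_v > 0, mae_v / sd_v, np.nan)
    n_bad = int(np.isnan(norm).sum())
    if n_bad:
        log.warning("mae_map: %d voxel/channel entries have zero data SD", n_bad)

    out = np.full((N_CHANNELS,) + atlas.mask.shape, np.nan)
    for c in range(N_CHANNELS):
        out[c][ix] = norm[c]
    return out


def normalize_intensity(
    observed_image,
    atlas: NormativeAtlas,
    covariates: CovariateRow,
    roi_masks,
    channels=None,
) -> np.ndarray:
    """Scale each channel so its ROI median matches the predicted ROI median.

    ``roi_masks`` is either one boolean volume shared by all channels or a
    sequence of one per channel.  The single global factor per channel is
    median(predicted)/median(observed) over ROI voxels.
    """
    observed_image = np.asarray(observed_image, dtype=float)
    mean, _ = predict_image(atlas, covariates, include_noise=False)
    if channels is None:
        channels = range(observed_image.shape[0])
    rois = roi_masks
    if isinstance(rois, np.ndarray) and rois.ndim == 3:
        rois = [rois] * observed_image.shape[0]
    out = observed_image.copy()
    for c in channels:
        roi = np.asarray(rois[c], dtype=bool)
        if not roi.any():
            raise ValueError(f"channel {c}: empty ROI")
        if not (roi <= atlas.mask).all():
            raise ValueError(f"channel {c}: ROI extends outside the atlas mask")
        med_obs = np.median(observed_image[c][roi])
        med_pred = np.median(mean[c][roi])
        if med_obs == 0 or not np.isfinite(med_obs):
            raise NormalizationError(f"channel {c}: observed ROI median is zero/non-finite")
        if med_pred == 0 or not np.isfinite(med_pred):
            raise NormalizationError(f"channel {c}: predicted ROI median is zero/non-finite")
        out[c] = observed_image[c] * (med_pred / med_obs)
    return out
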