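"""Lesion-detection and longitudinal-consistency evaluation.

Per-subject ROC/AUC of voxel scores against planted (or outlined) lesion
masks for three scoring routes — covariate-blind sample Z, model-based Z and
the zeta anomaly score — compared with a Friedman test and post hoc Wilcoxon
signed-rank tests; plus deviation-map "fingerprint" identification, ranking
spatial correlations of a follow-up scan's deviation map against a candidate
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DetectionResult",
    "MethodComparison",
    "FingerprintResult",
    "UndefinedResultError",
    "roc_auc",
    "sample_zscore",
    "compare_methods",
    "auc_age_dependence",
    "fingerprint_identify",
    "interval_similarity",
]

log = logging.getLogger(__name__)


class UndefinedResultError(ValueError):
    """A statistic is undefined for this input (e.g. an empty class)."""


@dataclass
class DetectionResult:
    """Per-subject AUCs of the three scoring methods."""

    subject_id: str
    auc_raw_z: float
    auc_gpr_z: float
    auc_zeta: float
    n_lesion_voxels: int
    n_background_voxels: int

    def __post_init__(self):
        for name in ("auc_raw_z", "auc_gpr_z", "auc_zeta"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def roc_auc(scores, lesion_mask, brain_mask) -> float:
    """AUC = P(score_lesion > score_background) + ½ P(tie).

    Computed exactly through the Mann–Whitney rank statistic with midrank
    tie handling; no threshold grid.
    """
    scores = np.asarray(scores, dtype=float)
    lesion = np.asarray(lesion_mask, dtype=bool) & np.asarray(brain_mask, dtype=bool)
    background = np.asarray(brain_mask, dtype=bool) & ~np.asarray(lesion_mask, dtype=bool)
    pos = scores[lesion]
    neg = scores[background]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedResultError(
            f"AUC undefined: {len(pos)} lesion and {len(neg)} background voxels"
        )
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def sample_zscore(cohort, subject_id: str) -> np.ndarray:
    """Covariate-blind per-voxel Z: (x − leave-target-out mean) / SD.

    Returns a (5, X, Y, Z) volume, NaN (with a QC log entry) at zero-SD
    voxels, zero outside the mask.
    """
    if cohort.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    si = cohort.index_of(subject_id)
    others = np.delete(cohort.images, si, axis=0)  # (n-1, 5, X, Y, Z)
    mu = others.mean(axis=0)
    sd = others.std(axis=0, ddof=1)
    # constant-across-cohort voxels are degenerate even when rounding leaves
    # the computed sd a few ulp above zero
    degenerate = others.max(axis=0) == others.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~degenerate & (sd > 0), (cohort.images[si] - mu) / sd, np.nan)
    z[:, ~cohort.mask] = 0.0
    bad = int((np.isnan(z)[:, cohort.mask]).sum())
    if bad:
        log.warning("sample_zscore(%s): %d zero-SD voxel entries set NaN", subject_id, bad)
    return z


@dataclass
class MethodComparison:
    """Friedman omnibus + pairwise Wilcoxon post hoc report."""

    friedman_statistic: float
    friedman_p: float
    method_names: tuple
    median_auc: dict
    wilcoxon: dict = field(default_factory=dict)  # (a, b) -> {"statistic", "p", "median_gain"}
    posthoc_run: bool = False


def compare_methods(
    detection_results,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> MethodComparison:
    """Friedman chi-square on within-subject AUC ranks; if significant at
    ``alpha``, pairwise Wilcoxon signed-rank tests on AUC differences."""
    results = list(detection_results)
    if len(results) < 6:
        raise ValueError("need at least 6 subjects for the comparison")
    names = ("raw_z", "gpr_z", "zeta")
    data = np.array([[r.auc_raw_z, r.auc_gpr_z, r.auc_zeta] for r in results])

    if np.allclose(data, data[:, :1]):
        return MethodComparison(
            friedman_statistic=0.0,
            friedman_p=1.0,
            method_names=names,
            median_auc={n: float(np.median(data[:, j])) for j, n in enumerate(names)},
        )

    stat, p = stats.friedmanchisquare(*(data[:, j] for j in range(3)))
    comp = MethodComparison(
        friedman_statistic=float(stat),
        friedman_p=float(p),
        method_names=names,
        median_auc={n: float(np.median(data[:, j])) for j, n in enumerate(names)},
    )
    if p < alpha:
        comp.posthoc_run = True
        for a in range(3):
            for b in range(a + 1, 3):
                diff = data[:, b] - data[:, a]
                if np.allclose(diff, 0):
                    comp.wilcoxon[(names[a], names[b])] = {
                        "statistic": 0.0, "p": 1.0, "median_gain": 0.0,
                    }
                    continue
                method = "exact" if len(diff) <= 25 and not np.any(diff == 0) else "approx"
                w, wp = stats.wilcoxon(diff, alternative=alternative, method=method,
                                       correction=(method == "approx"))
                comp.wilcoxon[(names[a], names[b])] = {
                    "statistic": float(w),
                    "p": float(wp),
                    "median_gain": float(np.median(diff)),
                }
    return comp


def auc_age_dependence(detection_results, pma) -> dict:
    """Spearman rank correlation of per-subject AUC with scan age, per method."""
    results = list(detection_results)
    pma = np.asarray(pma, dtype=float)
    if len(results) < 5 or len(pma) != len(results):
        raise ValueError("need >= 5 subjects and one PMA per result")
    out = {}
    for name, vals in (
        ("raw_z", [r.auc_raw_z for r in results]),
        ("gpr_z", [r.auc_gpr_z for r in results]),
        ("zeta", [r.auc_zeta for r in results]),
    ):
        vals = np.asarray(vals, dtype=float)
        if np.all(vals == vals[0]):
            out[name] = {"rho": np.nan, "p": np.nan, "note": "constant AUCs: rho undefined"}
            continue
        rho, p = stats.spearmanr(pma, vals)
        out[name] = {"rho": float(rho), "p": float(p)}
    return out


@dataclass
class FingerprintResult:
    """Correlation-ranking identification of follow-up deviation maps."""

    correlations: np.ndarray  # (n_followup, n_candidates)
    ranks: np.ndarray  # (n_followup,) rank of own first scan, 1 = identified
    identified: np.ndarray  # (n_followup,) bool
    identification_rate: float
    excluded: list = field(default_factory=list)

    @property
    def n_followup(self) -> int:
        return len(self.ranks)


def fingerprint_identify(
    followup_maps,
    candidate_maps,
    self_index,
    mask=None,
) -> FingerprintResult:
    """Rank each follow-up map's Pearson correlation against all candidates.

    ``followup_maps`` (n_f, V or volume) and ``candidate_maps`` (n_c, ...)
    are single-channel deviation maps (channels are scored separately, never
    pooled); ``self_index[i]`` is the candidate position of follow-up i's
    own first scan.  A tie at the top rank counts as a failed
    identification (pessimistic tie-breaking).  Zero-variance maps are
    excluded with a flag.
    """
    F = np.asarray(followup_maps, dtype=float)
    C = np.asarray(candidate_maps, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        F = F.reshape((F.shape[0],) + mask.shape)[:, mask]
        C = C.reshape((C.shape[0],) + mask.shape)[:, mask]
    else:
        F = F.reshape(F.shape[0], -1)
        C = C.reshape(C.shape[0], -1)
    self_index = np.asarray(self_index, dtype=int)
    if len(self_index) != len(F):
        raise ValueError("one self_index entry per follow-up map required")

    Fs = F.std(axis=1)
    Cs = C.std(axis=1)
    excluded = [int(i) for i in np.where(Fs == 0)[0]]
    if np.any(Cs == 0):
        raise UndefinedResultError(
            f"candidate maps {list(np.where(Cs == 0)[0])} have zero variance"
        )

    Fc = F - F.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    denom = np.outer(Fs, Cs) * F.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Fc @ Cc.T) / denom  # (n_f, n_c)

    n_f = len(F)
    ranks = np.zeros(n_f, dtype=int)
    identified = np.zeros(n_f, dtype=bool)
    keep = np.ones(n_f, dtype=bool)
    for i in range(n_f):
        if i in excluded:
            keep[i] = False
            continue
        own = corr[i, self_index[i]]
        others = np.delete(corr[i], self_index[i])
        ranks[i] = 1 + int(np.sum(others >= own))  # ties count against us
        identified[i] = bool(np.all(others < own))
    if excluded:
        log.warning("fingerprint_identify: excluded zero-variance follow-ups %s", excluded)
    n_valid = int(keep.sum())
    rate = float(identified[keep].sum() / n_valid) if n_valid else np.nan
    return FingerprintResult(
        correlations=corr,
        ranks=ranks[keep],
        identified=identified[keep],
        identification_rate=rate,
        excluded=excluded,
    )


def interval_similarity(intervals_weeks, self_correlations) -> dict:
    """Pearson r between inter-scan interval and self-map similarity.

    Reports r on the raw interval (longer interval → lower similarity gives
    a negative r) along with |r| and the p-value.
    """
    x = np.asarray(intervals_weeks, dtype=float)
    y = np.asarray(self_correlations, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 (interval, correlation) pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"r": np.nan, "abs_r": np.nan, "p": np.nan, "note": "constant input: r undefined"}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "abs_r": float(abs(r)), "p": float(p), "n": len(x)}
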