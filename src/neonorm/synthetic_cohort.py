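"""Synthetic multi-channel cohorts with known growth structure.

Generates cohorts of 5-channel volumes (two intensity contrasts plus three
displacement components) whose voxelwise means follow a smooth age
trajectory — baseline + linear + logistic terms in age-at-scan plus a
prematurity term in (scan age − birth age) — with a stable subject-specific
deviation field (the "fingerprint"), correlated cross-channel noise,
optional planted spherical lesions and follow-up timepoints.  Everything is
seeded and bit-reproducible, and the hidden per-subject effects are returned
so recovery tests can assert against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.special import expit

__all__ = [
    "CovariateRow",
    "TissueLabelMap",
    "GrowthCurveSpec",
    "Cohort",
    "LesionSet",
    "LesionPlacementError",
    "CHANNEL_NAMES",
    "sample_covariates",
    "ground_truth_mean",
    "generate_cohort",
    "plant_lesions",
    "generate_followup",
    "default_label_map",
    "default_growth_spec",
    "sphere_offsets",
]

N_CHANNELS = 5
CHANNEL_NAMES = ("intensity1", "intensity2", "disp_x", "disp_y", "disp_z")


class LesionPlacementError(RuntimeError):
    """Could not place the requested lesions inside the mask."""


@dataclass(frozen=True)
class CovariateRow:
    """One subject's design-matrix entry: scan age, birth age, sex."""

    subject_id: str
    pma_weeks: float
    ga_weeks: float
    sex: int
    timepoint: int = 0

    def __post_init__(self):
        if not (20.0 <= self.ga_weeks <= self.pma_weeks <= 46.0):
            raise ValueError(
                f"{self.subject_id}: require 20 <= ga ({self.ga_weeks}) <= "
                f"pma ({self.pma_weeks}) <= 46"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"{self.subject_id}: sex must be 0 or 1, got {self.sex}")

    def design(self) -> np.ndarray:
        return np.array([self.pma_weeks, self.ga_weeks, float(self.sex)])


def design_matrix(covariates) -> np.ndarray:
    """(n, 3) array of (pma, ga, sex) rows."""
    return np.array([c.design() for c in covariates])


@dataclass
class TissueLabelMap:
    """Integer label volume; 0 = background, excluded from all modelling."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")

    @property
    def grid_shape(self):
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def present_labels(self):
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)


@dataclass
class LabelChannelCurve:
    """Per-label growth-curve coefficients, one value per channel."""

    baseline: np.ndarray
    linear_slope: np.ndarray
    sigmoid_amplitude: np.ndarray
    sigmoid_midpoint: np.ndarray
    sigmoid_width: np.ndarray
    prematurity_slope: np.ndarray
    sex_effect: np.ndarray
    channel_correlation: np.ndarray  # (5, 5) SPD, unit diagonal

    def __post_init__(self):
        for name in (
            "baseline",
            "linear_slope",
            "sigmoid_amplitude",
            "sigmoid_midpoint",
            "sigmoid_width",
            "prematurity_slope",
            "sex_effect",
        ):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (N_CHANNELS,))
            object.__setattr__(self, name, np.array(v))
        C = np.asarray(self.channel_correlation, dtype=float)
        if C.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("channel_correlation must be 5x5")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("channel_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("channel_correlation must be positive definite")
        self.channel_correlation = C


@dataclass
class GrowthCurveSpec:
    """Ground-truth curve family keyed by tissue label."""

    curves: dict[int, LabelChannelCurve]

    def __getitem__(self, label: int) -> LabelChannelCurve:
        return self.curves[label]

    def __contains__(self, label: int) -> bool:
        return label in self.curves


@dataclass
class Cohort:
    """Aligned multi-channel volumes + covariates + mask + affines."""

    covariates: list[CovariateRow]
    images: np.ndarray  # (n_subjects, 5, X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool
    affines: np.ndarray  # (n_subjects, 3, 4)
    channel_names: tuple = CHANNEL_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.images.ndim != 5 or self.images.shape[1] != N_CHANNELS:
            raise ValueError("images must be (n_subjects, 5, X, Y, Z)")
        if self.images.shape[2:] != self.mask.shape:
            raise ValueError("image grid does not match mask grid")
        if self.images.shape[0] != len(self.covariates):
            raise ValueError("one covariate row per subject required")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def grid_shape(self):
        return self.mask.shape

    @property
    def subject_ids(self):
        return [c.subject_id for c in self.covariates]

    def index_of(self, subject_id: str) -> int:
        for i, c in enumerate(self.covariates):
            if c.subject_id == subject_id:
                return i
        raise KeyError(subject_id)


@dataclass
class SubjectLesion:
    mask: np.ndarray  # (X, Y, Z) bool
    amplitude_sd: float
    channel_index: int


@dataclass
class LesionSet:
    """Planted lesion masks per subject, with effect size and target channel."""

    lesions: dict[str, SubjectLesion]

    def mask_for(self, subject_id: str) -> np.ndarray:
        return self.lesions[subject_id].mask


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def sample_covariates(
    n: int,
    seed: int = 0,
    pma_range: tuple[float, float] = (37.0, 45.0),
    preterm_fraction: float = 0.3,
):
    """Sample n covariate rows with a controlled preterm-birth fraction.

    PMA ~ Uniform(pma_range); with probability ``preterm_fraction`` GA is
    drawn preterm (Uniform(24, 36.5)), otherwise at term
    (Uniform(37, min(42, pma))).  Sex is Bernoulli(1/2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = float(pma_range[0]), float(pma_range[1])
    if not (20.0 <= lo < hi <= 46.0):
        raise ValueError(f"pma_range must satisfy 20 <= lo < hi <= 46, got {pma_range}")
    if lo < 37.0:
        raise ValueError("pma_range lower bound below 37 cannot host term births")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        pma = rng.uniform(lo, hi)
        if rng.uniform() < preterm_fraction:
            ga = rng.uniform(24.0, 36.5)
        else:
            ga = rng.uniform(37.0, min(42.0, pma))
        rows.append(
            CovariateRow(f"sub-{i:04d}", float(pma), float(ga), int(rng.integers(0, 2)))
        )
    return rows


def ground_truth_mean(spec: GrowthCurveSpec, label: int, cov: CovariateRow) -> np.ndarray:
    """Noise-free 5-channel mean at one covariate point.

    mean_c = baseline + slope·pma + amplitude·logistic((pma − midpoint)/width)
             + prematurity_slope·(pma − ga) + sex_effect·sex
    """
    if label not in spec:
        raise KeyError(f"label {label} not in growth spec")
    c = spec[label]
    pma, ga, sex = cov.pma_weeks, cov.ga_weeks, float(cov.sex)
    return (
        c.baseline
        + c.linear_slope * pma
        + c.sigmoid_amplitude * expit((pma - c.sigmoid_midpoint) / c.sigmoid_width)
        + c.prematurity_slope * (pma - ga)
        + c.sex_effect * sex
    )


def default_label_map(shape=(8, 8, 8), n_labels: int = 2) -> TissueLabelMap:
    """Ball-shaped mask split into concentric label shells."""
    shape = tuple(int(s) for s in shape)
    center = (np.array(shape) - 1) / 2.0
    coords = np.indices(shape).astype(float)
    r = np.sqrt(sum((coords[k] - center[k]) ** 2 for k in range(3)))
    rmax = min(shape) / 2.0
    labels = np.zeros(shape, dtype=int)
    inside = r <= rmax
    edges = np.linspace(0.0, rmax, n_labels + 1)
    for i in range(n_labels):
        shell = inside & (r >= edges[i]) & (r <= edges[i + 1])
        labels[shell] = n_labels - i  # innermost shell gets highest label
    return TissueLabelMap(labels)


def full_grid_label_map(shape=(6, 6, 6)) -> TissueLabelMap:
    """Single-label map covering the whole grid (no background voxels)."""
    labels = np.ones(tuple(int(s) for s in shape), dtype=int)
    return TissueLabelMap(labels)


def default_growth_spec(
    labels=(1, 2),
    sigmoid_amplitude: float = 2.0,
    prematurity_slope: float = 0.05,
    sigmoid_midpoint: float = 40.0,
    sigmoid_width: float = 1.5,
    linear_slope: float = 0.05,
    sex_effect: float = 0.0,
    channel_correlation: np.ndarray | None = None,
    seed: int = 12345,
) -> GrowthCurveSpec:
    """A reasonable default curve family with mildly label/channel-varied coefficients."""
    rng = np.random.default_rng(seed)
    if channel_correlation is None:
        # moderately correlated channels, guaranteed SPD
        A = rng.normal(0.0, 0.4, size=(N_CHANNELS, N_CHANNELS))
        C = A @ A.T + np.eye(N_CHANNELS) * 1.5
        d = np.sqrt(np.diag(C))
        channel_correlation = C / np.outer(d, d)
    curves = {}
    for li, label in enumerate(labels):
        scale = 1.0 + 0.25 * li
        curves[int(label)] = LabelChannelCurve(
            baseline=10.0 * scale + rng.normal(0, 0.5, N_CHANNELS),
            linear_slope=linear_slope * (1 + 0.2 * rng.normal(size=N_CHANNELS)),
            sigmoid_amplitude=sigmoid_amplitude * scale * (1 + 0.1 * rng.normal(size=N_CHANNELS)),
            sigmoid_midpoint=sigmoid_midpoint + rng.normal(0, 0.5, N_CHANNELS),
            sigmoid_width=sigmoid_width * np.ones(N_CHANNELS),
            prematurity_slope=prematurity_slope * np.ones(N_CHANNELS),
            sex_effect=sex_effect * np.ones(N_CHANNELS),
            channel_correlation=channel_correlation,
        )
    return GrowthCurveSpec(curves)


def _sample_affines(covariates, rng):
    """Mild growth-linked affine per subject: stretch increases with PMA."""
    affs = np.zeros((len(covariates), 3, 4))
    for i, cov in enumerate(covariates):
        stretch = 1.0 + 0.02 * (cov.pma_weeks - 40.0) + rng.normal(0.0, 0.01, 3)
        shear = rng.normal(0.0, 0.01, 3)
        U = np.diag(stretch)
        U[0, 1] = shear[0] * stretch[0]
        U[0, 2] = shear[1] * stretch[0]
        U[1, 2] = shear[2] * stretch[1]
        # small random rotation via matrix exponential of a skew generator
        w = rng.normal(0.0, 0.02, 3)
        S = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        R = np.eye(3) + S + 0.5 * (S @ S)
        Q, _ = np.linalg.qr(R)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        affs[i, :, :3] = Q @ U
        affs[i, :, 3] = rng.normal(0.0, 0.5, 3)
    return affs


def generate_cohort(
    n: int | None,
    grid: TissueLabelMap,
    spec: GrowthCurveSpec,
    noise_sd: float = 1.0,
    subject_effect_sd: float = 0.5,
    seed: int = 0,
    covariates: list[CovariateRow] | None = None,
    pma_range: tuple[float, float] = (37.0, 45.0),
    preterm_fraction: float = 0.3,
):
    """Generate a cohort and return (Cohort, hidden_effects).

    Per voxel v (with label ℓ), channel c, subject s:

        y = mean_c(ℓ, cov_s) + u_s(v, c) + ε(v, c, s)

    with u_s ~ N(0, subject_effect_sd²) i.i.d. over (v, c) but fixed per
    subject (the fingerprint) and ε correlated across channels by the
    label's channel_correlation, scaled to noise_sd.  hidden_effects has
    shape (n, 5, X, Y, Z) and is zero outside the mask.
    """
    if noise_sd < 0 or subject_effect_sd < 0:
        raise ValueError("noise_sd and subject_effect_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if covariates is None:
        if n is None or n < 1:
            raise ValueError("n must be >= 1 when covariates are not supplied")
        covariates = sample_covariates(n, seed=rng.integers(2**31), pma_range=pma_range,
                                       preterm_fraction=preterm_fraction)
    n = len(covariates)
    shape = grid.grid_shape
    mask = grid.mask
    images = np.zeros((n, N_CHANNELS) + shape)
    hidden = np.zeros_like(images)

    label_vox = {lab: np.where(grid.labels == lab) for lab in grid.present_labels}
    chol = {lab: np.linalg.cholesky(spec[lab].channel_correlation) for lab in grid.present_labels}

    for s, cov in enumerate(covariates):
        u = rng.normal(0.0, 1.0, size=(N_CHANNELS, mask.sum())) * subject_effect_sd
        mv = np.where(mask)
        hidden[s][(slice(None),) + mv] = u
        for lab, vox in label_vox.items():
            mean = ground_truth_mean(spec, lab, cov)  # (5,)
            eps = chol[lab] @ rng.normal(0.0, 1.0, size=(N_CHANNELS, len(vox[0])))
            images[s][(slice(None),) + vox] = mean[:, None] + noise_sd * eps
        images[s] += hidden[s]
        images[s][:, ~mask] = 0.0

    cohort = Cohort(
        covariates=list(covariates),
        images=images,
        mask=mask,
        affines=_sample_affines(covariates, rng),
        meta={
            "grid": grid,
            "spec": spec,
            "noise_sd": float(noise_sd),
            "subject_effect_sd": float(subject_effect_sd),
            "seed": int(seed),
        },
    )
    return cohort, hidden


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets with dx²+dy²+dz² <= radius² (discrete sphere)."""
    r = int(radius)
    rng_ = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(rng_, rng_, rng_, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def plant_lesions(
    cohort: Cohort,
    subject_ids,
    n_lesions_per_subject: int = 3,
    radius_voxels: int = 1,
    amplitude_sd: float = 4.0,
    channel_index: int = 0,
    seed: int = 0,
    noise_sd: float | None = None,
    max_retries: int = 200,
):
    """Add spherical lesions to one channel; returns (new Cohort, LesionSet).

    Lesion voxels on ``channel_index`` are shifted by
    ``amplitude_sd · noise_sd``; all other voxels are untouched.  Centres
    are drawn so the full sphere lies inside the mask.
    """
    if radius_voxels < 1:
        raise ValueError("radius_voxels must be >= 1")
    if amplitude_sd == 0.0 and noise_sd != 0.0:
        pass  # images unchanged but masks still produced
    if noise_sd is None:
        noise_sd = cohort.meta.get("noise_sd")
        if noise_sd is None:
            raise ValueError("noise_sd not in cohort meta; pass it explicitly")
    rng = np.random.default_rng(seed)
    offsets = sphere_offsets(radius_voxels)
    struct = np.zeros((2 * radius_voxels + 1,) * 3, dtype=bool)
    struct[tuple((offsets + radius_voxels).T)] = True
    valid = binary_erosion(cohort.mask, structure=struct)
    valid_idx = np.argwhere(valid)
    if len(valid_idx) == 0:
        raise LesionPlacementError(
            f"no voxel can host a radius-{radius_voxels} sphere inside the mask"
        )

    images = cohort.images.copy()
    lesions = {}
    shift = float(amplitude_sd) * float(noise_sd)
    for sid in subject_ids:
        si = cohort.index_of(sid)
        lmask = np.zeros(cohort.grid_shape, dtype=bool)
        placed = 0
        for _ in range(max_retries):
            if placed == n_lesions_per_subject:
                break
            c = valid_idx[rng.integers(len(valid_idx))]
            vox = c[None, :] + offsets
            if lmask[tuple(vox.T)].any():  # avoid overlapping lesions
                continue
            lmask[tuple(vox.T)] = True
            placed += 1
        if placed < n_lesions_per_subject:
            raise LesionPlacementError(
                f"{sid}: placed {placed}/{n_lesions_per_subject} lesions after "
                f"{max_retries} attempts"
            )
        images[si, channel_index][lmask] += shift
        lesions[sid] = SubjectLesion(lmask, float(amplitude_sd), int(channel_index))

    out = replace(cohort, images=images, meta=dict(cohort.meta))
    return out, LesionSet(lesions)


def generate_followup(
    cohort: Cohort,
    hidden,
    subject_ids,
    interval_weeks: float,
    effect_persistence: float,
    seed: int = 0,
):
    """Second-timepoint cohort for a subset of subjects.

    The hidden subject effect evolves as an AR(1)-style blend,
    ``u(t2) = p·u(t1) + √(1−p²)·fresh``, keeping its marginal variance;
    fresh noise ε is redrawn.  PMA advances by ``interval_weeks``; GA and
    sex are unchanged.  Returns (Cohort, hidden_effects_t2).
    """
    if not (0.0 <= effect_persistence <= 1.0):
        raise ValueError("effect_persistence must be in [0, 1]")
    grid: TissueLabelMap = cohort.meta["grid"]
    spec: GrowthCurveSpec = cohort.meta["spec"]
    noise_sd = cohort.meta["noise_sd"]
    subject_sd = cohort.meta["subject_effect_sd"]
    rng = np.random.default_rng(seed)
    mask = cohort.mask
    p = float(effect_persistence)

    new_rows, new_images, new_hidden, new_affines = [], [], [], []
    label_vox = {lab: np.where(grid.labels == lab) for lab in grid.present_labels}
    chol = {lab: np.linalg.cholesky(spec[lab].channel_correlation) for lab in grid.present_labels}

    for sid in subject_ids:
        si = cohort.index_of(sid)
        cov = cohort.covariates[si]
        new_pma = cov.pma_weeks + float(interval_weeks)
        if new_pma > 46.0:
            raise ValueError(f"{sid}: pma after interval ({new_pma}) exceeds 46 weeks")
        row = CovariateRow(sid, new_pma, cov.ga_weeks, cov.sex, timepoint=cov.timepoint + 1)

        fresh = rng.normal(0.0, 1.0, size=(N_CHANNELS, int(mask.sum()))) * subject_sd
        u2 = np.zeros((N_CHANNELS,) + cohort.grid_shape)
        mv = np.where(mask)
        u1 = hidden[si][(slice(None),) + mv]
        u2[(slice(None),) + mv] = p * u1 + np.sqrt(max(0.0, 1.0 - p * p)) * fresh

        img = np.zeros((N_CHANNELS,) + cohort.grid_shape)
        for lab, vox in label_vox.items():
            mean = ground_truth_mean(spec, lab, row)
            eps = chol[lab] @ rng.normal(0.0, 1.0, size=(N_CHANNELS, len(vox[0])))
            img[(slice(None),) + vox] = mean[:, None] + noise_sd * eps
        img += u2
        img[:, ~mask] = 0.0

        new_rows.append(row)
        new_images.append(img)
        new_hidden.append(u2)
        new_affines.append(cohort.affines[si])

    followup = Cohort(
        covariates=new_rows,
        images=np.array(new_images),
        mask=mask,
        affines=np.array(new_affines),
        meta=dict(cohort.meta),
    )
    return followup, np.array(new_hidden)
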