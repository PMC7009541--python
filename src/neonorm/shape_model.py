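"""Global shape model: stretch/shear decomposition of per-subject affine
transforms, single-output GP growth fits of the six elements, and rendering
of template-space predictions into native space."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from . import gp_kernels as gpk
from .synthetic_cohort import design_matrix

__all__ = [
    "AffineDecomposition",
    "DecompositionError",
    "ShapeGrowthModel",
    "decompose_affine",
    "recompose_affine",
    "fit_shape_growth",
    "predict_shape",
    "render_native",
]

ELEMENT_NAMES = ("stretch_x", "stretch_y", "stretch_z", "shear_xy", "shear_xz", "shear_yz")


class DecompositionError(ValueError):
    """Linear part is singular or orientation-reversing."""


@dataclass
class AffineDecomposition:
    """A = rotation · upper_triangular(stretch, shear).

    Stretch is the positive diagonal of the triangular factor; shear is the
    dimensionless ratio triple (U12/U11, U13/U11, U23/U22).  Rotation and
    translation are carried but never modelled.
    """

    stretch: np.ndarray  # (3,) > 0
    shear: np.ndarray  # (3,) — xy, xz, yz ratios
    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    @property
    def elements(self) -> np.ndarray:
        return np.concatenate([self.stretch, self.shear])

    @property
    def triangular(self) -> np.ndarray:
        sx, sy, sz = self.stretch
        hxy, hxz, hyz = self.shear
        return np.array(
            [
                [sx, hxy * sx, hxz * sx],
                [0.0, sy, hyz * sy],
                [0.0, 0.0, sz],
            ]
        )


def decompose_affine(linear_part, translation=None, method: str = "qr") -> AffineDecomposition:
    """Split a 3×3 linear map into rotation × (stretch + shear).

    ``method='qr'`` gives the graphics-convention RQ form A = R·U with R a
    proper rotation and U upper triangular, positive diagonal.
    ``method='polar'`` (sensitivity variant) uses the polar decomposition
    A = R·P and re-triangularizes P; both round-trip exactly.
    """
    A = np.asarray(linear_part, dtype=float)
    if A.shape == (3, 4):
        translation = A[:, 3]
        A = A[:, :3]
    if A.shape != (3, 3):
        raise ValueError("linear_part must be 3x3 (or a 3x4 affine)")
    det = np.linalg.det(A)
    if det <= 1e-12:
        raise DecompositionError(f"determinant must be positive, got {det:.3g}")
    if translation is None:
        translation = np.zeros(3)

    if method == "qr":
        Q, U = np.linalg.qr(A)
        # enforce positive diagonal of U (QR sign ambiguity)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q = Q * signs[None, :]
        U = U * signs[:, None]
    elif method == "polar":
        Wm, s, Vt = np.linalg.svd(A)
        R = Wm @ Vt
        P = Vt.T @ np.diag(s) @ Vt  # symmetric positive definite
        # re-triangularize: P = Q2 U with Q2 rotation folded into R
        Q2, U = np.linalg.qr(P)
        signs = np.sign(np.diag(U))
        signs[signs == 0] = 1.0
        Q2 = Q2 * signs[None, :]
        U = U * signs[:, None]
        Q = R @ Q2
    else:
        raise ValueError(f"unknown decomposition method {method!r}")

    if np.linalg.det(Q) < 0:  # pragma: no cover — excluded by det(A) > 0
        raise DecompositionError("decomposition produced a reflection")
    stretch = np.diag(U).copy()
    shear = np.array([U[0, 1] / U[0, 0], U[0, 2] / U[0, 0], U[1, 2] / U[1, 1]])
    return AffineDecomposition(stretch, shear, Q, np.asarray(translation, dtype=float))


def recompose_affine(dec: AffineDecomposition) -> np.ndarray:
    """3×4 affine from a decomposition (rotation · triangular, + translation)."""
    out = np.zeros((3, 4))
    out[:, :3] = dec.rotation @ dec.triangular
    out[:, 3] = dec.translation
    return out


@dataclass
class ShapeGrowthModel:
    """Six independent single-output GP fits over (PMA, GA, sex)."""

    fits: dict  # element name -> MOGPFit

    def predict(self, covariates, include_noise: bool = False):
        """(mean, sd) dicts keyed by element name at the given CovariateRow."""
        x = covariates.design()[None, :]
        mean, sd = {}, {}
        for name, fit in self.fits.items():
            mu, var = gpk.predict(fit, x, output_index=0, include_noise=include_noise)
            mean[name] = float(mu[0])
            sd[name] = float(np.sqrt(var[0]))
        return mean, sd

    def predicted_affine(self, covariates) -> np.ndarray:
        """3×4 affine with predicted stretch/shear, identity rotation, zero shift."""
        mean, _ = self.predict(covariates)
        dec = AffineDecomposition(
            stretch=np.array([mean[n] for n in ELEMENT_NAMES[:3]]),
            shear=np.array([mean[n] for n in ELEMENT_NAMES[3:]]),
            rotation=np.eye(3),
            translation=np.zeros(3),
        )
        return recompose_affine(dec)


def fit_shape_growth(
    decompositions,
    covariates,
    n_restarts: int = 1,
    seed: int = 0,
    maxiter: int = 200,
) -> ShapeGrowthModel:
    """Fit the six stretch/shear elements as independent single-output GPs,
    using the same kernel family and design matrix as the voxel models."""
    if len(decompositions) != len(covariates):
        raise ValueError("one decomposition per covariate row required")
    if len(decompositions) < 10:
        raise ValueError("need at least 10 subjects")
    X = design_matrix(covariates)
    E = np.array([d.elements for d in decompositions])  # (n, 6)
    fits = {}
    for j, name in enumerate(ELEMENT_NAMES):
        fits[name] = gpk.optimize_hyperparameters(
            X,
            E[:, j : j + 1],
            n_restarts=n_restarts,
            seed=seed + j,
            fit_coreg=False,
            maxiter=maxiter,
        )
    return ShapeGrowthModel(fits)


def predict_shape(model: ShapeGrowthModel, covariates):
    return model.predict(covariates)


def render_native(
    template_volume,
    affine,
    displacement=None,
    order: int = 1,
    displacement_before_affine: bool = True,
) -> np.ndarray:
    """Resample a template-space volume through (affine ∘ displacement).

    ``affine`` (3×4, voxel coordinates) maps template voxels to native
    voxels; rendering samples the template at the inverse-mapped position of
    each native voxel.  ``displacement`` is a (3, X, Y, Z) field of offsets
    in template voxel units, applied to the template-side coordinate (the
    default composition order; set ``displacement_before_affine=False`` to
    offset on the native side before inverting the affine).  Trilinear
    interpolation; out-of-field voxels are 0.
    """
    vol = np.asarray(template_volume, dtype=float)
    A = np.asarray(affine, dtype=float)
    if A.shape == (3, 3):
        A = np.hstack([A, np.zeros((3, 1))])
    if A.shape != (3, 4):
        raise ValueError("affine must be 3x4 (or 3x3)")
    M, t = A[:, :3], A[:, 3]
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("predicted affine is not invertible")
    Minv = np.linalg.inv(M)

    grid = np.indices(vol.shape).astype(float)  # native voxel coords p
    pts = grid.reshape(3, -1)
    if not displacement_before_affine and displacement is not None:
        d = np.asarray(displacement, dtype=float).reshape(3, -1)
        pts = pts + d
    src = Minv @ (pts - t[:, None])  # template coords
    if displacement_before_affine and displacement is not None:
        disp = np.asarray(displacement, dtype=float)
        # displacement sampled at the template-side coordinate
        d = np.stack(
            [map_coordinates(disp[k], src, order=order, mode="nearest") for k in range(3)]
        )
        src = src + d
    out = map_coordinates(vol, src, order=order, mode="constant", cval=0.0)
    return out.reshape(vol.shape)
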