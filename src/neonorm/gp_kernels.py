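"""Exact Gaussian process machinery for multi-output normative regression.

The model is an intrinsic co-regionalization model (ICM): a single input
kernel ``k(x, x')`` — the sum of a linear, a squared-exponential (RBF) and a
white-noise term — is shared across ``m`` outputs through a positive
semi-definite output-mixing matrix ``B = W Wᵀ + diag(κ)``, giving the joint
covariance ``K((x, i), (x', j)) = B_ij · k(x, x')``.

With outputs stacked output-major (all points of output 0, then output 1,
...), the training covariance is the Kronecker product ``B ⊗ K_x``.  All
likelihood, gradient and predictive computations below exploit this through
the eigendecompositions of ``B`` (m×m) and ``K_x`` (n×n), so a full
hyperparameter optimization costs O(n³) per iteration instead of O((nm)³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize

__all__ = [
    "KernelParams",
    "CoregionalizationParams",
    "MOGPFit",
    "NumericalError",
    "OptimizationError",
    "kernel_matrix",
    "icm_covariance",
    "icm_train_covariance",
    "log_marginal_likelihood",
    "optimize_hyperparameters",
    "predict",
]

#: smallest admissible joint covariance eigenvalue before jitter escalation
JITTER_LADDER = (1e-8, 1e-6, 1e-4)


class NumericalError(RuntimeError):
    """Joint covariance could not be factorized even at maximum jitter."""


class OptimizationError(RuntimeError):
    """All optimizer restarts failed; carries the best partial result."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class KernelParams:
    """Hyperparameters of the shared input kernel k = linear + RBF + white."""

    linear_variance: float = 1.0
    rbf_variance: float = 1.0
    rbf_lengthscale: float | np.ndarray = 1.0  # scalar (shared) or 3-vector (ARD)
    white_variance: float = 1e-2

    def __post_init__(self):
        ls = np.asarray(self.rbf_lengthscale, dtype=float)
        if np.any(ls <= 0):
            raise ValueError("rbf_lengthscale must be positive")
        if self.linear_variance < 0 or self.rbf_variance < 0:
            raise ValueError("kernel variances must be non-negative")
        if self.white_variance < 0:
            raise ValueError("white_variance must be non-negative")

    @property
    def is_ard(self) -> bool:
        return np.ndim(self.rbf_lengthscale) > 0


@dataclass
class CoregionalizationParams:
    """Output-mixing parameters: B = mixing_weights @ mixing_weights.T + diag(per_output_variance)."""

    mixing_weights: np.ndarray  # (m, R)
    per_output_variance: np.ndarray  # (m,)

    def __post_init__(self):
        self.mixing_weights = np.atleast_2d(np.asarray(self.mixing_weights, dtype=float))
        self.per_output_variance = np.asarray(self.per_output_variance, dtype=float)
        if self.per_output_variance.shape != (self.mixing_weights.shape[0],):
            raise ValueError("per_output_variance must have one entry per output")
        if np.any(self.per_output_variance < 0):
            raise ValueError("per_output_variance must be non-negative")

    @property
    def n_outputs(self) -> int:
        return self.mixing_weights.shape[0]

    @property
    def rank(self) -> int:
        return self.mixing_weights.shape[1]

    @property
    def B(self) -> np.ndarray:
        W = self.mixing_weights
        return W @ W.T + np.diag(self.per_output_variance)

    @classmethod
    def identity(cls, n_outputs: int) -> "CoregionalizationParams":
        return cls(np.zeros((n_outputs, 1)), np.ones(n_outputs))


def _check_finite(X, name="X"):
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def _scaled_sqdist(X1, X2, lengthscale):
    """Pairwise squared distances of lengthscale-scaled inputs."""
    ls = np.asarray(lengthscale, dtype=float)
    A = X1 / ls
    B = X2 / ls
    aa = np.sum(A * A, axis=1)
    bb = np.sum(B * B, axis=1)
    D = aa[:, None] + bb[None, :] - 2.0 * (A @ B.T)
    np.maximum(D, 0.0, out=D)
    return D


def kernel_matrix(params: KernelParams, X1, X2=None, include_white: bool = False):
    """Assemble k(X1, X2) = σ²_lin ⟨x, x'⟩ + σ²_rbf exp(−½‖(x−x')/ℓ‖²) (+ σ²_w δ).

    The white term is only meaningful on the training block (exact index
    match); requesting it on a cross-covariance is an error.
    """
    X1 = _check_finite(X1, "X1")
    same = X2 is None or X2 is X1
    X2a = X1 if same else _check_finite(X2, "X2")
    K = params.linear_variance * (X1 @ X2a.T)
    if params.rbf_variance > 0:
        K += params.rbf_variance * np.exp(-0.5 * _scaled_sqdist(X1, X2a, params.rbf_lengthscale))
    if include_white:
        if not same:
            raise ValueError("white term applies only to the training block, not cross-covariances")
        K[np.diag_indices_from(K)] += params.white_variance
    return K


def icm_covariance(
    kernel: KernelParams,
    coreg: CoregionalizationParams,
    X1,
    output_index1,
    X2=None,
    output_index2=None,
    include_white: bool = False,
):
    """Joint covariance over explicit (input, output) row pairs.

    Entry (r, c) is ``B[i_r, j_c] · k(x_r, x'_c)``.  With ``include_white``
    (same-row-set case only) the coupled noise ``B_ii σ²_w`` is added on the
    diagonal, i.e. on exact row matches.
    """
    i1 = np.asarray(output_index1, dtype=int)
    same = X2 is None or X2 is X1
    i2 = i1 if (same and output_index2 is None) else np.asarray(output_index2, dtype=int)
    m = coreg.n_outputs
    if np.any(i1 < 0) or np.any(i1 >= m) or np.any(i2 < 0) or np.any(i2 >= m):
        raise ValueError(f"output indices must lie in [0, {m})")
    B = coreg.B
    Kx = kernel_matrix(kernel, X1, X2, include_white=False)
    K = B[np.ix_(i1, i2)] * Kx
    if include_white:
        if not same:
            raise ValueError("white term applies only to the training block")
        K[np.diag_indices_from(K)] += kernel.white_variance * B[i1, i1]
    return K


def icm_train_covariance(
    kernel: KernelParams,
    coreg: CoregionalizationParams,
    X,
    noise_mode: str = "coupled",
    independent_noise=None,
):
    """Dense (n·m)×(n·m) training covariance, output-major: kron(B, K_x) + noise."""
    X = _check_finite(X)
    n = X.shape[0]
    Kx = kernel_matrix(kernel, X, include_white=False)
    K = np.kron(coreg.B, Kx)
    if noise_mode == "coupled":
        K += kernel.white_variance * np.kron(coreg.B, np.eye(n))
    elif noise_mode == "independent":
        noise = _independent_noise_vector(kernel, coreg, independent_noise)
        K += np.kron(np.diag(noise), np.eye(n))
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return K


def _independent_noise_vector(kernel, coreg, independent_noise):
    if independent_noise is None:
        return np.full(coreg.n_outputs, kernel.white_variance, dtype=float)
    v = np.asarray(independent_noise, dtype=float)
    if v.shape != (coreg.n_outputs,) or np.any(v <= 0):
        raise ValueError("independent_noise must be a positive vector, one entry per output")
    return v


# ---------------------------------------------------------------------------
# Kronecker-factorized Gaussian algebra
# ---------------------------------------------------------------------------


class _Factor:
    """Eigen-factorization of the joint training covariance.

    coupled:      K = B ⊗ (K_nw + σ²_w I)        = (U⊗V)(S⊗Λ)(U⊗V)ᵀ
    independent:  K = B ⊗ K_nw + diag(d) ⊗ I
                    = (D½⊗I)(Ũ⊗V)(S̃⊗Λ + I)(Ũ⊗V)ᵀ(D½⊗I)
    """

    __slots__ = ("V", "lam", "U", "s", "joint", "dhalf", "logdet", "n", "m")

    def __init__(self, V, lam, U, s, joint, dhalf, logdet):
        self.V, self.lam, self.U, self.s = V, lam, U, s
        self.joint, self.dhalf, self.logdet = joint, dhalf, logdet
        self.n, self.m = joint.shape

    def transform_Y(self, Y):
        """Return Ỹ = Vᵀ (Y D^{-1/2}) U in the factor's inner basis."""
        if self.dhalf is not None:
            Y = Y / self.dhalf
        return self.V.T @ Y @ self.U

    def alpha_matrix(self, Y):
        """mat(K⁻¹ y) as an (n, m) array."""
        A = self.V @ (self.transform_Y(Y) / self.joint) @ self.U.T
        if self.dhalf is not None:
            A = A / self.dhalf
        return A


def _factorize(kernel, coreg, X, noise_mode, independent_noise=None):
    Kx_nw = kernel_matrix(kernel, X, include_white=False)
    B = coreg.B
    if noise_mode == "coupled":
        Kx = Kx_nw + kernel.white_variance * np.eye(X.shape[0])
        dhalf = None
        for jitter in (0.0,) + JITTER_LADDER:
            lam, V = eigh(Kx + jitter * np.eye(Kx.shape[0]))
            s, U = eigh(B)
            joint = np.outer(lam, s)
            if joint.min() > 0:
                logdet = float(np.sum(np.log(joint)))
                return _Factor(V, lam, U, s, joint, dhalf, logdet)
        raise NumericalError(
            f"joint covariance not positive definite at max jitter "
            f"{JITTER_LADDER[-1]:g} (min eigenvalue {joint.min():.3g})"
        )
    elif noise_mode == "independent":
        d = _independent_noise_vector(kernel, coreg, independent_noise)
        dhalf = np.sqrt(d)
        Bt = B / np.outer(dhalf, dhalf)
        s, U = eigh(Bt)
        for jitter in (0.0,) + JITTER_LADDER:
            lam, V = eigh(Kx_nw + jitter * np.eye(Kx_nw.shape[0]))
            joint = np.outer(lam, s) + 1.0
            if joint.min() > 0:
                logdet = float(Kx_nw.shape[0] * np.sum(np.log(d)) + np.sum(np.log(joint)))
                return _Factor(V, lam, U, s, joint, dhalf, logdet)
        raise NumericalError("joint covariance not positive definite at max jitter")
    raise ValueError(f"unknown noise_mode {noise_mode!r}")


def log_marginal_likelihood(
    X,
    Y,
    kernel: KernelParams,
    coreg: CoregionalizationParams | None = None,
    noise_mode: str = "coupled",
    independent_noise=None,
) -> float:
    """−½ yᵀK⁻¹y − ½ log|K| − (nm/2) log 2π on the output-major stacked vector."""
    X = _check_finite(X)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.reshape(X.shape[0], -1)
    if coreg is None:
        coreg = CoregionalizationParams.identity(Y.shape[1])
    fac = _factorize(kernel, coreg, X, noise_mode, independent_noise)
    Yt = fac.transform_Y(Y)
    quad = float(np.sum(Yt * Yt / fac.joint))
    n, m = Y.shape
    return -0.5 * quad - 0.5 * fac.logdet - 0.5 * n * m * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Fitted model and prediction
# ---------------------------------------------------------------------------


@dataclass
class MOGPFit:
    """A finalized per-voxel (or per-element) fit.

    Inputs are stored standardized; ``input_loc``/``input_scale`` map raw
    covariates into model space and ``output_means``/``output_scales`` map
    standardized predictions back to data units.
    """

    kernel: KernelParams
    coreg: CoregionalizationParams
    X: np.ndarray  # (n, p) standardized training inputs
    Y: np.ndarray  # (n, m) standardized training outputs
    input_loc: np.ndarray
    input_scale: np.ndarray
    output_means: np.ndarray
    output_scales: np.ndarray
    noise_mode: str = "coupled"
    lml: float = np.nan
    _factor: _Factor | None = field(default=None, repr=False, compare=False)
    _alpha: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[1]

    def finalize(self) -> "MOGPFit":
        self._factor = _factorize(self.kernel, self.coreg, self.X, self.noise_mode)
        self._alpha = self._factor.alpha_matrix(self.Y)
        return self

    # -- serialization (JSON-safe plain types) ------------------------------

    def to_dict(self) -> dict:
        return {
            "kernel": {
                "linear_variance": float(self.kernel.linear_variance),
                "rbf_variance": float(self.kernel.rbf_variance),
                "rbf_lengthscale": np.asarray(self.kernel.rbf_lengthscale).tolist(),
                "white_variance": float(self.kernel.white_variance),
            },
            "coreg": {
                "mixing_weights": self.coreg.mixing_weights.tolist(),
                "per_output_variance": self.coreg.per_output_variance.tolist(),
            },
            "X": self.X.tolist(),
            "Y": self.Y.tolist(),
            "input_loc": self.input_loc.tolist(),
            "input_scale": self.input_scale.tolist(),
            "output_means": self.output_means.tolist(),
            "output_scales": self.output_scales.tolist(),
            "noise_mode": self.noise_mode,
            "lml": float(self.lml),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MOGPFit":
        ls = d["kernel"]["rbf_lengthscale"]
        kernel = KernelParams(
            d["kernel"]["linear_variance"],
            d["kernel"]["rbf_variance"],
            np.asarray(ls) if isinstance(ls, list) else float(ls),
            d["kernel"]["white_variance"],
        )
        coreg = CoregionalizationParams(
            np.asarray(d["coreg"]["mixing_weights"]),
            np.asarray(d["coreg"]["per_output_variance"]),
        )
        fit = cls(
            kernel=kernel,
            coreg=coreg,
            X=np.asarray(d["X"], dtype=float),
            Y=np.asarray(d["Y"], dtype=float),
            input_loc=np.asarray(d["input_loc"], dtype=float),
            input_scale=np.asarray(d["input_scale"], dtype=float),
            output_means=np.asarray(d["output_means"], dtype=float),
            output_scales=np.asarray(d["output_scales"], dtype=float),
            noise_mode=d["noise_mode"],
            lml=d["lml"],
        )
        return fit.finalize()


def standardize_inputs(X_raw, loc=None, scale=None):
    """Z-score continuous covariate columns; binary columns pass through.

    A column is treated as binary (left unscaled) when its values are a
    subset of {0, 1}.  Returns (X_std, loc, scale).
    """
    X_raw = _check_finite(X_raw, "inputs")
    if loc is None:
        loc = np.zeros(X_raw.shape[1])
        scale = np.ones(X_raw.shape[1])
        for j in range(X_raw.shape[1]):
            col = X_raw[:, j]
            if np.all(np.isin(col, (0.0, 1.0))):
                continue
            loc[j] = col.mean()
            sd = col.std()
            scale[j] = sd if sd > 0 else 1.0
    return (X_raw - loc) / scale, loc, scale


def _pack(kernel, coreg, fit_coreg, ard):
    parts = [
        np.log(max(kernel.linear_variance, 1e-12)),
        np.log(max(kernel.rbf_variance, 1e-12)),
    ]
    ls = np.atleast_1d(np.asarray(kernel.rbf_lengthscale, dtype=float))
    parts.extend(np.log(ls))
    parts.append(np.log(max(kernel.white_variance, 1e-12)))
    theta = np.array(parts)
    if fit_coreg:
        theta = np.concatenate(
            [theta, coreg.mixing_weights.ravel(), np.log(np.maximum(coreg.per_output_variance, 1e-12))]
        )
    return theta


def _unpack(theta, m, rank, fit_coreg, ard, n_inputs):
    kdim = n_inputs if ard else 1
    lv, rv = np.exp(theta[0]), np.exp(theta[1])
    ls = np.exp(theta[2 : 2 + kdim])
    wv = np.exp(theta[2 + kdim])
    kernel = KernelParams(lv, rv, ls if ard else float(ls[0]), wv)
    off = 3 + kdim
    if fit_coreg:
        W = theta[off : off + m * rank].reshape(m, rank)
        kappa = np.exp(theta[off + m * rank : off + m * rank + m])
        coreg = CoregionalizationParams(W, kappa)
    else:
        coreg = CoregionalizationParams.identity(m)
    return kernel, coreg


def _neg_lml_and_grad(theta, X, Y, m, rank, fit_coreg, ard, sqd, lin_gram):
    """Objective for the coupled-noise model with analytic gradients.

    Gradient identities (α = K⁻¹y, K = B ⊗ K_x):
      ∂LML/∂θ = ½ αᵀ(∂K)α − ½ tr(K⁻¹ ∂K)
      tr(K⁻¹ (B ⊗ dK_x)) = m · Σᵢ (Vᵀ dK_x V)ᵢᵢ / λᵢ
      tr(K⁻¹ (dB ⊗ K_x)) = n · tr(B⁻¹ dB)
    """
    n = X.shape[0]
    kernel, coreg = _unpack(theta, m, rank, fit_coreg, ard, X.shape[1])
    B = coreg.B

    ls = np.atleast_1d(np.asarray(kernel.rbf_lengthscale, dtype=float))
    if ard:
        D = sum(sqd[k] / ls[k] ** 2 for k in range(len(sqd)))
    else:
        D = sqd[0] / ls[0] ** 2
    E = np.exp(-0.5 * D)
    Kx = kernel.linear_variance * lin_gram + kernel.rbf_variance * E
    Kx[np.diag_indices_from(Kx)] += kernel.white_variance

    lam, V = eigh(Kx)
    s, U = eigh(B)
    lam = np.maximum(lam, 1e-12)
    s = np.maximum(s, 1e-12)
    joint = np.outer(lam, s)

    Yt = V.T @ Y @ U
    Wt = Yt / joint
    quad = float(np.sum(Yt * Wt))
    logdet = float(np.sum(np.log(joint)))
    lml = -0.5 * quad - 0.5 * logdet - 0.5 * n * m * np.log(2.0 * np.pi)

    A = V @ Wt @ U.T  # mat(alpha), (n, m)
    AB = A @ B
    inv_lam_V = V / lam  # V Λ⁻¹ columns, for diag(Vᵀ dKx V)/λ sums

    grads = np.empty_like(theta)

    def kernel_grad(dKx):
        t1 = float(np.sum(AB * (dKx @ A)))
        t2 = m * float(np.einsum("ij,ij->", inv_lam_V, dKx @ V))
        return 0.5 * t1 - 0.5 * t2

    # log-variance params: chain rule multiplies by the variance itself
    grads[0] = kernel_grad(lin_gram) * kernel.linear_variance
    grads[1] = kernel_grad(E) * kernel.rbf_variance
    kdim = X.shape[1] if ard else 1
    for k in range(kdim):
        Dk = (sqd[k] if ard else sqd[0]) / ls[k] ** 2
        # ∂K/∂log ℓ_k = σ²_rbf E ∘ (r²_k/ℓ²_k)
        grads[2 + k] = kernel_grad(kernel.rbf_variance * E * Dk)
    # white: dKx = I
    t1 = float(np.sum(AB * A))
    t2 = m * float(np.sum(1.0 / lam))
    grads[2 + kdim] = (0.5 * t1 - 0.5 * t2) * kernel.white_variance

    if fit_coreg:
        off = 3 + kdim
        M = A.T @ Kx @ A  # (m, m)
        Binv = (U / s) @ U.T
        Wm = coreg.mixing_weights
        gW = (M @ Wm) - n * (Binv @ Wm)
        grads[off : off + m * rank] = gW.ravel()
        gk = (0.5 * np.diag(M) - 0.5 * n * np.diag(Binv)) * coreg.per_output_variance
        grads[off + m * rank : off + m * rank + m] = gk

    return -lml, -grads


def optimize_hyperparameters(
    X_raw,
    Y_raw,
    init: tuple[KernelParams, CoregionalizationParams] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    rank: int = 2,
    noise_mode: str = "coupled",
    fit_coreg: bool = True,
    ard: bool = False,
    maxiter: int = 200,
    standardize: bool = True,
) -> MOGPFit:
    """Maximize log marginal likelihood over kernel + coregionalization params.

    Quasi-Newton (L-BFGS-B) on log-transformed positive parameters; best of
    ``n_restarts`` seeded restarts kept (ties broken by lowest restart
    index).  Raises OptimizationError carrying the best partial result if
    every restart fails.
    """
    X_raw = _check_finite(X_raw, "inputs")
    Y_raw = np.atleast_2d(np.asarray(Y_raw, dtype=float))
    if Y_raw.shape[0] != X_raw.shape[0]:
        raise ValueError("X and Y must have matching first dimension")
    if X_raw.shape[0] < 3:
        raise ValueError("need at least 3 training points")
    n, m = Y_raw.shape

    if standardize:
        X, in_loc, in_scale = standardize_inputs(X_raw)
        out_means = Y_raw.mean(axis=0)
        out_sd = Y_raw.std(axis=0)
        out_scales = np.where(out_sd > 0, out_sd, 1.0)
        Y = (Y_raw - out_means) / out_scales
    else:
        X, in_loc, in_scale = X_raw, np.zeros(X_raw.shape[1]), np.ones(X_raw.shape[1])
        out_means, out_scales = np.zeros(m), np.ones(m)
        Y = Y_raw

    if init is None:
        kernel0 = KernelParams(0.2, 0.5, np.ones(X.shape[1]) if ard else 1.0, 0.3)
        if fit_coreg:
            W0 = np.full((m, rank), np.sqrt(0.5 / rank))
            coreg0 = CoregionalizationParams(W0, np.full(m, 0.5))
        else:
            coreg0 = CoregionalizationParams.identity(m)
    else:
        kernel0, coreg0 = init
        if fit_coreg:
            rank = coreg0.rank

    theta0 = _pack(kernel0, coreg0, fit_coreg, ard)
    kdim = X.shape[1] if ard else 1
    bounds = [(-16.0, 8.0)] * (3 + kdim)
    if fit_coreg:
        bounds += [(-8.0, 8.0)] * (m * rank) + [(-16.0, 8.0)] * m

    sqd_dims = tuple((X[:, k, None] - X[None, :, k]) ** 2 for k in range(X.shape[1]))
    # isotropic case: one shared lengthscale over the summed squared distance
    sqd = sqd_dims if ard else (sum(sqd_dims),)
    lin_gram = X @ X.T
    rng = np.random.default_rng(seed)

    use_grad = noise_mode == "coupled"

    def objective(theta):
        if use_grad:
            return _neg_lml_and_grad(theta, X, Y, m, rank, fit_coreg, ard, sqd, lin_gram)
        kernel, coreg = _unpack(theta, m, rank, fit_coreg, ard, X.shape[1])
        return -log_marginal_likelihood(X, Y, kernel, coreg, noise_mode)

    best = None
    best_lml = -np.inf
    failures = []
    for r in range(max(1, n_restarts)):
        theta = theta0 if r == 0 else theta0 + rng.normal(0.0, 1.0, size=theta0.shape)
        try:
            res = minimize(
                objective,
                theta,
                jac=use_grad,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter},
            )
            lml = -float(res.fun)
        except (NumericalError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            failures.append(exc)
            continue
        if np.isfinite(lml) and lml > best_lml:
            best_lml = lml
            best = res.x
    if best is None:
        raise OptimizationError(f"all {n_restarts} restarts failed: {failures}", best=None)

    kernel, coreg = _unpack(best, m, rank, fit_coreg, ard, X.shape[1])
    fit = MOGPFit(
        kernel=kernel,
        coreg=coreg,
        X=X,
        Y=Y,
        input_loc=in_loc,
        input_scale=in_scale,
        output_means=out_means,
        output_scales=out_scales,
        noise_mode=noise_mode,
        lml=best_lml,
    )
    return fit.finalize()


def predict(fit: MOGPFit, X_new_raw, output_index=None, include_noise: bool = True):
    """Posterior predictive mean and variance at new covariates.

    Returns (mean, variance), each of shape (m_new,) when ``output_index``
    is an int, or (m_new, n_outputs) when None.  ``include_noise`` adds each
    output's noise share (``B_ii σ²_w`` in the coupled model) — this is the
    variant used for deviation Z-scores.  Values are de-standardized back to
    data units.
    """
    if fit._factor is None:
        fit.finalize()
    Xn = (np.atleast_2d(np.asarray(X_new_raw, dtype=float)) - fit.input_loc) / fit.input_scale
    fac = fit._factor
    B = fit.coreg.B
    Kstar = kernel_matrix(fit.kernel, fit.X, Xn, include_white=False)  # (n, m_new)
    mean_std = Kstar.T @ fit._alpha @ B  # (m_new, m)

    T2 = (fac.V.T @ Kstar) ** 2  # (n, m_new)
    if fac.dhalf is None:
        G = fac.U.T @ B  # (m, m) columns per output
    else:
        G = fac.U.T @ (B / fac.dhalf[:, None])
    inner = (1.0 / fac.joint) @ (G**2)  # (n, m)
    q = T2.T @ inner  # (m_new, m)

    kss = fit.kernel.linear_variance * np.sum(Xn * Xn, axis=1) + fit.kernel.rbf_variance
    var_std = np.outer(kss, np.diag(B)) - q
    if include_noise:
        if fit.noise_mode == "coupled":
            var_std = var_std + fit.kernel.white_variance * np.diag(B)[None, :]
        else:
            var_std = var_std + fit.kernel.white_variance
    np.maximum(var_std, 1e-12, out=var_std)

    mean = mean_std * fit.output_scales + fit.output_means
    var = var_std * fit.output_scales**2
    if output_index is not None:
        return mean[:, output_index], var[:, output_index]
    return mean, var
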