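"""Mean and covariance structure of the cell type-specific mixed model.

For CTP data, individual ``i``'s length-``C`` pseudobulk vector is modelled
as ``y_i = beta + alpha_i + Gamma_i + delta_i`` with

* ``alpha_i ~ N(0, sigma_alpha2)`` — interindividual variance shared across
  cell types,
* ``Gamma_i ~ N(0, V)`` — cell type-specific interindividual (co)variance,
* ``delta_ic ~ N(0, nu_ic)`` — known measurement noise from averaging cells,

so the per-individual covariance block is
``sigma_alpha2 * J_C + V + diag(nu_i)``.  For OP data each individual
contributes a scalar with variance ``sigma_alpha2 + P_i' V P_i + nu_i`` and
mean ``P_i' beta``.  Four nested structures of ``V`` are supported:

* ``hom``  — V = 0 (all interindividual variance shared),
* ``iid``  — V = v * I (equal cell type-specific variances),
* ``free`` — V diagonal (independent cell type-specific variances),
* ``full`` — V an arbitrary symmetric matrix; ``sigma_alpha2`` is fixed to
  zero because passing a constant between ``sigma_alpha2`` and ``V + c*J``
  leaves the likelihood unchanged.

The log-likelihood and restricted log-likelihood have a fast path that
exploits block-diagonality (cost ``O(N C^3)``), extended to a blocked extra
random effect (e.g. experimental batch) by a Woodbury low-rank update.  A
naive dense multivariate-normal construction is kept as the contract: the
fast path must agree with it to numerical tolerance.

Variance components are allowed to be negative during fitting to avoid
boundary bias; a parameter vector is only rejected when the *total* implied
covariance stops being positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .pseudobulk import PseudobulkGene

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "SingularCovarianceError",
    "n_variance_params",
    "n_model_params",
    "pack",
    "unpack",
    "ctp_covariance",
    "op_covariance",
    "gaussian_loglik",
    "restricted_loglik",
]

STRUCTURES = ("hom", "iid", "free", "full")
MODES = ("ctp", "op")

_LOG2PI = float(np.log(2.0 * np.pi))
MIN_EIGENVALUE = 1e-10  # total covariance must clear this to be admissible


class SingularCovarianceError(ValueError):
    """Raised when a parameter set implies a non-positive-definite covariance."""


@dataclass
class ModelSpec:
    """Which covariance structure and data mode to fit.

    Parameters
    ----------
    structure
        One of ``hom``, ``iid``, ``free``, ``full``.
    mode
        ``ctp`` (individual x cell type vectors) or ``op`` (one scalar per
        individual).
    covariates
        Optional (N, K) individual-level fixed-effect design, added to the
        cell-type intercepts.  Shared across an individual's cell types in
        CTP mode.
    random_blocks
        Optional length-N block labels (e.g. experimental batch) fitted as
        one extra variance component shared by all observations in a block.
    """

    structure: str = "free"
    mode: str = "ctp"
    covariates: np.ndarray | None = None
    random_blocks: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def has_random_blocks(self) -> bool:
        return self.random_blocks is not None


@dataclass
class VarianceComponents:
    """Parameter vector of the mixed model.

    ``beta`` stacks the C cell-type means followed by covariate
    coefficients.  ``V`` is the C x C cell type-specific covariance
    (diagonal under ``free``, scalar multiple of I under ``iid``, zero under
    ``hom``).  ``batch_var`` is the variance of the optional blocked random
    effect.
    """

    beta: np.ndarray
    sigma_alpha2: float
    V: np.ndarray
    batch_var: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[0] != self.V.shape[1]:
            raise ValueError("V must be square")
        if not np.allclose(self.V, self.V.T, atol=1e-12):
            raise ValueError("V must be symmetric")


def n_variance_params(spec: ModelSpec, C: int) -> int:
    """Number of free variance parameters (excluding beta)."""
    base = {"hom": 1, "iid": 2, "free": C + 1, "full": C * (C + 1) // 2}[spec.structure]
    return base + (1 if spec.has_random_blocks else 0)


def n_model_params(spec: ModelSpec, C: int) -> int:
    """Total parameter count R (beta plus variance components).

    For the no-covariate Free model this is ``2C + 1``, the count used in
    the Wald-test denominator degrees of freedom ``N - R``.
    """
    return C + spec.n_covariates + n_variance_params(spec, C)


def pack(spec: ModelSpec, params: VarianceComponents) -> np.ndarray:
    """Flatten variance components into the optimizer's parameter vector."""
    s = spec.structure
    if s == "hom":
        theta = [params.sigma_alpha2]
    elif s == "iid":
        theta = [params.sigma_alpha2, float(params.V[0, 0])]
    elif s == "free":
        theta = [params.sigma_alpha2, *np.diag(params.V)]
    else:  # full: sigma_alpha2 pinned at 0
        C = params.V.shape[0]
        iu = np.triu_indices(C)
        theta = list(params.V[iu])
    if spec.has_random_blocks:
        theta.append(params.batch_var)
    return np.asarray(theta, dtype=float)


def unpack(spec: ModelSpec, theta: np.ndarray, C: int,
           beta: np.ndarray | None = None) -> VarianceComponents:
    """Inverse of :func:`pack`."""
    theta = np.asarray(theta, dtype=float)
    batch_var = float(theta[-1]) if spec.has_random_blocks else 0.0
    core = theta[:-1] if spec.has_random_blocks else theta
    s = spec.structure
    if s == "hom":
        sa2, V = float(core[0]), np.zeros((C, C))
    elif s == "iid":
        sa2, V = float(core[0]), float(core[1]) * np.eye(C)
    elif s == "free":
        sa2, V = float(core[0]), np.diag(core[1:])
    else:
        sa2 = 0.0
        V = np.zeros((C, C))
        iu = np.triu_indices(C)
        V[iu] = core
        V = V + V.T - np.diag(np.diag(V))
    if beta is None:
        beta = np.zeros(C + spec.n_covariates)
    return VarianceComponents(beta=beta, sigma_alpha2=sa2, V=V, batch_var=batch_var)


# ---------------------------------------------------------------------------
# design and covariance construction
# ---------------------------------------------------------------------------

def _require_complete(pb: PseudobulkGene) -> None:
    if np.isnan(pb.y_ct).any():
        raise ValueError("pseudobulk has missing CTP entries; impute before modelling")


def ctp_design(spec: ModelSpec, pb: PseudobulkGene) -> np.ndarray:
    """Fixed-effect design as (N, C, C+K) blocks: cell-type intercepts
    followed by individual-level covariates repeated across cell types."""
    N, C = pb.y_ct.shape
    X = np.broadcast_to(np.eye(C), (N, C, C))
    if spec.covariates is not None:
        W = np.repeat(spec.covariates[:, None, :], C, axis=1)  # (N, C, K)
        X = np.concatenate([X, W], axis=2)
    return np.ascontiguousarray(X)


def op_design(spec: ModelSpec, pb: PseudobulkGene) -> np.ndarray:
    """Fixed-effect design as (N, C+K): proportion-weighted cell-type means
    plus covariates."""
    X = pb.P
    if spec.covariates is not None:
        X = np.hstack([X, spec.covariates])
    return np.ascontiguousarray(X)


def _ctp_blocks(spec: ModelSpec, params: VarianceComponents,
                pb: PseudobulkGene) -> np.ndarray:
    """Per-individual C x C covariance blocks, shape (N, C, C)."""
    N, C = pb.nu_ct.shape
    base = params.sigma_alpha2 * np.ones((C, C)) + params.V
    blocks = np.broadcast_to(base, (N, C, C)).copy()
    idx = np.arange(C)
    blocks[:, idx, idx] += pb.nu_ct
    return blocks


def _op_variances(spec: ModelSpec, params: VarianceComponents,
                  pb: PseudobulkGene) -> np.ndarray:
    quad = np.einsum("ic,cd,id->i", pb.P, params.V, pb.P)
    return params.sigma_alpha2 + quad + pb.nu_op


def _block_indicator(labels: np.ndarray, reps: int) -> np.ndarray:
    """(n_obs, B) 0/1 indicator; each individual's label repeated `reps`
    times for CTP stacking."""
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(uniq)))
    Z[np.arange(len(labels)), inv] = 1.0
    if reps > 1:
        Z = np.repeat(Z, reps, axis=0)
    return Z


def ctp_covariance(spec: ModelSpec, params: VarianceComponents,
                   pb: PseudobulkGene) -> tuple[np.ndarray, np.ndarray]:
    """Dense NC x NC covariance and length-NC mean of the CTP model.

    Observations are stacked individual-major (individual i's C cell types
    contiguous).  This is the naive reference construction; the fast
    likelihood path must agree with it.
    """
    _require_complete(pb)
    N, C = pb.y_ct.shape
    blocks = _ctp_blocks(spec, params, pb)
    Sigma = linalg.block_diag(*blocks)
    if spec.has_random_blocks:
        Z = _block_indicator(spec.random_blocks, reps=C)
        Sigma = Sigma + params.batch_var * Z @ Z.T
    X = ctp_design(spec, pb).reshape(N * C, -1)
    mean = X @ params.beta
    _check_pd(Sigma, spec, params)
    return Sigma, mean


def op_covariance(spec: ModelSpec, params: VarianceComponents,
                  pb: PseudobulkGene) -> tuple[np.ndarray, np.ndarray]:
    """Dense N x N covariance and length-N mean of the OP model."""
    Sigma = np.diag(_op_variances(spec, params, pb))
    if spec.has_random_blocks:
        Z = _block_indicator(spec.random_blocks, reps=1)
        Sigma = Sigma + params.batch_var * Z @ Z.T
    mean = op_design(spec, pb) @ params.beta
    _check_pd(Sigma, spec, params)
    return Sigma, mean


def _check_pd(Sigma: np.ndarray, spec: ModelSpec,
              params: VarianceComponents) -> None:
    w = np.linalg.eigvalsh(Sigma)
    if w.min() <= MIN_EIGENVALUE:
        raise SingularCovarianceError(
            f"total covariance not positive definite (min eigenvalue "
            f"{w.min():.3e}) for structure={spec.structure!r}, "
            f"sigma_alpha2={params.sigma_alpha2:.4g}, "
            f"V diag={np.diag(params.V)}, batch_var={params.batch_var:.4g}"
        )


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

@dataclass
class _GLSParts:
    """Sufficient pieces of the GLS normal equations under the model
    covariance: A = X' Sigma^-1 X, b = X' Sigma^-1 y, quad = y' Sigma^-1 y,
    logdet = log|Sigma|."""

    A: np.ndarray
    b: np.ndarray
    quad: float
    logdet: float
    n_obs: int
    logdet_xtx: float = 0.0


def _gls_parts_fast(spec: ModelSpec, params: VarianceComponents,
                    pb: PseudobulkGene) -> _GLSParts:
    """Blockwise accumulation of the GLS parts; O(N C^3) without random
    blocks, plus an O(B^3) Woodbury correction with them."""
    if spec.mode == "ctp":
        _require_complete(pb)
        blocks = _ctp_blocks(spec, params, pb)  # (N, C, C)
        N, C = pb.y_ct.shape
        X = ctp_design(spec, pb)  # (N, C, p)
        y = pb.y_ct[:, :, None]  # (N, C, 1)
        try:
            L = np.linalg.cholesky(blocks)
        except np.linalg.LinAlgError as e:
            raise SingularCovarianceError(
                f"per-individual covariance block not positive definite for "
                f"structure={spec.structure!r}, "
                f"sigma_alpha2={params.sigma_alpha2:.4g}, "
                f"V diag={np.diag(params.V)}"
            ) from e
        diag = np.diagonal(L, axis1=1, axis2=2)
        if diag.min() <= np.sqrt(MIN_EIGENVALUE):
            raise SingularCovarianceError(
                "per-individual covariance block numerically singular"
            )
        logdet = float(2.0 * np.log(diag).sum())
        rhs = np.concatenate([X, y], axis=2)  # (N, C, p+1)
        sol = np.linalg.solve(blocks, rhs)  # Sigma_i^-1 [X_i y_i]
        WX, Wy = sol[:, :, :-1], sol[:, :, -1:]
        A = np.einsum("icp,icq->pq", X, WX)
        b = np.einsum("icp,ic->p", X, Wy[:, :, 0])
        quad = float(np.einsum("ic,ic->", pb.y_ct, Wy[:, :, 0]))
        n_obs = N * C
        if spec.has_random_blocks:
            Z = _block_indicator(spec.random_blocks, reps=C).reshape(N, C, -1)
            WZ = np.linalg.solve(blocks, Z)
            A, b, quad, logdet = _woodbury_correct(
                params.batch_var, Z, WZ, WX, Wy[:, :, 0],
                A, b, quad, logdet)
        return _GLSParts(A=A, b=b, quad=quad, logdet=logdet, n_obs=n_obs,
                         logdet_xtx=_logdet_xtx(X))

    # OP mode: diagonal base covariance
    var = _op_variances(spec, params, pb)
    if var.min() <= MIN_EIGENVALUE:
        raise SingularCovarianceError(
            f"total OP variance not positive for structure={spec.structure!r}, "
            f"sigma_alpha2={params.sigma_alpha2:.4g}, V diag={np.diag(params.V)}"
        )
    X = op_design(spec, pb)
    y = pb.y_op
    w = 1.0 / var
    A = X.T @ (X * w[:, None])
    b = X.T @ (y * w)
    quad = float(y @ (y * w))
    logdet = float(np.log(var).sum())
    if spec.has_random_blocks:
        N = len(y)
        Z = _block_indicator(spec.random_blocks, reps=1).reshape(N, 1, -1)
        Xb = X.reshape(N, 1, -1)
        WZ = Z * w[:, None, None]
        WX = Xb * w[:, None, None]
        Wy = (y * w).reshape(N, 1)
        A, b, quad, logdet = _woodbury_correct(
            params.batch_var, Z, WZ, WX, Wy, A, b, quad, logdet)
    return _GLSParts(A=A, b=b, quad=quad, logdet=logdet, n_obs=len(y),
                     logdet_xtx=_logdet_xtx(X[:, None, :]))


def _woodbury_correct(batch_var, Z, WZ, WX, Wy, A, b, quad, logdet):
    """Rank-B update for Sigma + batch_var * Z Z'.

    Given blockwise pieces under the base covariance W = Sigma_base^-1,
    corrects A, b, quad and logdet via the Woodbury identity
    (Sigma + v Z Z')^-1 = W - W Z (I/v + Z'WZ)^-1 Z' W.
    """
    if batch_var == 0:
        return A, b, quad, logdet
    B = Z.shape[-1]
    ZtWZ = np.einsum("icb,icd->bd", Z, WZ)
    ZtWX = np.einsum("icb,icp->bp", Z, WX)
    ZtWy = np.einsum("icb,ic->b", Z, Wy)
    # (Sigma + v Z Z')^-1 = W - v W Z M^-1 Z' W with M = I + v Z'WZ;
    # this form stays valid for negative v as long as M is well-conditioned.
    cap = np.eye(B) + batch_var * ZtWZ
    sign, cap_logdet = np.linalg.slogdet(cap)
    if sign <= 0:
        raise SingularCovarianceError(
            f"batch capacitance matrix not positive definite "
            f"(batch_var={batch_var:.4g})")
    cap_inv_ZtWX = np.linalg.solve(cap, ZtWX)
    cap_inv_ZtWy = np.linalg.solve(cap, ZtWy)
    A = A - batch_var * ZtWX.T @ cap_inv_ZtWX
    b = b - batch_var * ZtWX.T @ cap_inv_ZtWy
    quad = quad - batch_var * float(ZtWy @ cap_inv_ZtWy)
    logdet = logdet + float(cap_logdet)
    return A, b, quad, logdet


def _gls_parts_dense(spec: ModelSpec, params: VarianceComponents,
                     pb: PseudobulkGene) -> _GLSParts:
    """Reference construction from the dense covariance matrix."""
    if spec.mode == "ctp":
        Sigma, _ = ctp_covariance(spec, params, pb)
        N, C = pb.y_ct.shape
        X = ctp_design(spec, pb).reshape(N * C, -1)
        y = pb.y_ct.reshape(-1)
    else:
        Sigma, _ = op_covariance(spec, params, pb)
        X = op_design(spec, pb)
        y = pb.y_op
    cf = linalg.cho_factor(Sigma)
    logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
    WX = linalg.cho_solve(cf, X)
    Wy = linalg.cho_solve(cf, y)
    return _GLSParts(A=X.T @ WX, b=X.T @ Wy, quad=float(y @ Wy),
                     logdet=logdet, n_obs=len(y),
                     logdet_xtx=_logdet_xtx(X.reshape(len(y), 1, -1)))


def _logdet_xtx(X: np.ndarray) -> float:
    """log|X'X| over (N, C, p) design blocks (parameter-free REML
    normalizer making the restricted likelihood invariant to full-rank
    reparameterizations of the fixed-effect design)."""
    XtX = np.einsum("icp,icq->pq", X, X)
    sign, val = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise SingularCovarianceError("fixed-effect design X'X is singular")
    return float(val)


def _parts(spec, params, pb, method):
    if method == "fast":
        return _gls_parts_fast(spec, params, pb)
    if method == "dense":
        return _gls_parts_dense(spec, params, pb)
    raise ValueError(f"unknown likelihood method {method!r}")


def gaussian_loglik(spec: ModelSpec, params: VarianceComponents,
                    pb: PseudobulkGene, method: str = "fast",
                    profile_beta: bool = False) -> float:
    """Multivariate-normal log-likelihood of the pseudobulk data.

    With ``profile_beta`` the fixed effects are replaced by their GLS
    estimate under the given variance components (the profiled likelihood
    maximized by ML).
    """
    parts = _parts(spec, params, pb, method)
    if profile_beta:
        beta = np.linalg.solve(parts.A, parts.b)
    else:
        beta = params.beta
    rss = parts.quad - 2.0 * beta @ parts.b + beta @ parts.A @ beta
    return -0.5 * (parts.n_obs * _LOG2PI + parts.logdet + rss)


def restricted_loglik(spec: ModelSpec, params: VarianceComponents,
                      pb: PseudobulkGene, method: str = "fast") -> float:
    """REML log-likelihood (fixed effects residualized out).

    Uses the standard form
    ``-0.5 [ (n-K) log 2pi + log|Sigma| + log|X'Sigma^-1 X| + y'Py ]``
    with ``P`` the REML projection; invariant to any full-rank
    reparameterization of the fixed-effect design.
    """
    parts = _parts(spec, params, pb, method)
    K = parts.A.shape[0]
    sign, logdet_A = np.linalg.slogdet(parts.A)
    if sign <= 0:
        raise SingularCovarianceError("X' Sigma^-1 X is singular")
    beta = np.linalg.solve(parts.A, parts.b)
    yPy = parts.quad - parts.b @ beta
    return -0.5 * ((parts.n_obs - K) * _LOG2PI + parts.logdet + logdet_A
                   - parts.logdet_xtx + yPy)


def gls_solution(spec: ModelSpec, params: VarianceComponents,
                 pb: PseudobulkGene, method: str = "fast"
                 ) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed-effect estimate and its model-based covariance
    ``(X' Sigma^-1 X)^-1`` under the given variance components."""
    parts = _parts(spec, params, pb, method)
    cov = np.linalg.inv(parts.A)
    return cov @ parts.b, cov
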