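"""Fitting variance components by ML, REML, and Haseman-Elston regression.

Likelihood methods maximize the (restricted) Gaussian log-likelihood with
BFGS, rerunning up to ``n_restarts`` random restarts when the initial
attempt fails (optimizer error, non-finite objective, or an inadmissible
covariance at the optimum).  Negative variance components are permitted to
avoid boundary bias; only the total implied covariance must stay positive
definite.  Haseman-Elston (HE) is a closed-form method-of-moments fit:
covariate-residualized second moments, with the known noise ``nu``
subtracted, are regressed onto the covariance design of each component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import model as mdl
from .model import (
    ModelSpec,
    PseudobulkGene,
    SingularCovarianceError,
    VarianceComponents,
)

__all__ = ["FitResult", "fit_ml", "fit_reml", "fit_he", "fit", "gls_beta"]

_GRAD_TOL = 1e-6
_MAX_ITER = 500


@dataclass
class FitResult:
    """Outcome of a variance-component fit."""

    params: VarianceComponents
    objective: float  # final (restricted) log-likelihood, or -moment loss
    converged: bool
    n_restarts_used: int
    method: str  # 'ml' | 'reml' | 'he'
    spec: ModelSpec
    message: str = ""

    def to_record(self) -> dict:
        """Flat JSON-serializable summary."""
        return {
            "method": self.method,
            "structure": self.spec.structure,
            "mode": self.spec.mode,
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "objective": float(self.objective),
            "beta": [float(v) for v in self.params.beta],
            "sigma_alpha2": float(self.params.sigma_alpha2),
            "V": [[float(v) for v in row] for row in self.params.V],
            "batch_var": float(self.params.batch_var),
        }


def _objective(spec: ModelSpec, pb: PseudobulkGene, method: str):
    """Negative (restricted/profiled) log-likelihood as a function of the
    packed variance parameters.  Inadmissible parameter vectors map to a
    large finite penalty so line searches can back off."""
    C = pb.n_cell_types

    def f(theta: np.ndarray) -> float:
        params = mdl.unpack(spec, theta, C)
        try:
            if method == "reml":
                ll = mdl.restricted_loglik(spec, params, pb)
            else:
                ll = mdl.gaussian_loglik(spec, params, pb, profile_beta=True)
        except (SingularCovarianceError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return f


def _objective_and_grad(spec: ModelSpec, pb: PseudobulkGene, method: str):
    """Negative (restricted/profiled) log-likelihood with its analytic
    gradient in the packed variance parameters.

    Uses the standard variance-component score: for each component with
    covariance derivative ``D_j``,
    ``d(-ll)/dtheta_j = 0.5 * [tr(Sigma^-1 D_j) - u' D_j u]`` for profiled
    ML and additionally ``- tr(A^-1 X' Sigma^-1 D_j Sigma^-1 X)`` for REML,
    where ``u = Sigma^-1 (y - X beta_gls)`` and ``A = X' Sigma^-1 X``.  The
    fixed-effect estimate is the minimizer of the quadratic form, so its
    dependence on theta drops out (envelope theorem).  Only available
    without blocked random effects; block-diagonal structure keeps the cost
    O(N C^3) per evaluation.
    """
    C = pb.n_cell_types
    structure = spec.structure
    if spec.mode == "ctp":
        mdl._require_complete(pb)
        X = mdl.ctp_design(spec, pb)  # (N, C, p)
        y = pb.y_ct
    else:
        Xr = mdl.op_design(spec, pb)  # (N, p)
        X = Xr[:, None, :]
        y = pb.y_op[:, None]
    N, _, p = X.shape
    n_obs = y.size
    n_par = mdl.n_variance_params(spec, C)
    penalty = (1e12, np.zeros(n_par))
    iu = np.triu_indices(C)
    logdet_xtx = mdl._logdet_xtx(X)  # REML normalizer, theta-independent

    def fg(theta: np.ndarray):
        params = mdl.unpack(spec, theta, C)
        if spec.mode == "ctp":
            blocks = mdl._ctp_blocks(spec, params, pb)
            try:
                L = np.linalg.cholesky(blocks)
            except np.linalg.LinAlgError:
                return penalty
            diag = np.diagonal(L, axis1=1, axis2=2)
            if diag.min() <= np.sqrt(mdl.MIN_EIGENVALUE):
                return penalty
            logdet = float(2.0 * np.log(diag).sum())
            W = np.linalg.inv(blocks)  # (N, C, C), C is small
        else:
            var = mdl._op_variances(spec, params, pb)
            if var.min() <= mdl.MIN_EIGENVALUE:
                return penalty
            logdet = float(np.log(var).sum())
            W = (1.0 / var)[:, None, None]
        WX = W @ X if spec.mode == "ctp" else X * W  # (N, C, p)
        Wy = (W @ y[:, :, None])[:, :, 0] if spec.mode == "ctp" else y * W[:, :, 0]
        A = np.einsum("icp,icq->pq", X, WX)
        b = np.einsum("icp,ic->p", X, Wy)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return penalty
        beta = np.linalg.solve(A, b)
        quad = float(np.einsum("ic,ic->", y, Wy)) - float(b @ beta)
        if method == "reml":
            nll = 0.5 * ((n_obs - p) * mdl._LOG2PI + logdet + logdet_A
                         - logdet_xtx + quad)
        else:
            nll = 0.5 * (n_obs * mdl._LOG2PI + logdet + quad)
        u = Wy - np.einsum("icp,p->ic", WX, beta)  # Sigma^-1 residual, (N, C)

        A_inv = np.linalg.inv(A) if method == "reml" else None

        def comp(tr_term, quad_term, M=None):
            g = tr_term - quad_term
            if method == "reml" and M is not None:
                g -= float(np.einsum("pq,qp->", A_inv, M))
            elif method == "reml":
                raise AssertionError("REML component missing its M matrix")
            return 0.5 * g

        grads = []
        if spec.mode == "ctp":
            # derivative blocks: J (shared), e_c e_c' (diag), E_cd (full)
            if structure in ("hom", "iid", "free"):
                t1 = WX.sum(axis=1)  # (N, p): X' W 1 rows
                M_J = np.einsum("ip,iq->pq", t1, t1)
                us = u.sum(axis=1)
                grads.append(comp(float(W.sum()), float(us @ us), M_J))
            if structure == "iid":
                diagW = np.diagonal(W, axis1=1, axis2=2)
                M_I = np.einsum("icp,icq->pq", WX, WX)
                grads.append(comp(float(diagW.sum()), float((u**2).sum()), M_I))
            elif structure == "free":
                diagW = np.diagonal(W, axis1=1, axis2=2)  # (N, C)
                M_c = np.einsum("icp,icq->cpq", WX, WX)
                for c in range(C):
                    grads.append(comp(float(diagW[:, c].sum()),
                                      float((u[:, c] ** 2).sum()), M_c[c]))
            elif structure == "full":
                for c, d in zip(*iu):
                    if c == d:
                        tr = float(W[:, c, c].sum())
                        q = float((u[:, c] ** 2).sum())
                        M = np.einsum("ip,iq->pq", WX[:, c], WX[:, c])
                    else:
                        tr = 2.0 * float(W[:, c, d].sum())
                        q = 2.0 * float((u[:, c] * u[:, d]).sum())
                        Mcd = np.einsum("ip,iq->pq", WX[:, c], WX[:, d])
                        M = Mcd + Mcd.T
                    grads.append(comp(tr, q, M))
        else:
            w = W[:, 0, 0]
            u1 = u[:, 0]
            WX1 = WX[:, 0, :]  # (N, p)

            def op_comp(dvar):
                tr = float((w * dvar).sum())
                q = float((u1**2 * dvar).sum())
                M = np.einsum("ip,iq->pq", WX1 * dvar[:, None], WX1)
                return comp(tr, q, M)

            P2 = pb.P**2
            if structure in ("hom", "iid", "free"):
                grads.append(op_comp(np.ones(N)))
            if structure == "iid":
                grads.append(op_comp(P2.sum(axis=1)))
            elif structure == "free":
                for c in range(C):
                    grads.append(op_comp(P2[:, c]))
            elif structure == "full":
                for c, d in zip(*iu):
                    dvar = (P2[:, c] if c == d
                            else 2.0 * pb.P[:, c] * pb.P[:, d])
                    grads.append(op_comp(dvar))
        return nll, np.asarray(grads)

    return fg


def _initial_theta(spec: ModelSpec, pb: PseudobulkGene) -> np.ndarray:
    """Deterministic first attempt: split the residual sample variance
    equally between the shared and cell type-specific components."""
    C = pb.n_cell_types
    s2 = _residual_variance(spec, pb)
    half = s2 / 2.0
    V = half * np.eye(C)
    sa2 = half
    if spec.structure == "hom":
        V = np.zeros((C, C))
        sa2 = s2
    elif spec.structure == "full":
        V = s2 * np.eye(C)
        sa2 = 0.0
    params = VarianceComponents(
        beta=np.zeros(C + spec.n_covariates), sigma_alpha2=sa2, V=V)
    return mdl.pack(spec, params)


def _residual_variance(spec: ModelSpec, pb: PseudobulkGene) -> float:
    if spec.mode == "ctp":
        y = pb.y_ct.reshape(-1)
        X = mdl.ctp_design(spec, pb).reshape(len(y), -1)
    else:
        y = pb.y_op
        X = mdl.op_design(spec, pb)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r.var(ddof=min(X.shape[1], len(y) - 1)))


def _random_theta(spec: ModelSpec, pb: PseudobulkGene,
                  rng: np.random.Generator) -> np.ndarray:
    """Restart draw: each variance component |N(0, s2/2)| on the scale of
    the data's residual variance."""
    n = mdl.n_variance_params(spec, pb.n_cell_types)
    s2 = _residual_variance(spec, pb)
    theta = np.abs(rng.normal(0.0, np.sqrt(max(s2, 1e-6) / 2.0), size=n))
    if spec.structure == "full":
        # off-diagonal entries start at zero: keep the draw PSD-ish
        C = pb.n_cell_types
        V = np.diag(theta[: C]) if n >= C else np.diag(np.full(C, theta[0]))
        params = VarianceComponents(beta=np.zeros(C + spec.n_covariates),
                                    sigma_alpha2=0.0, V=V)
        packed = mdl.pack(spec, params)
        if spec.has_random_blocks:
            packed[-1] = theta[-1]
        return packed
    return theta


def _fit_likelihood(pb: PseudobulkGene, spec: ModelSpec, method: str,
                    n_restarts: int = 10, seed: int | None = None,
                    nelder_mead_refine: bool = False,
                    theta0: np.ndarray | None = None) -> FitResult:
    C = pb.n_cell_types
    R = mdl.n_model_params(spec, C)
    N = pb.n_individuals
    if N <= R:
        raise ValueError(
            f"need more individuals than parameters (N={N}, R={R})")
    use_grad = not spec.has_random_blocks
    if use_grad:
        fg = _objective_and_grad(spec, pb, method)
        f = lambda t: fg(t)[0]  # noqa: E731 - scalar view for refinement
    else:
        f = _objective(spec, pb, method)
        fg = None
    rng = np.random.default_rng(seed)

    starts = [theta0 if theta0 is not None else _initial_theta(spec, pb)]
    best = None
    n_used = 0
    message = ""
    for attempt, start in enumerate(_start_stream(starts, spec, pb, rng,
                                                  n_restarts)):
        n_used = attempt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = None
                x = start
                # a stalled line search (precision loss) often recovers
                # after resetting the Hessian approximation at the stall
                for _ in range(3):
                    if use_grad:
                        res = optimize.minimize(
                            fg, x, jac=True, method="BFGS",
                            options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER})
                    else:
                        res = optimize.minimize(
                            f, x, method="BFGS",
                            options={"gtol": _GRAD_TOL, "maxiter": _MAX_ITER})
                    if res.success or np.allclose(res.x, x):
                        break
                    x = res.x
            except (ValueError, np.linalg.LinAlgError) as e:  # optimizer blew up
                message = str(e)
                continue
        if nelder_mead_refine:
            res = optimize.minimize(f, res.x, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10})
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            # covers both non-finite likelihoods and the inadmissible-
            # covariance penalty: the fast path raises inside f there
            message = "objective inadmissible at optimum"
            continue
        if use_grad:
            ok = bool(res.success) or bool(
                np.linalg.norm(fg(res.x)[1], ord=np.inf) < 1e-3)
        else:
            ok = bool(res.success) or _gradient_small(f, res.x)
        cand = (res.fun, res.x, ok)
        if best is None or cand[0] < best[0]:
            best = cand
        if ok:
            break
    if best is None:
        params = mdl.unpack(spec, starts[0], C)
        return FitResult(params=params, objective=-np.inf, converged=False,
                         n_restarts_used=n_used, method=method, spec=spec,
                         message=message or "all restarts failed")

    fun, theta, ok = best
    params = mdl.unpack(spec, theta, C)
    beta, _ = mdl.gls_solution(spec, params, pb)
    params.beta = beta
    return FitResult(params=params, objective=-fun, converged=ok,
                     n_restarts_used=n_used, method=method, spec=spec,
                     message=message)


def _start_stream(starts, spec, pb, rng, n_restarts):
    yield starts[0]
    for _ in range(n_restarts):
        yield _random_theta(spec, pb, rng)


def _gradient_small(f, x, tol=1e-3) -> bool:
    g = optimize.approx_fprime(x, f, 1.49e-8)
    return bool(np.linalg.norm(g, ord=np.inf) < tol)


def fit_ml(pb: PseudobulkGene, spec: ModelSpec, n_restarts: int = 10,
           seed: int | None = None, nelder_mead_refine: bool = False,
           theta0: np.ndarray | None = None) -> FitResult:
    """Maximum-likelihood fit (fixed effects profiled out)."""
    return _fit_likelihood(pb, spec, "ml", n_restarts, seed,
                           nelder_mead_refine, theta0)


def fit_reml(pb: PseudobulkGene, spec: ModelSpec, n_restarts: int = 10,
             seed: int | None = None, nelder_mead_refine: bool = False,
             theta0: np.ndarray | None = None) -> FitResult:
    """Restricted maximum-likelihood fit."""
    return _fit_likelihood(pb, spec, "reml", n_restarts, seed,
                           nelder_mead_refine, theta0)


# ---------------------------------------------------------------------------
# Haseman-Elston (method of moments)
# ---------------------------------------------------------------------------

def _ols_residuals(spec: ModelSpec, pb: PseudobulkGene):
    if spec.mode == "ctp":
        y = pb.y_ct.reshape(-1)
        X = mdl.ctp_design(spec, pb).reshape(len(y), -1)
    else:
        y = pb.y_op
        X = mdl.op_design(spec, pb)
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise ValueError("singular fixed-effect design in HE fit")
    beta = np.linalg.solve(XtX, X.T @ y)
    return y - X @ beta, beta


def fit_he(pb: PseudobulkGene, spec: ModelSpec) -> FitResult:
    """Closed-form Haseman-Elston moment fit.

    Regresses the entries of the noise-corrected empirical second-moment
    matrix of OLS residuals onto the covariance design of each variance
    component.  Deterministic; no iteration.
    """
    if spec.has_random_blocks:
        raise NotImplementedError("HE with blocked random effects is not supported")
    N, C = pb.y_ct.shape
    if spec.mode == "ctp":
        mdl._require_complete(pb)
        r, beta = _ols_residuals(spec, pb)
        R = r.reshape(N, C)
        # residual second moments shrink under OLS projection; dividing by
        # the per-cell-type residual df (intercept + K covariates removed)
        # restores unbiasedness of the moment matrix
        df = N - 1 - spec.n_covariates
        if df <= 0:
            raise ValueError("not enough individuals for the HE moment fit")
        S = np.einsum("ic,id->cd", R, R) / df - np.diag(pb.nu_ct.mean(axis=0))
        theta, V, sa2 = _solve_he_ctp(spec.structure, S, C)
    else:
        r, beta = _ols_residuals(spec, pb)
        p = C + spec.n_covariates
        if N <= p:
            raise ValueError("not enough individuals for the HE moment fit")
        s = r**2 * (N / (N - p)) - pb.nu_op
        theta, V, sa2 = _solve_he_op(spec.structure, s, pb.P, C)
    params = VarianceComponents(beta=beta, sigma_alpha2=sa2, V=V)
    loss = 0.0
    return FitResult(params=params, objective=loss, converged=True,
                     n_restarts_used=0, method="he", spec=spec)


def _solve_he_ctp(structure: str, S: np.ndarray, C: int):
    """Least-squares projection of the moment matrix S onto the covariance
    basis of each structure (J, I, unit diagonals, symmetric units)."""
    offdiag_mean = (S.sum() - np.trace(S)) / (C * (C - 1)) if C > 1 else 0.0
    diag = np.diag(S)
    if structure == "hom":
        sa2 = float(S.mean())
        return np.array([sa2]), np.zeros((C, C)), sa2
    if structure == "iid":
        sa2 = float(offdiag_mean)
        v = float(diag.mean() - sa2)
        return np.array([sa2, v]), v * np.eye(C), sa2
    if structure == "free":
        sa2 = float(offdiag_mean)
        v = diag - sa2
        return np.concatenate([[sa2], v]), np.diag(v), sa2
    # full: basis spans all symmetric matrices -> V is the symmetrized S
    V = (S + S.T) / 2.0
    return None, V, 0.0


def _solve_he_op(structure: str, s: np.ndarray, P: np.ndarray, C: int):
    """Regress per-individual squared residuals (noise-subtracted) onto the
    variance design [1, P_ic^2, ...] of each structure."""
    N = len(s)
    if structure == "hom":
        return None, np.zeros((C, C)), float(s.mean())
    if structure == "iid":
        D = np.column_stack([np.ones(N), (P**2).sum(axis=1)])
    elif structure == "free":
        D = np.column_stack([np.ones(N), P**2])
    else:  # full: all quadratic terms P_ic P_ic', no shared component
        cols = []
        for c in range(C):
            for d in range(c, C):
                w = P[:, c] * P[:, d]
                cols.append(w if c == d else 2 * w)
        D = np.column_stack(cols)
    DtD = D.T @ D
    if np.linalg.matrix_rank(DtD) < DtD.shape[0]:
        raise ValueError("singular HE moment design (collinear cell types)")
    coef = np.linalg.solve(DtD, D.T @ s)
    if structure == "iid":
        return coef, coef[1] * np.eye(C), float(coef[0])
    if structure == "free":
        return coef, np.diag(coef[1:]), float(coef[0])
    V = np.zeros((C, C))
    k = 0
    for c in range(C):
        for d in range(c, C):
            V[c, d] = V[d, c] = coef[k]
            k += 1
    return coef, V, 0.0


_FITTERS = {"ml": fit_ml, "reml": fit_reml}


def fit(pb: PseudobulkGene, spec: ModelSpec, method: str = "reml",
        **kwargs) -> FitResult:
    """Dispatch to :func:`fit_ml`, :func:`fit_reml`, or :func:`fit_he`."""
    if method == "he":
        return fit_he(pb, spec)
    try:
        fitter = _FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown fitting method {method!r}") from None
    return fitter(pb, spec, **kwargs)


def gls_beta(pb: PseudobulkGene, fitted: FitResult
             ) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed-effect estimate under a fitted covariance, with its
    model-based covariance.  HE pipelines use the plain OLS estimate
    instead (the HE moment covariance can be singular)."""
    if fitted.method == "he":
        r, beta = _ols_residuals(fitted.spec, pb)
        if fitted.spec.mode == "ctp":
            X = mdl.ctp_design(fitted.spec, pb).reshape(-1, len(beta))
        else:
            X = mdl.op_design(fitted.spec, pb)
        dof = max(X.shape[0] - X.shape[1], 1)
        cov = np.linalg.inv(X.T @ X) * float(r @ r) / dof
        return beta, cov
    return mdl.gls_solution(fitted.spec, fitted.params, pb)
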