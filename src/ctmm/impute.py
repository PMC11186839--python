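"""Imputation of structured-missing pseudobulk entries.

Individual x cell type pseudobulk matrices acquire missing entries whenever
an individual has too few cells of a cell type — entire (individual, cell
type) pairs go missing for every gene at once.  Two imputers are provided:

* **low-rank** (softImpute-style): iterative SVD with soft-thresholded
  singular values, applied per gene or to the horizontally stacked
  N x (C*G) transcriptome-wide matrix (which borrows strength across genes
  sharing individual-level structure, and is the recommended default);
* **MVN**: an EM-fitted C-variate Gaussian across individuals, with missing
  entries replaced by conditional means given the observed entries of the
  same row.

Imputed noise variances can come out negative; ``repair_negative_nu``
applies the mode-specific repair (clamp to 0 for OP; replace by the
per-gene, per-cell-type maximum observed raw value for CTP, so repaired
entries down-weight themselves in the likelihood).

``copy_mask_evaluate`` benchmarks an imputer by copying one individual's
real missingness pattern onto others ("copy-mask") until a target fraction
of pairs is hidden, imputing, and scoring the held-out truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MaskPlan",
    "soft_impute",
    "impute_pergene_lowrank",
    "impute_pergene_mvn",
    "impute_transcriptomewide_lowrank",
    "repair_negative_nu",
    "copy_mask",
    "copy_mask_evaluate",
    "column_mean_impute",
]


@dataclass
class MaskPlan:
    """Record of one copy-mask replicate."""

    masked_pairs: list[tuple[int, int]]  # (individual index, cell type index)
    fraction: float
    replicate_id: int


# ---------------------------------------------------------------------------
# low-rank (softImpute-style) completion
# ---------------------------------------------------------------------------

def soft_impute(X: np.ndarray, lam: float = 0.0, rank: int | None = None,
                tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Complete a matrix by iterative soft-thresholded SVD.

    Missing entries (NaN) are repeatedly refilled from a reconstruction
    whose singular values are shrunk by ``lam`` (and optionally truncated
    at ``rank``).  Observed entries are never altered.
    """
    X = np.asarray(X, dtype=float)
    miss = np.isnan(X)
    if not miss.any():
        return X.copy()
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing; cannot impute")
    if lam <= 0 and rank is None:
        # unshrunk full-rank reconstruction is the identity on refilled
        # entries; fall back to a hard rank cap so the iteration does work
        rank = max(1, min(X.shape) - 1)
    col_means = np.nanmean(X, axis=0)
    Z = np.where(miss, col_means, X)
    prev = Z[miss].copy()
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        s = np.maximum(s - lam, 0.0)
        if rank is not None:
            s[rank:] = 0.0
        Z = np.where(miss, (U * s) @ Vt, X)
        delta = np.linalg.norm(Z[miss] - prev)
        denom = np.linalg.norm(prev) + 1e-12
        if delta / denom < tol:
            break
        prev = Z[miss].copy()
    return Z


def _cv_lambda(X: np.ndarray, lams, rng: np.random.Generator,
               n_folds: int = 5) -> float:
    """Pick the soft-threshold by entry-held-out cross-validation."""
    obs = np.argwhere(~np.isnan(X))
    if len(obs) < 2 * n_folds:
        return float(lams[0])
    perm = rng.permutation(len(obs))
    folds = np.array_split(perm, n_folds)
    errs = np.zeros(len(lams))
    for fold in folds:
        held = obs[fold]
        Xm = X.copy()
        Xm[held[:, 0], held[:, 1]] = np.nan
        if np.isnan(Xm).all(axis=0).any():
            continue
        for k, lam in enumerate(lams):
            Z = soft_impute(Xm, lam=lam, max_iter=100)
            errs[k] += float(
                ((Z[held[:, 0], held[:, 1]] - X[held[:, 0], held[:, 1]]) ** 2).sum())
    return float(lams[int(np.argmin(errs))])


def impute_pergene_lowrank(y: np.ndarray, lam: float | None = None,
                           seed: int = 0) -> np.ndarray:
    """Low-rank completion of one gene's N x C matrix.

    When ``lam`` is None, the shrinkage is chosen by 5-fold entry-held-out
    cross-validation over a small grid scaled to the matrix's top singular
    value.
    """
    y = np.asarray(y, dtype=float)
    if not np.isnan(y).any():
        return y.copy()
    if lam is None:
        filled = np.where(np.isnan(y), np.nanmean(y, axis=0), y)
        top = np.linalg.svd(filled, compute_uv=False)[0]
        lams = top * np.array([0.005, 0.01, 0.05, 0.1, 0.2])
        lam = _cv_lambda(y, lams, np.random.default_rng(seed))
    return soft_impute(y, lam=lam)


def impute_transcriptomewide_lowrank(stack: np.ndarray,
                                     lam: float | None = None,
                                     seed: int = 0) -> np.ndarray:
    """Joint low-rank completion of the N x (C*G) stacked matrix; with a
    single gene this is exactly the per-gene imputer."""
    return impute_pergene_lowrank(stack, lam=lam, seed=seed)


def column_mean_impute(y: np.ndarray) -> np.ndarray:
    """Baseline: fill each missing entry with its column mean."""
    y = np.asarray(y, dtype=float)
    return np.where(np.isnan(y), np.nanmean(y, axis=0), y)


# ---------------------------------------------------------------------------
# MVN (EM) imputation
# ---------------------------------------------------------------------------

def impute_pergene_mvn(y: np.ndarray, max_iter: int = 200,
                       tol: float = 1e-8, ridge: float = 1e-8
                       ) -> tuple[np.ndarray, bool]:
    """EM-fitted multivariate-normal imputation of an N x C matrix.

    Rows (individuals) are treated as i.i.d. C-variate Gaussian draws;
    missing entries become conditional means given the observed entries in
    the same row under the final (mu, Sigma).  Returns the completed matrix
    and a convergence flag.
    """
    y = np.asarray(y, dtype=float)
    miss = np.isnan(y)
    if not miss.any():
        return y.copy(), True
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing; cannot impute")
    N, C = y.shape
    mu = np.nanmean(y, axis=0)
    filled = np.where(miss, mu, y)
    Sigma = np.cov(filled, rowvar=False) + ridge * np.eye(C)
    converged = False
    ll_prev = -np.inf
    patterns = {}
    for i in range(N):
        patterns.setdefault(tuple(miss[i]), []).append(i)
    for _ in range(max_iter):
        Ey = filled.copy()
        cond_cov_sum = np.zeros((C, C))
        for pat, rows in patterns.items():
            m = np.array(pat)
            if not m.any():
                continue
            o = ~m
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(m, o)]
            Smm = Sigma[np.ix_(m, m)]
            K = np.linalg.solve(Soo, Smo.T).T  # regression of missing on observed
            for i in rows:
                Ey[i, m] = mu[m] + K @ (y[i, o] - mu[o])
            cc = Smm - K @ Smo.T
            block = np.zeros((C, C))
            block[np.ix_(m, m)] = cc
            cond_cov_sum += len(rows) * block
        mu_new = Ey.mean(axis=0)
        centered = Ey - mu_new
        Sigma_new = (centered.T @ centered + cond_cov_sum) / N \
            + ridge * np.eye(C)
        shift = np.max(np.abs(Sigma_new - Sigma)) + np.max(np.abs(mu_new - mu))
        mu, Sigma, filled = mu_new, Sigma_new, Ey
        if shift < tol:
            converged = True
            break
    out = np.where(miss, filled, y)
    return out, converged


# ---------------------------------------------------------------------------
# negative-noise repair
# ---------------------------------------------------------------------------

def repair_negative_nu(nu_imputed: np.ndarray, mode: str,
                       raw_nu: np.ndarray | None = None) -> np.ndarray:
    """Repair negative imputed noise variances.

    OP mode clamps negatives to zero (they then barely perturb the
    individual-level noise); CTP mode replaces each negative with the
    maximum *observed* raw ``nu`` of that cell type for the gene, so the
    repaired entry contributes little to the likelihood.
    """
    nu = np.asarray(nu_imputed, dtype=float)
    if mode == "op":
        return np.clip(nu, 0.0, None)
    if mode != "ctp":
        raise ValueError(f"unknown mode {mode!r}")
    if raw_nu is None:
        raise ValueError("CTP repair requires the raw (pre-imputation) nu")
    raw = np.asarray(raw_nu, dtype=float)
    out = nu.copy()
    for c in range(nu.shape[1]):
        neg = out[:, c] < 0
        if not neg.any():
            continue
        observed = raw[:, c][~np.isnan(raw[:, c])]
        if observed.size == 0:
            raise ValueError(
                f"cell type column {c} has no observed raw nu to repair with")
        out[neg, c] = observed.max()
    return out


# ---------------------------------------------------------------------------
# copy-mask benchmarking
# ---------------------------------------------------------------------------

def copy_mask(mask: np.ndarray, fraction: float, rng: np.random.Generator,
              replicate_id: int = 0) -> MaskPlan:
    """Copy real missingness patterns onto observed individuals.

    Repeatedly samples a donor individual that has missing cell types and a
    recipient, masking the recipient's same cell types, until at least
    ``fraction`` of all (individual, cell type) pairs are masked.
    """
    mask = np.asarray(mask, dtype=bool)
    N, C = mask.shape
    donors = np.flatnonzero(mask.any(axis=1))
    if donors.size == 0:
        raise ValueError("no individual with missing cell types to donate a pattern")
    target = fraction * N * C
    new_mask = mask.copy()
    pairs: list[tuple[int, int]] = []
    guard = 0
    while len(pairs) < target and guard < 100 * N:
        guard += 1
        donor = int(rng.choice(donors))
        recipient = int(rng.integers(N))
        if recipient == donor:
            continue
        cts = np.flatnonzero(mask[donor])
        fresh = [c for c in cts if not new_mask[recipient, c]]
        if not fresh:
            continue
        for c in fresh:
            new_mask[recipient, c] = True
            pairs.append((recipient, int(c)))
    return MaskPlan(masked_pairs=pairs, fraction=len(pairs) / (N * C),
                    replicate_id=replicate_id)


def copy_mask_evaluate(y_per_gene: dict[str, np.ndarray],
                       mask: np.ndarray,
                       imputer,
                       n_replicates: int = 10,
                       fraction: float = 0.10,
                       seed: int = 0) -> pd.DataFrame:
    """Median imputation accuracy per gene x cell type over copy-mask
    replicates.

    ``imputer`` maps an N x C matrix with NaNs to a completed matrix.  For
    each replicate, a fresh copy-mask hides ~``fraction`` of pairs; the
    imputed values at newly hidden (previously observed) entries are scored
    against the truth by Pearson correlation and MSE across individuals.
    Pairs with fewer than two masked values have undefined correlation and
    report NaN.  Replicate ``r`` uses seed ``seed + r``.
    """
    genes = list(y_per_gene)
    N, C = mask.shape
    records = {(g, c): {"corr": [], "mse": []} for g in genes for c in range(C)}
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        plan = copy_mask(mask, fraction, rng, replicate_id=r)
        hidden = np.zeros((N, C), dtype=bool)
        for i, c in plan.masked_pairs:
            hidden[i, c] = True
        for g in genes:
            truth = np.asarray(y_per_gene[g], dtype=float)
            y_masked = truth.copy()
            y_masked[mask | hidden] = np.nan
            completed = imputer(y_masked)
            for c in range(C):
                rows = hidden[:, c] & ~np.isnan(truth[:, c])
                t, z = truth[rows, c], completed[rows, c]
                if rows.sum() >= 2 and np.std(t) > 0 and np.std(z) > 0:
                    corr = float(np.corrcoef(t, z)[0, 1])
                else:
                    corr = np.nan
                mse = float(np.mean((t - z) ** 2)) if rows.any() else np.nan
                records[(g, c)]["corr"].append(corr)
                records[(g, c)]["mse"].append(mse)
    rows = []
    for (g, c), rec in records.items():
        corr = np.asarray(rec["corr"], dtype=float)
        mse = np.asarray(rec["mse"], dtype=float)
        rows.append({
            "gene": g,
            "cell_type": c,
            "median_correlation": (float(np.nanmedian(corr))
                                   if np.isfinite(corr).any() else np.nan),
            "median_mse": (float(np.nanmedian(mse))
                           if np.isfinite(mse).any() else np.nan),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)
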