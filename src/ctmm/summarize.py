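"""Transcriptome-level summaries of fitted variance components.

``variance_shares`` decomposes a gene's total (standardized) interindividual
variance into fractions attributable to fixed covariates, the blocked random
effect (batch), the cell type-shared component ``sigma_alpha2``, the
proportion-weighted cell type-specific component ``sum_c w_c V_cc`` (with
``w_c`` the mean proportion of cell type ``c``), and residual cell-level
noise (mean ``nu``).  ``full_model_correlations`` converts a Full-model
covariance into between-cell-type correlations of the cell type-specific
effect, excluding genes whose fitted V has a negative diagonal entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import FitResult
from .pseudobulk import PseudobulkGene

__all__ = ["VarianceShares", "variance_shares", "full_model_correlations",
           "shares_table"]

_SHARE_FIELDS = ("share_covariates", "share_batch", "share_alpha",
                 "share_ct_specific", "share_nu")


@dataclass
class VarianceShares:
    """Per-gene fractions of total interindividual variance (sum to 1)."""

    gene: str
    share_covariates: float
    share_batch: float
    share_alpha: float
    share_ct_specific: float
    share_nu: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _SHARE_FIELDS])


def variance_shares(fit_free: FitResult, pb: PseudobulkGene) -> VarianceShares:
    """ANOVA-style decomposition of a gene's interindividual variance.

    The covariate share is the sample variance of the fitted fixed-effect
    predictor beyond the cell-type intercepts (on the standardized OP
    scale); the cell type-specific share weights each ``V_cc`` by the mean
    proportion of cell type ``c``; the noise share is the mean ``nu``.
    Components are normalized to sum to one.
    """
    if not fit_free.converged:
        raise ValueError("variance shares require a converged fit")
    spec = fit_free.spec
    params = fit_free.params
    C = pb.n_cell_types

    if spec.n_covariates > 0:
        W = spec.covariates
        coef = params.beta[C:]
        fitted = W @ coef
        var_cov = float(np.var(fitted, ddof=1)) if len(fitted) > 1 else 0.0
    else:
        var_cov = 0.0
    var_batch = float(params.batch_var) if spec.has_random_blocks else 0.0
    w = pb.P.mean(axis=0)
    var_ct = float(w @ np.diag(params.V))
    var_nu = float(np.nanmean(pb.nu_ct)) if spec.mode == "ctp" \
        else float(np.nanmean(pb.nu_op))
    parts = np.array([var_cov, var_batch, params.sigma_alpha2, var_ct, var_nu])
    total = parts.sum()
    if total <= 0:
        raise ValueError(
            f"gene {pb.name!r}: nonpositive total variance {total:.4g}")
    shares = parts / total
    return VarianceShares(pb.name, *map(float, shares))


def shares_table(shares: list[VarianceShares]) -> pd.DataFrame:
    """Stack per-gene shares and append mean and median summary rows,
    since transcriptome-wide reports quote both."""
    df = pd.DataFrame([{"gene": s.gene,
                        **{f: getattr(s, f) for f in _SHARE_FIELDS}}
                       for s in shares])
    summary = pd.DataFrame({
        "gene": ["__mean__", "__median__"],
        **{f: [df[f].mean(), df[f].median()] for f in _SHARE_FIELDS},
    })
    return pd.concat([df, summary], ignore_index=True)


def full_model_correlations(fit_full: FitResult) -> tuple[np.ndarray, bool]:
    """Correlations of the cell type-specific effect between cell types.

    ``corr[c, c'] = V[c, c'] / sqrt(V[c, c] * V[c', c'])``.  Returns the
    C x C correlation matrix and an ``excluded`` flag: genes with any
    negative diagonal entry of the fitted V are excluded (correlations
    undefined); pairs involving a zero diagonal are NaN.
    """
    if fit_full.spec.structure != "full":
        raise ValueError("correlations require a Full-model fit")
    V = fit_full.params.V
    d = np.diag(V)
    if (d < 0).any():
        return np.full_like(V, np.nan), True
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(d, d))
        corr = np.where(denom > 0, V / denom, np.nan)
    np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
    return corr, False
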