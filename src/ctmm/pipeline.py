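"""End-to-end per-gene analysis pipeline.

For each gene: aggregate cells to pseudobulk, apply the cell-count
missingness rules, standardize to the OP scale, impute missing entries,
repair negative noise variances, fit the requested model structures and
estimators, test for cell type-specific variance and for mean
differentiation, and emit one results row per (estimator, test).  Genes
are processed independently, so results do not depend on processing order;
the only all-genes-in-memory step is optional transcriptome-wide
imputation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import fit as _fit
from . import impute as _impute
from . import testing as _testing
from .model import ModelSpec
from .pseudobulk import (
    PseudobulkGene,
    aggregate,
    apply_missingness,
    standardize,
)

logger = logging.getLogger("ctmm")

__all__ = ["RunConfig", "run_pipeline", "prepare_gene", "analyze_gene"]


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    mode: str = "ctp"  # ctp | op
    estimators: tuple[str, ...] = ("reml",)
    tests: tuple[str, ...] = ("lrt",)  # lrt | wald_fisher | wald_jackknife
    min_cells: int = 10
    min_cells_per_individual: int = 100
    imputer: str = "lowrank"  # lowrank | mvn | transcriptome
    covariates: pd.DataFrame | None = None  # indexed by individual
    batch: pd.Series | None = None  # indexed by individual
    alpha: float = 0.05
    seed: int = 0
    mean_test: bool = True
    keep_largest_replicate: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("ctp", "op"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for e in self.estimators:
            if e not in ("ml", "reml", "he"):
                raise ValueError(f"unknown estimator {e!r}")
        for t in self.tests:
            if t not in ("lrt", "wald_fisher", "wald_jackknife"):
                raise ValueError(f"unknown test {t!r}")
        if self.imputer not in ("lowrank", "mvn", "transcriptome"):
            raise ValueError(f"unknown imputer {self.imputer!r}")


def prepare_gene(cells, config: RunConfig) -> PseudobulkGene:
    """Aggregate, filter and standardize one gene (imputation not yet
    applied)."""
    pb = aggregate(cells, keep_largest_replicate=config.keep_largest_replicate)
    pb = apply_missingness(pb, min_cells=config.min_cells,
                           min_cells_per_individual=config.min_cells_per_individual)
    return standardize(pb)


def _impute_gene(pb: PseudobulkGene, config: RunConfig) -> PseudobulkGene:
    if pb.is_complete:
        return pb
    out = pb.copy()
    if config.imputer == "mvn":
        out.y_ct, _ = _impute.impute_pergene_mvn(pb.y_ct)
        nu_imp, _ = _impute.impute_pergene_mvn(pb.nu_ct)
    else:  # lowrank (per gene); 'transcriptome' handled in run_pipeline
        out.y_ct = _impute.impute_pergene_lowrank(pb.y_ct, seed=config.seed)
        nu_imp = _impute.impute_pergene_lowrank(pb.nu_ct, seed=config.seed)
    out.nu_ct = _impute.repair_negative_nu(nu_imp, "ctp", raw_nu=pb.nu_ct)
    out.mask = np.zeros_like(pb.mask)
    return out


def _model_spec(config: RunConfig, structure: str,
                individuals: np.ndarray) -> ModelSpec:
    covariates = None
    if config.covariates is not None:
        covariates = (config.covariates.reindex(individuals)
                      .to_numpy(dtype=float))
        if np.isnan(covariates).any():
            missing = set(individuals) - set(config.covariates.index)
            raise ValueError(f"covariates missing for individuals {missing}")
    blocks = None
    if config.batch is not None:
        blocks = config.batch.reindex(individuals).to_numpy()
        if pd.isna(blocks).any():
            missing = set(individuals) - set(config.batch.index)
            raise ValueError(f"batch missing for individuals {missing}")
    return ModelSpec(structure=structure, mode=config.mode,
                     covariates=covariates, random_blocks=blocks)


def analyze_gene(pb: PseudobulkGene, config: RunConfig) -> list[dict]:
    """Fit and test one imputed, standardized gene; one row per
    (estimator, test)."""
    rows = []
    C = pb.n_cell_types
    spec_free = _model_spec(config, "free", pb.individuals)
    spec_hom = _model_spec(config, "hom", pb.individuals)
    for method in config.estimators:
        t0 = time.perf_counter()
        if method == "he":
            free = _fit.fit_he(pb, spec_free)
        else:
            free = _fit.fit(pb, spec_free, method=method, seed=config.seed)
        base = {
            "gene": pb.name,
            "mode": config.mode,
            "method": method,
            "converged": free.converged,
            "sigma_alpha2": free.params.sigma_alpha2,
        }
        for c, ct in enumerate(pb.cell_types):
            base[f"V_{ct}"] = float(free.params.V[c, c])
        p_mean = np.nan
        if config.mean_test and free.converged:
            try:
                p_mean = _testing.mean_differentiation_test(pb, free).p_value
            except (ValueError, RuntimeError) as e:
                logger.warning("gene %s: mean test failed: %s", pb.name, e)
        tests = config.tests if method != "he" else ("wald_jackknife",)
        for test in tests:
            row = dict(base)
            row["test"] = test
            row["p_mean"] = p_mean
            row["p_variance"] = np.nan
            if not free.converged:
                rows.append(row)
                continue
            try:
                if test == "lrt":
                    hom = _fit.fit(pb, spec_hom, method=method,
                                   seed=config.seed)
                    if hom.converged:
                        row["p_variance"] = _testing.lrt_free_vs_hom(
                            free, hom).p_value
                else:
                    src = {"wald_fisher": "fisher",
                           "wald_jackknife": "jackknife"}[test]
                    row["p_variance"] = _testing.wald_variance_test(
                        free, pb, precision_source=src).p_value
            except (ValueError, RuntimeError) as e:
                logger.warning("gene %s: %s failed: %s", pb.name, test, e)
            rows.append(row)
        logger.debug("gene %s method %s: %.2fs, %d restarts", pb.name,
                     method, time.perf_counter() - t0, free.n_restarts_used)
    return rows


def run_pipeline(gene_stream, config: RunConfig) -> pd.DataFrame:
    """Run the full analysis over a stream of :class:`CellLevelGene`.

    Returns one row per gene per (estimator, test) with Bonferroni flags
    added per (method, test) family.  With
    ``config.imputer == 'transcriptome'``, all genes' pseudobulk is held in
    memory and imputed jointly in an N x (C*G) stack before fitting.
    """
    prepared: list[PseudobulkGene] = []
    skipped: list[str] = []
    for cells in gene_stream:
        try:
            prepared.append(prepare_gene(cells, config))
        except ValueError as e:
            logger.warning("gene %s skipped: %s", cells.name, e)
            skipped.append(cells.name)
    if not prepared:
        raise ValueError("no gene survived aggregation and filtering")

    if config.imputer == "transcriptome":
        prepared = _impute_transcriptomewide(prepared, config)
    else:
        prepared = [_impute_gene(pb, config) for pb in prepared]

    rows = []
    for pb in prepared:
        rows.extend(analyze_gene(pb, config))
    table = pd.DataFrame(rows)
    table["bonferroni_significant"] = False
    for (method, test), idx in table.groupby(["method", "test"]).groups.items():
        p = table.loc[idx, "p_variance"]
        flags, _ = _testing.bonferroni(p.fillna(1.0), alpha=config.alpha)
        table.loc[idx, "bonferroni_significant"] = flags
    return table


def _impute_transcriptomewide(prepared: list[PseudobulkGene],
                              config: RunConfig) -> list[PseudobulkGene]:
    ref = prepared[0]
    for pb in prepared[1:]:
        if not np.array_equal(pb.individuals, ref.individuals):
            raise ValueError("genes disagree on the individual set; cannot "
                             "stack for transcriptome-wide imputation")
    y_stack = np.hstack([pb.y_ct for pb in prepared])
    nu_stack = np.hstack([pb.nu_ct for pb in prepared])
    y_done = _impute.impute_transcriptomewide_lowrank(y_stack, seed=config.seed)
    nu_done = _impute.impute_transcriptomewide_lowrank(nu_stack, seed=config.seed)
    C = ref.n_cell_types
    out = []
    for g, pb in enumerate(prepared):
        done = pb.copy()
        done.y_ct = y_done[:, g * C:(g + 1) * C]
        nu_imp = nu_done[:, g * C:(g + 1) * C]
        done.nu_ct = _impute.repair_negative_nu(nu_imp, "ctp", raw_nu=pb.nu_ct)
        done.mask = np.zeros_like(pb.mask)
        out.append(done)
    return out


def provenance(config: RunConfig) -> dict:
    return {
        "ctmm_version": __version__,
        "mode": config.mode,
        "estimators": ",".join(config.estimators),
        "tests": ",".join(config.tests),
        "min_cells": config.min_cells,
        "min_cells_per_individual": config.min_cells_per_individual,
        "imputer": config.imputer,
        "alpha": config.alpha,
        "seed": config.seed,
    }
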