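"""Pseudobulk aggregation of cell-level expression.

A gene's cell-level expression is summarized per individual into two forms:

* **CTP** (cell type-specific pseudobulk): the mean expression over an
  individual's cells within each cell type, ``y_ct[i, c]``, together with an
  estimate of its sampling noise ``nu_ct[i, c] = sigma2_ic / n_ic`` where
  ``sigma2_ic`` is the within-pair cell-to-cell sample variance.
* **OP** (overall pseudobulk): the mean over all of an individual's cells,
  ``y_op[i]``, a bulk-RNA analog, with noise
  ``nu_op[i] = sum_c (n_ic / n_i**2) * sigma2_ic``.

The within-pair variance estimator is unbiased regardless of the cell-level
distribution, which is what lets downstream Gaussian mixed models separate
true interindividual variance from measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellLevelGene",
    "PseudobulkGene",
    "StandardizationRecord",
    "aggregate",
    "apply_missingness",
    "standardize",
    "unstandardize",
]


@dataclass
class CellLevelGene:
    """One gene's expression per cell, with individual and cell-type labels.

    Parameters
    ----------
    values
        Expression per cell (library-normalized / log-transformed units,
        as provided by upstream processing; no normalization happens here).
    individual
        Individual (donor) label per cell.
    cell_type
        Cell-type label per cell.
    name
        Optional gene name carried through to outputs.
    """

    values: np.ndarray
    individual: np.ndarray
    cell_type: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual = np.asarray(self.individual)
        self.cell_type = np.asarray(self.cell_type)
        if not (len(self.values) == len(self.individual) == len(self.cell_type)):
            raise ValueError("values, individual and cell_type must have equal length")
        if len(self.values) == 0:
            raise ValueError(f"gene {self.name!r} has no cells")


@dataclass
class StandardizationRecord:
    """Location/scale transform applied to a pseudobulk bundle (invertible)."""

    center: float
    scale: float  # OP sample standard deviation


@dataclass
class PseudobulkGene:
    """Per-gene individual x cell type pseudobulk bundle.

    ``y_ct``/``nu_ct`` hold NaN where the missingness rule fired; ``mask``
    is True exactly at those entries.  ``P`` rows are cell-type proportions
    ``n_ic / n_i`` and sum to one over an individual's observed cells.
    """

    individuals: np.ndarray  # (N,) labels
    cell_types: np.ndarray  # (C,) labels
    y_ct: np.ndarray  # (N, C)
    nu_ct: np.ndarray  # (N, C)
    n_ct: np.ndarray  # (N, C) integer cell counts
    P: np.ndarray  # (N, C)
    y_op: np.ndarray  # (N,)
    nu_op: np.ndarray  # (N,)
    mask: np.ndarray  # (N, C) bool, True = missing
    name: str = ""
    standardization: StandardizationRecord | None = None

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def copy(self) -> "PseudobulkGene":
        return replace(
            self,
            y_ct=self.y_ct.copy(),
            nu_ct=self.nu_ct.copy(),
            n_ct=self.n_ct.copy(),
            P=self.P.copy(),
            y_op=self.y_op.copy(),
            nu_op=self.nu_op.copy(),
            mask=self.mask.copy(),
        )

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tables (individual rows, cell-type columns) for TSV serialization."""
        idx = pd.Index(self.individuals, name="individual")
        cols = pd.Index(self.cell_types, name="cell_type")
        return {
            "y_ct": pd.DataFrame(self.y_ct, index=idx, columns=cols),
            "nu_ct": pd.DataFrame(self.nu_ct, index=idx, columns=cols),
            "n_ct": pd.DataFrame(self.n_ct, index=idx, columns=cols),
            "P": pd.DataFrame(self.P, index=idx, columns=cols),
        }


def aggregate(
    cells: CellLevelGene,
    keep_largest_replicate: bool = False,
    replicate_sep: str | None = None,
) -> PseudobulkGene:
    """Aggregate cell-level expression to OP and CTP summaries.

    Pairs observed with a single cell have an undefined within-pair variance
    and are flagged missing.  When ``keep_largest_replicate`` is set,
    individual labels of the form ``donor<sep>replicate`` are collapsed by
    keeping only the technical replicate with the most cells.

    Returns a :class:`PseudobulkGene` over all individuals and cell types
    present in the input, in sorted label order.
    """
    df = pd.DataFrame(
        {
            "y": cells.values,
            "individual": cells.individual,
            "cell_type": cells.cell_type,
        }
    )
    if keep_largest_replicate:
        sep = replicate_sep or "."
        donor = df["individual"].astype(str).str.rsplit(sep, n=1).str[0]
        sizes = df.groupby("individual", observed=True).size()
        best = (
            pd.DataFrame({"individual": sizes.index, "donor": [
                str(i).rsplit(sep, 1)[0] for i in sizes.index], "n": sizes.values})
            .sort_values("n", ascending=False)
            .drop_duplicates("donor")
        )
        keep = set(best["individual"])
        df = df[df["individual"].isin(keep)].copy()
        df["individual"] = donor[df.index]

    grouped = df.groupby(["individual", "cell_type"], observed=True)["y"]
    means = grouped.mean().unstack("cell_type")
    counts = grouped.size().unstack("cell_type").fillna(0).astype(int)
    # ddof=1 sample variance; NaN for n_ic <= 1
    variances = grouped.var(ddof=1).unstack("cell_type")

    individuals = means.index.to_numpy()
    cell_types = means.columns.to_numpy()
    y_ct = means.to_numpy(dtype=float)
    n_ct = counts.to_numpy()
    sigma2 = variances.to_numpy(dtype=float)

    n_i = n_ct.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nu_ct = sigma2 / n_ct
        P = n_ct / n_i[:, None]
    # OP over all cells of the individual
    tot = df.groupby("individual", observed=True)["y"].sum().reindex(means.index)
    y_op = tot.to_numpy(dtype=float) / n_i
    # nu_op = sum_c n_ic/n_i^2 * sigma2_ic over pairs where sigma2 is defined
    contrib = np.where(n_ct > 0, np.nan_to_num(sigma2) * n_ct, 0.0) / n_i[:, None] ** 2
    nu_op = contrib.sum(axis=1)

    mask = (n_ct == 0) | (n_ct == 1)  # unobserved pair, or variance undefined
    y_ct = np.where(mask, np.nan, y_ct)
    nu_ct = np.where(mask, np.nan, nu_ct)

    return PseudobulkGene(
        individuals=individuals,
        cell_types=cell_types,
        y_ct=y_ct,
        nu_ct=nu_ct,
        n_ct=n_ct,
        P=P,
        y_op=y_op,
        nu_op=nu_op,
        mask=mask,
        name=cells.name,
    )


def apply_missingness(
    pb: PseudobulkGene,
    min_cells: int = 10,
    min_cells_per_individual: int = 100,
) -> PseudobulkGene:
    """Apply the cell-count missingness rules.

    Individual-cell type pairs with no more than ``min_cells`` cells are set
    to missing (the within-pair Gaussian approximation needs enough cells);
    individuals with fewer than ``min_cells_per_individual`` cells in total
    are dropped entirely.
    """
    n_i = pb.n_ct.sum(axis=1)
    keep = n_i >= min_cells_per_individual
    if not keep.any():
        raise ValueError("all individuals fall below the per-individual cell minimum")

    out = pb.copy()
    out.individuals = pb.individuals[keep]
    for attr in ("y_ct", "nu_ct", "n_ct", "P", "mask"):
        setattr(out, attr, getattr(out, attr)[keep])
    out.y_op = out.y_op[keep]
    out.nu_op = out.nu_op[keep]

    fire = out.n_ct <= min_cells
    out.mask = out.mask | fire
    out.y_ct = np.where(out.mask, np.nan, out.y_ct)
    out.nu_ct = np.where(out.mask, np.nan, out.nu_ct)
    if out.mask.all():
        raise ValueError("all pseudobulk entries are missing after filtering")
    return out


def standardize(pb: PseudobulkGene) -> PseudobulkGene:
    """Scale a pseudobulk bundle so OP has mean 0 and (sample) variance 1.

    CTP values are shifted by the OP mean and divided by the OP standard
    deviation; noise variances are divided by the OP variance.  The
    transform is stored on the result and inverted by :func:`unstandardize`.
    """
    if pb.n_individuals < 2:
        raise ValueError("standardization requires at least two individuals")
    center = float(np.mean(pb.y_op))
    scale = float(np.std(pb.y_op, ddof=1))
    if scale == 0 or not np.isfinite(scale):
        raise ValueError(f"gene {pb.name!r}: OP vector is constant; cannot standardize")

    out = pb.copy()
    out.y_op = (pb.y_op - center) / scale
    out.y_ct = (pb.y_ct - center) / scale
    out.nu_op = pb.nu_op / scale**2
    out.nu_ct = pb.nu_ct / scale**2
    out.standardization = StandardizationRecord(center=center, scale=scale)
    return out


def unstandardize(pb: PseudobulkGene) -> PseudobulkGene:
    """Invert :func:`standardize` using the stored record."""
    rec = pb.standardization
    if rec is None:
        raise ValueError("pseudobulk bundle carries no standardization record")
    out = pb.copy()
    out.y_op = pb.y_op * rec.scale + rec.center
    out.y_ct = pb.y_ct * rec.scale + rec.center
    out.nu_op = pb.nu_op * rec.scale**2
    out.nu_ct = pb.nu_ct * rec.scale**2
    out.standardization = None
    return out
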