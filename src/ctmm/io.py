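"""Reading expression matrices and writing results tables.

Input is a genes x cells expression matrix — MatrixMarket sparse (with an
accompanying one-name-per-line gene file) or dense TSV (gene rows, cell
columns) — plus a TSV cell-metadata table with columns ``cell_id``,
``individual`` and ``cell_type``.  Expression is assumed already
library-normalized and log-transformed upstream.
"""

from __future__ import annotations

from collections.abc import Iterator
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .pseudobulk import CellLevelGene

__all__ = ["read_cell_metadata", "read_cell_matrix", "write_results",
           "write_pseudobulk"]

METADATA_COLUMNS = ("cell_id", "individual", "cell_type")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Cell metadata TSV with columns cell_id, individual, cell_type."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(
            f"{path}: metadata is missing required column(s) {missing}; "
            f"found {list(meta.columns)}")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"{path}: duplicated cell_id {dup!r}")
    return meta


def read_cell_matrix(matrix_path: str | Path,
                     metadata_path: str | Path,
                     genes_path: str | Path | None = None,
                     ) -> Iterator[CellLevelGene]:
    """Stream one gene at a time from an expression matrix.

    ``matrix_path`` is either a MatrixMarket ``.mtx`` file (genes x cells,
    1-based indices per the MatrixMarket standard, gene names from
    ``genes_path``) or a dense TSV with gene rows (index = gene names) and
    cell columns.  Cells are matched to the metadata by position for MTX
    and by ``cell_id`` for TSV.
    """
    meta = read_cell_metadata(metadata_path)
    path = Path(matrix_path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        mat = sparse.csr_matrix(mat)
        if mat.shape[1] != len(meta):
            raise ValueError(
                f"{path}: matrix has {mat.shape[1]} cells but metadata has "
                f"{len(meta)} rows")
        if genes_path is not None:
            genes = [ln.strip().split("\t")[0]
                     for ln in Path(genes_path).read_text().splitlines()
                     if ln.strip()]
            if len(genes) != mat.shape[0]:
                raise ValueError(
                    f"{genes_path}: {len(genes)} gene names for "
                    f"{mat.shape[0]} matrix rows")
        else:
            genes = [f"gene{g}" for g in range(mat.shape[0])]
        individual = meta["individual"].to_numpy()
        cell_type = meta["cell_type"].to_numpy()
        for g, name in enumerate(genes):
            yield CellLevelGene(values=np.asarray(mat[g].todense()).ravel(),
                                individual=individual, cell_type=cell_type,
                                name=name)
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(meta["cell_id"]) - set(dense.columns)
        if missing:
            raise ValueError(
                f"{path}: {len(missing)} metadata cell(s) absent from the "
                f"matrix, e.g. {sorted(missing)[:3]}")
        dense = dense[meta["cell_id"]]
        individual = meta["individual"].to_numpy()
        cell_type = meta["cell_type"].to_numpy()
        for name, row in dense.iterrows():
            yield CellLevelGene(values=row.to_numpy(dtype=float),
                                individual=individual, cell_type=cell_type,
                                name=str(name))


def write_results(table: pd.DataFrame, path: str | Path,
                  provenance: dict | None = None) -> None:
    """Write a results table as TSV, with provenance as ``#``-comment
    header lines (config, seed, package version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_pseudobulk(pb, prefix: str | Path) -> None:
    """Serialize a pseudobulk bundle as TSV tables (y_ct, nu_ct, n_ct, P)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name, frame in pb.to_frames().items():
        frame.to_csv(f"{prefix}.{name}.tsv", sep="\t")
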