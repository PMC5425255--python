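"""Core data container: a genes x cells expression matrix with a layer tag.

The matrix travels through the pipeline as raw counts, CPM or log10-CPM;
operations declare which layer they accept and refuse the others, which
catches the classic normalise-twice / log-twice mistakes at the boundary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import LayerError

LAYERS = ("counts", "cpm", "log_cpm")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x cells matrix plus per-gene / per-cell annotation tables.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are cell ids. Non-negative.
    layer
        One of ``counts`` (integer raw counts), ``cpm`` (columns sum to 1e6)
        or ``log_cpm`` (log10(cpm + pseudocount)).
    gene_annotations
        Indexed like ``values``; an ``is_pseudogene`` boolean column is added
        (all False) when absent.
    cell_annotations
        Indexed by cell id; ``total_reads`` and ``n_genes_detected`` are
        computed from the counts layer when absent.
    """

    values: pd.DataFrame
    layer: str = "counts"
    gene_annotations: pd.DataFrame | None = None
    cell_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise LayerError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        vals = np.asarray(self.values.values, dtype=float)
        if self.layer != "log_cpm" and (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.layer == "counts" and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts layer must be integer-valued")
        if self.gene_annotations is None:
            self.gene_annotations = pd.DataFrame(index=self.values.index)
        if "is_pseudogene" not in self.gene_annotations.columns:
            self.gene_annotations = self.gene_annotations.assign(is_pseudogene=False)
        if self.cell_annotations is None:
            self.cell_annotations = pd.DataFrame(index=self.values.columns)
        if self.layer == "counts":
            if "total_reads" not in self.cell_annotations.columns:
                self.cell_annotations["total_reads"] = vals.sum(axis=0)
            if "n_genes_detected" not in self.cell_annotations.columns:
                self.cell_annotations["n_genes_detected"] = (vals > 0).sum(axis=0)
        if not self.gene_annotations.index.equals(self.values.index):
            raise ValueError("gene annotation index does not match matrix rows")
        if not self.cell_annotations.index.equals(self.values.columns):
            raise ValueError("cell annotation index does not match matrix columns")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_layer(self, *layers: str) -> None:
        if self.layer not in layers:
            raise LayerError(
                f"operation requires layer in {layers}, got {self.layer!r}"
            )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(
            self.values.loc[genes],
            layer=self.layer,
            gene_annotations=self.gene_annotations.loc[genes],
            cell_annotations=self.cell_annotations.copy(),
        )

    def subset_cells(self, cells) -> "ExpressionMatrix":
        cells = pd.Index(cells)
        return ExpressionMatrix(
            self.values[cells],
            layer=self.layer,
            gene_annotations=self.gene_annotations.copy(),
            cell_annotations=self.cell_annotations.loc[cells],
        )

    def with_values(self, values: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values,
            layer=layer,
            gene_annotations=self.gene_annotations.copy(),
            cell_annotations=self.cell_annotations.copy(),
        )


# ---------------------------------------------------------------------------
# I/O: MTX + TSV sidecars, dense CSV/TSV, HDF5 container
# ---------------------------------------------------------------------------

def write_mtx(m: ExpressionMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.csr_matrix(m.values.values))
    m.gene_annotations.to_csv(out / "genes.tsv", sep="\t")
    m.cell_annotations.to_csv(out / "cells.tsv", sep="\t")
    (out / "layer.txt").write_text(m.layer + "\n")


def read_mtx(in_dir: str | Path) -> ExpressionMatrix:
    src = Path(in_dir)
    mat = scipy.io.mmread(src / "matrix.mtx").toarray()
    genes = pd.read_csv(src / "genes.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(src / "cells.tsv", sep="\t", index_col=0)
    layer_file = src / "layer.txt"
    layer = layer_file.read_text().strip() if layer_file.exists() else "counts"
    values = pd.DataFrame(mat, index=genes.index, columns=cells.index)
    return ExpressionMatrix(values, layer=layer, gene_annotations=genes,
                            cell_annotations=cells)


def write_csv(m: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    m.values.to_csv(path, sep=sep)


def read_csv(path: str | Path, sep: str = ",", layer: str = "counts") -> ExpressionMatrix:
    values = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(values, layer=layer)


def write_hdf5(m: ExpressionMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values.values)
        f.create_dataset("genes", data=np.asarray(m.genes, dtype="S"))
        f.create_dataset("cells", data=np.asarray(m.cells, dtype="S"))
        f.attrs["layer"] = m.layer
        f.create_dataset(
            "is_pseudogene", data=m.gene_annotations["is_pseudogene"].values
        )


def read_hdf5(path: str | Path) -> ExpressionMatrix:
    with h5py.File(path, "r") as f:
        genes = [g.decode() for g in f["genes"][...]]
        cells = [c.decode() for c in f["cells"][...]]
        values = pd.DataFrame(f["values"][...], index=genes, columns=cells)
        layer = f.attrs["layer"]
        gene_ann = pd.DataFrame(
            {"is_pseudogene": f["is_pseudogene"][...].astype(bool)}, index=genes
        )
    return ExpressionMatrix(values, layer=str(layer), gene_annotations=gene_ann)
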