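"""Quality filtering and normalisation of single-cell count matrices.

Fixed pipeline order: QC-filter cells (total reads and detected genes),
then filter genes (detection counted on the retained cells only, plus
pseudogene removal), then counts-per-million normalisation, then log10.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import EmptyResultError


@dataclasses.dataclass
class QCReport:
    excluded_cells: pd.DataFrame  # index: cell id; columns: total_reads, n_genes_detected, reason

    def write(self, path) -> None:
        self.excluded_cells.to_csv(path, sep="\t")


def qc_filter_cells(m: ExpressionMatrix, min_reads: float = 1e6,
                    min_genes: int = 1000) -> tuple[ExpressionMatrix, QCReport]:
    """Drop low-quality libraries: below ``min_reads`` total reads or fewer
    than ``min_genes`` expressed (count > 0) genes."""
    m.require_layer("counts")
    totals = m.values.sum(axis=0)
    detected = (m.values > 0).sum(axis=0)
    ok = (totals >= min_reads) & (detected >= min_genes)
    if not ok.any():
        raise EmptyResultError("no cells pass QC")
    excluded = m.cells[~ok]
    reasons = []
    for c in excluded:
        why = []
        if totals[c] < min_reads:
            why.append(f"total_reads<{min_reads:g}")
        if detected[c] < min_genes:
            why.append(f"n_genes_detected<{min_genes}")
        reasons.append(";".join(why))
    report = QCReport(pd.DataFrame(
        {"total_reads": totals[excluded], "n_genes_detected": detected[excluded],
         "reason": reasons}, index=excluded))
    kept = m.subset_cells(m.cells[ok])
    kept.cell_annotations["total_reads"] = totals[ok]
    kept.cell_annotations["n_genes_detected"] = detected[ok]
    return kept, report


def filter_genes(m: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Remove genes detected in fewer than ``min_cells`` cells ("less than
    10 cells" rule => a gene in exactly ``min_cells`` is kept) and genes
    flagged as pseudogenes."""
    m.require_layer("counts")
    detected_in = (m.values > 0).sum(axis=1)
    keep = (detected_in >= min_cells) & (~m.gene_annotations["is_pseudogene"])
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return m.subset_genes(m.genes[keep])


def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to one million total counts (layer counts -> cpm)."""
    m.require_layer("counts")
    totals = m.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero cell(s) cannot be normalised: "
                         f"{list(zero.index[:5])}")
    cpm = m.values / totals * 1e6
    return m.with_values(cpm, layer="cpm")


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log10(cpm + pseudocount); with the default pseudocount zeros map to 0."""
    m.require_layer("cpm")
    if (m.values.values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return m.with_values(np.log10(m.values + pseudocount), layer="log_cpm")


def preprocess_pipeline(m: ExpressionMatrix, min_reads: float = 1e6,
                        min_genes: int = 1000, min_cells: int = 10,
                        pseudocount: float = 1.0
                        ) -> tuple[ExpressionMatrix, QCReport]:
    """QC cells -> filter genes -> CPM -> log10, returning the QC report."""
    kept, report = qc_filter_cells(m, min_reads=min_reads, min_genes=min_genes)
    kept = filter_genes(kept, min_cells=min_cells)
    return log_transform(normalize_cpm(kept), pseudocount=pseudocount), report
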