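"""QC filtering, log-normalisation and marker-based cell-type annotation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AnnotatedMatrix, EmptyResultError, OrganofitError

#: genes whose symbol starts with this prefix count toward the mito fraction
MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    """Cell/gene inclusion thresholds.

    The mitochondrial-fraction cut only applies when the gene table actually
    contains flagged mito genes (symbols starting with ``MT-``).
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_gene) < 0 or self.max_mito_fraction < 0:
            raise ValueError("QC thresholds must be non-negative")


def qc_filter(
    m: AnnotatedMatrix, thresholds: QCThresholds | None = None
) -> tuple[AnnotatedMatrix, pd.DataFrame]:
    """Remove low-coverage cells and rarely detected genes.

    Cells are filtered first (too few detected genes; excessive mito
    fraction), then genes detected in too few surviving cells.  Order of
    surviving cells and genes is preserved.  Returns the filtered matrix and
    a per-criterion report of how many records each cut removed.
    """
    t = thresholds or QCThresholds()
    counts = m.counts

    genes_per_cell = counts.getnnz(axis=1)
    cell_keep = genes_per_cell >= t.min_genes_per_cell

    mito = m.genes["symbol"].str.startswith(MITO_PREFIX).to_numpy()
    n_mito_removed = 0
    if mito.any():
        libsize = np.asarray(counts.sum(axis=1)).ravel()
        mito_frac = np.divide(
            np.asarray(counts[:, mito].sum(axis=1)).ravel(),
            libsize,
            out=np.zeros(m.n_cells),
            where=libsize > 0,
        )
        mito_ok = mito_frac <= t.max_mito_fraction
        n_mito_removed = int((cell_keep & ~mito_ok).sum())
        cell_keep &= mito_ok

    if not cell_keep.any():
        raise EmptyResultError("QC removed every cell")

    filtered = m.subset_cells(cell_keep)
    cells_per_gene = filtered.counts.getnnz(axis=0)
    gene_keep = cells_per_gene >= t.min_cells_per_gene
    filtered = filtered.subset_genes(gene_keep)

    report = pd.DataFrame(
        {
            "criterion": [
                "cells_min_genes",
                "cells_max_mito",
                "genes_min_cells",
                "cells_kept",
                "genes_kept",
            ],
            "n": [
                int((genes_per_cell < t.min_genes_per_cell).sum()),
                n_mito_removed,
                int((~gene_keep).sum()),
                filtered.n_cells,
                filtered.n_genes,
            ],
        }
    )
    return filtered, report


def lognormalize(m: AnnotatedMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalised log expression: ``log2(1 + target_sum * x / libsize)``.

    Stored as (and returned from) the ``"lognorm"`` layer.
    """
    lib = np.asarray(m.counts.sum(axis=1)).ravel()
    if (lib == 0).any():
        raise OrganofitError("zero library size; run qc_filter first")
    dense = m.counts.toarray()
    layer = np.log2(1.0 + target_sum * dense / lib[:, None])
    m.layers["lognorm"] = layer
    return layer


def get_lognorm(m: AnnotatedMatrix) -> np.ndarray:
    if "lognorm" not in m.layers:
        return lognormalize(m)
    return m.layers["lognorm"]


def annotate_cell_types(
    m: AnnotatedMatrix,
    marker_panels: dict[str, list[str]],
    tie_tolerance: float = 1e-6,
) -> pd.Series:
    """Assign each cell the panel with the highest mean marker expression.

    Panels map a cell-type name to marker gene symbols (epithelial, immune,
    stromal in the standard run).  A cell whose top-two panel means are
    within ``tie_tolerance`` is labelled ``"unknown"``.  The result is also
    written into ``m.cells["cell_type"]``.
    """
    if not marker_panels:
        raise OrganofitError("no marker panels supplied")
    expr = get_lognorm(m)
    symbols = m.genes["symbol"]
    names = sorted(marker_panels)
    means = np.zeros((m.n_cells, len(names)))
    for k, name in enumerate(names):
        idx = np.flatnonzero(symbols.isin(marker_panels[name]).to_numpy())
        if idx.size == 0:
            raise OrganofitError(f"marker panel {name!r} shares no genes with the matrix")
        means[:, k] = expr[:, idx].mean(axis=1)
    order = np.argsort(means, axis=1)
    best, second = order[:, -1], order[:, -2]
    margin = means[np.arange(m.n_cells), best] - means[np.arange(m.n_cells), second]
    labels = np.array(names, dtype=object)[best]
    labels[margin <= tie_tolerance] = "unknown"
    result = pd.Series(labels, name="cell_type")
    m.cells["cell_type"] = result.to_numpy()
    return result
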