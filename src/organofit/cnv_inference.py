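"""Expression-inferred copy-number profiles and CNV-burden malignancy calls.

Single-cell RNA-seq does not measure DNA, but broad copy-number events leave
a dosage footprint on expression: averaging reference-centred log expression
over windows of genomically adjacent genes suppresses gene-level noise and
leaves the chromosome-scale signal.  Profiles are centred on a reference of
presumed-diploid cells (immune + stromal by default), so a reference cell's
profile is ~0 everywhere and a one-copy gain shows as a positive log2 shift.

Malignancy is then called from the profiles themselves: epithelial cells
split by 2-means on CNV burden (mean squared profile), and a high-burden
cell is malignant if it also correlates with the high-burden centroid —
guarding against isolated noisy cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AnnotatedMatrix,
    CHROMOSOMES,
    InsufficientCellsError,
    OrganofitError,
)
from .preprocess import get_lognorm

REFERENCE_CELL_TYPES = ("immune", "stromal")


@dataclass
class CNVProfileSet:
    """Per-cell smoothed copy-number estimates over genomic windows.

    ``values`` is cells x windows on the log2-ratio scale (0 = neutral).
    ``windows`` records, per window, the chromosome, the half-open span of
    retained-gene positions it averages, and its genomic bp extent.
    """

    values: np.ndarray
    windows: pd.DataFrame   # window_id, chrom, gene_lo, gene_hi, start_bp, end_bp
    cells: pd.DataFrame     # row metadata (barcode, patient, source, ...)
    reference_cell_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    @property
    def barcodes(self) -> np.ndarray:
        return self.cells["barcode"].to_numpy()

    def subset(self, mask: np.ndarray) -> "CNVProfileSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CNVProfileSet(
            values=self.values[idx],
            windows=self.windows,
            cells=self.cells.iloc[idx].reset_index(drop=True),
            reference_cell_ids=self.reference_cell_ids,
        )

    def burden(self) -> np.ndarray:
        """Mean squared profile value per cell."""
        return (self.values**2).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.windows["window_id"].tolist()
        )
        df.insert(0, "barcode", self.barcodes)
        return df

    def windows_bed(self) -> pd.DataFrame:
        """Window extents as BED (half-open bp intervals)."""
        bed = self.windows[["chrom", "start_bp", "end_bp", "window_id"]].copy()
        bed["start_bp"] = bed["start_bp"] - 1  # BED is 0-based half-open
        return bed


def infer_cnv(
    m: AnnotatedMatrix,
    reference: np.ndarray | None = None,
    groups: pd.Series | None = None,
    window: int = 51,
    clip: float = 1.5,
    min_mean_count: float = 0.1,
    min_reference_cells: int = 20,
    stride: int | None = None,
    exclude: list[str] | None = None,
) -> CNVProfileSet:
    """Infer smoothed per-cell CNV profiles from expression.

    Pipeline: (1) drop genes with mean count below ``min_mean_count``;
    (2) centre each gene's log-normalised expression on the reference-cell
    mean; (3) clip to ``[-clip, clip]``; (4) within each chromosome take a
    flat moving average over ``window`` genes (truncated at chromosome ends),
    then keep every ``stride``-th position (default ``window // 2``) for
    storage; (5) subtract each cell's median; (6) re-centre each window on
    the reference mean, so reference cells sit at ~0 by construction.

    ``reference`` is a boolean cell mask (default: immune + stromal from
    ``m.cells["cell_type"]``).  If ``groups`` is given (e.g. the patient
    column), centring in steps 2 and 6 is done within each group against
    that group's own reference cells, while gene retention and window
    layout stay global so profiles remain comparable across groups.
    Genes are ordered internally by (chromosome, start), so the result is
    invariant to the input's gene column order.  Chromosomes with fewer
    than ``window / 2`` retained genes are skipped with a warning.

    ``exclude`` drops the listed gene symbols before windowing.  Genes with
    strong cell-state-specific regulation (proliferation, hypoxia and other
    program genes, cell-type markers) vary with a cell's state rather than
    its genome and would otherwise imprint on the dosage signal; callers
    that know such panels should exclude them.
    """
    if reference is None:
        if "cell_type" not in m.cells.columns:
            raise OrganofitError("no reference mask and no cell_type annotation")
        reference = m.cells["cell_type"].isin(REFERENCE_CELL_TYPES).to_numpy()
    reference = np.asarray(reference, dtype=bool)

    chrom_rank = {c: i for i, c in enumerate(CHROMOSOMES)}
    order = np.lexsort(
        (
            m.genes["gene_id"].to_numpy(),
            m.genes["start"].to_numpy(),
            m.genes["chrom"].map(chrom_rank).to_numpy(),
        )
    )
    mean_counts = np.asarray(m.counts.mean(axis=0)).ravel()
    order = order[mean_counts[order] >= min_mean_count]
    if exclude:
        banned = m.genes["symbol"].isin(exclude).to_numpy()
        order = order[~banned[order]]
    if order.size == 0:
        raise OrganofitError("no genes pass the mean-count filter")

    expr = get_lognorm(m)[:, order]
    genes = m.genes.iloc[order].reset_index(drop=True)

    if groups is None:
        groups = pd.Series(["all"] * m.n_cells)
    groups = pd.Series(np.asarray(groups), dtype=object)
    group_masks: dict[str, np.ndarray] = {
        g: (groups == g).to_numpy() for g in sorted(groups.unique())
    }
    for g, gm in group_masks.items():
        n_ref = int((gm & reference).sum())
        if n_ref < min_reference_cells:
            raise InsufficientCellsError(
                f"group {g!r}: {n_ref} reference cells < {min_reference_cells}"
            )

    centred = np.empty_like(expr)
    for gm in group_masks.values():
        ref_mean = expr[gm & reference].mean(axis=0)
        centred[gm] = expr[gm] - ref_mean
    np.clip(centred, -clip, clip, out=centred)

    if stride is None:
        stride = max(1, window // 2)
    half = window // 2
    smooth_cols: list[np.ndarray] = []
    win_rows: list[dict] = []
    chrom_of = genes["chrom"].to_numpy()
    for chrom in CHROMOSOMES:
        pos = np.flatnonzero(chrom_of == chrom)
        n_c = pos.size
        if n_c == 0:
            continue
        if n_c < window / 2:
            warnings.warn(
                f"{chrom}: only {n_c} retained genes (< window/2 = {window / 2:g}); skipped",
                stacklevel=2,
            )
            continue
        block = centred[:, pos]
        csum = np.cumsum(block, axis=1)
        csum = np.hstack([np.zeros((block.shape[0], 1)), csum])
        lo_all = pos[0]
        for c in range(0, n_c, stride):
            lo, hi = max(0, c - half), min(n_c, c + half + 1)
            smooth_cols.append((csum[:, hi] - csum[:, lo]) / (hi - lo))
            win_rows.append(
                {
                    "window_id": f"{chrom}:{c}",
                    "chrom": chrom,
                    "gene_lo": int(lo_all + lo),
                    "gene_hi": int(lo_all + hi),
                    "start_bp": int(genes["start"].iloc[lo_all + lo]),
                    "end_bp": int(genes["start"].iloc[lo_all + hi - 1]) + 1,
                }
            )
    if not smooth_cols:
        raise OrganofitError("every chromosome was skipped; window too large")
    values = np.column_stack(smooth_cols)

    values -= np.median(values, axis=1, keepdims=True)
    for gm in group_masks.values():
        values[gm] -= values[gm & reference].mean(axis=0)

    windows = pd.DataFrame(win_rows)
    return CNVProfileSet(
        values=values,
        windows=windows,
        cells=m.cells.reset_index(drop=True),
        reference_cell_ids=m.cells.loc[reference, "barcode"].to_numpy(),
    )


def two_means_1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 2-means partition of a 1-D sample.

    In one dimension the optimal 2-means split is a threshold on the sorted
    values, so it can be found exactly by scanning split points with prefix
    sums — no iterative clustering, no initialisation dependence.  Returns
    (labels in {0, 1} with 1 = upper cluster, cluster means [low, high]).
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    if n < 2:
        raise ValueError("need at least two points")
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    k = np.arange(1, n)  # size of the lower cluster
    ss_lo = csq[:-1] - csum[:-1] ** 2 / k
    ss_hi = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    split = int(np.argmin(ss_lo + ss_hi)) + 1
    labels = np.zeros(n, dtype=int)
    labels[order[split:]] = 1
    means = np.array([xs[:split].mean(), xs[split:].mean()])
    return labels, means


def call_malignancy(
    profiles: CNVProfileSet,
    corr_threshold: float = 0.3,
    min_epithelial: int = 10,
    burden_gap_tol: float = 0.02,
    groups: str = "patient",
) -> pd.DataFrame:
    """Split epithelial cells into malignant and benign by CNV burden.

    Per patient: 2-means clustering of epithelial cells on log burden
    (burden is a positive mean-square, so the log stabilises the variance of
    the aneuploid cluster and keeps a rare benign compartment separable); the
    higher-burden cluster's mean profile is the malignant centroid, and a
    cell is malignant iff it sits in the high-burden cluster *and* its
    profile correlates with that centroid above ``corr_threshold``.  If the
    two burden-cluster centres are indistinguishable — absolute gap below
    ``burden_gap_tol``, or below three pooled within-cluster standard
    deviations (what 2-means produces when it merely splits one unimodal
    cloud) — the patient is flagged ``no_malignant_compartment`` and every
    cell is benign.  Non-epithelial cells are always benign.
    """
    cells = profiles.cells
    if "cell_type" not in cells.columns:
        raise OrganofitError("profiles lack cell_type metadata")
    burden = profiles.burden()
    labels = np.full(profiles.n_cells, "benign", dtype=object)
    corr = np.full(profiles.n_cells, np.nan)
    flags = np.full(profiles.n_cells, "", dtype=object)

    for patient in sorted(cells[groups].unique()):
        epi = (
            (cells[groups] == patient) & (cells["cell_type"] == "epithelial")
        ).to_numpy()
        n_epi = int(epi.sum())
        if n_epi < min_epithelial:
            raise InsufficientCellsError(
                f"{patient}: {n_epi} epithelial cells < {min_epithelial}"
            )
        b = np.log(burden[epi] + 1e-12)
        km_labels, centers = two_means_1d(b)
        gap = float(centers[1] - centers[0])
        within_sd = float(
            np.mean([b[km_labels == k].std() for k in (0, 1) if (km_labels == k).sum() > 1])
        )
        if gap < burden_gap_tol or gap < 3.0 * within_sd:
            flags[epi] = "no_malignant_compartment"
            continue
        in_high = km_labels == 1
        high_idx = np.flatnonzero(epi)[in_high]
        centroid = profiles.values[high_idx].mean(axis=0)
        cz = centroid - centroid.mean()
        cn = np.linalg.norm(cz)
        vals = profiles.values[epi] - profiles.values[epi].mean(axis=1, keepdims=True)
        norms = np.linalg.norm(vals, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = vals @ cz / (norms * cn)
        corr[epi] = r
        mal = in_high & (r > corr_threshold)
        labels[np.flatnonzero(epi)[mal]] = "malignant"

    out = pd.DataFrame(
        {
            "barcode": profiles.barcodes,
            "patient": cells[groups].to_numpy(),
            "cell_type": cells["cell_type"].to_numpy(),
            "burden": burden,
            "corr_to_malignant_centroid": corr,
            "label": labels,
            "flag": flags,
        }
    )
    return out
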