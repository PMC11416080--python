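"""Domain containers, file formats and configuration.

The pipeline compares paired primary-tumour (PBC) and organoid (BCO)
single-cell expression matrices.  Everything downstream operates on a single
in-memory container, :class:`AnnotatedMatrix`: a sparse cell x gene count
matrix plus a gene table carrying genomic coordinates (needed to order genes
along chromosomes for expression-based CNV inference) and a cell table
carrying sample metadata (patient, source, subtype, cell-type and malignancy
labels).

On disk the package speaks plain-text formats only: MatrixMarket triplets for
counts, TSV sidecars for genes/barcodes/cell metadata, GMT for gene sets,
TSV for subtype centroids, Newick for trees, YAML for configuration and JSON
for run summaries.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SOURCES: tuple[str, ...] = ("PBC", "BCO")
SUBTYPES: tuple[str, ...] = ("HRpos", "HER2pos", "TNBC")
CELL_TYPES: tuple[str, ...] = ("epithelial", "immune", "stromal", "unknown")

#: numeric TSVs are written at this precision so re-reading reproduces the
#: report to 6 decimals
FLOAT_FORMAT = "%.6f"


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class OrganofitError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(OrganofitError):
    """Matrix shape disagrees with its gene or barcode sidecar."""


class MissingAnnotationError(OrganofitError):
    """A required gene/cell annotation column is absent."""


class DuplicateBarcodeError(OrganofitError):
    """The same cell barcode appears more than once."""


class EmptyResultError(OrganofitError):
    """An operation removed or excluded every cell."""


class InsufficientCellsError(OrganofitError):
    """Too few cells of the required kind to run an operation."""


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream.

    All randomness in the pipeline flows from one integer seed fanned out to
    named substreams, so that e.g. the permutation null and the simulator do
    not perturb each other when one of them changes.
    """
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------

GENE_COLUMNS = ("gene_id", "symbol", "chrom", "start")
CELL_COLUMNS = ("barcode", "patient", "source")


def validate_gene_table(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise MissingAnnotationError(f"gene table lacks columns {missing}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise MissingAnnotationError(f"duplicate gene_id {dup!r}")
    bad = set(genes["chrom"]) - set(CHROMOSOMES)
    if bad:
        raise MissingAnnotationError(f"unknown chromosomes {sorted(bad)}")
    if (genes["start"].astype(int) < 1).any():
        raise MissingAnnotationError("gene start coordinates must be >= 1 (1-based)")
    out = genes.reset_index(drop=True).copy()
    out["start"] = out["start"].astype(int)
    return out


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise MissingAnnotationError(f"cell table lacks columns {missing}")
    if cells["barcode"].duplicated().any():
        dup = cells.loc[cells["barcode"].duplicated(), "barcode"].iloc[0]
        raise DuplicateBarcodeError(f"duplicate barcode {dup!r}")
    bad = set(cells["source"]) - set(SOURCES)
    if bad:
        raise MissingAnnotationError(f"unknown sources {sorted(bad)}; expected {SOURCES}")
    return cells.reset_index(drop=True).copy()


# ---------------------------------------------------------------------------
# AnnotatedMatrix
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedMatrix:
    """Sparse cell x gene counts with gene coordinates and cell metadata.

    Cells are rows.  ``genes`` is indexed positionally in matrix column
    order; ``cells`` positionally in row order.  ``layers`` holds derived
    matrices of the same shape (e.g. ``"lognorm"``).
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = validate_gene_table(self.genes)
        self.cells = validate_cell_table(self.cells)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise DimensionMismatchError(
                f"counts {self.counts.shape} vs {len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise DimensionMismatchError(f"layer {name!r} shape {layer.shape}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> np.ndarray:
        return self.cells["barcode"].to_numpy()

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AnnotatedMatrix(
            counts=self.counts[idx],
            genes=self.genes,
            cells=self.cells.iloc[idx].reset_index(drop=True),
            layers={k: v[idx] for k, v in self.layers.items()},
        )

    def subset_genes(self, mask: np.ndarray) -> "AnnotatedMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AnnotatedMatrix(
            counts=self.counts[:, idx],
            genes=self.genes.iloc[idx].reset_index(drop=True),
            cells=self.cells,
            layers={k: v[:, idx] for k, v in self.layers.items()},
        )

    def gene_index(self, symbol: str) -> int:
        """Positional column index of a gene symbol; raises KeyError if absent."""
        hits = np.flatnonzero((self.genes["symbol"] == symbol).to_numpy())
        if hits.size == 0:
            raise KeyError(symbol)
        return int(hits[0])

    def concat(self, other: "AnnotatedMatrix") -> "AnnotatedMatrix":
        if not self.genes["gene_id"].equals(other.genes["gene_id"]):
            raise DimensionMismatchError("cannot concatenate matrices with different gene tables")
        layers = {
            k: np.vstack([self.layers[k], other.layers[k]])
            for k in self.layers
            if k in other.layers
        }
        return AnnotatedMatrix(
            counts=sp.vstack([self.counts, other.counts]).tocsr(),
            genes=self.genes,
            cells=pd.concat([self.cells, other.cells], ignore_index=True),
            layers=layers,
        )


def concat_matrices(mats: Sequence[AnnotatedMatrix]) -> AnnotatedMatrix:
    out = mats[0]
    for m in mats[1:]:
        out = out.concat(m)
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    cells_path: str | Path | None = None,
    orientation: str = "genes-by-cells",
) -> AnnotatedMatrix:
    """Read a MatrixMarket count matrix with its TSV sidecars.

    ``orientation`` declares how the MTX file is laid out; the 10x convention
    stores genes as rows (``"genes-by-cells"``, the default), which is
    transposed on read so cells are always rows internally.  Barcodes in
    ``barcodes.tsv`` align with matrix cells in record order.  If
    ``cells_path`` is given, its metadata is joined by barcode and every
    barcode must be present there.
    """
    mat = sp.coo_matrix(scipy.io.mmread(str(mtx_path)))
    if orientation == "genes-by-cells":
        mat = mat.T
    elif orientation != "cells-by-genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = mat.tocsr()

    genes = validate_gene_table(pd.read_csv(genes_path, sep="\t"))
    barcodes = pd.read_csv(barcodes_path, sep="\t")
    if "barcode" not in barcodes.columns:
        raise MissingAnnotationError("barcodes.tsv must have a 'barcode' column")
    if barcodes["barcode"].duplicated().any():
        raise DuplicateBarcodeError("duplicate barcodes in barcodes.tsv")

    if mat.shape[1] != len(genes):
        raise DimensionMismatchError(
            f"matrix has {mat.shape[1]} genes but gene table has {len(genes)}"
        )
    if mat.shape[0] != len(barcodes):
        raise DimensionMismatchError(
            f"matrix has {mat.shape[0]} cells but barcodes file has {len(barcodes)}"
        )

    if cells_path is not None:
        meta = validate_cell_table(pd.read_csv(cells_path, sep="\t"))
        joined = barcodes.merge(meta, on="barcode", how="left", validate="one_to_one")
        unmatched = joined["patient"].isna()
        if unmatched.any():
            missing = joined.loc[unmatched, "barcode"].iloc[0]
            raise MissingAnnotationError(f"barcode {missing!r} absent from cell metadata")
        cells = joined
    else:
        cells = barcodes.copy()
        cells["patient"] = "NA"
        cells["source"] = "PBC"

    return AnnotatedMatrix(counts=mat, genes=genes, cells=cells)


def write_matrix(m: AnnotatedMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx (genes x cells, 10x orientation) + genes/barcodes TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(m.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(out / "matrix.mtx"), counts, field="integer")
    m.genes.loc[:, list(GENE_COLUMNS)].to_csv(out / "genes.tsv", sep="\t", index=False)
    m.cells[["barcode"]].to_csv(out / "barcodes.tsv", sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise OrganofitError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + list(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Subtype centroid table: rows indexed by gene symbol, one column per subtype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise OrganofitError("centroid table needs at least two subtype columns")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults; YAML round-trippable.

    CNV windows are flat moving averages over ``cnv_window`` genes along each
    chromosome; profiles are clipped at ``cnv_clip`` on the log2 scale.  The
    deviation/retention statistics use the correlation threshold
    ``retention_tau`` and the minimum-evidence rule
    ``max(retention_min_abs, retention_min_frac * n_bco_malignant)``.
    """

    seed: int = 0
    # QC
    qc_min_genes_per_cell: int = 200
    qc_min_cells_per_gene: int = 3
    qc_max_mito_fraction: float = 0.2
    # cell typing
    tie_tolerance: float = 1e-6
    # CNV inference
    cnv_window: int = 51
    cnv_clip: float = 1.5
    cnv_min_mean_count: float = 0.1
    cnv_min_reference_cells: int = 20
    # malignancy
    malignancy_corr_threshold: float = 0.3
    malignancy_min_epithelial: int = 10
    # clones & fidelity
    clone_k_min: int = 2
    clone_k_max: int = 6
    clone_min_cells: int = 20
    retention_tau: float = 0.5
    retention_min_abs: int = 5
    retention_min_frac: float = 0.01
    preserved_min_retention: float = 0.5
    cnv_change_delta: float = 0.15
    n_permutations: int = 100
    # signature scoring
    score_n_bins: int = 25
    score_n_ctrl: int = 100
    stem_kmeans_k: int = 6
    stem_n_pcs: int = 50
    # composition
    composition_epsilon: float = 1e-3
    # resource paths (relative to the run directory unless absolute)
    gene_sets_path: str = "data/gene_sets/signatures.gmt"
    marker_panels_path: str = "data/gene_sets/cell_type_markers.gmt"
    centroids_path: str = "data/centroids.tsv"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise OrganofitError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)


# ---------------------------------------------------------------------------
# report container and writer
# ---------------------------------------------------------------------------

@dataclass
class FidelityReport:
    """Collected outputs of the fidelity pipeline for one run.

    All frames may be empty (zero patients) but must carry their columns so
    headers round-trip.
    """

    deviation_scores: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient", "barcode", "D_paired", "D_background", "D_random"]
        )
    )
    deviation_tests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient", "comparison", "t", "p"]
        )
    )
    retention: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient", "subtype", "retention_rate", "n_clones", "n_retained", "preserved"]
        )
    )
    retention_by_subtype: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subtype", "mean_retention", "n_patients"])
    )
    composition_tests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cell_type", "mean_fc", "median_fc", "iqr", "t", "df", "p", "p_adj", "flag"]
        )
    )
    trees: dict[str, str] = field(default_factory=dict)  # patient -> newick

    def summary(self) -> dict:
        out: dict = {"n_patients": int(len(self.retention))}
        if len(self.retention):
            out["mean_retention"] = float(self.retention["retention_rate"].mean())
            out["retention_by_subtype"] = {
                str(r["subtype"]): float(r["mean_retention"])
                for _, r in self.retention_by_subtype.iterrows()
            }
            out["retention_by_patient"] = {
                str(r["patient"]): float(r["retention_rate"])
                for _, r in self.retention.iterrows()
            }
        return out


def write_report(report: FidelityReport, out_dir: str | Path) -> list[Path]:
    """Write the report as TSV tables, a JSON summary, and Newick trees."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "deviation_scores.tsv": report.deviation_scores,
        "deviation_tests.tsv": report.deviation_tests,
        "retention.tsv": report.retention,
        "retention_by_subtype.tsv": report.retention_by_subtype,
        "composition_tests.tsv": report.composition_tests,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report.summary(), indent=2, sort_keys=True) + "\n")
    written.append(summary_path)
    if report.trees:
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for patient in sorted(report.trees):
            path = tree_dir / f"{patient}.nwk"
            path.write_text(report.trees[patient])
            written.append(path)
    return written
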