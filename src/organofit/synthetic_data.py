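"""Paired primary-tumour / organoid scRNA-seq simulator with known truth.

The generator emulates the structure of a paired-design organoid fidelity
study: for each patient it emits a primary-tissue (PBC) sample and a matched
organoid (BCO) sample drawn from the same clonal architecture, so that every
downstream statistic (CNV inference, clone clustering, deviation scores,
retention rates, composition tests, signature scoring, subtype calls) can be
checked against designed ground truth.

Model
-----
Counts for cell *i*, gene *j* are negative binomial with mean

    mu_ij = L_i * m_ij / sum_j m_ij ,   Var = mu + mu^2 / theta ,

where ``L_i`` is a log-normal library size and ``m_ij`` is the product of a
per-gene relative abundance and multiplicative effects:

* **CNV dosage** — malignant cells carry their clone's segments; expression
  of segment genes is multiplied by ``copy_ratio ** alpha``.  Immune and
  stromal cells are CNV-neutral.
* **cell-type markers** — each of the epithelial / immune / stromal panels
  is boosted in its own compartment.
* **subtype program** — malignant cells over-express their molecular
  subtype's marker panel (ESR1 for HR-positive, ERBB2 for HER2-positive, a
  basal panel for TNBC; TNBC malignant cells additionally suppress
  CLDN3/4/7 and CDH1, the claudin-low phenotype).
* **hypoxia / stem-cell-division programs** — each cell carries latent
  activities ``a_h = b_h + z_h`` and ``a_s = b_s + z_s`` with ``(z_h, z_s)``
  bivariate standard normal at correlation ``rho``; an activity multiplies
  its signature genes' abundance by ``exp(beta * a)``.  Organoid culture is
  oxygen-rich, so the whole hypoxia activity of BCO cells is scaled by the
  attenuation factor ``delta_h`` in [0, 1].  A clone flagged ``stem`` gets a
  positive shift on both activities plus CD44-high / ALDH1A2-low marker
  expression, and can be given ``bco_fraction = 0`` to model the loss of a
  stem/hypoxia subpopulation in culture.

Row-normalising ``m`` makes the realised library size independent of CNV
load, as in real data where sequencing depth is a technical property of the
cell, not of its genome.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    AnnotatedMatrix,
    CHROMOSOMES,
    OrganofitError,
    substream,
    write_gmt,
    write_matrix,
)

COMPARTMENTS = ("epithelial-malignant", "epithelial-benign", "immune", "stromal")

#: compartment -> three-way cell type used by annotation / composition
COMPARTMENT_CELL_TYPE = {
    "epithelial-malignant": "epithelial",
    "epithelial-benign": "epithelial",
    "immune": "immune",
    "stromal": "stromal",
}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNVSegmentSpec:
    """A copy-number event on one chromosome.

    ``gene_span`` is a half-open index range *within* the chromosome's gene
    order (``None`` = whole chromosome); ``copy_ratio`` is 1.0 for neutral,
    2.0 for a one-copy gain of a diploid locus, 0.5 for a one-copy loss.
    """

    chrom: str
    copy_ratio: float
    gene_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        if self.gene_span is not None and self.gene_span[0] >= self.gene_span[1]:
            raise ValueError("gene_span must be a non-empty half-open [lo, hi)")


@dataclass(frozen=True)
class CloneSpec:
    clone_id: str
    segments: tuple[CNVSegmentSpec, ...]
    pbc_fraction: float
    bco_fraction: float
    stem: bool = False  # CD44-high / ALDH1A2-low, hypoxia+stemness shifted


@dataclass(frozen=True)
class PatientSpec:
    patient: str
    subtype: str
    composition_pbc: dict[str, float]  # simplex over COMPARTMENTS
    composition_bco: dict[str, float]
    clones: tuple[CloneSpec, ...]
    n_cells_pbc: int = 500
    n_cells_bco: int = 450

    def __post_init__(self) -> None:
        for comp in (self.composition_pbc, self.composition_bco):
            if set(comp) != set(COMPARTMENTS):
                raise ValueError(f"composition must cover {COMPARTMENTS}")
            if abs(sum(comp.values()) - 1.0) > 1e-8:
                raise ValueError("composition must sum to 1")
        if self.n_cells_pbc < 1 or self.n_cells_bco < 1:
            raise ValueError("need at least one cell per sample")
        for attr in ("pbc_fraction", "bco_fraction"):
            total = sum(getattr(c, attr) for c in self.clones)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"clone {attr}s must sum to 1 (got {total:g})")

    @property
    def designed_retention(self) -> float:
        """PBC-cell-weighted fraction of clones that survive into the organoid."""
        return float(sum(c.pbc_fraction for c in self.clones if c.bco_fraction > 0))


@dataclass
class SimParams:
    """Global simulator parameters, shared across the patients of one study."""

    n_genes: int = 2000
    n_chromosomes: int = 22
    n_cnv_chromosomes: int = 14   # chr1..chr14 may carry events; the rest host markers
    baseline_sigma: float = 1.0   # log-normal spread of relative gene abundance
    theta: float = 10.0           # NB dispersion, Var = mu + mu^2/theta (UMI-scale noise)
    alpha: float = 1.0            # dosage exponent: multiplier = copy_ratio**alpha
    lib_mean: float = 6000.0      # expected counts per cell
    lib_sigma: float = 0.3        # log-normal sigma of library size
    marker_boost: float = 8.0     # cell-type panel fold change in its compartment
    subtype_boost: float = 4.0    # subtype panel fold change in malignant cells
    panel_size: int = 25
    subtype_panel_size: int = 30
    n_hypoxia_genes: int = 150
    n_stemdiv_genes: int = 150
    n_proliferation_genes: int = 40
    beta_signature: float = 0.7   # natural-log fold change per unit latent activity
    signature_abundance_shift: float = 1.0  # median abundance multiplier of signature genes
    rho: float = 0.5              # latent correlation, hypoxia vs stem-cell-division
    hypoxia_baseline: float = 1.0  # tissue-level hypoxic activity (latent SD units)
    stemdiv_baseline: float = 0.5
    delta_h: float = 0.5          # BCO hypoxia attenuation in [0, 1]
    stem_shift: float = 1.5       # latent shift for stem-flagged clones
    proliferation_boost: float = 2.0       # malignant over benign
    bco_proliferation_boost: float = 1.5   # extra boost in organoid malignant cells
    claudin_low_factor: float = 0.3        # CLDN/CDH1 suppression in TNBC malignant
    cd44_stem_boost: float = 6.0
    aldh1a2_stem_factor: float = 0.1
    esr1_bco_factor: float = 0.5  # ESR1 attenuation in HR-positive organoid cells
    max_marker_segment_overlap: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must be in [-1, 1]")
        if not 0 <= self.delta_h <= 1:
            raise ValueError("delta_h must be in [0, 1]")
        if self.n_cnv_chromosomes >= self.n_chromosomes:
            raise ValueError("need at least one CNV-free chromosome for marker genes")


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------

@dataclass
class GeneUniverse:
    """Fixed gene annotation shared by every sample of a simulated study."""

    genes: pd.DataFrame                     # gene_id, symbol, chrom, start
    baseline: np.ndarray                    # relative abundance per gene
    chrom_slices: dict[str, tuple[int, int]]
    cell_type_panels: dict[str, list[int]]  # epithelial/immune/stromal -> indices
    subtype_panels: dict[str, list[int]]    # HRpos/HER2pos/TNBC -> indices
    signatures: dict[str, list[int]]        # hypoxia/stem_cell_division/proliferation
    special: dict[str, int]                 # symbol -> column index

    def symbols(self, indices: list[int]) -> list[str]:
        return self.genes["symbol"].iloc[indices].tolist()

    def segment_gene_indices(self, seg: CNVSegmentSpec) -> np.ndarray:
        lo, hi = self.chrom_slices[seg.chrom]
        if seg.gene_span is None:
            return np.arange(lo, hi)
        a, b = seg.gene_span
        if b > hi - lo:
            raise ValueError(f"gene_span {seg.gene_span} exceeds {seg.chrom} size {hi - lo}")
        return np.arange(lo + a, lo + b)


def build_universe(params: SimParams) -> GeneUniverse:
    """Lay genes out over pseudo-chromosomes and pick marker/signature genes.

    CNV events are restricted to the first ``n_cnv_chromosomes``; marker and
    signature genes live on the remaining chromosomes so cell-type and
    program expression differences cannot masquerade as copy-number signal.
    Marker-type genes get a floor on baseline abundance — markers are, by
    selection, genes one can detect.
    """
    rng = substream(params.seed, "universe")
    n, n_chrom = params.n_genes, params.n_chromosomes
    per = np.full(n_chrom, n // n_chrom)
    per[: n % n_chrom] += 1
    chrom_names = list(CHROMOSOMES[:n_chrom])
    chroms = np.repeat(chrom_names, per)
    within = np.concatenate([np.arange(k) for k in per])
    genes = pd.DataFrame(
        {
            "gene_id": [f"ENSG{i:05d}" for i in range(n)],
            "symbol": [f"G{i:04d}" for i in range(n)],
            "chrom": chroms,
            "start": (within + 1) * 100_000,
        }
    )
    chrom_slices: dict[str, tuple[int, int]] = {}
    pos = 0
    for c, k in zip(chrom_names, per):
        chrom_slices[c] = (pos, pos + int(k))
        pos += int(k)

    baseline = rng.lognormal(mean=0.0, sigma=params.baseline_sigma, size=n)

    neutral_lo = chrom_slices[chrom_names[params.n_cnv_chromosomes]][0]
    pool = rng.permutation(np.arange(neutral_lo, n)).tolist()

    def take(k: int) -> list[int]:
        if len(pool) < k:
            raise OrganofitError("not enough CNV-free genes for marker/signature panels")
        out = pool[:k]
        del pool[:k]
        return sorted(out)

    cell_type_panels = {
        "epithelial": take(params.panel_size),
        "immune": take(params.panel_size),
        "stromal": take(params.panel_size),
    }
    subtype_panels = {
        "HRpos": take(params.subtype_panel_size),
        "HER2pos": take(params.subtype_panel_size),
        "TNBC": take(params.subtype_panel_size),
    }
    signatures = {
        "hypoxia": take(params.n_hypoxia_genes),
        "stem_cell_division": take(params.n_stemdiv_genes),
        "proliferation": take(params.n_proliferation_genes),
    }
    special_syms = ["CD44", "ALDH1A2", "CLDN3", "CLDN4", "CLDN7", "CDH1"]
    special = {s: take(1)[0] for s in special_syms}
    # named genes embedded in their natural panels
    special["ESR1"] = subtype_panels["HRpos"][0]
    special["ERBB2"] = subtype_panels["HER2pos"][0]
    special["MKI67"] = signatures["proliferation"][0]
    symbols = genes["symbol"].to_numpy().copy()
    for sym, idx in special.items():
        symbols[idx] = sym
    for panel, prefix in (
        (cell_type_panels["epithelial"], "EPI"),
        (cell_type_panels["immune"], "IMM"),
        (cell_type_panels["stromal"], "STR"),
    ):
        for rank, idx in enumerate(panel):
            symbols[idx] = f"{prefix}{rank:02d}"
    genes["symbol"] = symbols

    # marker genes are, by selection, detectable: redraw their abundance from
    # the upper half of the log-normal (keeps spread, no ties)
    for indices in [*cell_type_panels.values(), *subtype_panels.values(),
                    list(special.values())]:
        idx = np.asarray(indices, dtype=int)
        baseline[idx] = np.exp(
            params.baseline_sigma * np.abs(rng.standard_normal(idx.size))
        )
    # signature genes keep the full log-normal spread (so bin-matched control
    # pools are not dominated by other signatures' genes), shifted modestly
    # upward: program genes of a solid tumour are moderately expressed
    for indices in signatures.values():
        idx = np.asarray(indices, dtype=int)
        baseline[idx] = params.signature_abundance_shift * rng.lognormal(
            mean=0.0, sigma=params.baseline_sigma, size=idx.size
        )

    return GeneUniverse(
        genes=genes,
        baseline=baseline,
        chrom_slices=chrom_slices,
        cell_type_panels=cell_type_panels,
        subtype_panels=subtype_panels,
        signatures=signatures,
        special=special,
    )


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass
class TruthTables:
    """Designed ground truth accompanying a simulated patient pair.

    ``patients`` has one row per patient: subtype and designed retention
    (the PBC-fraction sum over clones with ``bco_fraction > 0``, exactly).
    """

    cells: pd.DataFrame      # barcode, patient, source, compartment, cell_type,
                             # malignant, clone_id, hypoxia_activity, stemdiv_activity
    segments: pd.DataFrame   # patient, clone_id, chrom, gene_start, gene_end, copy_ratio
    patients: pd.DataFrame   # patient, subtype, designed_retention
    designed_rho: float

    @property
    def designed_retention(self) -> float:
        """Mean designed retention over patients."""
        return float(self.patients["designed_retention"].mean())

    @staticmethod
    def merge(truths: list["TruthTables"]) -> "TruthTables":
        return TruthTables(
            cells=pd.concat([t.cells for t in truths], ignore_index=True),
            segments=pd.concat([t.segments for t in truths], ignore_index=True),
            patients=pd.concat([t.patients for t in truths], ignore_index=True),
            designed_rho=truths[0].designed_rho,
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _check_marker_overlap(spec: PatientSpec, params: SimParams, uni: GeneUniverse) -> None:
    seg_genes: set[int] = set()
    for clone in spec.clones:
        for seg in clone.segments:
            seg_genes.update(uni.segment_gene_indices(seg).tolist())
    all_markers = [i for p in uni.cell_type_panels.values() for i in p]
    if not all_markers:
        return
    frac = len(seg_genes.intersection(all_markers)) / len(all_markers)
    if frac > params.max_marker_segment_overlap:
        warnings.warn(
            f"{spec.patient}: {frac:.0%} of cell-type marker genes fall inside "
            "CNV truth segments; type annotation may bleed into CNV signal",
            stacklevel=3,
        )


def _dosage_vector(clone: CloneSpec, params: SimParams, uni: GeneUniverse) -> np.ndarray:
    d = np.ones(params.n_genes)
    for seg in clone.segments:
        d[uni.segment_gene_indices(seg)] *= seg.copy_ratio ** params.alpha
    return d


def simulate_pair(
    spec: PatientSpec,
    params: SimParams,
    universe: GeneUniverse | None = None,
) -> tuple[AnnotatedMatrix, TruthTables]:
    """Simulate the matched PBC + BCO samples of one patient.

    Returns one :class:`AnnotatedMatrix` holding both sources (the ``source``
    column distinguishes them) and the :class:`TruthTables` recording each
    cell's compartment, clone and latent activities.
    """
    uni = universe if universe is not None else build_universe(params)
    _check_marker_overlap(spec, params, uni)
    rng = substream(params.seed, f"simulate:{spec.patient}")
    chol = np.linalg.cholesky(np.array([[1.0, params.rho], [params.rho, 1.0]]))

    blocks: list[sp.csr_matrix] = []
    rows: list[dict] = []
    for source, n_cells, comp in (
        ("PBC", spec.n_cells_pbc, spec.composition_pbc),
        ("BCO", spec.n_cells_bco, spec.composition_bco),
    ):
        comp_counts = rng.multinomial(n_cells, [comp[c] for c in COMPARTMENTS])
        compartment = np.repeat(COMPARTMENTS, comp_counts)
        n = len(compartment)
        malignant = compartment == "epithelial-malignant"

        clone_ids = np.full(n, "", dtype=object)
        frac_attr = "pbc_fraction" if source == "PBC" else "bco_fraction"
        fracs = np.array([getattr(c, frac_attr) for c in spec.clones])
        n_mal = int(malignant.sum())
        if n_mal and fracs.sum() > 0:
            clone_counts = rng.multinomial(n_mal, fracs / fracs.sum())
            clone_ids[malignant] = np.repeat(
                [c.clone_id for c in spec.clones], clone_counts
            )
        stem_clones = {c.clone_id for c in spec.clones if c.stem}
        is_stem = np.isin(clone_ids, list(stem_clones))

        # latent activities (all cells; hypoxia acts tissue-wide)
        z = rng.standard_normal((n, 2)) @ chol.T
        a_h = params.hypoxia_baseline + z[:, 0] + params.stem_shift * is_stem
        a_s = params.stemdiv_baseline + z[:, 1] + params.stem_shift * is_stem
        if source == "BCO":
            a_h = a_h * params.delta_h

        m = np.tile(uni.baseline, (n, 1))
        for ct, panel in uni.cell_type_panels.items():
            mask = np.array([COMPARTMENT_CELL_TYPE[c] == ct for c in compartment])
            m[np.ix_(mask, panel)] *= params.marker_boost
        if n_mal:
            m[np.ix_(malignant, uni.subtype_panels[spec.subtype])] *= params.subtype_boost
            for clone in spec.clones:
                members = clone_ids == clone.clone_id
                if members.any():
                    m[members] *= _dosage_vector(clone, params, uni)[None, :]
            prolif = uni.signatures["proliferation"]
            boost = params.proliferation_boost
            if source == "BCO":
                boost *= params.bco_proliferation_boost
            m[np.ix_(malignant, prolif)] *= boost
            if spec.subtype == "TNBC":
                claudins = [uni.special[g] for g in ("CLDN3", "CLDN4", "CLDN7", "CDH1")]
                m[np.ix_(malignant, claudins)] *= params.claudin_low_factor
            if spec.subtype == "HRpos" and source == "BCO":
                m[malignant, uni.special["ESR1"]] *= params.esr1_bco_factor
            if is_stem.any():
                m[is_stem, uni.special["CD44"]] *= params.cd44_stem_boost
                m[is_stem, uni.special["ALDH1A2"]] *= params.aldh1a2_stem_factor
        m[:, uni.signatures["hypoxia"]] *= np.exp(params.beta_signature * a_h)[:, None]
        m[:, uni.signatures["stem_cell_division"]] *= np.exp(
            params.beta_signature * a_s
        )[:, None]

        lib = rng.lognormal(
            mean=np.log(params.lib_mean) - params.lib_sigma**2 / 2,
            sigma=params.lib_sigma,
            size=n,
        )
        mu = m / m.sum(axis=1, keepdims=True) * lib[:, None]
        counts = rng.negative_binomial(params.theta, params.theta / (params.theta + mu))
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))

        for i in range(n):
            rows.append(
                {
                    "barcode": f"{spec.patient}_{source}_{i:04d}",
                    "patient": spec.patient,
                    "source": source,
                    "subtype": spec.subtype,
                    "compartment": compartment[i],
                    "cell_type": COMPARTMENT_CELL_TYPE[compartment[i]],
                    "malignant": bool(malignant[i]),
                    "clone_id": clone_ids[i],
                    "hypoxia_activity": float(a_h[i]),
                    "stemdiv_activity": float(a_s[i]),
                }
            )

    truth_cells = pd.DataFrame(rows)
    seg_rows = []
    for clone in spec.clones:
        for seg in clone.segments:
            idx = uni.segment_gene_indices(seg)
            seg_rows.append(
                {
                    "patient": spec.patient,
                    "clone_id": clone.clone_id,
                    "chrom": seg.chrom,
                    "gene_start": int(idx[0]),
                    "gene_end": int(idx[-1]) + 1,
                    "start_bp": int(uni.genes["start"].iloc[idx[0]]),
                    "end_bp": int(uni.genes["start"].iloc[idx[-1]]) + 1,
                    "copy_ratio": seg.copy_ratio,
                }
            )
    segments = pd.DataFrame(
        seg_rows,
        columns=[
            "patient", "clone_id", "chrom", "gene_start", "gene_end",
            "start_bp", "end_bp", "copy_ratio",
        ],
    )

    cells = truth_cells[["barcode", "patient", "source", "subtype"]].copy()
    matrix = AnnotatedMatrix(
        counts=sp.vstack(blocks).tocsr(),
        genes=uni.genes,
        cells=cells,
    )
    truth = TruthTables(
        cells=truth_cells,
        segments=segments,
        patients=pd.DataFrame(
            {
                "patient": [spec.patient],
                "subtype": [spec.subtype],
                "designed_retention": [spec.designed_retention],
            }
        ),
        designed_rho=params.rho,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# the six-patient study preset
# ---------------------------------------------------------------------------

def _chrom_event(chrom: str, ratio: float) -> CNVSegmentSpec:
    return CNVSegmentSpec(chrom=chrom, copy_ratio=ratio)


def _clone(
    clone_id: str,
    truncal: tuple[CNVSegmentSpec, ...],
    private: list[tuple[str, float]],
    pbc: float,
    bco: float,
    stem: bool = False,
) -> CloneSpec:
    segs = truncal + tuple(_chrom_event(c, r) for c, r in private)
    return CloneSpec(clone_id, segs, pbc, bco, stem=stem)


def preset_study(seed: int = 0) -> tuple[list[PatientSpec], SimParams]:
    """The default six-patient paired study: 2 HR-positive, 2 HER2-positive, 2 TNBC.

    Clonal architecture follows the usual truncal/branch structure of breast
    tumours: every clone of a patient shares two truncal whole-chromosome
    events (always including the recurrent chr8 gain, MYC-like) and adds two
    private events, so all clones of a patient carry an equal CNV load while
    remaining mutually distinguishable, and foreign patients' profiles are
    related (recurrent events) but distinct — which is what separates the
    paired, background and random comparisons.  Both TNBC patients include a
    stem/hypoxia-high clone with ``bco_fraction = 0``, modelling the loss of
    that subpopulation under oxygen-rich culture; organoid compositions are
    nearly all-epithelial.

    Designed retentions: P01 1.00, P02 0.80 (HR-positive), P03 0.80,
    P04 0.55 (HER2-positive), P05 0.75, P06 0.45 (TNBC).
    """
    params = SimParams(seed=seed)
    g, l = 2.0, 0.5  # one-copy gain / loss ratios
    chr8 = _chrom_event("chr8", g)

    def patient(pid, subtype, clones, comp_pbc):
        return PatientSpec(
            patient=pid,
            subtype=subtype,
            composition_pbc=comp_pbc,
            composition_bco=bco_comp,
            clones=clones,
        )

    def comp(em, eb, imm, strm):
        return dict(zip(COMPARTMENTS, (em, eb, imm, strm)))

    bco_comp = comp(0.92, 0.06, 0.013, 0.007)
    t01 = (chr8, _chrom_event("chr1", g))
    t02 = (chr8, _chrom_event("chr5", l))
    t03 = (chr8, _chrom_event("chr2", g))
    t04 = (chr8, _chrom_event("chr6", l))
    t05 = (chr8, _chrom_event("chr4", g))
    t06 = (chr8, _chrom_event("chr7", g))
    patients = [
        patient(
            "P01", "HRpos",
            (
                _clone("P01_A", t01, [("chr2", g), ("chr3", l)], 0.60, 0.60),
                _clone("P01_B", t01, [("chr5", l), ("chr12", l)], 0.40, 0.40),
            ),
            comp(0.46, 0.10, 0.30, 0.14),
        ),
        patient(
            "P02", "HRpos",
            (
                _clone("P02_A", t02, [("chr3", g), ("chr10", g)], 0.45, 0.55),
                _clone("P02_B", t02, [("chr7", g), ("chr14", g)], 0.35, 0.45),
                _clone("P02_C", t02, [("chr11", g), ("chr13", g)], 0.20, 0.0),
            ),
            comp(0.42, 0.12, 0.32, 0.14),
        ),
        patient(
            "P03", "HER2pos",
            (
                _clone("P03_A", t03, [("chr1", l), ("chr4", g)], 0.50, 0.65),
                _clone("P03_B", t03, [("chr9", l), ("chr6", l)], 0.30, 0.35),
                _clone("P03_C", t03, [("chr12", g), ("chr10", g)], 0.20, 0.0),
            ),
            comp(0.50, 0.08, 0.28, 0.14),
        ),
        patient(
            "P04", "HER2pos",
            (
                _clone("P04_A", t04, [("chr2", l), ("chr7", l)], 0.35, 0.60),
                _clone("P04_B", t04, [("chr10", g), ("chr11", l)], 0.20, 0.40),
                _clone("P04_C", t04, [("chr13", l), ("chr14", l)], 0.45, 0.0),
            ),
            comp(0.44, 0.10, 0.31, 0.15),
        ),
        patient(
            "P05", "TNBC",
            (
                _clone("P05_A", t05, [("chr1", g), ("chr9", g)], 0.45, 0.75),
                _clone("P05_B", t05, [("chr13", l), ("chr6", g)], 0.30, 0.25),
                _clone("P05_C", t05, [("chr14", g), ("chr12", l)], 0.25, 0.0, stem=True),
            ),
            comp(0.48, 0.08, 0.29, 0.15),
        ),
        patient(
            "P06", "TNBC",
            (
                _clone("P06_A", t06, [("chr2", g), ("chr5", g)], 0.30, 0.80),
                _clone("P06_B", t06, [("chr9", l), ("chr4", l)], 0.15, 0.20),
                _clone("P06_C", t06, [("chr10", l), ("chr1", g)], 0.55, 0.0, stem=True),
            ),
            comp(0.45, 0.09, 0.30, 0.16),
        ),
    ]
    return patients, params


def retention_sweep_patient(level: float, patient: str = "PS") -> PatientSpec:
    """A single-patient design whose designed retention equals ``level``.

    Two equally CNV-loaded clones: clone A (PBC fraction ``level``) survives
    into the organoid, clone B (``1 - level``) is lost.  At ``level == 1``
    both clones survive.  Used for the retention-recovery sweep.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    g, l = 2.0, 0.5
    truncal = (_chrom_event("chr8", g), _chrom_event("chr3", g))
    a = _clone(f"{patient}_A", truncal, [("chr1", g), ("chr5", l)],
               level if level < 1.0 else 0.6,
               1.0 if level < 1.0 else 0.6)
    b = _clone(f"{patient}_B", truncal, [("chr9", l), ("chr12", g)],
               1.0 - level if level < 1.0 else 0.4,
               0.0 if level < 1.0 else 0.4)
    return PatientSpec(
        patient=patient,
        subtype="HRpos",
        composition_pbc=dict(zip(COMPARTMENTS, (0.50, 0.08, 0.28, 0.14))),
        composition_bco=dict(zip(COMPARTMENTS, (0.92, 0.06, 0.013, 0.007))),
        clones=(a, b),
    )


def rho_recovery_patient(
    n_pbc: int = 2300, n_bco: int = 1200, patient: str = "PR"
) -> PatientSpec:
    """A mostly-malignant single-clone patient for latent-coupling recovery.

    Both sources draw from one clone, so PBC/BCO differences reduce to the
    organoid hypoxia attenuation ``delta_h``; the large malignant count
    gives the per-cell score correlation a stable estimate.
    """
    clone = CloneSpec("PR_A", (_chrom_event("chr8", 2.0),), 1.0, 1.0)
    comp = dict(zip(COMPARTMENTS, (0.88, 0.02, 0.06, 0.04)))
    return PatientSpec(
        patient=patient,
        subtype="TNBC",
        composition_pbc=comp,
        composition_bco=comp,
        clones=(clone,),
        n_cells_pbc=n_pbc,
        n_cells_bco=n_bco,
    )


def simulate_study(
    specs: list[PatientSpec], params: SimParams
) -> tuple[AnnotatedMatrix, TruthTables, GeneUniverse]:
    """Simulate all patients of a study on one shared gene universe."""
    uni = build_universe(params)
    mats, truths = [], []
    for spec in specs:
        m, t = simulate_pair(spec, params, universe=uni)
        mats.append(m)
        truths.append(t)
    matrix = mats[0]
    for m in mats[1:]:
        matrix = matrix.concat(m)
    truth = TruthTables.merge(truths)
    return matrix, truth, uni


# ---------------------------------------------------------------------------
# truth-based evaluation helpers
# ---------------------------------------------------------------------------

def segment_detection_auroc(profiles, truth: TruthTables) -> pd.DataFrame:
    """How well |CNV| separates windows inside truth segments from neutral ones.

    For each designed clone with enough cells, the clone's mean |profile| is
    scored against window labels: positive = window fully inside one of the
    clone's segments, negative = window on no segment; windows straddling a
    segment boundary are excluded.  Returns one AUROC per (patient, clone).
    """
    from sklearn.metrics import roc_auc_score

    aligned = truth.cells.set_index("barcode").reindex(profiles.barcodes)
    w = profiles.windows
    rows = []
    for (patient, clone), seg_grp in truth.segments.groupby(
        ["patient", "clone_id"], sort=True
    ):
        members = (
            (aligned["patient"] == patient) & (aligned["clone_id"] == clone)
        ).to_numpy()
        if members.sum() < 5:
            continue
        centroid = np.abs(profiles.values[members].mean(axis=0))
        inside = np.zeros(len(w), dtype=bool)
        partial = np.zeros(len(w), dtype=bool)
        for _, s in seg_grp.iterrows():
            on = (w["chrom"] == s["chrom"]).to_numpy()
            full = on & (w["start_bp"] >= s["start_bp"]).to_numpy() & (
                w["end_bp"] <= s["end_bp"]
            ).to_numpy()
            inside |= full
            partial |= on & ~full
        keep = ~(partial & ~inside)
        labels = inside[keep]
        if labels.sum() == 0 or labels.all():
            continue
        rows.append(
            {
                "patient": patient,
                "clone_id": clone,
                "auroc": float(roc_auc_score(labels, centroid[keep])),
            }
        )
    return pd.DataFrame(rows, columns=["patient", "clone_id", "auroc"])


# ---------------------------------------------------------------------------
# generator-emitted resources (marker panels, signatures, subtype centroids)
# ---------------------------------------------------------------------------

def marker_panel_sets(uni: GeneUniverse) -> dict[str, list[str]]:
    return {ct: uni.symbols(idx) for ct, idx in uni.cell_type_panels.items()}


def signature_sets(uni: GeneUniverse) -> dict[str, list[str]]:
    out = {name: uni.symbols(idx) for name, idx in uni.signatures.items()}
    out["claudin_low"] = ["CLDN3", "CLDN4", "CLDN7", "CDH1"]
    out["subtype_markers"] = sorted(
        s for idx in uni.subtype_panels.values() for s in uni.symbols(idx)
    )
    return out


def subtype_centroids(uni: GeneUniverse, params: SimParams) -> pd.DataFrame:
    """Expected malignant-cell log-normal expression of subtype marker genes.

    The centroid of subtype *s* holds each marker gene's expected
    log2-normalised expression in a malignant cell of that subtype:
    own-subtype markers boosted, foreign markers at baseline.  Values are
    analytic (no sampling), so the table is deterministic given the universe.
    """
    marker_idx = sorted(i for idx in uni.subtype_panels.values() for i in idx)
    total = uni.baseline.sum()
    cols = {}
    for s, own in uni.subtype_panels.items():
        m = uni.baseline[marker_idx].copy()
        own_mask = np.isin(marker_idx, own)
        m[own_mask] *= params.subtype_boost
        cols[s] = np.log2(1 + 1e4 * m / total)
    return pd.DataFrame(cols, index=uni.symbols(marker_idx)).rename_axis("gene")


# ---------------------------------------------------------------------------
# on-disk study layout
# ---------------------------------------------------------------------------

def write_study(
    out_dir: str | Path,
    matrix: AnnotatedMatrix,
    truth: TruthTables,
    uni: GeneUniverse,
    params: SimParams,
) -> None:
    """Write the directory layout the CLI stages consume.

    ``data/`` holds per-sample MTX matrices with sidecars, the combined cell
    table, gene sets and the centroid table; ``truth/`` holds the designed
    ground truth for validation.
    """
    out = Path(out_dir)
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    matrix.cells.to_csv(data / "cells.tsv", sep="\t", index=False)
    for (patient, source), idx in matrix.cells.groupby(
        ["patient", "source"], sort=True
    ).indices.items():
        sub = matrix.subset_cells(np.asarray(idx))
        write_matrix(sub, data / "samples" / f"{patient}_{source}")
    sets_dir = data / "gene_sets"
    sets_dir.mkdir(exist_ok=True)
    write_gmt(marker_panel_sets(uni), sets_dir / "cell_type_markers.gmt")
    write_gmt(signature_sets(uni), sets_dir / "signatures.gmt")
    subtype_centroids(uni, params).to_csv(data / "centroids.tsv", sep="\t")

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.cells.to_csv(truth_dir / "cells.tsv", sep="\t", index=False)
    truth.segments.to_csv(truth_dir / "segments.tsv", sep="\t", index=False)
    truth.patients.to_csv(truth_dir / "patients.tsv", sep="\t", index=False)
    truth_dir.joinpath("params.json").write_text(
        json.dumps(asdict(params), indent=2, sort_keys=True) + "\n"
    )


def read_study(out_dir: str | Path) -> AnnotatedMatrix:
    """Read back a study directory written by :func:`write_study`."""
    from .core_io import read_matrix

    data = Path(out_dir) / "data"
    cells_path = data / "cells.tsv"
    sample_dirs = sorted((data / "samples").iterdir())
    mats = []
    for d in sample_dirs:
        mats.append(
            read_matrix(
                d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv", cells_path
            )
        )
    matrix = mats[0]
    for m in mats[1:]:
        matrix = matrix.concat(m)
    return matrix
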