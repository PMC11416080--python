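"""End-to-end pipeline orchestration on in-memory matrices.

The :func:`run_pipeline` function chains every stage — QC, normalisation,
cell typing, CNV inference, malignancy calling, clone clustering, deviation
and retention statistics, clone trees, composition tests, signature scoring,
subtype calling and the hypoxia–stemness analysis — deterministically from a
single :class:`~organofit.core_io.PipelineConfig`.  The CLI is a thin layer
that reads a study directory, calls this, and writes the tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import composition as comp_mod
from .cnv_fidelity import (
    CloneSet,
    DeviationScores,
    RetentionResult,
    clone_tree,
    cluster_clones,
    cnv_change_proportions,
    deviation_scores,
    retention_rate,
)
from .cnv_inference import CNVProfileSet, call_malignancy, infer_cnv
from .core_io import AnnotatedMatrix, FidelityReport, OrganofitError, PipelineConfig
from .preprocess import QCThresholds, annotate_cell_types, get_lognorm, qc_filter
from .signatures_subtypes import (
    RegressionResult,
    SampleClustering,
    StemClusterResult,
    call_subtypes_per_sample,
    find_stem_cluster,
    hypoxia_stemness_regression,
    marker_high_fraction,
    sample_correlation_clustering,
    score_signature,
)

#: marker genes whose per-sample high fractions are always reported
MARKER_GENES = ("ESR1", "ERBB2", "MKI67")


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    matrix: AnnotatedMatrix
    qc_report: pd.DataFrame
    profiles: CNVProfileSet
    malignancy: pd.DataFrame
    clone_sets: dict[str, CloneSet]
    trees: dict[str, CloneSet]
    deviation: DeviationScores
    retention: RetentionResult
    cnv_changes: pd.DataFrame
    proportions: pd.DataFrame
    composition_tests: pd.DataFrame
    signature_scores: pd.DataFrame          # barcode x signature (long format)
    marker_fractions: pd.DataFrame
    subtype_calls: pd.DataFrame
    sample_clustering: SampleClustering | None
    stem: StemClusterResult | None
    regression: RegressionResult | None
    report: FidelityReport = field(default_factory=FidelityReport)


def malignant_mask(result_or_calls: pd.DataFrame) -> np.ndarray:
    return (result_or_calls["label"] == "malignant").to_numpy()


def run_pipeline(
    matrix: AnnotatedMatrix,
    marker_panels: dict[str, list[str]],
    gene_sets: dict[str, list[str]],
    centroids: pd.DataFrame,
    config: PipelineConfig | None = None,
    subtypes: pd.Series | None = None,
) -> PipelineResult:
    """Run the full fidelity pipeline on a combined multi-patient matrix.

    ``marker_panels`` maps cell types to marker symbols (used for annotation
    and then excluded, with the program gene sets, from CNV inference);
    ``gene_sets`` must contain ``hypoxia`` and ``stem_cell_division`` entries
    for the regression stage; ``centroids`` is the subtype centroid table.
    ``subtypes`` (patient -> subtype) feeds the per-subtype retention means;
    when absent it is taken from a ``subtype`` column of the cell table.
    """
    cfg = config or PipelineConfig()

    m, qc_report = qc_filter(
        matrix,
        QCThresholds(
            min_genes_per_cell=cfg.qc_min_genes_per_cell,
            min_cells_per_gene=cfg.qc_min_cells_per_gene,
            max_mito_fraction=cfg.qc_max_mito_fraction,
        ),
    )
    get_lognorm(m)
    annotate_cell_types(m, marker_panels, tie_tolerance=cfg.tie_tolerance)

    if subtypes is None and "subtype" in m.cells.columns:
        subtypes = (
            m.cells[["patient", "subtype"]].drop_duplicates().set_index("patient")["subtype"]
        )

    program_genes = sorted(
        {g for panel in marker_panels.values() for g in panel}
        | {g for genes in gene_sets.values() for g in genes}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        profiles = infer_cnv(
            m,
            groups=m.cells["patient"],
            window=cfg.cnv_window,
            clip=cfg.cnv_clip,
            min_mean_count=cfg.cnv_min_mean_count,
            min_reference_cells=cfg.cnv_min_reference_cells,
            exclude=program_genes,
        )
    malignancy = call_malignancy(
        profiles,
        corr_threshold=cfg.malignancy_corr_threshold,
        min_epithelial=cfg.malignancy_min_epithelial,
    )
    mal = malignant_mask(malignancy)
    m.cells["malignant"] = np.where(mal, "malignant", "benign")

    src = m.cells["source"].to_numpy()
    pat = m.cells["patient"].to_numpy()
    patients = sorted(set(pat))
    k_range = (cfg.clone_k_min, cfg.clone_k_max)

    clone_sets: dict[str, CloneSet] = {}
    trees: dict[str, CloneSet] = {}
    for p in patients:
        pbc_mask = mal & (src == "PBC") & (pat == p)
        if pbc_mask.sum() < cfg.clone_min_cells:
            raise OrganofitError(f"{p}: too few malignant PBC cells to cluster clones")
        clone_sets[p] = cluster_clones(
            profiles.subset(pbc_mask),
            patient=p,
            k_range=k_range,
            min_cells=cfg.clone_min_cells,
        )
        merged_mask = mal & (pat == p)
        trees[p] = clone_tree(
            profiles.subset(merged_mask),
            patient=p,
            k_range=k_range,
            min_cells=cfg.clone_min_cells,
        )

    bco = profiles.subset(mal & (src == "BCO"))
    deviation = deviation_scores(
        bco, clone_sets, n_perm=cfg.n_permutations, rng=cfg.rng("deviation_null")
    )
    retention = retention_rate(
        clone_sets,
        bco,
        tau=cfg.retention_tau,
        min_abs=cfg.retention_min_abs,
        min_frac=cfg.retention_min_frac,
        preserved_min=cfg.preserved_min_retention,
        subtypes=subtypes,
    )
    cnv_changes = cnv_change_proportions(profiles.subset(mal), delta=cfg.cnv_change_delta)

    proportions = comp_mod.proportions(m.cells, ["epithelial", "immune", "stromal"])
    composition_tests = comp_mod.fold_change_test(
        proportions, epsilon=cfg.composition_epsilon
    )

    # signature scores for every set in the GMT (claudin-low is a negated set:
    # high score = low claudin programme)
    score_frames = []
    scorable = {k: v for k, v in gene_sets.items() if k != "subtype_markers"}
    exclude_union = sorted({g for genes in scorable.values() for g in genes})
    for name in sorted(scorable):
        genes = scorable[name]
        try:
            s = score_signature(
                m,
                genes,
                n_bins=cfg.score_n_bins,
                n_ctrl=cfg.score_n_ctrl,
                rng=cfg.rng(f"score:{name}"),
                min_genes=min(5, len(genes)),
                exclude=exclude_union,
            )
        except OrganofitError:
            continue
        if name == "claudin_low":
            s = -s
        score_frames.append(
            pd.DataFrame({"barcode": s.index, "signature": name, "score": s.to_numpy()})
        )
    signature_scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=["barcode", "signature", "score"])
    )

    marker_fractions = pd.concat(
        [marker_high_fraction(m, g) for g in MARKER_GENES if g in set(m.genes["symbol"])],
        ignore_index=True,
    ) if any(g in set(m.genes["symbol"]) for g in MARKER_GENES) else pd.DataFrame()

    subtype_calls = call_subtypes_per_sample(m, mal, centroids)

    expr = get_lognorm(m)
    bulks = {}
    for (p, s_), idx in m.cells.groupby(["patient", "source"], sort=True).indices.items():
        mask = np.zeros(m.n_cells, dtype=bool)
        mask[np.asarray(idx)] = True
        mask &= mal
        if mask.any():
            bulks[f"{p}_{s_}"] = expr[mask].mean(axis=0)
    sample_clustering = None
    if len(bulks) >= 3 and "subtype_markers" in gene_sets:
        pb = pd.DataFrame(bulks, index=m.genes["symbol"].to_numpy())
        sample_clustering = sample_correlation_clustering(pb, gene_sets["subtype_markers"])

    # stem-cluster identification and hypoxia regression on TNBC malignant cells
    stem = None
    regression = None
    if subtypes is not None:
        tnbc_patients = set(subtypes[subtypes == "TNBC"].index)
        tn_mask = mal & np.isin(pat, sorted(tnbc_patients))
        if tn_mask.sum() >= 2 * cfg.stem_kmeans_k:
            tn = m.subset_cells(tn_mask)
            try:
                stem = find_stem_cluster(
                    tn,
                    k=cfg.stem_kmeans_k,
                    n_pcs=cfg.stem_n_pcs,
                    seed=int(cfg.rng("stem_kmeans").integers(2**31)),
                )
            except (OrganofitError, KeyError):
                stem = None
            wide = signature_scores.pivot(index="barcode", columns="signature", values="score")
            if {"hypoxia", "stem_cell_division"} <= set(wide.columns):
                tn_barcodes = tn.barcodes
                sh = wide.loc[tn_barcodes, "hypoxia"]
                ss = wide.loc[tn_barcodes, "stem_cell_division"]
                regression = hypoxia_stemness_regression(
                    sh, ss, sources=tn.cells["source"]
                )

    report_obj = FidelityReport(
        deviation_scores=deviation.scores,
        deviation_tests=deviation.tests,
        retention=retention.per_patient[
            ["patient", "subtype", "retention_rate", "n_clones", "n_retained", "preserved"]
        ],
        retention_by_subtype=retention.by_subtype,
        composition_tests=composition_tests[
            ["cell_type", "mean_fc", "median_fc", "iqr", "t", "df", "p", "p_adj", "flag"]
        ],
        trees={p: trees[p].tree or "" for p in trees},
    )
    return PipelineResult(
        matrix=m,
        qc_report=qc_report,
        profiles=profiles,
        malignancy=malignancy,
        clone_sets=clone_sets,
        trees=trees,
        deviation=deviation,
        retention=retention,
        cnv_changes=cnv_changes,
        proportions=proportions,
        composition_tests=composition_tests,
        signature_scores=signature_scores,
        marker_fractions=marker_fractions,
        subtype_calls=subtype_calls,
        sample_clustering=sample_clustering,
        stem=stem,
        regression=regression,
        report=report_obj,
    )


def estimate_patient_retention(
    spec,
    params,
    config: PipelineConfig | None = None,
    universe=None,
) -> tuple[float, float]:
    """Simulate one patient and estimate its organoid CNV retention.

    Runs the minimal chain — QC, normalisation, marker annotation, CNV
    inference, malignancy calling, clone clustering of malignant PBC cells,
    clone-weighted retention of malignant BCO cells — and returns
    ``(designed_retention, estimated_retention)``.  Used for recovery sweeps
    against designed truth.
    """
    from . import synthetic_data as syn

    cfg = config or PipelineConfig()
    uni = universe if universe is not None else syn.build_universe(params)
    matrix, truth = syn.simulate_pair(spec, params, universe=uni)
    m, _ = qc_filter(matrix)
    get_lognorm(m)
    annotate_cell_types(m, syn.marker_panel_sets(uni), tie_tolerance=cfg.tie_tolerance)
    program_genes = sorted(
        {g for panel in syn.marker_panel_sets(uni).values() for g in panel}
        | {g for genes in syn.signature_sets(uni).values() for g in genes}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        profiles = infer_cnv(
            m,
            window=cfg.cnv_window,
            clip=cfg.cnv_clip,
            min_mean_count=cfg.cnv_min_mean_count,
            min_reference_cells=cfg.cnv_min_reference_cells,
            exclude=program_genes,
        )
    calls = call_malignancy(
        profiles,
        corr_threshold=cfg.malignancy_corr_threshold,
        min_epithelial=cfg.malignancy_min_epithelial,
    )
    mal = malignant_mask(calls)
    src = m.cells["source"].to_numpy()
    cs = cluster_clones(
        profiles.subset(mal & (src == "PBC")),
        patient=spec.patient,
        k_range=(cfg.clone_k_min, cfg.clone_k_max),
        min_cells=cfg.clone_min_cells,
    )
    res = retention_rate(
        {spec.patient: cs},
        profiles.subset(mal & (src == "BCO")),
        tau=cfg.retention_tau,
        min_abs=cfg.retention_min_abs,
        min_frac=cfg.retention_min_frac,
    )
    estimated = float(res.per_patient["retention_rate"].iloc[0])
    return spec.designed_retention, estimated
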