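"""Signature scoring, subtype calling and the hypoxia–stemness analysis.

Implements the expression-program side of the fidelity comparison:

* **bin-matched module scores** — a cell's score for a gene set is the mean
  log-normalised expression of the set minus the mean of control genes
  drawn from the same average-expression bins, so the score is centred at 0
  and robust to per-cell depth and coverage (the standard control-gene
  scheme used for single-cell signature scoring);
* **marker-high fractions** — per-sample fractions of cells expressing a
  marker (ESR1, ERBB2, MKI67, ...), compared PBC vs BCO by two-proportion
  z-tests;
* **nearest-centroid subtype calls** — Spearman correlation of a sample's
  malignant pseudobulk against a supplied centroid table (a PAM50-style
  reduced classifier);
* **sample correlation clustering** — average-linkage dendrogram of sample
  pseudobulk correlations on subtype marker genes;
* **stem-cluster identification** — k-means clusters of TNBC malignant
  cells screened for the CD44-high / ALDH1A2-low cancer-stem phenotype;
* **hypoxia–stemness regression** — per-cell Pearson correlation between
  hypoxia and stem-cell-division scores with the regression t-test
  ``t = r * sqrt((n-2) / (1-r^2))``, plus PBC-vs-BCO comparison of hypoxia
  scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, cophenet, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.proportion import proportions_ztest

from .core_io import AnnotatedMatrix, OrganofitError, substream
from .preprocess import get_lognorm


# ---------------------------------------------------------------------------
# bin-matched signature scoring
# ---------------------------------------------------------------------------

def score_signature(
    m: AnnotatedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    min_genes: int = 5,
    exclude: list[str] | None = None,
) -> pd.Series:
    """Bin-matched control score of a gene set for every cell.

    Genes are binned into ``n_bins`` by mean expression across cells; for
    each signature gene, ``n_ctrl`` control genes are drawn from its bin
    (without replacement when the bin is large enough, with replacement
    otherwise).  score(cell) = mean(signature expression) - mean(control
    expression).  Scores are 0-centred by construction: a signature drawn
    from its own control pool scores ~0.

    The scored set itself is never used as control.  When several programs
    are scored on the same cells, pass the union of their gene sets as
    ``exclude`` so one program's genes cannot contaminate another's control
    pool — otherwise a co-regulated program biases the control mean and
    attenuates between-score correlations.
    """
    expr = get_lognorm(m)
    symbols = m.genes["symbol"]
    sig_idx = np.flatnonzero(symbols.isin(gene_set).to_numpy())
    if sig_idx.size < min_genes:
        raise OrganofitError(
            f"signature shares only {sig_idx.size} genes with the matrix (< {min_genes})"
        )
    rng = rng if rng is not None else substream(seed, "score_signature")

    mean_expr = expr.mean(axis=0)
    # rank-based binning keeps bins equally filled regardless of the
    # expression distribution's shape
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.arange(m.n_genes) * n_bins // m.n_genes

    banned = np.zeros(m.n_genes, dtype=bool)
    banned[sig_idx] = True
    if exclude is not None:
        banned |= symbols.isin(exclude).to_numpy()
    ctrl_idx: list[np.ndarray] = []
    for g in sig_idx:
        pool = np.flatnonzero((bins == bins[g]) & ~banned)
        if pool.size == 0:  # bin holds only banned genes; fall back to the bin
            pool = np.flatnonzero(bins == bins[g])
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)
    score = expr[:, sig_idx].mean(axis=1) - expr[:, ctrl].mean(axis=1)
    return pd.Series(score, index=m.barcodes, name="score")


# ---------------------------------------------------------------------------
# marker-high fractions
# ---------------------------------------------------------------------------

def marker_high_fraction(
    m: AnnotatedMatrix, gene: str, rule: str = "detected"
) -> pd.DataFrame:
    """Per-sample fraction of cells 'high' for a marker gene.

    ``rule="detected"``: high iff raw count >= 1.  ``rule="median"``: high
    iff log-normalised expression exceeds the sample median.  Each patient
    with both sources gets a two-proportion z-test PBC vs BCO.
    """
    try:
        j = m.gene_index(gene)
    except KeyError:
        # absent gene: fraction 0 everywhere
        frame = (
            m.cells.groupby(["patient", "source"], sort=True)
            .size()
            .rename("n_cells")
            .reset_index()
        )
        frame["gene"] = gene
        frame["n_high"] = 0
        frame["fraction"] = 0.0
        frame["z"] = np.nan
        frame["p"] = np.nan
        return frame[["gene", "patient", "source", "n_cells", "n_high", "fraction", "z", "p"]]

    if rule == "detected":
        high = np.asarray(m.counts[:, j].todense()).ravel() >= 1
    elif rule == "median":
        v = get_lognorm(m)[:, j]
        high = np.zeros(m.n_cells, dtype=bool)
        for _, idx in m.cells.groupby(["patient", "source"], sort=False).indices.items():
            idx = np.asarray(idx)
            high[idx] = v[idx] > np.median(v[idx])
    else:
        raise ValueError(f"unknown rule {rule!r}")

    rows = []
    for (p, src), idx in m.cells.groupby(["patient", "source"], sort=True).indices.items():
        idx = np.asarray(idx)
        rows.append(
            {
                "gene": gene,
                "patient": p,
                "source": src,
                "n_cells": len(idx),
                "n_high": int(high[idx].sum()),
                "fraction": float(high[idx].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["z"] = np.nan
    out["p"] = np.nan
    for p, grp in out.groupby("patient"):
        if set(grp["source"]) >= {"PBC", "BCO"}:
            counts = grp.set_index("source").loc[["PBC", "BCO"]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                z, pv = proportions_ztest(
                    counts["n_high"].to_numpy(), counts["n_cells"].to_numpy()
                )
            out.loc[out["patient"] == p, "z"] = float(z)
            out.loc[out["patient"] == p, "p"] = float(pv)
    return out


# ---------------------------------------------------------------------------
# subtype calls
# ---------------------------------------------------------------------------

@dataclass
class SubtypeCall:
    sample: str
    correlations: dict[str, float]
    called: str
    low_confidence: bool

    @property
    def max_r(self) -> float:
        return self.correlations[self.called]


def pseudobulk(m: AnnotatedMatrix, mask: np.ndarray) -> np.ndarray:
    """Mean log-normalised expression over the masked cells."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise OrganofitError("pseudobulk over zero cells")
    return get_lognorm(m)[mask].mean(axis=0)


def call_subtype(
    bulk: pd.Series,
    centroids: pd.DataFrame,
    min_shared: int = 10,
    low_confidence_r: float = 0.2,
    sample: str = "sample",
) -> SubtypeCall:
    """Nearest-centroid subtype call by Spearman correlation.

    ``bulk`` is a pseudobulk expression vector indexed by gene symbol;
    ``centroids`` a genes x subtypes table.  The call is the argmax
    correlation over shared genes; ties break by centroid column order with
    a warning, and a best correlation below ``low_confidence_r`` flags the
    call low-confidence.
    """
    shared = centroids.index.intersection(bulk.index)
    if len(shared) < min_shared:
        raise OrganofitError(
            f"centroid table shares only {len(shared)} genes with the sample (< {min_shared})"
        )
    x = bulk.loc[shared].to_numpy(dtype=float)
    corr = {}
    for s in centroids.columns:
        r = stats.spearmanr(x, centroids.loc[shared, s].to_numpy(dtype=float)).statistic
        corr[s] = float(r)
    best = max(corr.values())
    winners = [s for s in centroids.columns if corr[s] == best]
    if len(winners) > 1:
        warnings.warn(f"{sample}: subtype tie among {winners}; keeping {winners[0]}")
    return SubtypeCall(
        sample=sample,
        correlations=corr,
        called=winners[0],
        low_confidence=bool(best < low_confidence_r),
    )


def call_subtypes_per_sample(
    m: AnnotatedMatrix,
    malignant: np.ndarray,
    centroids: pd.DataFrame,
) -> pd.DataFrame:
    """Subtype call for every (patient, source) sample's malignant pseudobulk."""
    rows = []
    for (p, src), idx in m.cells.groupby(["patient", "source"], sort=True).indices.items():
        mask = np.zeros(m.n_cells, dtype=bool)
        mask[np.asarray(idx)] = True
        mask &= np.asarray(malignant, dtype=bool)
        if not mask.any():
            continue
        bulk = pd.Series(pseudobulk(m, mask), index=m.genes["symbol"].to_numpy())
        call = call_subtype(bulk, centroids, sample=f"{p}_{src}")
        row = {"patient": p, "source": src, "called": call.called,
               "low_confidence": call.low_confidence}
        row.update({f"r_{s}": call.correlations[s] for s in centroids.columns})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sample correlation clustering
# ---------------------------------------------------------------------------

def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage dendrogram as a Newick string."""
    root = to_tree(z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6f},{right}:{dr:.6f})"

    return rec(root) + ";\n"


@dataclass
class SampleClustering:
    correlation: pd.DataFrame     # samples x samples Pearson correlation
    linkage: np.ndarray
    newick: str
    cophenetic: pd.DataFrame      # samples x samples cophenetic distances


def sample_correlation_clustering(
    pseudobulks: pd.DataFrame, marker_genes: list[str]
) -> SampleClustering:
    """Correlation structure of sample pseudobulks on subtype marker genes.

    ``pseudobulks`` is genes x samples (log-normalised means).  Pearson
    correlations between samples on the marker genes are clustered with
    average linkage on the distance ``1 - r``; the dendrogram is returned as
    Newick together with the cophenetic distance matrix.
    """
    if pseudobulks.shape[1] < 3:
        raise OrganofitError("need at least 3 samples to cluster")
    shared = pseudobulks.index.intersection(pd.Index(marker_genes))
    if len(shared) < 2:
        raise OrganofitError("marker genes absent from pseudobulks")
    x = pseudobulks.loc[shared]
    corr = x.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    z = average(squareform(dist, checks=False))
    coph = pd.DataFrame(
        squareform(cophenet(z)), index=corr.index, columns=corr.columns
    )
    return SampleClustering(
        correlation=corr,
        linkage=z,
        newick=_linkage_to_newick(z, list(corr.columns)),
        cophenetic=coph,
    )


# ---------------------------------------------------------------------------
# stem cluster identification
# ---------------------------------------------------------------------------

@dataclass
class StemClusterResult:
    clusters: pd.DataFrame       # cluster, n_cells, mean_cd44, mean_aldh1a2, is_stem
    cell_clusters: pd.Series     # per-cell cluster id (index = barcode)
    stem_clusters: list[int]
    proportions: pd.DataFrame    # source, n_cells, n_stem, fraction
    z: float
    p: float
    flag: str


def find_stem_cluster(
    m: AnnotatedMatrix,
    k: int = 6,
    n_pcs: int = 50,
    cd44: str = "CD44",
    aldh1a2: str = "ALDH1A2",
    seed: int = 0,
) -> StemClusterResult:
    """Identify CD44-high / ALDH1A2-low clusters among (TNBC) malignant cells.

    Cells are k-means-clustered on the top principal components of
    log-normalised expression; a cluster is called "stem" iff its mean CD44
    is above the across-cluster 75th percentile AND its mean ALDH1A2 below
    the 25th percentile.  PBC vs BCO membership of stem clusters is compared
    with a two-proportion z-test.  ``m`` should already be restricted to the
    malignant cells of interest.
    """
    expr = get_lognorm(m)
    if m.n_cells < 2 * k:
        raise OrganofitError(f"{m.n_cells} cells too few for k={k} clusters")
    n_pcs = min(n_pcs, m.n_cells - 1, m.n_genes - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(expr - expr.mean(axis=0))
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31)).fit(pcs)
    lab = km.labels_

    v44 = expr[:, m.gene_index(cd44)]
    v_aldh = expr[:, m.gene_index(aldh1a2)]
    rows = []
    for c in range(k):
        mask = lab == c
        rows.append(
            {
                "cluster": c,
                "n_cells": int(mask.sum()),
                "mean_cd44": float(v44[mask].mean()),
                "mean_aldh1a2": float(v_aldh[mask].mean()),
            }
        )
    clusters = pd.DataFrame(rows)
    hi44 = np.percentile(clusters["mean_cd44"], 75)
    lo_aldh = np.percentile(clusters["mean_aldh1a2"], 25)
    clusters["is_stem"] = (clusters["mean_cd44"] >= hi44) & (
        clusters["mean_aldh1a2"] <= lo_aldh
    )
    stem = clusters.loc[clusters["is_stem"], "cluster"].tolist()
    flag = "" if stem else "no_stem_cluster"

    in_stem = np.isin(lab, stem)
    prop_rows = []
    for src in ("PBC", "BCO"):
        mask = (m.cells["source"] == src).to_numpy()
        prop_rows.append(
            {
                "source": src,
                "n_cells": int(mask.sum()),
                "n_stem": int((mask & in_stem).sum()),
                "fraction": float(in_stem[mask].mean()) if mask.any() else np.nan,
            }
        )
    props = pd.DataFrame(prop_rows)
    z = p = np.nan
    if (props["n_cells"] > 0).all() and in_stem.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            z, p = proportions_ztest(
                props["n_stem"].to_numpy(), props["n_cells"].to_numpy()
            )
    return StemClusterResult(
        clusters=clusters,
        cell_clusters=pd.Series(lab, index=m.barcodes, name="cluster"),
        stem_clusters=stem,
        proportions=props,
        z=float(z),
        p=float(p),
        flag=flag,
    )


# ---------------------------------------------------------------------------
# hypoxia vs stem-cell-division regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    t: float
    df: int
    p: float
    source_test: pd.DataFrame | None = None  # PBC vs BCO hypoxia t-test


def hypoxia_stemness_regression(
    scores_hypoxia: pd.Series,
    scores_stem_division: pd.Series,
    sources: pd.Series | None = None,
) -> RegressionResult:
    """Pearson/OLS coupling of per-cell hypoxia and stem-cell-division scores.

    The p-value is the two-sided regression t-test with
    ``t = r * sqrt((n-2) / (1-r^2))`` on ``n - 2`` degrees of freedom.  If
    ``sources`` (aligned per cell) is given, PBC and BCO hypoxia scores are
    additionally compared with a Student's t-test.
    """
    x = np.asarray(scores_hypoxia, dtype=float)
    y = np.asarray(scores_stem_division, dtype=float)
    if x.shape != y.shape:
        raise OrganofitError("score vectors must align")
    n = len(x)
    if n < 3:
        raise OrganofitError("need at least 3 cells")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = r * y.std(ddof=1) / x.std(ddof=1)
    intercept = float(y.mean() - slope * x.mean())
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))

    source_test = None
    if sources is not None:
        src = np.asarray(sources)
        a, b = x[src == "PBC"], x[src == "BCO"]
        if len(a) > 1 and len(b) > 1:
            ts, ps = stats.ttest_ind(a, b, equal_var=True)
            source_test = pd.DataFrame(
                {
                    "group": ["PBC", "BCO"],
                    "n": [len(a), len(b)],
                    "mean_hypoxia": [float(a.mean()), float(b.mean())],
                    "t": [float(ts)] * 2,
                    "p": [float(ps)] * 2,
                }
            )
    return RegressionResult(
        r=r, slope=float(slope), intercept=intercept, t=float(t), df=df, p=p,
        source_test=source_test,
    )
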