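"""Organoid fidelity statistics on inferred CNV profiles.

This is the analytical core of the pipeline: given per-cell CNV profiles,
it asks whether the organoid's malignant cells reproduce the clonal
copy-number structure of the matched primary tumour.

* **Clones** — malignant primary cells are clustered on their window
  profiles (Ward linkage, silhouette-selected k); each cluster's mean
  profile is a clone centroid, the unit of preservation.
* **Deviation scores** — for each organoid malignant cell *c* of patient
  *p*: ``D = 1 - r`` where *r* is the best Pearson correlation of *c*'s
  profile with (paired) *p*'s own clone centroids, (background) all other
  patients' centroids, or (random) *p*'s centroids after randomly permuting
  *c*'s windows, averaged over fresh permutations.  Low paired deviation
  against both nulls is what "the organoid preserves the tumour's CNV
  structure" means; groups are compared with Student's t-tests.
* **Retention** — each organoid malignant cell is assigned to its
  best-correlated primary clone if the correlation clears ``tau``; a clone
  is retained when enough organoid cells land on it, and the retention rate
  is the PBC-cell-weighted fraction of retained clones, so that losing a
  dominant clone costs more than losing a minor one.
* **Clone trees** — neighbour-joining on clone centroids plus an all-zero
  diploid profile, rooted at the diploid, with per-clone source counts —
  the expression-CNV analogue of a tumour phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.metrics import silhouette_score

from .core_io import InsufficientCellsError, OrganofitError
from .cnv_inference import CNVProfileSet


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and return (centered rows, row norms); norm 0 = constant row."""
    c = x - x.mean(axis=1, keepdims=True)
    return c, np.linalg.norm(c, axis=1)


def pearson_to_centroids(cells: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Pearson correlation of every cell profile against every centroid.

    Rows with (numerically) zero variance yield NaN correlations — a
    window-constant profile carries no usable CNV pattern.
    """
    cz, cn = _standardize_rows(np.atleast_2d(cells))
    kz, kn = _standardize_rows(np.atleast_2d(centroids))
    tol = 1e-9 * np.sqrt(cells.shape[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cz @ kz.T) / np.outer(cn, kn)
    r[cn < tol, :] = np.nan
    r[:, kn < tol] = np.nan
    return r


# ---------------------------------------------------------------------------
# clone clustering
# ---------------------------------------------------------------------------

@dataclass
class CloneSet:
    """Clone partition of one patient's malignant cells.

    ``assignments`` maps each member barcode to a clone id; ``centroids`` is
    clones x windows (mean member profile); ``counts`` tabulates PBC/BCO
    member cells per clone.  ``tree`` holds the Newick string once
    :func:`clone_tree` has run.
    """

    patient: str
    clone_ids: list[str]
    assignments: pd.DataFrame          # barcode, source, clone_id
    centroids: np.ndarray              # n_clones x n_windows
    counts: pd.DataFrame               # clone_id, n_pbc, n_bco
    tree: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def pbc_fractions(self) -> pd.Series:
        """Fraction of the patient's PBC malignant cells in each clone."""
        n = self.counts.set_index("clone_id")["n_pbc"]
        return n / n.sum()


def cluster_clones(
    profiles: CNVProfileSet,
    patient: str | None = None,
    k_range: tuple[int, int] = (2, 6),
    min_cells: int = 20,
) -> CloneSet:
    """Cluster one patient's malignant cell profiles into clones.

    Hierarchical Ward clustering on Euclidean window distances; the clone
    count k is chosen in ``k_range`` by maximal mean silhouette.  If the
    profiles are (near-)identical — silhouette undefined — a single clone is
    returned.  Deterministic, and invariant to cell order up to clone
    relabelling.
    """
    cells = profiles.cells
    pat = patient if patient is not None else str(cells["patient"].iloc[0])
    x = profiles.values
    n = x.shape[0]
    if n < min_cells:
        raise InsufficientCellsError(f"{pat}: {n} malignant cells < {min_cells}")

    flags: list[str] = []
    k_lo, k_hi = k_range
    k_hi = min(k_hi, n - 1)
    if np.allclose(x, x[0], atol=1e-12) or k_lo > k_hi:
        labels = np.zeros(n, dtype=int)
        flags.append("single_clone_fallback")
    else:
        z = linkage(x, method="ward")
        best_k, best_sil, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
        for k in range(max(2, k_lo), k_hi + 1):
            lab = fcluster(z, t=k, criterion="maxclust") - 1
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(x, lab, metric="euclidean")
            if sil > best_sil:
                best_k, best_sil, best_labels = k, sil, lab
        if not np.isfinite(best_sil):
            labels = np.zeros(n, dtype=int)
            flags.append("single_clone_fallback")
        else:
            labels = best_labels

    # stable clone ids: order clusters by descending size, ties by first member
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.argmax(labels == c))))
    remap = {c: i for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in labels])
    clone_ids = [f"{pat}_c{i + 1}" for i in range(len(order))]

    centroids = np.vstack([x[labels == i].mean(axis=0) for i in range(len(order))])
    assignments = pd.DataFrame(
        {
            "barcode": profiles.barcodes,
            "source": cells["source"].to_numpy(),
            "clone_id": [clone_ids[i] for i in labels],
        }
    )
    counts = (
        assignments.groupby("clone_id")["source"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(clone_ids)
        .reset_index()
    )
    for src in ("PBC", "BCO"):
        if src not in counts.columns:
            counts[src] = 0
    counts = counts.rename(columns={"PBC": "n_pbc", "BCO": "n_bco"})[
        ["clone_id", "n_pbc", "n_bco"]
    ]
    return CloneSet(
        patient=pat,
        clone_ids=clone_ids,
        assignments=assignments,
        centroids=centroids,
        counts=counts,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# deviation scores
# ---------------------------------------------------------------------------

@dataclass
class DeviationScores:
    """Per-cell deviation scores and the group tests comparing them."""

    scores: pd.DataFrame       # patient, barcode, D_paired, D_background, D_random
    tests: pd.DataFrame        # patient, comparison, t, p
    n_excluded_constant: int   # window-constant cells dropped (r undefined)


def deviation_scores(
    bco_profiles: CNVProfileSet,
    clone_sets: dict[str, CloneSet],
    n_perm: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> DeviationScores:
    """Deviation of organoid malignant cells from paired / background / random centroids.

    ``bco_profiles`` holds the BCO malignant cells of every patient;
    ``clone_sets`` the PBC clone sets keyed by patient.  D = 1 - best
    Pearson r, so D in [0, 2] and 0 means a perfect match to some centroid.
    The random null permutes each cell's window values with a fresh
    permutation per draw (``n_perm`` draws, averaged) before correlating
    with the paired centroids.  Student's t-tests (two-sided) compare
    paired vs background and paired vs random per patient.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cells = bco_profiles.cells
    patients = sorted(cells["patient"].unique())
    missing = [p for p in patients if p not in clone_sets]
    if missing:
        raise OrganofitError(f"no PBC clone set for patients {missing}")

    rows = []
    n_excluded = 0
    for p in patients:
        mask = (cells["patient"] == p).to_numpy()
        x = bco_profiles.values[mask]
        barcodes = bco_profiles.barcodes[mask]
        own = clone_sets[p].centroids
        foreign = np.vstack(
            [clone_sets[q].centroids for q in patients if q != p]
        ) if len(patients) > 1 else None

        r_own = pearson_to_centroids(x, own)
        constant = np.isnan(r_own).all(axis=1)
        n_excluded += int(constant.sum())
        d_paired = 1.0 - np.nanmax(r_own, axis=1, initial=-1.0)
        d_back = (
            1.0 - np.nanmax(pearson_to_centroids(x, foreign), axis=1, initial=-1.0)
            if foreign is not None
            else np.full(x.shape[0], np.nan)
        )

        # random null: permute each cell's windows, fresh permutation per draw
        n_windows = x.shape[1]
        d_rand = np.zeros(x.shape[0])
        for _ in range(n_perm):
            perm = rng.permuted(np.broadcast_to(np.arange(n_windows), x.shape), axis=1)
            xp = np.take_along_axis(x, perm, axis=1)
            d_rand += 1.0 - np.nanmax(pearson_to_centroids(xp, own), axis=1, initial=-1.0)
        d_rand /= n_perm

        for i in range(x.shape[0]):
            if constant[i]:
                continue
            rows.append(
                {
                    "patient": p,
                    "barcode": barcodes[i],
                    "D_paired": float(d_paired[i]),
                    "D_background": float(d_back[i]),
                    "D_random": float(d_rand[i]),
                }
            )

    scores = pd.DataFrame(
        rows, columns=["patient", "barcode", "D_paired", "D_background", "D_random"]
    )
    test_rows = []
    for p, grp in scores.groupby("patient", sort=True):
        for other in ("D_background", "D_random"):
            a, b = grp["D_paired"].to_numpy(), grp[other].dropna().to_numpy()
            if len(a) > 1 and len(b) > 1:
                t, pv = stats.ttest_ind(a, b, equal_var=True)
            else:
                t, pv = np.nan, np.nan
            test_rows.append(
                {
                    "patient": p,
                    "comparison": f"paired_vs_{other.removeprefix('D_')}",
                    "t": float(t),
                    "p": float(pv),
                }
            )
    tests = pd.DataFrame(test_rows, columns=["patient", "comparison", "t", "p"])
    return DeviationScores(scores=scores, tests=tests, n_excluded_constant=n_excluded)


# ---------------------------------------------------------------------------
# retention
# ---------------------------------------------------------------------------

@dataclass
class RetentionResult:
    per_patient: pd.DataFrame   # patient, subtype, retention_rate, n_clones, n_retained,
                                # n_bco_assigned, n_bco_unassigned, preserved, flag
    per_clone: pd.DataFrame     # patient, clone_id, pbc_fraction, n_bco_assigned, retained
    by_subtype: pd.DataFrame    # subtype, mean_retention, n_patients
    overall: float


def retention_rate(
    clone_sets: dict[str, CloneSet],
    bco_profiles: CNVProfileSet,
    tau: float = 0.5,
    min_abs: int = 5,
    min_frac: float = 0.01,
    preserved_min: float = 0.5,
    subtypes: pd.Series | None = None,
) -> RetentionResult:
    """Clone-weighted CNV retention of each patient's organoid.

    Each BCO malignant cell is assigned to the primary clone with maximal
    Pearson correlation if that correlation reaches ``tau``; a clone is
    retained iff its assigned BCO cells number at least
    ``max(min_abs, min_frac * n_bco_malignant)``; the retention rate is the
    sum of retained clones' PBC cell fractions.  Patients without BCO
    malignant cells get retention 0 with a flag.  ``subtypes`` maps patient
    to molecular subtype for the per-subtype means (unweighted over
    patients).
    """
    cells = bco_profiles.cells
    patient_rows, clone_rows = [], []
    for p in sorted(clone_sets):
        cs = clone_sets[p]
        mask = (cells["patient"] == p).to_numpy()
        x = bco_profiles.values[mask]
        n_bco = x.shape[0]
        flag = ""
        assigned = np.zeros(cs.n_clones, dtype=int)
        n_unassigned = 0
        if n_bco == 0:
            flag = "no_bco_malignant_cells"
            retention = 0.0
        else:
            r = pearson_to_centroids(x, cs.centroids)
            valid = ~np.isnan(r).all(axis=1)
            n_unassigned += int((~valid).sum())
            best = np.full(x.shape[0], -1)
            if valid.any():
                rv = np.where(np.isnan(r[valid]), -np.inf, r[valid])
                best_idx = rv.argmax(axis=1)
                best_r = rv[np.arange(rv.shape[0]), best_idx]
                ok = best_r >= tau
                hits = best_idx[ok]
                np.add.at(assigned, hits, 1)
                n_unassigned += int((~ok).sum())
            need = max(min_abs, int(np.ceil(min_frac * n_bco)))
            retained = assigned >= need
            fracs = cs.pbc_fractions().to_numpy()
            retention = float(fracs[retained].sum())
            for i, cid in enumerate(cs.clone_ids):
                clone_rows.append(
                    {
                        "patient": p,
                        "clone_id": cid,
                        "pbc_fraction": float(fracs[i]),
                        "n_bco_assigned": int(assigned[i]),
                        "retained": bool(retained[i]),
                    }
                )
        subtype = (
            str(subtypes.get(p)) if subtypes is not None and p in subtypes.index else "NA"
        )
        patient_rows.append(
            {
                "patient": p,
                "subtype": subtype,
                "retention_rate": retention,
                "n_clones": cs.n_clones,
                "n_retained": int(sum(r["retained"] for r in clone_rows if r["patient"] == p)),
                "n_bco_assigned": int(assigned.sum()),
                "n_bco_unassigned": int(n_unassigned),
                "preserved": bool(retention >= preserved_min),
                "flag": flag,
            }
        )
    per_patient = pd.DataFrame(patient_rows)
    per_clone = pd.DataFrame(
        clone_rows,
        columns=["patient", "clone_id", "pbc_fraction", "n_bco_assigned", "retained"],
    )
    by_subtype = (
        per_patient.groupby("subtype", sort=True)["retention_rate"]
        .agg(mean_retention="mean", n_patients="size")
        .reset_index()
    )
    overall = float(per_patient["retention_rate"].mean()) if len(per_patient) else 0.0
    return RetentionResult(
        per_patient=per_patient,
        per_clone=per_clone,
        by_subtype=by_subtype,
        overall=overall,
    )


# ---------------------------------------------------------------------------
# CNV change proportions
# ---------------------------------------------------------------------------

def cnv_change_proportions(
    profiles: CNVProfileSet, delta: float = 0.15
) -> pd.DataFrame:
    """Per-sample fractions of (cell, window) entries amplified / deleted / neutral.

    Amplified iff value > delta, deleted iff value < -delta; the three
    fractions sum to 1 per (patient, source) sample.
    """
    cells = profiles.cells
    rows = []
    for (p, src), idx in cells.groupby(["patient", "source"], sort=True).indices.items():
        v = profiles.values[np.asarray(idx)]
        n = v.size
        amp = float((v > delta).sum() / n)
        dele = float((v < -delta).sum() / n)
        rows.append(
            {
                "patient": p,
                "source": src,
                "amplified": amp,
                "deleted": dele,
                "neutral": 1.0 - amp - dele,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------

def clone_tree(
    merged_profiles: CNVProfileSet,
    patient: str | None = None,
    k_range: tuple[int, int] = (2, 6),
    min_cells: int = 20,
) -> CloneSet:
    """Re-cluster one patient's merged PBC+BCO malignant cells and build a tree.

    Neighbour-joining on Euclidean distances among clone centroids plus an
    all-zero diploid profile, rooted at the diploid (CNV accumulation is not
    clock-like, hence NJ rather than UPGMA).  With fewer than 2 clones a
    star (single-edge) tree is written.  The Newick string is stored on the
    returned :class:`CloneSet`; ``counts`` carries per-clone PBC/BCO cell
    numbers and the sidecar columns mean burden per clone.
    """
    cs = cluster_clones(merged_profiles, patient=patient, k_range=k_range, min_cells=min_cells)
    k = cs.n_clones
    burdens = (cs.centroids**2).mean(axis=1)
    if k < 2:
        d = float(np.linalg.norm(cs.centroids[0]))
        newick = f"({cs.clone_ids[0]}:{d:.6f})diploid;\n"
    else:
        ids = list(cs.clone_ids) + ["diploid"]
        pts = np.vstack([cs.centroids, np.zeros(cs.centroids.shape[1])])
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        tree = nj(DistanceMatrix(dist, ids=ids))
        rooted = tree.root_at(tree.find("diploid"))
        # NJ can produce tiny negative branch lengths; clamp at zero
        for node in rooted.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        newick = str(rooted)
    cs.tree = newick
    cs.counts = cs.counts.assign(mean_burden=burdens)
    return cs
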