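"""Expression-based CNV profiles and malignancy calling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.cluster import KMeans

from organofit.core_io import AnnotatedMatrix, InsufficientCellsError
from organofit.cnv_inference import (
    call_malignancy,
    infer_cnv,
    two_means_1d,
)
from organofit import synthetic_data as syn


def _matrix(counts, chroms=None, cell_type=None, patient=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    if chroms is None:
        chroms = ["chr1"] * g
    genes = pd.DataFrame(
        {
            "gene_id": [f"E{i}" for i in range(g)],
            "symbol": [f"G{i}" for i in range(g)],
            "chrom": chroms,
            "start": pd.Series(chroms).groupby(chroms, sort=False).cumcount() * 100 + 100,
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(n)],
            "patient": patient or ["P1"] * n,
            "source": ["PBC"] * n,
        }
    )
    if cell_type is not None:
        cells["cell_type"] = cell_type
    return AnnotatedMatrix(counts=sp.csr_matrix(counts), genes=genes, cells=cells)


class TestInferCNV:
    def test_reference_cells_center_at_zero(self, preset_run):
        prof = preset_run.profiles
        ref = prof.cells["cell_type"].isin(("immune", "stromal")).to_numpy()
        per_window_mean = prof.values[ref].mean(axis=0)
        assert np.abs(per_window_mean).max() < 0.05

    def test_constant_matrix_gives_zero_profiles(self):
        m = _matrix(np.full((30, 60), 3), cell_type=["immune"] * 30)
        prof = infer_cnv(m, window=11, min_reference_cells=10)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(40, 80))
        chroms = ["chr1"] * 40 + ["chr2"] * 40
        m = _matrix(counts, chroms=chroms, cell_type=["immune"] * 20 + ["epithelial"] * 20)
        prof = infer_cnv(m, window=11, min_reference_cells=10)
        perm = rng.permutation(80)
        m2 = m.subset_genes(perm)
        prof2 = infer_cnv(m2, window=11, min_reference_cells=10)
        np.testing.assert_allclose(prof.values, prof2.values, atol=1e-12)
        assert prof.windows["window_id"].tolist() == prof2.windows["window_id"].tolist()

    def test_small_chromosome_skipped_with_warning(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=(25, 50))
        chroms = ["chr1"] * 45 + ["chr2"] * 5
        m = _matrix(counts, chroms=chroms, cell_type=["immune"] * 25)
        with pytest.warns(UserWarning, match="chr2"):
            prof = infer_cnv(m, window=21, min_reference_cells=10)
        assert set(prof.windows["chrom"]) == {"chr1"}

    def test_too_few_reference_cells_raises(self):
        m = _matrix(np.ones((10, 30), dtype=int), cell_type=["immune"] * 10)
        with pytest.raises(InsufficientCellsError):
            infer_cnv(m, window=5, min_reference_cells=20)

    def test_wider_window_does_not_increase_reference_variance(self, preset_run):
        """Smoothing monotonicity: doubling the window cannot raise the
        per-window variance of reference cells."""
        m = preset_run.matrix
        ref = m.cells["cell_type"].isin(("immune", "stromal")).to_numpy()
        var = {}
        for w in (25, 50):
            prof = infer_cnv(m, groups=m.cells["patient"], window=w)
            var[w] = prof.values[ref].var(axis=1).mean()
        assert var[50] <= var[25] * 1.01


class TestTwoMeans1D:
    def test_exact_split_beats_or_matches_kmeans_inertia(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 120), rng.normal(5, 1, 40)])
        labels, means = two_means_1d(x)

        def inertia(lab):
            return sum(((x[lab == k] - x[lab == k].mean()) ** 2).sum() for k in (0, 1))

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(x.reshape(-1, 1))
        assert inertia(labels) <= inertia(km.labels_) + 1e-9
        assert means[1] > means[0]

    def test_brute_force_optimality_small_input(self):
        x = np.array([0.1, 0.2, 0.15, 3.0, 3.2, 0.9])
        labels, _ = two_means_1d(x)
        order = np.argsort(x)
        best = np.inf
        for split in range(1, len(x)):
            lo, hi = x[order[:split]], x[order[split:]]
            ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            best = min(best, ss)
        got = sum(((x[labels == k] - x[labels == k].mean()) ** 2).sum() for k in (0, 1))
        assert got == pytest.approx(best)


class TestCallMalignancy:
    def test_preset_agreement_with_truth(self, preset_run, preset_truth_aligned):
        predicted = preset_run.malignancy["label"].to_numpy() == "malignant"
        true = preset_truth_aligned["malignant"].to_numpy()
        assert (predicted == true).mean() >= 0.95

    def test_cnv_neutral_epithelium_flagged_no_malignant_compartment(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(3.0, size=(80, 120))
        chroms = ["chr1"] * 60 + ["chr2"] * 60
        types = ["immune"] * 30 + ["epithelial"] * 50
        m = _matrix(counts, chroms=chroms, cell_type=types)
        prof = infer_cnv(m, window=15, min_reference_cells=10)
        calls = call_malignancy(prof)
        assert (calls["label"] == "benign").all()
        epi = calls["cell_type"] == "epithelial"
        assert (calls.loc[epi, "flag"] == "no_malignant_compartment").all()

    def test_duplicating_cells_keeps_labels_per_barcode(self, preset_run):
        prof = preset_run.profiles
        p1 = (prof.cells["patient"] == "P01").to_numpy()
        sub = prof.subset(p1)
        base = call_malignancy(sub).set_index("barcode")["label"]

        dup = sub.subset(np.concatenate([np.arange(sub.n_cells), np.arange(sub.n_cells)]))
        dup.cells = dup.cells.copy()
        dup.cells.loc[sub.n_cells:, "barcode"] = (
            dup.cells.loc[sub.n_cells:, "barcode"] + "_copy"
        )
        dup_calls = call_malignancy(dup)
        first_half = dup_calls.iloc[: sub.n_cells].set_index("barcode")["label"]
        pd.testing.assert_series_equal(base, first_half)


class TestSegmentDetection:
    def test_auroc_against_designed_segments(self, preset_run, preset_study):
        aucs = syn.segment_detection_auroc(preset_run.profiles, preset_study["truth"])
        assert len(aucs) >= 12
        assert aucs.groupby("patient")["auroc"].min().min() >= 0.9
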