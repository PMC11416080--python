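"""Signature scoring, subtype calls, stem clusters and the regression."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from organofit.core_io import AnnotatedMatrix
from organofit.signatures_subtypes import (
    call_subtype,
    find_stem_cluster,
    hypoxia_stemness_regression,
    marker_high_fraction,
    sample_correlation_clustering,
    score_signature,
)
from organofit import synthetic_data as syn


def _matrix(counts, symbols=None, sources=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = pd.DataFrame(
        {
            "gene_id": [f"E{i}" for i in range(g)],
            "symbol": symbols or [f"G{i}" for i in range(g)],
            "chrom": ["chr1"] * g,
            "start": np.arange(1, g + 1) * 100,
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": [f"BC{i}" for i in range(n)],
            "patient": ["P1"] * n,
            "source": sources or ["PBC"] * n,
        }
    )
    return AnnotatedMatrix(counts=sp.csr_matrix(counts), genes=genes, cells=cells)


class TestScoreSignature:
    def test_uniform_matrix_scores_zero(self):
        m = _matrix(np.full((10, 40), 2))
        s = score_signature(m, [f"G{i}" for i in range(5)], n_bins=4, n_ctrl=10, seed=0)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_shift_invariance_of_lognorm_layer(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.poisson(3.0, size=(30, 50)))
        genes = [f"G{i}" for i in range(0, 10)]
        s1 = score_signature(m, genes, n_bins=5, n_ctrl=20, seed=1)
        m.layers["lognorm"] = m.layers["lognorm"] + 3.7
        s2 = score_signature(m, genes, n_bins=5, n_ctrl=20, seed=1)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_random_gene_set_scores_near_zero_mean(self, preset_run):
        """Bin-matched controls make random gene sets score ~0 on average.

        A single draw fluctuates with the within-bin spread of its genes, so
        unbiasedness is asserted on the grand mean over draws, with a looser
        per-draw bound.
        """
        m = preset_run.matrix
        rng = np.random.default_rng(13)
        means = []
        neutral = m.genes.loc[m.genes["symbol"].str.startswith("G"), "symbol"]
        for _ in range(5):
            genes = rng.choice(neutral, size=40, replace=False).tolist()
            s = score_signature(m, genes, rng=np.random.default_rng(rng.integers(2**31)))
            means.append(s.mean())
        assert np.abs(means).max() < 0.1
        assert abs(np.mean(means)) < 0.02

    def test_active_cells_separate_from_inactive(self, preset_run, preset_study):
        """Hypoxia-high cells score above hypoxia-low cells (AUROC >= 0.8)."""
        from sklearn.metrics import roc_auc_score

        truth = preset_study["truth"].cells.set_index("barcode")
        wide = preset_run.signature_scores.pivot(
            index="barcode", columns="signature", values="score"
        )
        aligned = truth.loc[wide.index]
        activity = aligned["hypoxia_activity"].to_numpy()
        hi = activity > np.quantile(activity, 0.75)
        lo = activity < np.quantile(activity, 0.25)
        mask = hi | lo
        auc = roc_auc_score(hi[mask], wide["hypoxia"].to_numpy()[mask])
        assert auc >= 0.8


class TestMarkerHighFraction:
    def test_absent_gene_gives_zero_fraction(self):
        m = _matrix(np.ones((4, 3), dtype=int))
        out = marker_high_fraction(m, "NOT_A_GENE")
        assert (out["fraction"] == 0.0).all()

    def test_ubiquitous_gene_detected_everywhere(self):
        m = _matrix(np.ones((4, 3), dtype=int))
        out = marker_high_fraction(m, "G0")
        assert (out["fraction"] == 1.0).all()

    def test_erbb2_high_in_her2_positive_preset(self, preset_run):
        mf = preset_run.marker_fractions
        erbb2 = mf[(mf["gene"] == "ERBB2") & mf["patient"].isin(["P03", "P04"])]
        # malignant-dominated organoids and primaries both express the
        # amplified receptor broadly
        assert (erbb2["fraction"] > 0.9).all()


class TestCallSubtype:
    def _centroids(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(20)]
        return pd.DataFrame(
            rng.normal(2, 1, size=(20, 3)),
            index=genes,
            columns=["HRpos", "HER2pos", "TNBC"],
        ).rename_axis("gene")

    def test_exact_centroid_recovers_subtype_with_r1(self):
        cent = self._centroids()
        bulk = cent["HER2pos"]
        call = call_subtype(bulk, cent)
        assert call.called == "HER2pos"
        assert call.max_r == pytest.approx(1.0)

    def test_anticorrelated_bulk_flagged_low_confidence(self):
        cent = self._centroids()
        bulk = -cent["HRpos"]
        call = call_subtype(bulk, cent)
        assert call.low_confidence

    def test_monotone_transform_invariance(self):
        cent = self._centroids()
        bulk = cent["TNBC"] * 0.3 + 1.0
        assert call_subtype(bulk, cent).called == "TNBC"
        assert call_subtype(np.exp(bulk / 3), cent).called == "TNBC"

    def test_preset_calls_all_samples_correctly(self, preset_run, preset_study):
        calls = preset_run.subtype_calls
        subt = preset_study["truth"].patients.set_index("patient")["subtype"]
        assert len(calls) == 12
        assert (calls["called"] == calls["patient"].map(subt)).all()


class TestSampleClustering:
    def test_duplicated_sample_merges_first_with_unit_correlation(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(30)]
        pb = pd.DataFrame(
            {
                "A": rng.normal(0, 1, 30),
                "C": rng.normal(0, 1, 30),
            },
            index=genes,
        )
        pb["B"] = pb["A"]
        res = sample_correlation_clustering(pb[["A", "B", "C"]], genes)
        assert res.correlation.loc["A", "B"] == pytest.approx(1.0)
        assert res.cophenetic.loc["A", "B"] < res.cophenetic.loc["A", "C"]

    def test_correlation_matrix_symmetric_unit_diagonal(self, preset_run):
        corr = preset_run.sample_clustering.correlation
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_preset_pairs_cocluster_within_patient(self, preset_run, preset_study):
        coph = preset_run.sample_clustering.cophenetic
        subt = preset_study["truth"].patients.set_index("patient")["subtype"]
        for p in subt.index:
            d_pair = coph.loc[f"{p}_PBC", f"{p}_BCO"]
            cross = [
                coph.loc[f"{p}_{s1}", f"{q}_{s2}"]
                for q in subt.index
                if subt[q] != subt[p]
                for s1 in ("PBC", "BCO")
                for s2 in ("PBC", "BCO")
            ]
            assert d_pair < min(cross)


class TestFindStemCluster:
    def _stem_matrix(self, rng):
        # 3 blobs in expression space; blob 0 is CD44-high/ALDH1A2-low
        n_per, g = 60, 40
        base = rng.poisson(3.0, size=(3 * n_per, g))
        base[:n_per, 0] += 30          # CD44
        base[n_per:, 1] += 30          # ALDH1A2 in non-stem blobs
        base[n_per : 2 * n_per, 2] += 40
        base[2 * n_per :, 3] += 40
        symbols = ["CD44", "ALDH1A2"] + [f"G{i}" for i in range(2, g)]
        sources = ["PBC"] * 90 + ["BCO"] * 90
        return _matrix(base, symbols=symbols, sources=sources)

    def test_cd44_high_aldh_low_cluster_selected(self):
        rng = np.random.default_rng(3)
        m = self._stem_matrix(rng)
        res = find_stem_cluster(m, k=3, n_pcs=10, seed=0)
        assert res.stem_clusters
        sel = res.clusters[res.clusters["is_stem"]]
        assert sel["mean_cd44"].max() == res.clusters["mean_cd44"].max()
        assert sel["mean_aldh1a2"].min() == res.clusters["mean_aldh1a2"].min()

    def test_no_qualifying_cluster_flagged(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, size=(60, 20))
        symbols = ["CD44", "ALDH1A2"] + [f"G{i}" for i in range(2, 20)]
        counts[:30, 0] += 20
        counts[:30, 1] += 20  # CD44-high cells are also ALDH1A2-high
        m = _matrix(counts, symbols=symbols)
        res = find_stem_cluster(m, k=2, n_pcs=5, seed=0)
        assert res.stem_clusters == []
        assert res.flag == "no_stem_cluster"

    def test_preset_stem_cells_depleted_in_organoid(self, preset_run):
        res = preset_run.stem
        assert res is not None and res.stem_clusters
        props = res.proportions.set_index("source")["fraction"]
        assert props["BCO"] < props["PBC"]
        assert res.p < 0.01


class TestRegression:
    def test_perfect_correlation(self):
        x = pd.Series(np.linspace(-1, 1, 50))
        res = hypoxia_stemness_regression(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(5)
        x = pd.Series(rng.standard_normal(1000))
        y = pd.Series(rng.standard_normal(1000))
        res = hypoxia_stemness_regression(x, y)
        assert abs(res.r) < 0.1

    def test_p_matches_scipy_pearsonr_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(400)
        y = 0.5 * x + rng.standard_normal(400)
        res = hypoxia_stemness_regression(pd.Series(x), pd.Series(y))
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-8)
        t_closed = res.r * np.sqrt((len(x) - 2) / (1 - res.r**2))
        assert res.t == pytest.approx(t_closed, abs=1e-10)
        assert res.df == len(x) - 2

    def test_slope_matches_ols(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        y = 1.5 * x + rng.standard_normal(200)
        res = hypoxia_stemness_regression(pd.Series(x), pd.Series(y))
        slope_ols = np.polyfit(x, y, 1)[0]
        assert res.slope == pytest.approx(slope_ols, rel=1e-9)
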