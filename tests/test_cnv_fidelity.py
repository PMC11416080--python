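"""Clone clustering, deviation scores, retention and clone trees."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import TreeNode

from organofit.cnv_inference import CNVProfileSet
from organofit.cnv_fidelity import (
    clone_tree,
    cluster_clones,
    cnv_change_proportions,
    deviation_scores,
    retention_rate,
)


def _profiles(values, patient="P1", source="PBC", barcodes=None):
    values = np.asarray(values, dtype=float)
    n, w = values.shape
    windows = pd.DataFrame(
        {
            "window_id": [f"chr1:{i}" for i in range(w)],
            "chrom": ["chr1"] * w,
            "gene_lo": np.arange(w),
            "gene_hi": np.arange(w) + 1,
            "start_bp": np.arange(w) * 1000 + 1,
            "end_bp": np.arange(w) * 1000 + 500,
        }
    )
    cells = pd.DataFrame(
        {
            "barcode": barcodes or [f"{patient}_{source}_{i}" for i in range(n)],
            "patient": [patient] * n,
            "source": [source] * n,
        }
    )
    return CNVProfileSet(values=values, windows=windows, cells=cells)


def _two_clone_values(rng, n_per=40, w=30, sep=1.0, noise=0.1):
    a = np.zeros(w)
    a[:8] = sep
    b = np.zeros(w)
    b[-8:] = -sep
    x = np.vstack(
        [a + rng.normal(0, noise, (n_per, w)), b + rng.normal(0, noise, (n_per, w))]
    )
    return x, np.array([0] * n_per + [1] * n_per)


class TestClusterClones:
    def test_recovers_two_implanted_clones(self):
        rng = np.random.default_rng(0)
        x, truth = _two_clone_values(rng)
        cs = cluster_clones(_profiles(x), k_range=(2, 6))
        assert cs.n_clones == 2
        lab = pd.factorize(cs.assignments["clone_id"])[0]
        acc = max((lab == truth).mean(), (lab == 1 - truth).mean())
        assert acc >= 0.95

    def test_identical_profiles_fall_back_to_single_clone(self):
        x = np.ones((25, 10))
        cs = cluster_clones(_profiles(x), k_range=(2, 6))
        assert cs.n_clones == 1
        assert "single_clone_fallback" in cs.flags

    def test_cell_order_permutation_gives_same_partition(self):
        rng = np.random.default_rng(1)
        x, _ = _two_clone_values(rng)
        prof = _profiles(x)
        cs1 = cluster_clones(prof, k_range=(2, 4))
        perm = rng.permutation(x.shape[0])
        cs2 = cluster_clones(prof.subset(perm), k_range=(2, 4))
        m1 = cs1.assignments.set_index("barcode")["clone_id"]
        m2 = cs2.assignments.set_index("barcode")["clone_id"]
        joined = pd.DataFrame({"a": m1, "b": m2.loc[m1.index]})
        # same partition up to clone relabelling
        assert (joined.groupby("a")["b"].nunique() == 1).all()
        assert (joined.groupby("b")["a"].nunique() == 1).all()

    def test_too_few_cells_raises(self):
        from organofit.core_io import InsufficientCellsError

        with pytest.raises(InsufficientCellsError):
            cluster_clones(_profiles(np.zeros((5, 4))), min_cells=20)


class TestDeviationScores:
    def test_cell_equal_to_centroid_has_zero_paired_deviation(self):
        rng = np.random.default_rng(2)
        x, _ = _two_clone_values(rng)
        cs = cluster_clones(_profiles(x), k_range=(2, 4))
        bco = _profiles(cs.centroids[[0]], source="BCO")
        dev = deviation_scores(bco, {"P1": cs}, n_perm=20, seed=0)
        assert dev.scores["D_paired"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_profile_excluded_and_counted(self):
        rng = np.random.default_rng(3)
        x, _ = _two_clone_values(rng)
        cs = cluster_clones(_profiles(x), k_range=(2, 4))
        vals = np.vstack([cs.centroids[0], np.full(x.shape[1], 0.7)])
        bco = _profiles(vals, source="BCO")
        dev = deviation_scores(bco, {"P1": cs}, n_perm=10, seed=0)
        assert dev.n_excluded_constant == 1
        assert len(dev.scores) == 1

    def test_preset_ordering_paired_background_random(self, preset_run):
        means = preset_run.deviation.scores.groupby("patient")[
            ["D_paired", "D_background", "D_random"]
        ].mean()
        assert (means["D_paired"] < means["D_background"]).all()
        assert (means["D_background"] < means["D_random"]).all()
        tests = preset_run.deviation.tests
        assert (tests["p"] < 0.01).all()

    def test_random_null_stochastically_dominates_paired(self, preset_run):
        scores = preset_run.deviation.scores
        u = stats.mannwhitneyu(
            scores["D_paired"], scores["D_random"], alternative="less"
        )
        assert u.pvalue < 0.01

    def test_scores_within_bounds(self, preset_run):
        s = preset_run.deviation.scores
        for col in ("D_paired", "D_background", "D_random"):
            assert s[col].between(0, 2).all()


class TestRetention:
    def test_self_retention_is_exactly_one(self):
        rng = np.random.default_rng(4)
        x, _ = _two_clone_values(rng)
        prof = _profiles(x)
        cs = cluster_clones(prof, k_range=(2, 4))
        res = retention_rate({"P1": cs}, prof)
        assert res.per_patient["retention_rate"].iloc[0] == 1.0

    def test_unreachable_threshold_gives_zero_retention(self):
        rng = np.random.default_rng(5)
        x, _ = _two_clone_values(rng, noise=0.2)
        prof = _profiles(x)
        cs = cluster_clones(prof, k_range=(2, 4))
        res = retention_rate({"P1": cs}, prof, tau=1.0)
        assert res.per_patient["retention_rate"].iloc[0] == 0.0

    def test_no_bco_cells_flagged(self):
        rng = np.random.default_rng(6)
        x, _ = _two_clone_values(rng)
        prof = _profiles(x)
        cs = cluster_clones(prof, k_range=(2, 4))
        empty = prof.subset(np.zeros(prof.n_cells, dtype=bool))
        res = retention_rate({"P1": cs}, empty)
        assert res.per_patient["retention_rate"].iloc[0] == 0.0
        assert res.per_patient["flag"].iloc[0] == "no_bco_malignant_cells"

    def test_lost_clone_reduces_retention_toward_design(self):
        """Organoid drawn from clone A only: retention ~ A's PBC fraction."""
        rng = np.random.default_rng(7)
        w = 30
        a = np.zeros(w); a[:8] = 1.0
        b = np.zeros(w); b[-8:] = -1.0
        pbc_vals = np.vstack(
            [a + rng.normal(0, 0.1, (60, w)), b + rng.normal(0, 0.1, (40, w))]
        )
        pbc = _profiles(pbc_vals)
        cs = cluster_clones(pbc, k_range=(2, 4))
        bco = _profiles(a + rng.normal(0, 0.1, (50, w)), source="BCO")
        res = retention_rate({"P1": cs}, bco)
        assert res.per_patient["retention_rate"].iloc[0] == pytest.approx(0.6, abs=0.1)

    def test_preset_estimates_track_design(self, preset_run, preset_study):
        est = preset_run.retention.per_patient.set_index("patient")["retention_rate"]
        des = preset_study["truth"].patients.set_index("patient")["designed_retention"]
        assert (est - des).abs().max() <= 0.10


class TestChangeProportions:
    def test_zero_profiles_all_neutral(self):
        out = cnv_change_proportions(_profiles(np.zeros((5, 10))))
        row = out.iloc[0]
        assert (row["amplified"], row["deleted"], row["neutral"]) == (0.0, 0.0, 1.0)

    def test_zero_threshold_leaves_no_neutral_on_noise(self):
        rng = np.random.default_rng(8)
        out = cnv_change_proportions(_profiles(rng.normal(0, 1, (5, 10))), delta=0.0)
        assert out["neutral"].iloc[0] == 0.0

    def test_gain_only_clone_amplified_exceeds_deleted(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.05, (20, 30))
        vals[:, :10] += 0.8
        out = cnv_change_proportions(_profiles(vals))
        assert out["amplified"].iloc[0] > out["deleted"].iloc[0]

    def test_fractions_sum_to_one(self, preset_run):
        out = preset_run.cnv_changes
        np.testing.assert_allclose(
            out[["amplified", "deleted", "neutral"]].sum(axis=1), 1.0
        )


class TestCloneTree:
    def test_two_clones_rooted_at_diploid(self):
        rng = np.random.default_rng(10)
        x, _ = _two_clone_values(rng)
        cs = clone_tree(_profiles(x), k_range=(2, 4))
        tree = TreeNode.read(io.StringIO(cs.tree))
        assert tree.name == "diploid"
        assert sorted(t.name for t in tree.tips()) == sorted(cs.clone_ids)

    def test_single_clone_star_tree(self):
        x = np.ones((25, 10)) * 0.5
        cs = clone_tree(_profiles(x), k_range=(2, 4))
        assert cs.n_clones == 1
        tree = TreeNode.read(io.StringIO(cs.tree))
        assert tree.name == "diploid"
        tip = next(iter(tree.tips()))
        assert tip.length == pytest.approx(np.linalg.norm(cs.centroids[0]), rel=1e-4)

    def test_clone_at_diploid_profile_has_zero_root_distance(self):
        rng = np.random.default_rng(11)
        w = 30
        clone = np.zeros(w); clone[:10] = 1.0
        vals = np.vstack(
            [np.zeros((30, w)) + rng.normal(0, 0.01, (30, w)),
             clone + rng.normal(0, 0.01, (30, w))]
        )
        cs = clone_tree(_profiles(vals), k_range=(2, 3))
        tree = TreeNode.read(io.StringIO(cs.tree))
        burdens = dict(zip(cs.counts["clone_id"], cs.counts["mean_burden"]))
        near_diploid = min(burdens, key=burdens.get)
        d = tree.find(near_diploid).accumulate_to_ancestor(tree)
        assert d == pytest.approx(0.0, abs=0.05)

    def test_nested_segments_order_root_distances(self):
        """Clone B carrying A's events plus extra sits further from the root."""
        rng = np.random.default_rng(12)
        w = 40
        a = np.zeros(w); a[:10] = 1.0
        b = a.copy(); b[20:30] = -1.0
        vals = np.vstack(
            [a + rng.normal(0, 0.05, (40, w)), b + rng.normal(0, 0.05, (40, w))]
        )
        cs = clone_tree(_profiles(vals), k_range=(2, 3))
        tree = TreeNode.read(io.StringIO(cs.tree))
        burdens = dict(zip(cs.counts["clone_id"], cs.counts["mean_burden"]))
        lo = min(burdens, key=burdens.get)
        hi = max(burdens, key=burdens.get)
        d_lo = tree.find(lo).accumulate_to_ancestor(tree)
        d_hi = tree.find(hi).accumulate_to_ancestor(tree)
        assert d_hi > d_lo

    def test_burden_mostly_increases_root_to_leaf_on_preset(self, preset_run):
        """CNV burden accumulates along most root-to-leaf paths."""
        good = total = 0
        for p, cs in preset_run.trees.items():
            tree = TreeNode.read(io.StringIO(cs.tree))
            burdens = dict(zip(cs.counts["clone_id"], cs.counts["mean_burden"]))
            dists = {
                cid: tree.find(cid).accumulate_to_ancestor(tree) for cid in burdens
            }
            order = sorted(burdens, key=dists.get)
            for earlier, later in zip(order, order[1:]):
                total += 1
                if burdens[later] >= burdens[earlier] - 1e-6:
                    good += 1
        assert total > 0
        assert good / total >= 0.8
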