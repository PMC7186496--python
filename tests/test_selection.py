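"""SVM-RFE ranking, t/F routing, stage-1 screen, intersection, sparse PCA."""

import numpy as np
import pytest
from sklearn.svm import SVC

from sahpanel.datasets import map_probes_to_genes
from sahpanel.diffexpr import Contrast
from sahpanel.selection import (
    PanelReport,
    SparsePCA,
    SVMRFE,
    apply_allowlist,
    cross_arm_intersect,
    spca_reduce,
    stage1_select,
    t_and_f_test,
)
from sahpanel.simulate import SimulationConfig, simulate_chip_arm


class TestSVMRFE:
    def test_separating_feature_survives(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 51))
            y = rng.integers(0, 2, size=30)
            X[:, 17] += 5.0 * y  # a perfectly separating feature among noise
            rfe = SVMRFE(kernel="linear", k_keep=3, step=1).fit(X, y)
            assert "f17" in rfe.surviving_

    def test_linear_dj_equals_half_squared_weight(self):
        """Single-elimination DJ ordering equals the squared-primal-weight
        ordering at every iteration (checked on random small instances)."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 12))
            y = rng.integers(0, 2, size=24)
            X[:, 0] += 1.5 * y
            surviving = list(range(12))
            Xs = (X - X.mean(0)) / X.std(0)
            while len(surviving) > 4:
                rfe = SVMRFE(kernel="linear", k_keep=len(surviving), step=1).fit(
                    X[:, surviving], y
                )
                svc = SVC(kernel="linear").fit(
                    (lambda Z: (Z - Z.mean(0)) / Z.std(0))(X[:, surviving]), y
                )
                w2 = 0.5 * svc.coef_.ravel() ** 2
                np.testing.assert_allclose(rfe.dj_scores_, w2, rtol=1e-8, atol=1e-12)
                surviving.pop(int(np.argmin(w2)))

    def test_single_pass_equals_initial_sort(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 15))
        y = rng.integers(0, 2, size=20)
        one_shot = SVMRFE(kernel="linear", k_keep=5, step=10).fit(X, y)
        ranked = SVMRFE(kernel="linear", k_keep=15, step=1).fit(X, y)
        order = np.argsort(-ranked.dj_scores_)
        expected_top = {f"f{i}" for i in order[:5]}
        assert set(one_shot.surviving_) == expected_top

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 10))
        y = rng.integers(0, 2, size=20)
        X[:, 3] += 2.0 * y
        names = [f"gene{i:02d}" for i in range(10)]
        perm = rng.permutation(10)
        a = SVMRFE(kernel="linear", k_keep=2, step=1).fit(X, y, feature_names=names)
        b = SVMRFE(kernel="linear", k_keep=2, step=1).fit(
            X[:, perm], y, feature_names=[names[i] for i in perm]
        )
        assert set(a.surviving_) == set(b.surviving_)
        for (_, ra), (_, rb) in zip(a.removal_log_, b.removal_log_):
            assert ra == rb

    def test_rbf_kernel_runs(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 8))
        y = rng.integers(0, 2, size=20)
        X[:, 2] += 3.0 * y
        rfe = SVMRFE(kernel="rbf", k_keep=2, step=1).fit(X, y)
        assert "f2" in rfe.surviving_

    def test_non_binary_labels_rejected(self):
        X = np.zeros((6, 3))
        with pytest.raises(ValueError, match="two classes"):
            SVMRFE().fit(X, np.array([0, 1, 2, 0, 1, 2]))


class TestTAndFTest:
    def test_identical_groups_nothing_significant(self, make_dataset):
        rng = np.random.default_rng(12)
        half = rng.normal(size=(40, 5))
        ds = make_dataset(np.hstack([half, half]), ["a"] * 5 + ["b"] * 5)
        out = t_and_f_test(ds, Contrast.between("a", "b"))
        assert not out["significant"].any()

    def test_f_test_calibration_under_equal_variances(self, make_dataset):
        """Null F-test rejection rate stays near its nominal level."""
        rng = np.random.default_rng(13)
        x = rng.normal(size=(2000, 10))
        ds = make_dataset(x, ["a"] * 5 + ["b"] * 5)
        out = t_and_f_test(ds, Contrast.between("a", "b"), alpha_level=0.05)
        rate = float((out["f_p"] < 0.05).mean())
        assert abs(rate - 0.05) <= 0.02

    def test_planted_shift_detected(self, make_dataset):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, size=(20, 10))
        x[0, :5] += 4.0  # 4-sigma shift in group a
        ds = make_dataset(x, ["a"] * 5 + ["b"] * 5)
        out = t_and_f_test(ds, Contrast.between("a", "b"), alpha_level=0.05)
        assert out["significant"].iloc[0]

    def test_variance_routing(self, make_dataset):
        rng = np.random.default_rng(15)
        x = np.vstack(
            [
                np.hstack([rng.normal(0, 1, 8), rng.normal(0, 1, 8)]),
                np.hstack([rng.normal(0, 1, 8), rng.normal(0, 8, 8)]),
            ]
        )
        ds = make_dataset(x, ["a"] * 8 + ["b"] * 8)
        out = t_and_f_test(ds, Contrast.between("a", "b"))
        assert out["variance_mode"].iloc[0] == "pooled"
        assert out["variance_mode"].iloc[1] == "welch"


class TestStage1:
    def test_recovers_strong_effect_genes(self):
        """>=80% of the strong-effect genes reach the stage-1 set."""
        cfg = SimulationConfig(
            n_genes=3000,
            n_de_genes=300,
            log2_effect=0.6,
            n_strong_de=47,
            strong_log2_effect=2.5,
            top_subset_size=3,
            biomarker_panel_size=9,
            seed=21,
        )
        ds, truth = simulate_chip_arm(cfg)
        result = stage1_select(ds, Contrast.between("SAH", "normal-1"), truth.annotation)
        recovered = set(result.stage1_genes) & truth.strong_genes
        assert len(recovered) >= 0.8 * len(truth.strong_genes)

    def test_impossible_threshold_gives_empty_set(self, small_chip_config):
        ds, truth = simulate_chip_arm(small_chip_config)
        with pytest.warns(UserWarning, match="empty"):
            result = stage1_select(
                ds,
                Contrast.between("SAH", "normal-1"),
                truth.annotation,
                fc_threshold=1e6,
            )
        assert result.stage1_genes == []

    def test_duplicate_probes_deduplicated(self, small_chip_config):
        ds, truth = simulate_chip_arm(small_chip_config)
        ann = truth.annotation
        dup_gene = ann["gene_id"][ann["gene_id"].duplicated()].iloc[0]
        probes = list(ann.loc[ann["gene_id"] == dup_gene, "probe_id"])
        assert map_probes_to_genes(probes + probes, ann) == [dup_gene]


class TestIntersect:
    def test_plain_intersection(self):
        sets = {"c1": {"A", "B", "C"}, "c2": {"B", "C", "D"}}
        assert cross_arm_intersect(sets) == ["B", "C"]

    def test_empty_member_annihilates(self):
        assert cross_arm_intersect({"c1": {"A"}, "c2": set()}) == []

    def test_single_contrast_rejected(self):
        with pytest.raises(ValueError):
            cross_arm_intersect({"c1": {"A"}})


class TestSparsePCA:
    def test_zero_penalty_matches_pca(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(16)
        X = rng.normal(size=(50, 9))
        X[:, :3] += 2.0 * rng.normal(size=(50, 1))
        ours = SparsePCA(n_components=1, sparsity=0.0).fit(X)
        ref = PCA(n_components=1).fit(X).components_[0]
        b = ours.components_[0]
        assert min(np.abs(b - ref).max(), np.abs(b + ref).max()) < 1e-6

    def test_large_penalty_empties_support(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 6))
        est = SparsePCA(n_components=2, sparsity=1e9).fit(X)
        assert est.selected_.sum() == 0
        assert est.converged_

    def test_two_block_support_recovery(self, make_dataset):
        """Two orthogonal planted directions with disjoint 5+4 supports are
        recovered exactly at moderate sparsity."""
        rng = np.random.default_rng(18)
        n = 80
        f1 = rng.normal(0, 3, size=n)
        f2 = rng.normal(0, 2, size=n)
        f2 -= f1 * (f2 @ f1) / (f1 @ f1)  # orthogonal planted directions
        X = rng.normal(0, 0.1, size=(n, 9))
        X[:, :5] += f1[:, None]
        X[:, 5:] += f2[:, None]
        est = SparsePCA(n_components=2, sparsity=1.5).fit(X)
        supports = [set(np.flatnonzero(c)) for c in est.components_]
        assert {frozenset(s) for s in supports} == {
            frozenset(range(5)),
            frozenset(range(5, 9)),
        }

    def test_spca_reduce_respects_gene_budget(self, make_dataset):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 0.3, size=(9, 25))
        x[:3, :12] += 3.0  # three dominant genes
        ds = make_dataset(x, ["a"] * 12 + ["b"] * 13)
        out = spca_reduce(ds, [f"g{i}" for i in range(9)], n_components=2, max_genes=5)
        assert 1 <= len(out.selected_genes) <= 5
        assert set(out.selected_genes) >= {"g0", "g1", "g2"}


class TestPanelReport:
    def test_nesting_violation_raises(self):
        report = PanelReport(
            ebayes_set={"p1"},
            rfe_top_set={"p1"},
            stage1_set={"A"},
            per_arm_significant={},
            intersection_set={"A", "B"},
            spca_candidates={"A"},
            final_panel={"A"},
        )
        with pytest.raises(AssertionError, match="intersection"):
            report.validate()

    def test_allowlist_filters(self):
        assert apply_allowlist({"b", "a", "c"}, ["a", "c", "z"]) == ["a", "c"]
        assert apply_allowlist({"b", "a"}, None) == ["a", "b"]
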