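import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from omicsurv import (
    ClinicalTable,
    OmicsMatrix,
    compare_diversity,
    loo_predict,
    shannon_diversity,
    stage_chi_square,
    stage_prediction,
    top_k_features,
)
from omicsurv.subtyping import SubtypeAssignment


def assignment(labels):
    n = len(labels)
    return SubtypeAssignment(
        [f"S{i:04d}" for i in range(n)], list(labels), len(set(labels)), 0.5
    )


def chi_square_oracle(table):
    """First-principles Pearson chi-square on a contingency table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


class TestStageChiSquare:
    def _run(self, counts_by_subtype):
        labels, stages = [], []
        for subtype, stage_counts in counts_by_subtype.items():
            for stage, c in stage_counts.items():
                labels += [subtype] * c
                stages += [stage] * c
        a = assignment(labels)
        clin = ClinicalTable(a.sample_ids, stages)
        return stage_chi_square(a, clin)

    def test_proportional_table_is_null(self):
        stat, p, _ = self._run(
            {"ASD-1": {"I": 10, "II": 20}, "ASD-2": {"I": 5, "II": 10}}
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_is_extreme(self):
        stat, p, _ = self._run({"ASD-1": {"I": 20}, "ASD-2": {"IV": 20}})
        assert p < 1e-8
        assert stat == pytest.approx(chi_square_oracle([[20, 0], [0, 20]]))

    @pytest.mark.parametrize("shape", [(2, 2), (2, 3), (3, 3), (4, 4)])
    def test_matches_first_principles_oracle(self, shape):
        rng = np.random.default_rng(shape[0] * 10 + shape[1])
        stages = ["I", "II", "III", "IV"][: shape[1]]
        counts = {
            f"ASD-{i + 1}": {
                s: int(rng.integers(3, 20)) for s in stages
            }
            for i in range(shape[0])
        }
        stat, _, table = self._run(counts)
        assert stat == pytest.approx(chi_square_oracle(table.to_numpy()))

    def test_margins_match_group_sizes(self):
        _, _, table = self._run(
            {"ASD-1": {"I": 7, "IV": 3}, "ASD-2": {"I": 2, "IV": 8}}
        )
        assert table.sum(axis=1).tolist() == [10, 10]
        assert table.sum(axis=0).tolist() == [9, 11]

    def test_na_samples_excluded_and_single_stage_rejected(self):
        a = assignment(["ASD-1", "ASD-1", "ASD-2", "ASD-2"])
        clin = ClinicalTable(a.sample_ids, ["I", "NA", "I", "NA"])
        with pytest.raises(ValueError, match="one stage"):
            stage_chi_square(a, clin)


class TestLooPredict:
    def test_separable_blobs_reach_auroc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 8]
        )
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        rep = loo_predict(X, y, "random_forest", seed=0, n_estimators=100)
        assert rep.value == pytest.approx(1.0)
        assert rep.majority_share == pytest.approx(0.5)

    def test_permuted_labels_mean_auroc_near_half(self):
        aucs = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            X = rng.standard_normal((40, 10))
            y = np.array([0] * 20 + [1] * 20)
            rng.shuffle(y)
            aucs.append(loo_predict(X, y, "logistic", seed=rep).value)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_duplication_stable_in_separable_limit(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.standard_normal((15, 4)), rng.standard_normal((15, 4)) + 6]
        )
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        a = loo_predict(X, y, "logistic").value
        b = loo_predict(
            np.vstack([X, X]), np.concatenate([y, y]), "logistic"
        ).value
        assert abs(a - b) <= 0.02

    def test_single_class_rejected(self):
        X = np.zeros((12, 2))
        with pytest.raises(ValueError, match="classes"):
            loo_predict(X, np.zeros(12, int), "logistic")

    @pytest.mark.parametrize("model", ["knn", "svm", "logistic"])
    def test_alternative_classifiers_supported(self, model):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.standard_normal((10, 2)), rng.standard_normal((10, 2)) + 7]
        )
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        rep = loo_predict(X, y, model, seed=0)
        assert rep.value > 0.95

    def test_auroc_invariant_to_monotone_score_transforms(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        s = rng.standard_normal(50)
        base = roc_auc_score(y, s)
        for f in (np.exp, np.tanh, lambda v: v**3 + 2):
            assert roc_auc_score(y, f(s)) == pytest.approx(base)


class TestTopKFeatures:
    def test_perfectly_informative_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        n = 60
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X = rng.standard_normal((n, 10))
        X[:, 4] = y * 5 + 0.01 * rng.standard_normal(n)
        ids = [f"f{j}" for j in range(10)]
        top = top_k_features(X, y, k=3, seed=0, n_estimators=200, feature_ids=ids)
        assert top[0] == "f4"

    def test_output_length_and_determinism(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 6))
        y = rng.integers(0, 2, 30)
        ids = [f"f{j}" for j in range(6)]
        a = top_k_features(X, y, k=6, seed=1, n_estimators=50, feature_ids=ids)
        b = top_k_features(X, y, k=6, seed=1, n_estimators=50, feature_ids=ids)
        assert a == b and len(a) == 6
        with pytest.raises(ValueError, match="exceeds"):
            top_k_features(X, y, k=7, feature_ids=ids)


class TestStagePrediction:
    def test_perfectly_encoded_stage_predicted(self):
        stages = ["I"] * 15 + ["IV"] * 15
        X = np.array([[0.0] if s == "I" else [5.0] for s in stages])
        X = X + 0.01 * np.random.default_rng(6).standard_normal(X.shape)
        rep = stage_prediction(X, stages, mode="all_stages", n_estimators=100)
        assert rep.value == pytest.approx(1.0)
        assert rep.majority_share == pytest.approx(0.5)

    def test_eligibility_rule_rejects_low_stage14_share(self):
        stages = ["I"] * 5 + ["II"] * 10 + ["III"] * 5  # 25% in I+IV
        X = np.zeros((20, 2))
        with pytest.raises(ValueError, match="0.250"):
            stage_prediction(X, stages, mode="stage1_vs_4")

    def test_stage14_mode_restricts_and_reports_majority(self):
        rng = np.random.default_rng(7)
        stages = ["I"] * 12 + ["IV"] * 6 + ["II"] * 6
        X = rng.standard_normal((24, 3))
        X[:12] += 4
        rep = stage_prediction(X, stages, mode="stage1_vs_4", n_estimators=100)
        assert rep.extra["n_used"] == 18
        assert rep.majority_share == pytest.approx(12 / 18)


class TestDiversity:
    def _micro(self, values):
        values = np.asarray(values, dtype=float)
        return OmicsMatrix(
            [f"S{i:04d}" for i in range(values.shape[0])],
            [f"t{j}" for j in range(values.shape[1])],
            values,
            "microbiome",
            state="normalized",
        )

    def test_uniform_four_taxa_is_ln4(self):
        h = shannon_diversity(self._micro([[0.25, 0.25, 0.25, 0.25]]))
        assert h[0] == pytest.approx(np.log(4))

    def test_single_taxon_is_zero(self):
        h = shannon_diversity(self._micro([[1.0, 0.0]]))
        assert h[0] == 0.0

    def test_identical_groups_give_p_one(self):
        div = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        a = assignment(["ASD-1"] * 3 + ["ASD-2"] * 3)
        _, p = compare_diversity(a, div)
        assert p == pytest.approx(1.0)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(8)
        div = np.r_[rng.normal(1, 0.1, 30), rng.normal(2, 0.1, 30)]
        a = assignment(["ASD-1"] * 30 + ["ASD-2"] * 30)
        _, p = compare_diversity(a, div)
        assert p < 1e-6
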