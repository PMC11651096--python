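import numpy as np
import pandas as pd
import pytest

from omicsurv import (
    cox_screen,
    direct_cox_baseline,
    evaluate_subtypes,
    km_estimate,
    order_labels_by_prognosis,
    select_k_and_cluster,
)
from omicsurv._cox import univariate_cox
from omicsurv.core_io import SurvivalTable
from omicsurv.subtyping import SubtypeAssignment

from conftest import make_latent, make_survival


class TestUnivariateCoxAgainstLifelines:
    def test_coefficients_and_pvalues_match(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        n = 60
        X = rng.standard_normal((n, 4))
        # moderate real effect on feature 0
        t = rng.exponential(np.exp(-0.6 * X[:, 0]))
        e = (rng.random(n) > 0.25).astype(int)
        res = univariate_cox(X, t, e)
        # lifelines stops at its default Newton precision (gradient ~1e-4),
        # so agreement is bounded by that, not by machine epsilon
        for j in range(4):
            df = pd.DataFrame({"T": t, "E": e, "x": X[:, j]})
            cph = CoxPHFitter().fit(df, "T", "E")
            assert res.coef[j] == pytest.approx(
                float(cph.summary["coef"].iloc[0]), rel=2e-3, abs=1e-4
            )
            assert res.p_value[j] == pytest.approx(
                float(cph.summary["p"].iloc[0]), rel=5e-3, abs=1e-6
            )

    def test_efron_tie_handling_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(1)
        n = 50
        X = rng.standard_normal((n, 2))
        t = rng.integers(1, 8, n).astype(float)  # heavy ties
        e = (rng.random(n) > 0.3).astype(int)
        res = univariate_cox(X, t, e)
        for j in range(2):
            df = pd.DataFrame({"T": t, "E": e, "x": X[:, j]})
            cph = CoxPHFitter().fit(df, "T", "E")
            assert res.coef[j] == pytest.approx(
                float(cph.summary["coef"].iloc[0]), rel=2e-3, abs=1e-4
            )

    def test_pvalue_agrees_with_permutation_oracle(self):
        # small-n oracle: permutation distribution of the Wald statistic
        rng = np.random.default_rng(2)
        n = 30
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(n, dtype=int)
        res = univariate_cox(x[:, None], t, e)
        z_obs = abs(res.coef[0] / res.se[0])
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r = univariate_cox(x[perm][:, None], t, e)
            hits += abs(r.coef[0] / r.se[0]) >= z_obs
        p_perm = hits / n_perm
        mc_sd = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert abs(res.p_value[0] - p_perm) < 4 * mc_sd + 0.03


class TestCoxScreen:
    def test_perfect_concordance_feature_selected(self):
        n = 50
        rng = np.random.default_rng(3)
        t = np.sort(rng.exponential(1, n))
        x = -(np.argsort(np.argsort(t)) + 1.0)  # negative death-order rank
        lat = make_latent(np.column_stack([x, rng.standard_normal(n)]))
        surv = SurvivalTable(lat.sample_ids, t, np.ones(n, int))
        screen = cox_screen(lat, surv)
        assert screen.p_value[0] < 1e-4
        assert bool(screen.selected[0])

    def test_null_selection_rate_within_binomial_band(self):
        rng = np.random.default_rng(4)
        n, p = 200, 1000
        lat = make_latent(rng.standard_normal((n, p)))
        surv = make_survival(n, seed=5, censor=0.2)
        screen = cox_screen(lat, surv, alpha=0.05)
        frac = screen.selected.mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / p)
        assert 0.05 - half < frac < 0.05 + half

    def test_constant_feature_flagged_not_selected(self):
        n = 30
        lat = make_latent(
            np.column_stack([np.ones(n), np.random.default_rng(6).standard_normal(n)])
        )
        surv = make_survival(n, seed=6)
        screen = cox_screen(lat, surv)
        assert screen.flag[0] == "zero_variance"
        assert not screen.selected[0]
        assert np.isnan(screen.p_value[0])

    def test_zero_events_rejected(self):
        n = 20
        lat = make_latent(np.random.default_rng(7).standard_normal((n, 3)))
        surv = SurvivalTable(
            lat.sample_ids, np.ones(n) * 5, np.zeros(n, int)
        )
        with pytest.raises(ValueError, match="events"):
            cox_screen(lat, surv)

    def test_selected_iff_p_below_alpha(self):
        rng = np.random.default_rng(8)
        lat = make_latent(rng.standard_normal((60, 50)))
        surv = make_survival(60, seed=8)
        screen = cox_screen(lat, surv, alpha=0.1)
        ok = np.array([f in ("ok", "boundary") for f in screen.flag])
        with np.errstate(invalid="ignore"):
            expected = ok & (screen.p_value < 0.1)
        np.testing.assert_array_equal(screen.selected, expected)


class TestClusterSelection:
    def test_three_well_separated_blobs_recover_k3(self):
        rng = np.random.default_rng(9)
        centers = np.array([[0.0, 0], [10, 0], [0, 10]])
        pts = np.vstack([c + 0.5 * rng.standard_normal((50, 2)) for c in centers])
        truth = np.repeat([0, 1, 2], 50)
        a = select_k_and_cluster(make_latent(pts), seed=0)
        assert a.K == 3
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, a.numeric_labels()) == 1.0

    def test_two_blobs_twenty_sigma_apart(self):
        rng = np.random.default_rng(10)
        pts = np.vstack(
            [rng.standard_normal((40, 3)), rng.standard_normal((40, 3)) + 20]
        )
        a = select_k_and_cluster(make_latent(pts), seed=0)
        assert a.K == 2
        assert a.silhouette > 0.9

    def test_single_blob_has_low_silhouette_everywhere(self):
        rng = np.random.default_rng(11)
        a = select_k_and_cluster(make_latent(rng.standard_normal((80, 4))), seed=0)
        assert all(s < 0.3 for s in a.candidate_scores.values())

    def test_too_few_features_is_the_na_condition(self):
        with pytest.raises(ValueError, match="no survival-related features"):
            select_k_and_cluster(make_latent(np.zeros((30, 1))), seed=0)


class TestPrognosisOrdering:
    def _assignment(self, labels):
        n = len(labels)
        return SubtypeAssignment(
            [f"S{i:04d}" for i in range(n)], list(labels), len(set(labels)), 0.5
        )

    def test_better_surviving_group_becomes_asd1(self):
        # group B: all events before t=1; group A: all censored late
        labels = ["ASD-1"] * 10 + ["ASD-2"] * 10
        t = np.r_[np.full(10, 0.5), np.full(10, 100.0)]
        e = np.r_[np.ones(10, int), np.zeros(10, int)]
        surv = SurvivalTable([f"S{i:04d}" for i in range(20)], t, e)
        out = order_labels_by_prognosis(self._assignment(labels), surv)
        assert out.labels[:10] == ["ASD-2"] * 10
        assert out.labels[10:] == ["ASD-1"] * 10

    def test_idempotent_and_name_invariant(self):
        rng = np.random.default_rng(12)
        labels = ["ASD-1" if x < 0.5 else "ASD-2" for x in rng.random(40)]
        surv = make_survival(40, seed=12)
        once = order_labels_by_prognosis(self._assignment(labels), surv)
        twice = order_labels_by_prognosis(once, surv)
        assert once.labels == twice.labels
        swapped = ["ASD-2" if l == "ASD-1" else "ASD-1" for l in labels]
        out_sw = order_labels_by_prognosis(self._assignment(swapped), surv)
        assert out_sw.labels == once.labels


class TestEvaluation:
    def test_identical_groups_give_null_logrank(self):
        t = np.r_[1.0, 2, 3, 4, 1, 2, 3, 4]
        e = np.r_[1, 1, 0, 1, 1, 1, 0, 1]
        ids = [f"S{i:04d}" for i in range(8)]
        a = SubtypeAssignment(ids, ["ASD-1"] * 4 + ["ASD-2"] * 4, 2, 0.0)
        ev = evaluate_subtypes(a, SurvivalTable(ids, t, e))
        assert ev.logrank_p == pytest.approx(1.0)

    def test_perfectly_separated_pair_has_cindex_one(self):
        ids = ["S0000", "S0001"]
        a = SubtypeAssignment(ids, ["ASD-1", "ASD-2"], 2, 0.0)
        surv = SurvivalTable(ids, [10.0, 1.0], [1, 1])
        ev = evaluate_subtypes(a, surv)
        assert ev.c_index == pytest.approx(1.0)

    def test_random_labels_cindex_near_half(self):
        vals = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n = 200
            surv = make_survival(n, seed=rep, censor=0.3)
            labels = ["ASD-1" if x < 0.5 else "ASD-2" for x in rng.random(n)]
            a = SubtypeAssignment(surv.sample_ids, labels, 2, 0.0)
            vals.append(evaluate_subtypes(a, surv).c_index)
        assert 0.45 < np.mean(vals) < 0.55

    def test_km_curves_are_valid_survival_functions(self):
        surv = make_survival(50, seed=13)
        labels = ["ASD-1"] * 25 + ["ASD-2"] * 25
        a = SubtypeAssignment(surv.sample_ids, labels, 2, 0.0)
        ev = evaluate_subtypes(a, surv)
        for df in ev.km_curves.values():
            s = df["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)


class TestKMEstimate:
    def test_two_deaths_no_censoring(self):
        df = km_estimate([1.0, 2.0], [1, 1])
        s = dict(zip(df["time"], df["survival"]))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        df = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(df["survival"].to_numpy() == 1.0)

    def test_hand_computed_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2 and 4:
        # S(1) = 3/4; at t=3 risk set = {3,4}: S(3) = 3/4 * 1/2 = 0.375
        df = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        s = dict(zip(df["time"], df["survival"]))
        assert s[1.0] == pytest.approx(0.75)
        assert s[3.0] == pytest.approx(0.375)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


class TestDirectCoxBaseline:
    def test_monotone_risk_feature_recovers_true_halves(self):
        n = 60
        rng = np.random.default_rng(14)
        t = np.sort(rng.exponential(1, n))
        x = np.argsort(np.argsort(t)).astype(float)  # death-order rank
        lat = make_latent(x[:, None])
        surv = SurvivalTable(lat.sample_ids, t, np.ones(n, int))
        a, ev = direct_cox_baseline(lat, surv)
        # the half that dies first must be ASD-2
        first_half = set(np.array(lat.sample_ids)[: n // 2])
        labels = dict(zip(a.sample_ids, a.labels))
        assert all(labels[s] == "ASD-2" for s in first_half)
        assert ev.logrank_p < 1e-6

    def test_always_two_groups_even_with_many_features(self):
        rng = np.random.default_rng(15)
        n = 40
        lat = make_latent(rng.standard_normal((n, 80)))  # p > n triggers PCA
        surv = make_survival(n, seed=15)
        a, _ = direct_cox_baseline(lat, surv)
        assert a.K == 2
        assert set(a.labels) == {"ASD-1", "ASD-2"}
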