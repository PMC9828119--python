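"""Outcome layer: aggregation, logistic fits, subset search, ROC/Youden, KM, Fisher."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from timephen import outcome, synthetic
from timephen.cell_data import CELL_COLUMNS, Cohort, core_area_mm2
from timephen.outcome import (
    aggregate_patients,
    bootstrap_compare,
    cv_misclassification,
    enrichment_test,
    exhaustive_search,
    filter_followup,
    fit_logistic,
    km_estimate,
    ppv_npv_from_rates,
    roc_auc,
    subgroup_evaluate,
    youden_stratify,
)


def _mini_cohort(core_patient_pairs, patient_rows):
    cores = pd.DataFrame(
        [
            {"core_id": c, "patient_id": p, "diameter_mm": 1.2, "area_mm2": core_area_mm2()}
            for c, p in core_patient_pairs
        ]
    )
    defaults = {
        "figo_stage": "IA", "grade": "G1", "lvsi": False, "adjuvant_rt": "none",
        "mmrp_deficient": "no", "pole_mutated": "no", "ctnnb1_mutated": "no",
        "relapse": False, "relapse_type": "none", "followup_months": 100.0,
    }
    patients = pd.DataFrame([{**defaults, **row} for row in patient_rows])
    return Cohort(cells=pd.DataFrame(columns=list(CELL_COLUMNS)), cores=cores, patients=patients)


class TestAggregation:
    def test_mixed_two_core_patient_carriage_without_purity(self):
        cohort = _mini_cohort(
            [("c1", "p1"), ("c2", "p1")], [{"patient_id": "p1"}]
        )
        assign = pd.DataFrame(
            {"core_id": ["c1", "c2"], "semantic_name": ["immune_desert", "immune_exclusion"]}
        )
        out = aggregate_patients(assign, cohort)
        row = out.iloc[0]
        assert row["carriage_immune_desert"] == 1 and row["carriage_immune_exclusion"] == 1
        assert row[[f"purity_{n}" for n in synthetic.ARCHETYPE_NAMES]].sum() == 0

    def test_single_core_patient_purity_equals_carriage(self):
        cohort = _mini_cohort([("c1", "p1")], [{"patient_id": "p1"}])
        assign = pd.DataFrame({"core_id": ["c1"], "semantic_name": ["immune_desert"]})
        row = aggregate_patients(assign, cohort).iloc[0]
        assert row["carriage_immune_desert"] == row["purity_immune_desert"] == 1

    def test_margin_cohort_bookkeeping(self):
        assignments, cohort = synthetic.build_margin_cohort()
        pats = aggregate_patients(assignments, cohort)
        assert len(pats) == 235
        assert (pats["n_cores"] == 2).sum() == 169
        assert (pats["n_cores"] == 1).sum() == 66
        assert int(pats["n_cores"].sum()) == 404

    def test_patient_without_cores_dropped_with_warning(self):
        cohort = _mini_cohort(
            [("c1", "p1")], [{"patient_id": "p1"}, {"patient_id": "p2"}]
        )
        assign = pd.DataFrame({"core_id": ["c1"], "semantic_name": ["immune_desert"]})
        with pytest.warns(UserWarning, match="no assigned cores"):
            out = aggregate_patients(assign, cohort)
        assert list(out["patient_id"]) == ["p1"]


class TestFollowupFilter:
    def test_short_nonrelapse_excluded_relapse_retained(self):
        pats = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "relapse": [False, True, False],
                "followup_months": [20.0, 20.0, 40.0],
            }
        )
        kept, excluded = filter_followup(pats)
        assert list(kept["patient_id"]) == ["b", "c"]
        assert list(excluded["patient_id"]) == ["a"]


class TestLogistic:
    def test_two_by_two_closed_form_log_odds_ratio(self):
        # table {{10,40},{30,20}}: coef = ln((10*20)/(40*30))
        x = np.r_[np.ones(10), np.zeros(40), np.ones(30), np.zeros(20)]
        y = np.r_[np.ones(50), np.zeros(50)]
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert fit.coef["x"] == pytest.approx(math.log((10 * 20) / (40 * 30)), abs=1e-6)
        assert fit.converged and not fit.ridged

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        n = 5000
        df = pd.DataFrame({"x": rng.integers(0, 2, n), "y": rng.integers(0, 2, n)})
        fit = fit_logistic(df, "y", ["x"])
        assert abs(fit.coef["x"]) < 0.1

    def test_single_class_outcome_is_error(self):
        df = pd.DataFrame({"x": [0, 1, 0], "y": [1, 1, 1]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, "y", ["x"])

    def test_separation_triggers_ridge_flag(self):
        df = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1], "y": [0, 0, 0, 1, 1, 1]})
        fit = fit_logistic(df, "y", ["x"])
        assert fit.ridged

    def test_planted_parameter_recovery(self):
        cfg = synthetic.SyntheticConfig(n_patients=5000, rng_seed=17)
        cohort, truth = synthetic.generate_cohort(cfg, with_cells=False)
        df = cohort.patients.merge(truth.patients, on="patient_id")
        df["carrier"] = df["exclusion_carrier"].astype(int)
        df["y"] = df["relapse"].astype(int)
        fit = fit_logistic(df, "y", ["carrier"])
        assert abs(fit.coef["intercept"] - cfg.outcome_beta0) < 3 * fit.se["intercept"]
        assert abs(fit.coef["carrier"] - cfg.outcome_beta_exclusion) < 3 * fit.se["carrier"]


class TestExhaustiveSearch:
    @staticmethod
    def _planted(rng, n=400, beta=2.5):
        info = (rng.random(n) < 0.3).astype(int)
        noise1 = (rng.random(n) < 0.4).astype(int)
        noise2 = (rng.random(n) < 0.5).astype(int)
        p = 1 / (1 + np.exp(-(-2.0 + beta * info)))
        y = (rng.random(n) < p).astype(int)
        return pd.DataFrame({"info": info, "noise1": noise1, "noise2": noise2, "y": y})

    def test_subset_count_is_two_pow_minus_one(self):
        rng = np.random.default_rng(1)
        df = self._planted(rng)
        res = exhaustive_search(df, "y", ("info", "noise1", "noise2"), repeats=2, rng=0)
        assert len(res.table) == 7

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(2)
        df = self._planted(rng)
        r1 = exhaustive_search(df, "y", ("info", "noise1", "noise2"), repeats=3, rng=42)
        r2 = exhaustive_search(df, "y", ("info", "noise1", "noise2"), repeats=3, rng=42)
        assert r1.best_features == r2.best_features
        assert list(r1.table["mean_error"]) == list(r2.table["mean_error"])

    def test_candidate_guard(self):
        df = pd.DataFrame(np.zeros((4, 21)))
        with pytest.raises(ValueError, match="guard"):
            exhaustive_search(df, 0, tuple(range(1, 22)))

    def test_reference_only_candidates_reproduce_reference_model(self):
        """Searching over exactly the reference covariates selects a subset of them."""
        rng = np.random.default_rng(3)
        df = self._planted(rng)
        res = exhaustive_search(df, "y", ("info",), repeats=3, rng=1)
        assert res.best_features == ("info",)
        err = cv_misclassification(df, "y", ("info",), repeats=3, rng=1)
        assert 0 <= res.best_error <= 1 and 0 <= err <= 1


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_half(self):
        auc, _ = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_one_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_pair_counting_oracle(self, seed):
        """Rank identity equals exhaustive pair counting to 1e-12 (50 draws/seed)."""
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert abs(auc - wins / (len(pos) * len(neg))) < 1e-12


class TestYouden:
    def test_perfectly_separable(self):
        s = youden_stratify([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert s.sensitivity == 1.0 and s.specificity == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(30), 1)
        labels = rng.integers(0, 2, 30)
        got = youden_stratify(scores, labels)
        best = None
        for t in list(np.unique(scores)) + [np.inf]:
            pred = scores >= t
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            if best is None or (sens + spec - 1, spec) > best:
                best = (sens + spec - 1, spec)
        assert got.sensitivity + got.specificity - 1 == pytest.approx(best[0])
        assert got.specificity == pytest.approx(best[1])

    def test_fixture_scores(self):
        s = youden_stratify([0.9, 0.8, 0.7, 0.4, 0.3, 0.1], [1, 1, 0, 1, 0, 0])
        # exhaustive scan: J = 2/3 at both 0.4 (sens 1, spec 2/3) and 0.8
        # (sens 2/3, spec 1); the tie goes to the higher-specificity cut
        assert s.cutoff == pytest.approx(0.8)
        assert s.sensitivity == pytest.approx(2 / 3) and s.specificity == 1.0


class TestPredictiveValues:
    def test_perfect_test(self):
        assert ppv_npv_from_rates(1.0, 1.0, 0.3) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_with_confusion_matrix(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = rng.integers(1, 50, 4)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        prev = (tp + fn) / (tp + fp + fn + tn)
        ppv, npv = ppv_npv_from_rates(sens, spec, prev)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ppv_npv_from_rates(1.2, 0.5, 0.1)


class TestBootstrapCompare:
    def test_identical_scores_all_ties(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        res = bootstrap_compare(s, s, y, B=200, rng=1)
        assert res.ties == 200 and res.a_wins == 0 and res.b_wins == 0

    def test_exchangeable_scores_symmetric_across_experiments(self):
        """Exchangeable score pairs: neither model wins systematically.

        Within one experiment the bootstrap concentrates around the fixed
        full-sample AUCs, so symmetry only holds across independent score
        draws: the fraction of experiments where A takes the majority of
        non-tied replicates is Binomial(1/2).
        """
        rng = np.random.default_rng(5)
        n = 60
        y = np.r_[np.ones(20, int), np.zeros(40, int)]
        a_major = 0
        n_exp = 40
        for _ in range(n_exp):
            a, b = rng.random(n), rng.random(n)
            res = bootstrap_compare(a, b, y, B=100, rng=rng)
            a_major += res.a_wins > res.b_wins
        half_width = 2.576 * math.sqrt(0.25 / n_exp)
        assert abs(a_major / n_exp - 0.5) < half_width + 1 / n_exp

    def test_perfect_vs_random_wins_everything(self):
        rng = np.random.default_rng(6)
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        perfect = y.astype(float)
        random_scores = rng.random(n)
        res = bootstrap_compare(perfect, random_scores, y, B=500, rng=3)
        assert res.a_wins == 500
        assert res.auc_a_p5 == 1.0


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curves, _, _ = km_estimate([5, 10, 15], [0, 0, 0], ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_hand_computed_product_limit(self):
        curves, _, _ = km_estimate([1, 2, 3], [1, 1, 1], ["g"] * 3)
        surv = curves["g"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_identical_groups_null_logrank(self):
        t = [3, 5, 8, 12, 20, 3, 5, 8, 12, 20]
        e = [1, 0, 1, 0, 1, 1, 0, 1, 0, 1]
        g = ["a"] * 5 + ["b"] * 5
        _, chi2, p = km_estimate(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 0], ["a", "a"])


class TestEnrichment:
    def test_two_by_two_exact_value(self):
        res = enrichment_test([[3, 1], [1, 3]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.4857, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            enrichment_test([[0, 0], [1, 2]])

    def test_monte_carlo_flagged_and_seeded(self):
        table = [[10, 5, 3], [4, 12, 6], [2, 3, 15]]
        r1 = enrichment_test(table, n_mc=2000, rng=7)
        r2 = enrichment_test(table, n_mc=2000, rng=7)
        assert r1.method == "monte_carlo"
        assert r1.p_value == r2.p_value
        assert r1.p_value < 0.05  # clearly associated table

    def test_null_calibration_validity(self):
        """Under independent margins, P(p <= a) <= a (+MC slack): exact-test validity."""
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(1000):
            a = rng.random(400) < 0.4
            b = rng.random(400) < 0.3
            tab = [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
            ps.append(enrichment_test(tab).p_value)
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.10, 0.25):
            se = math.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se
        assert stats.kstest(ps, "uniform").statistic < 0.15


class TestSubgroup:
    @staticmethod
    def _table(rng, n, effect_in_stratum1=2.5):
        stratum = rng.integers(0, 2, n)
        x = (rng.random(n) < 0.4).astype(int)
        logit = -1.5 + np.where(stratum == 1, effect_in_stratum1, 0.0) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return pd.DataFrame({"x": x, "noise": rng.random(n), "stratum": stratum, "relapse": y})

    def test_constant_stratifier_equals_global(self):
        rng = np.random.default_rng(9)
        df = self._table(rng, 300)
        df["stratum"] = "all"
        fit_a = fit_logistic(df, "relapse", ["x"])
        fit_b = fit_logistic(df, "relapse", ["noise"])
        res = subgroup_evaluate(df, fit_a, fit_b, "stratum")
        assert len(res) == 1
        global_auc, _ = roc_auc(fit_a.predict_proba(df), df["relapse"])
        assert res.iloc[0]["auc_a"] == pytest.approx(global_auc)

    def test_effect_confined_to_one_stratum_widens_its_gap(self):
        """Over 50 seeded replicates, the planted stratum shows the bigger AUC gap."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            df = self._table(rng, 400)
            fit_a = fit_logistic(df, "relapse", ["x"])
            fit_b = fit_logistic(df, "relapse", ["noise"])
            res = subgroup_evaluate(df, fit_a, fit_b, "stratum").set_index("stratum")
            gap = res["auc_a"] - res["auc_b"]
            if gap.loc[1] > gap.loc[0]:
                wins += 1
        assert stats.binomtest(wins, 50, 0.5, alternative="greater").pvalue < 0.01

    def test_one_class_stratum_skipped_with_flag(self):
        rng = np.random.default_rng(10)
        df = self._table(rng, 200)
        df.loc[df["stratum"] == 1, "relapse"] = 0
        fit_a = fit_logistic(df, "relapse", ["x"])
        fit_b = fit_logistic(df, "relapse", ["noise"])
        res = subgroup_evaluate(df, fit_a, fit_b, "stratum").set_index("stratum")
        assert res.loc[1, "flag"] == "skipped_one_class"
        assert np.isnan(res.loc[1, "auc_a"])
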