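"""Folds, threshold selection, joint screening, clinical models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from pcgscreen import metrics, screening


def threshold_oracle(scores, labels):
    """Exhaustive midpoint search under the sensitivity > 50% constraint."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    best_key, best_thr = None, None
    for thr in (uniq[:-1] + uniq[1:]) / 2:
        pred = scores >= thr
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        if sens <= 0.5:
            continue
        key = (sens + spec, spec, -thr)
        if best_key is None or key > best_key:
            best_key, best_thr = key, thr
    return float(uniq[0]) if best_thr is None else float(best_thr)


class TestMakeFolds:
    def test_holdout_size(self):
        pids = [f"p{i}" for i in range(2124)]
        labels = np.zeros(2124, bool)
        labels[:45] = True
        plan = screening.make_folds(pids, labels, holdout_frac=0.10, seed=0)
        assert len(plan.holdout) == 212

    def test_partition_property(self):
        pids = [f"p{i}" for i in range(200)]
        labels = np.random.default_rng(0).random(200) < 0.1
        plan = screening.make_folds(pids, labels, seed=3)
        folded = set(plan.fold_of)
        assert folded | set(plan.holdout) == set(pids)
        assert folded & set(plan.holdout) == set()

    def test_even_positive_stratification(self):
        pids = [f"p{i}" for i in range(400)]
        labels = np.zeros(400, bool)
        labels[:40] = True
        plan = screening.make_folds(pids, labels, holdout_frac=0.0, seed=1)
        counts = [sum(1 for p in plan.fold_ids(k) if int(p[1:]) < 40) for k in range(8)]
        assert counts == [5] * 8  # 40 positives over 8 folds -> exactly 5 each

    def test_deterministic(self):
        pids = [f"p{i}" for i in range(100)]
        labels = np.random.default_rng(1).random(100) < 0.2
        a = screening.make_folds(pids, labels, seed=9)
        b = screening.make_folds(pids, labels, seed=9)
        assert a.fold_of == b.fold_of and a.holdout == b.holdout

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            screening.make_folds(["a", "b"], [0, 1], n_folds=8)


class TestSelectThreshold:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1]
        thr = screening.select_threshold(scores, labels)
        sens, spec = metrics.sensitivity_specificity(scores, labels, thr)
        assert sens == 1.0 and spec == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=30), 1)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert screening.select_threshold(scores, labels) == pytest.approx(
            threshold_oracle(scores, labels))

    def test_sensitivity_constraint_binds(self):
        """Constructed so the unconstrained optimum has sensitivity 0.4:
        the returned threshold must differ and satisfy the constraint."""
        # 5 positives: 2 high, 3 low; many negatives in between
        scores = np.array([10, 9, 1.0, 1.1, 1.2] + [5.0, 5.1, 5.2, 5.3] * 5)
        labels = np.array([1, 1, 1, 1, 1] + [0] * 20, bool)
        # unconstrained: threshold above 5.3 gives sens 0.4, spec 1.0 (0.4+1.0=1.4)
        oracle_unconstrained = max(
            ((metrics.sensitivity_specificity(scores, labels, t)) for t in np.unique(scores)),
            key=lambda sp: sp[0] + sp[1])
        assert oracle_unconstrained[0] < 0.5
        thr = screening.select_threshold(scores, labels)
        sens, _ = metrics.sensitivity_specificity(scores, labels, thr)
        assert sens > 0.5

    def test_no_feasible_threshold_warns(self):
        # the only positive has the strictly lowest score: every midpoint
        # cut gives sensitivity 0, so the minimum score is returned
        scores = [0.5, 1.0, 2.0]
        labels = [1, 0, 0]
        with pytest.warns(UserWarning):
            thr = screening.select_threshold(scores, labels)
        sens, _ = metrics.sensitivity_specificity(scores, labels, thr)
        assert sens == 1.0


class TestJointScreen:
    def test_definitions_on_mr3_asymptomatic(self):
        assert screening.joint_positive(0, 0, 0, 3, False, 1)
        assert not screening.joint_positive(0, 0, 0, 3, False, 2)
        assert not screening.joint_positive(0, 0, 0, 3, False, 3)

    def test_all_grades_zero_negative(self):
        for d in (1, 2, 3):
            assert not screening.joint_positive(0, 0, 0, 0, True, d)

    def test_stenosis_clause_ignores_symptoms(self):
        for d in (1, 2, 3):
            assert screening.joint_positive(1, 0, 0, 0, False, d)

    def test_symptomatic_definition(self):
        assert screening.symptomatic_flag({"breathless_rest": 1, "breathless_level": 0, "mmrc": 0})
        assert screening.symptomatic_flag({"breathless_rest": 0, "breathless_level": 0, "mmrc": 2})
        assert not screening.symptomatic_flag({"breathless_rest": 0, "breathless_level": 0, "mmrc": 1})
        assert not screening.symptomatic_flag({"breathless_rest": np.nan, "breathless_level": np.nan,
                                               "mmrc": np.nan})

    def test_missing_echo_excluded(self):
        table = pd.DataFrame([
            {"participant_id": "a", "AS": 1, "MS": 0, "AR": 0, "MR": 0,
             "max_grade": 2.0, "breathless_rest": 0, "breathless_level": 0, "mmrc": 0},
            {"participant_id": "b", "AS": np.nan, "MS": 0, "AR": 0, "MR": 0,
             "max_grade": 2.0, "breathless_rest": 0, "breathless_level": 0, "mmrc": 0},
        ])
        with pytest.warns(UserWarning):
            out = screening.joint_screen(table, "max_grade", 1, 1.0)
        assert list(out["participant_id"]) == ["a"]
        assert bool(out["positive_class"][0]) and bool(out["screen_positive"][0])


class TestClinicalModels:
    def test_known_logistic_model_recovery(self):
        """Simulate from stated coefficients at n=2000; every recovered
        coefficient lies within 2 standard errors."""
        rng = np.random.default_rng(42)
        n = 2000
        murmur = np.abs(rng.normal(1.0, 1.0, n))
        age = rng.normal(65, 10, n)
        hr = rng.normal(65, 9, n)
        true_beta = {"const": -3.0, "murmur": 1.2, "age": 0.03, "heart_rate": -0.02}
        logit = (true_beta["const"] + true_beta["murmur"] * murmur
                 + true_beta["age"] * (age - 65) + true_beta["heart_rate"] * (hr - 65))
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        table = pd.DataFrame({"murmur": murmur, "age": age - 65, "heart_rate": hr - 65,
                              "MR>=3": y.astype(float)})
        spec = screening.fit_clinical_model("MR>=3", table)
        truth = [true_beta["const"], true_beta["murmur"], true_beta["age"],
                 true_beta["heart_rate"]]
        for est, se, tv in zip(spec.coefficients, spec.std_errors, truth):
            assert abs(est - tv) <= 2 * se

    def test_mode_imputation_keeps_n(self):
        rng = np.random.default_rng(1)
        n = 500
        df = pd.DataFrame({
            "murmur": np.abs(rng.normal(1, 1, n)),
            "age": rng.normal(0, 10, n),
            "gender_female": (rng.random(n) < 0.5).astype(float),
            "breathless_uphill": (rng.random(n) < 0.3).astype(float),
            "heart_rate": rng.normal(0, 9, n),
        })
        df.loc[rng.choice(n, 20, replace=False), "breathless_uphill"] = np.nan
        logit = -2.0 + 1.0 * df["murmur"]
        df["AR>=3"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        spec = screening.fit_clinical_model("AR>=3", df)
        probs = screening.predict_clinical(spec, df)
        assert len(probs) == n and np.isfinite(probs).all()

    def test_formula_covariates(self):
        assert screening.CLINICAL_FORMULAS["MR>=3"] == ["murmur", "age", "heart_rate"]
        assert "murmur:gender_female" in screening.CLINICAL_FORMULAS["AS>=1"]
        assert screening.CLINICAL_FORMULAS["AR>=3"] == [
            "murmur", "age", "gender_female", "breathless_uphill", "heart_rate"]


class TestSymptomSubgroupTest:
    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p for [[10, 5], [2, 30]] via exhaustive tail
        enumeration of the hypergeometric distribution."""
        tp = [True] * 10 + [False] * 5
        fn = [True] * 2 + [False] * 30
        prev_tp, prev_fn, p = screening.symptom_subgroup_test(tp, fn)
        assert prev_tp == pytest.approx(10 / 15)
        assert prev_fn == pytest.approx(2 / 32)
        # enumeration: sum P(X=k) over all tables as or less probable
        m, n_draw, k_tot = 15 + 32, 15, 12
        rv = hypergeom(m, k_tot, n_draw)
        p_obs = rv.pmf(10)
        p_oracle = sum(rv.pmf(k) for k in range(0, min(n_draw, k_tot) + 1)
                       if rv.pmf(k) <= p_obs * (1 + 1e-12))
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_proportions_p_one(self):
        tp = [True] * 5 + [False] * 5
        fn = [True] * 5 + [False] * 5
        _, _, p = screening.symptom_subgroup_test(tp, fn)
        assert p == pytest.approx(1.0)

    def test_p_in_unit_interval(self, rng):
        for _ in range(5):
            tp = rng.random(rng.integers(2, 20)) < 0.5
            fn = rng.random(rng.integers(2, 20)) < 0.5
            _, _, p = screening.symptom_subgroup_test(tp, fn)
            assert 0.0 <= p <= 1.0

    def test_empty_subset_flagged(self):
        prev_tp, prev_fn, p = screening.symptom_subgroup_test([], [True, False])
        assert np.isnan(p) and np.isnan(prev_tp) and prev_fn == 0.5
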