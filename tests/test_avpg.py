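"""Multiposition gradient model: evaluation, OLS, stepwise BIC, sweep."""

import numpy as np
import pytest

from pcgscreen import avpg


def simulate_grades(rng, n):
    mg = np.abs(rng.normal(0.8, 1.0, (n, 4)))
    noise = (rng.random((n, 4)) < 0.05).astype(int)
    return mg, noise


class TestEvaluate:
    def test_printed_model_zero_input(self):
        assert avpg.evaluate(avpg.PRINTED_MODEL, [0, 0, 0, 0], [0, 0, 0, 0]) == pytest.approx(3.5)

    def test_printed_model_clean_grades(self):
        # 3.5 + 0.6*4 + 1.1*1 + 0.5*1
        val = avpg.evaluate(avpg.PRINTED_MODEL, [2, 1, 1, 0], [0, 0, 0, 0])
        assert val == pytest.approx(7.5)

    def test_noisy_positions_forced_to_zero(self):
        # only the triple-noise mitral term survives: 3.5 + 8.9*1.5
        val = avpg.evaluate(avpg.PRINTED_MODEL, [2, 0, 0, 1.5], [1, 1, 1, 0])
        assert val == pytest.approx(16.85)

    def test_all_noisy_rejected(self):
        with pytest.raises(ValueError):
            avpg.evaluate(avpg.PRINTED_MODEL, [1, 1, 1, 1], [1, 1, 1, 1])

    def test_linear_in_coefficients(self, rng):
        mg, noise = simulate_grades(rng, 1)
        terms = [("MG_A",), ("MG_P", "MG_P")]
        s1 = avpg.LinearModelSpec(terms, [1.0, 2.0], 0.5)
        s2 = avpg.LinearModelSpec(terms, [3.0, -1.0], 1.5)
        s_sum = avpg.LinearModelSpec(terms, [4.0, 1.0], 2.0)
        v = (avpg.evaluate(s1, mg[0], noise[0]) + avpg.evaluate(s2, mg[0], noise[0]))
        assert avpg.evaluate(s_sum, mg[0], noise[0]) == pytest.approx(v)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            avpg.LinearModelSpec([("MG_A",), ("MG_A",)], [1, 1], 0.0)

    def test_cubic_grade_terms_rejected(self):
        with pytest.raises(ValueError):
            avpg.LinearModelSpec([("MG_A", "MG_A", "MG_A")], [1], 0.0)


class TestFitOls:
    def test_exact_linear_recovery(self, rng):
        mg, noise = simulate_grades(rng, 50)
        noise[:] = 0
        y = 4.0 + 2.5 * mg[:, 0]
        fit = avpg.fit_ols([("MG_A",)], mg, noise, y)
        assert fit.spec.coefficients[0] == pytest.approx(2.5, abs=1e-9)
        assert fit.spec.intercept == pytest.approx(4.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_recovery_within_2se(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mg, noise = simulate_grades(rng, 1000)
            noise[:] = 0
            y = 2.0 + 1.0 * mg[:, 0] ** 2 + rng.normal(0, 1.0, 1000)
            fit = avpg.fit_ols([("MG_A", "MG_A")], mg, noise, y)
            ok = (abs(fit.spec.intercept - 2.0) <= 2 * fit.std_errors[0]
                  and abs(fit.spec.coefficients[0] - 1.0) <= 2 * fit.std_errors[1])
            hits += ok
        assert hits >= 19

    def test_bic_closed_form(self, rng):
        mg, noise = simulate_grades(rng, 200)
        y = rng.normal(5, 2, 200)
        terms = [("MG_A",), ("MG_T",)]
        fit = avpg.fit_ols(terms, mg, noise, y)
        design = avpg.design_matrix(terms, mg, noise)
        beta = np.linalg.lstsq(np.column_stack([np.ones(200), design]), y, rcond=None)[0]
        rss = np.sum((y - beta[0] - design @ beta[1:]) ** 2)
        k = len(terms) + 2  # terms + intercept + variance
        assert fit.bic == pytest.approx(200 * np.log(rss / 200) + k * np.log(200), rel=1e-9)

    def test_residual_orthogonality(self, rng):
        mg, noise = simulate_grades(rng, 300)
        y = rng.normal(0, 1, 300) + mg[:, 1]
        terms = [("MG_P",), ("MG_M", "MG_M")]
        fit = avpg.fit_ols(terms, mg, noise, y)
        design = avpg.design_matrix(terms, mg, noise)
        pred = fit.spec.intercept + design @ np.asarray(fit.spec.coefficients)
        resid = y - pred
        assert np.max(np.abs(design.T @ resid)) < 1e-8

    def test_rank_deficiency_reported(self, rng):
        mg = np.zeros((50, 4))
        mg[:, 0] = rng.normal(size=50)
        mg[:, 1] = mg[:, 0]  # collinear
        noise = np.zeros((50, 4), dtype=int)
        with pytest.raises(np.linalg.LinAlgError):
            avpg.fit_ols([("MG_A",), ("MG_P",)], mg, noise, rng.normal(size=50))


class TestStepwise:
    def test_recovers_generating_terms(self):
        """y = 2 + 1*MG_A^2 + 0.5*MG_T + noise: both true terms selected in
        >= 80% of 20 replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            mg, noise = simulate_grades(rng, 1000)
            y = 2.0 + 1.0 * np.where(noise[:, 0], 0, mg[:, 0]) ** 2 \
                + 0.5 * np.where(noise[:, 2], 0, mg[:, 2]) + rng.normal(0, 1.0, 1000)
            fit = avpg.stepwise_select(mg, noise, y)
            terms = set(fit.spec.terms)
            hits += ("MG_A", "MG_A") in terms and ("MG_T",) in terms
        assert hits >= 16

    def test_null_response_stays_sparse(self):
        """Pure-noise response keeps the model intercept-dominant."""
        sparse = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            mg, noise = simulate_grades(rng, 500)
            y = rng.normal(0, 1, 500)
            fit = avpg.stepwise_select(mg, noise, y)
            sparse += len(fit.spec.terms) <= 1
        assert sparse >= 16

    def test_local_optimality(self, rng):
        mg, noise = simulate_grades(rng, 600)
        y = 1.0 + 0.8 * mg[:, 1] ** 2 + rng.normal(0, 1, 600)
        fit = avpg.stepwise_select(mg, noise, y)
        # no single-term removal lowers BIC
        for term in fit.spec.terms:
            reduced = [t for t in fit.spec.terms if t != term]
            assert avpg.fit_ols(reduced, mg, noise, y).bic >= fit.bic - 1e-9

    def test_deterministic(self, rng):
        mg, noise = simulate_grades(rng, 400)
        y = 2.0 + mg[:, 0] + rng.normal(0, 1, 400)
        a = avpg.stepwise_select(mg, noise, y)
        b = avpg.stepwise_select(mg, noise, y)
        assert a.spec.terms == b.spec.terms

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            avpg.stepwise_select(np.zeros((0, 4)), np.zeros((0, 4)), np.zeros(0))


class TestThresholdSweep:
    def test_perfect_predictions(self, rng):
        avpg_vals = rng.uniform(3, 50, 200)
        res = avpg.threshold_sweep_auc(avpg_vals, avpg_vals, range(7, 31), n_boot=50)
        assert all(v["auc"] == 1.0 for v in res.values())

    def test_permuted_predictions_near_half(self):
        rng = np.random.default_rng(6)
        avpg_vals = rng.uniform(3, 40, 500)
        pred = rng.permutation(avpg_vals)
        res = avpg.threshold_sweep_auc(pred, avpg_vals, [10], n_boot=50, seed=1)
        assert 0.4 <= res[10]["auc"] <= 0.6

    def test_ci_contains_point(self):
        rng = np.random.default_rng(7)
        avpg_vals = rng.uniform(3, 40, 300)
        pred = avpg_vals + rng.normal(0, 5, 300)
        res = avpg.threshold_sweep_auc(pred, avpg_vals, range(8, 20), n_boot=200, seed=2)
        for v in res.values():
            assert v["ci_low"] <= v["auc"] <= v["ci_high"]
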