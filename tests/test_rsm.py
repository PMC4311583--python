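"""Quadratic response-surface fit, ANOVA decomposition and diagnostics."""

import numpy as np
import pytest

from mediaopt import (
    CCDSpec,
    Factor,
    ResponseVector,
    TruthSpec,
    anova,
    build_ccd,
    fit_quadratic,
    fit_stats,
    simulate_ccd,
)
from mediaopt.rsm import expand_quadratic, quadratic_terms, replicate_groups

# coded-space coefficients the cellulase CCD study reports (2-dp display
# rounding; the exact fit is cross-checked against a normal-equations
# oracle in TestFit below)
STUDY_TRUTH = {
    "Intercept": 27.32,
    "CMC": 1.28,
    "MgSO4": 0.86,
    "pH": -2.27,
    "CMC:MgSO4": -0.85,
    "CMC:pH": 0.98,
    "MgSO4:pH": -0.006,
    "CMC^2": -0.41,
    "MgSO4^2": -1.94,
    "pH^2": -1.33,
}


def _abstract_ccd(k=3, n_center=6):
    factors = [Factor(name=f"X{i + 1}", center=0.0, step=1.0) for i in range(k)]
    return build_ccd(CCDSpec(factors=factors, n_center=n_center))


class TestFit:
    def test_study_coefficients_to_reported_rounding(self, ccd_fit):
        model, _ = ccd_fit
        for term, expected in STUDY_TRUTH.items():
            assert model.coefficients[term] == pytest.approx(expected, abs=0.01), term

    def test_study_predictions_at_center_and_axial(self, ccd_fit, ccd_study):
        model, _ = ccd_fit
        assert model.predict([0.0, 0.0, 0.0])[0] == pytest.approx(27.31957, abs=5e-5)
        assert model.predict([1.681793, 0.0, 0.0])[0] == pytest.approx(28.31881, abs=5e-5)

    def test_matches_normal_equations_oracle(self, ccd_study, ccd_fit):
        """OLS coefficients agree with a brute-force normal-equations
        solve on the expanded model matrix."""
        design, response = ccd_study
        model, _ = ccd_fit
        X = expand_quadratic(design.coded.to_numpy(), model.factor_names).to_numpy()
        y = response.aligned_to(design)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(model.coefficients.to_numpy(), beta, atol=1e-10)

    def test_fitted_plus_residual_is_observed(self, ccd_fit, ccd_study):
        model, _ = ccd_fit
        _, response = ccd_study
        assert np.allclose(model.fitted + model.residuals, response.values, atol=1e-10)
        assert model.p == 10 and model.residual_df == 10

    def test_noiseless_synthetic_recovery(self):
        design = _abstract_ccd()
        names = design.process_columns
        coefs = {"Intercept": 25.0}
        rng = np.random.default_rng(11)
        for t in quadratic_terms(names):
            coefs[t] = float(rng.normal(0, 2))
        resp = simulate_ccd(design, TruthSpec(ccd_coefficients=coefs))
        model = fit_quadratic(design, resp)
        for t, v in coefs.items():
            assert model.coefficients[t] == pytest.approx(v, abs=1e-8), t

    def test_insufficient_runs_rejected(self):
        # 9 runs cannot support the 10-parameter quadratic in 3 factors
        sub = _abstract_ccd(k=3, n_center=6).coded.iloc[:9]
        from mediaopt.designs import DesignMatrix

        tiny = DesignMatrix(
            coded=sub, roles={c: "process" for c in sub.columns},
            design_kind="central-composite",
        )
        resp = ResponseVector(values=np.ones(9), run_ids=tiny.run_ids)
        with pytest.raises(ValueError, match="insufficient"):
            fit_quadratic(tiny, resp)

    def test_singular_design_names_collinear_columns(self):
        import pandas as pd

        from mediaopt.designs import DesignMatrix

        # two-level-only design: X^2 columns collinear with the intercept
        coded = pd.DataFrame(
            {"A": [-1, 1, -1, 1] * 3, "B": [-1, -1, 1, 1] * 3},
            index=pd.RangeIndex(1, 13, name="run"),
        )
        d = DesignMatrix(
            coded=coded, roles={"A": "process", "B": "process"},
            design_kind="central-composite",
        )
        resp = ResponseVector(values=np.arange(12.0), run_ids=d.run_ids)
        with pytest.raises(ValueError, match="collinear"):
            fit_quadratic(d, resp)


class TestAnova:
    def test_study_f_statistics(self, ccd_fit):
        _, aov = ccd_fit
        assert aov.model_f == pytest.approx(3.79, abs=0.005)
        assert aov.lack_of_fit_f == pytest.approx(1.08, abs=0.005)
        assert aov.row("pH")["F"] == pytest.approx(12.68749, abs=1e-4)
        assert aov.row("model")["p"] == pytest.approx(0.0247, abs=1e-4)
        assert aov.row("lack of fit")["p"] == pytest.approx(0.4672, abs=1e-4)

    def test_study_df_bookkeeping(self, ccd_fit):
        _, aov = ccd_fit
        assert int(aov.row("model")["df"]) == 9
        assert int(aov.row("residual")["df"]) == 10
        assert int(aov.row("corrected total")["df"]) == 19
        assert int(aov.row("lack of fit")["df"]) == 5
        assert int(aov.row("pure error")["df"]) == 5

    def test_sum_of_squares_conservation(self, ccd_fit):
        _, aov = ccd_fit
        assert aov.ss_model + aov.ss_residual == pytest.approx(aov.ss_total, abs=1e-8)
        assert aov.row("lack of fit")["ss"] + aov.row("pure error")["ss"] == pytest.approx(
            aov.ss_residual, abs=1e-8
        )

    def test_term_ss_equals_beta_squared_times_column_ss(self, ccd_fit, ccd_study):
        """On the orthogonal CCD, deletion SS for linear and interaction
        terms equals beta^2 * sum(x^2)."""
        design, _ = ccd_study
        model, aov = ccd_fit
        X = expand_quadratic(design.coded.to_numpy(), model.factor_names)
        for term in model.factor_names + ["CMC:MgSO4", "CMC:pH", "MgSO4:pH"]:
            beta = model.coefficients[term]
            ss_direct = beta**2 * (X[term] ** 2).sum()
            assert aov.row(term)["ss"] == pytest.approx(ss_direct, abs=1e-8), term

    def test_noiseless_fit_has_zero_residual_and_pure_error(self):
        design = _abstract_ccd()
        coefs = {t: 1.0 for t in ["Intercept"] + quadratic_terms(design.process_columns)}
        resp = simulate_ccd(design, TruthSpec(ccd_coefficients=coefs))
        model = fit_quadratic(design, resp)
        aov = anova(model, design, resp)
        assert aov.ss_residual == pytest.approx(0.0, abs=1e-16)
        assert aov.row("pure error")["ss"] == pytest.approx(0.0, abs=1e-16)

    def test_no_replicates_omits_lack_of_fit(self):
        design = _abstract_ccd(n_center=1)
        rng = np.random.default_rng(5)
        resp = ResponseVector(
            values=rng.normal(10, 1, design.n_runs), run_ids=design.run_ids
        )
        model = fit_quadratic(design, resp)
        aov = anova(model, design, resp)
        assert not aov.has_lack_of_fit
        assert "lack of fit" not in set(aov.table["source"])

    def test_replicate_group_detection_finds_centers(self, ccd_study):
        design, _ = ccd_study
        groups = replicate_groups(design)
        assert len(groups) == 1
        assert len(groups[0]) == 6


class TestFitStats:
    def test_study_diagnostics(self, ccd_fit, ccd_study):
        model, aov = ccd_fit
        _, response = ccd_study
        st = fit_stats(model, aov, response)
        assert st.cv_pct == pytest.approx(9.51, abs=0.005)
        assert st.adequate_precision == pytest.approx(6.553, abs=0.005)
        assert 0 < st.r_squared < 1
        assert st.r_squared == pytest.approx(aov.ss_model / aov.ss_total, abs=1e-12)

    def test_noiseless_r_squared_is_one(self):
        design = _abstract_ccd()
        coefs = {t: 0.5 for t in ["Intercept"] + quadratic_terms(design.process_columns)}
        resp = simulate_ccd(design, TruthSpec(ccd_coefficients=coefs))
        model = fit_quadratic(design, resp)
        aov = anova(model, design, resp)
        st = fit_stats(model, aov, resp)
        assert st.r_squared == pytest.approx(1.0, abs=1e-12)


class TestParameterRecovery:
    def test_linear_coefficient_rmse_scales_with_theory(self):
        """Over repeated simulations, the RMSE of each linear coefficient
        approaches sigma / sqrt(sum(x^2)) — the exact OLS standard error
        on this orthogonal design."""
        design = _abstract_ccd()
        names = design.process_columns
        sigma = 2.0
        coefs = {t: 0.0 for t in ["Intercept"] + quadratic_terms(names)}
        coefs.update({"Intercept": 25.0, "X1": 1.5, "X2": -1.0})
        truth = TruthSpec(ccd_coefficients=coefs, noise_sd=sigma, seed=314)
        rng = np.random.default_rng(truth.seed)
        errs = {n: [] for n in names}
        for _ in range(500):
            resp = simulate_ccd(design, truth, rng=rng)
            model = fit_quadratic(design, resp)
            for n in names:
                errs[n].append(model.linear[n] - coefs[n])
        col_ss = (design.coded.to_numpy() ** 2).sum(axis=0)[0]
        theory = sigma / np.sqrt(col_ss)
        for n in names:
            rmse = float(np.sqrt(np.mean(np.square(errs[n]))))
            assert abs(rmse - theory) / theory < 0.15, n

    def test_mean_model_f_matches_noncentral_f_expectation(self):
        """The Monte-Carlo mean of the overall model F statistic matches
        E[F] = df2*(df1 + lambda) / (df1*(df2 - 2)) for the noncentral F
        implied by the simulation truth."""
        design = _abstract_ccd()
        names = design.process_columns
        sigma = 2.36
        coefs = {t: 0.0 for t in ["Intercept"] + quadratic_terms(names)}
        coefs.update({"Intercept": 27.3, "X1": 1.3, "X3": -2.3, "X2^2": -1.9})
        X = expand_quadratic(design.coded.to_numpy(), names)
        beta = np.array([coefs[t] for t in X.columns])
        mu = X.to_numpy() @ beta
        lam = float(((mu - mu.mean()) ** 2).sum()) / sigma**2
        df1, df2 = 9, 10
        expected = df2 * (df1 + lam) / (df1 * (df2 - 2))
        truth = TruthSpec(ccd_coefficients=coefs, noise_sd=sigma, seed=2718)
        rng = np.random.default_rng(truth.seed)
        fs = []
        for _ in range(400):
            resp = simulate_ccd(design, truth, rng=rng)
            model = fit_quadratic(design, resp)
            fs.append(anova(model, design, resp).model_f)
        fs = np.asarray(fs)
        se = fs.std(ddof=1) / np.sqrt(len(fs))
        assert abs(fs.mean() - expected) < 4 * se + 0.02 * expected
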