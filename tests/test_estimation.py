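"""Tests of the leverage estimators and dispersion/CVR diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from plever import (
    Model2Params,
    ProteinLeverageRegressor,
    cvr,
    dispersion_summary,
    fit_leverage,
    fit_power_law,
    idr_from_model,
    simulate_pl_generative,
    spearman_diagnostic,
)


def strict_defence_table(protein: float = 1305.0, n: int = 60) -> pd.DataFrame:
    """Constant protein intake over a grid of non-protein intakes: L = -1 exactly."""
    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "protein_kj": protein,
            "nonprotein_kj": np.linspace(2000.0, 10000.0, n),
        }
    )


class TestFitLeverage:
    def test_strict_defence_is_complete_leverage(self):
        est = fit_leverage(strict_defence_table())
        assert est.L_hat == pytest.approx(-1.0, abs=1e-10)
        assert est.P_hat == pytest.approx(1305.0, abs=1e-6)

    def test_no_leverage_slope_within_two_se(self):
        params = Model2Params.from_share_moments(0.2, 0.05, 0.0)
        est = fit_leverage(simulate_pl_generative(params, 50_000, seed=21))
        assert abs(est.L_hat) < 2 * est.se_L

    def test_generative_recovery(self):
        params = Model2Params.from_share_moments(0.2, 0.05, -0.5)
        est = fit_leverage(simulate_pl_generative(params, 100_000, seed=22))
        assert est.L_hat == pytest.approx(-0.5, abs=2 * est.se_L)
        assert est.n_used == 100_000

    def test_rejects_nonpositive_intakes_listing_rows(self):
        df = strict_defence_table()
        df.loc[3, "protein_kj"] = -5.0
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_leverage(df)

    def test_rejects_rank_deficient_design(self):
        df = strict_defence_table()
        df["age"] = 40.0  # constant column collides with the intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_leverage(df, covariates=["age"])

    def test_rejects_unknown_covariate(self):
        with pytest.raises(ValueError, match="not in table"):
            fit_leverage(strict_defence_table(), covariates=["bmi"])

    def test_needs_three_records(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_leverage(strict_defence_table(n=2))

    def test_covariate_adjustment_removes_confounding(self):
        """A confounder shifting both share and energy biases the crude slope;
        adjusting restores the generating leverage."""
        rng = np.random.default_rng(23)
        n = 50_000
        L_true = -0.4
        age = rng.normal(0.0, 1.0, n)
        x = np.log(0.18) + 0.15 * age + rng.normal(0.0, 0.2, n)  # log share
        y = math.log(9000.0) + L_true * x + 0.3 * age + rng.normal(0.0, 0.3, n)
        share = np.exp(x)
        energy = np.exp(y)
        df = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "protein_kj": energy * share,
                "nonprotein_kj": energy * (1.0 - share),
                "age": age,
            }
        )
        crude = fit_leverage(df)
        adjusted = fit_leverage(df, covariates=["age"])
        assert abs(crude.L_hat - L_true) > 10 * crude.se_L  # confounded
        assert adjusted.L_hat == pytest.approx(L_true, abs=2 * adjusted.se_L)
        assert adjusted.covariates_adjusted == ("age",)

    @pytest.mark.parametrize("L_true", [0.0, -0.25, -0.5, -1.0])
    def test_estimator_consistency_and_coverage(self, L_true):
        """Across 200 generative replicates the mean estimate is unbiased and
        the +/- 2 SE interval covers the truth at a nominal-like rate."""
        params = Model2Params.from_share_moments(0.2, 0.05, L_true)
        seeds = np.random.SeedSequence(24).spawn(200)
        estimates, covered = [], 0
        for s in seeds:
            table = simulate_pl_generative(params, 5_000, int(s.generate_state(1)[0] % 2**31))
            est = fit_leverage(table)
            estimates.append(est.L_hat)
            covered += abs(est.L_hat - L_true) < 2 * est.se_L
        assert np.mean(estimates) == pytest.approx(L_true, abs=0.01)
        assert 0.90 <= covered / 200 <= 0.99


class TestFitPowerLaw:
    def test_strict_defence_exact(self):
        est = fit_power_law(strict_defence_table())
        assert est.L_hat == pytest.approx(-1.0, abs=1e-8)
        assert est.P_hat == pytest.approx(1305.0, rel=1e-8)

    def test_noiseless_power_law_recovery(self):
        p = np.linspace(0.08, 0.35, 80)
        energy = 9000.0 * p**-0.3
        df = pd.DataFrame(
            {
                "subject_id": np.arange(80),
                "protein_kj": energy * p,
                "nonprotein_kj": energy * (1.0 - p),
            }
        )
        est = fit_power_law(df)
        assert est.L_hat == pytest.approx(-0.3, abs=1e-6)
        assert est.P_hat == pytest.approx(9000.0, rel=1e-6)

    def test_agrees_with_log_scale_fit_under_lognormal_noise(self):
        params = Model2Params.from_share_moments(0.2, 0.05, -0.5)
        table = simulate_pl_generative(params, 50_000, seed=25)
        loglog = fit_leverage(table)
        power = fit_power_law(table)
        assert power.L_hat == pytest.approx(loglog.L_hat, abs=2 * (loglog.se_L + power.se_L))


class TestDiagnostics:
    def test_constant_protein_gives_zero_dispersion(self):
        summary = dispersion_summary(strict_defence_table())
        assert summary.id_U == 0.0
        assert summary.idr == 0.0

    def test_complete_leverage_idr_near_zero(self):
        params = Model2Params.from_share_moments(0.2, 0.05, -1.0, sigma_eps2=1e-8)
        table = simulate_pl_generative(params, 20_000, seed=26)
        assert dispersion_summary(table).idr < 1e-3

    def test_sample_idr_matches_forward_model(self):
        params = Model2Params.from_share_moments(0.2, 0.05, -0.5)
        table = simulate_pl_generative(params, 100_000, seed=27)
        assert dispersion_summary(table).idr == pytest.approx(
            idr_from_model(params).idr, rel=0.10
        )

    def test_spearman_detects_leverage_sign(self):
        params = Model2Params.from_share_moments(0.2, 0.05, -0.5)
        rho, pval = spearman_diagnostic(simulate_pl_generative(params, 5_000, seed=28))
        assert rho < 0
        assert pval < 1e-6

    @pytest.mark.parametrize(
        "biomarker,dat,expected", [(0.2, 0.2, 1.0), (0.24, 0.25, 0.96), (0.3, 0.15, 2.0)]
    )
    def test_cvr_arithmetic(self, biomarker, dat, expected):
        assert cvr(biomarker, dat).cvr == pytest.approx(expected, rel=1e-12)

    @given(cv_b=st.floats(0.01, 5.0), cv_d=st.floats(0.01, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cvr_positive_and_reciprocal(self, cv_b, cv_d):
        assert cvr(cv_b, cv_d).cvr * cvr(cv_d, cv_b).cvr == pytest.approx(1.0, rel=1e-9)

    def test_cvr_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cvr(0.0, 0.2)


class TestSklearnRegressor:
    def test_matches_module_function_and_predicts(self):
        df = strict_defence_table()
        X = df[["protein_kj", "nonprotein_kj"]].to_numpy()
        reg = ProteinLeverageRegressor().fit(X)
        assert reg.leverage_ == pytest.approx(-1.0, abs=1e-10)
        assert reg.protein_target_ == pytest.approx(1305.0, abs=1e-6)
        # under complete leverage E(p) = P / p
        np.testing.assert_allclose(reg.predict([0.15, 0.3]), [1305.0 / 0.15, 1305.0 / 0.3])

    def test_powerlaw_method(self):
        X = strict_defence_table()[["protein_kj", "nonprotein_kj"]].to_numpy()
        reg = ProteinLeverageRegressor(method="powerlaw").fit(X)
        assert reg.leverage_ == pytest.approx(-1.0, abs=1e-8)

    def test_clonable_and_validates(self):
        reg = ProteinLeverageRegressor(method="powerlaw")
        assert clone(reg).get_params() == {"method": "powerlaw"}
        with pytest.raises(ValueError, match="shape"):
            reg.fit(np.ones((4, 3)))
        with pytest.raises(AttributeError):
            ProteinLeverageRegressor().predict([0.2])
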