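"""Mixed-model ladder: centering, likelihood oracles, fitting, ladder logic."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM

import stepnof1 as s
from stepnof1.cohort import simulate_ar1
from stepnof1.mlm import (
    MlmFit,
    MlmSpec,
    fit_mlm,
    mlm_loglik,
    prepare_frame,
    run_ladder,
)
from stepnof1.nof1 import fit_ols


class TestCentering:
    def test_two_value_participant(self):
        df = pd.DataFrame({"participant_id": ["A", "A"], "x": [2.0, 4.0]})
        out = s.center_covariates(df, ["x"])
        assert out["x_pmean"].tolist() == [3.0, 3.0]
        assert out["x_within"].tolist() == [-1.0, 1.0]

    def test_within_deviations_sum_to_zero(self, small_study):
        out = s.center_covariates(small_study.data, ["barriers"])
        sums = out.groupby("participant_id")["barriers_within"].sum()
        assert np.allclose(sums.fillna(0.0), 0.0, atol=1e-9)

    def test_between_values_match_hand_computation(self):
        df = pd.DataFrame({
            "participant_id": ["A"] * 2 + ["B"] * 3,
            "x": [1.0, 3.0, 4.0, 6.0, 8.0],
        })
        out = s.center_covariates(df, ["x"])
        grand = (2.0 + 6.0) / 2
        assert out.loc[out.participant_id == "A", "x_between"].iloc[0] == 2.0 - grand
        assert out.loc[out.participant_id == "B", "x_between"].iloc[0] == 6.0 - grand

    def test_missing_propagates_and_all_missing_rejected(self):
        df = pd.DataFrame({
            "participant_id": ["A", "A", "B"],
            "x": [1.0, np.nan, np.nan],
        })
        with pytest.raises(ValueError, match="entirely missing"):
            s.center_covariates(df, ["x"])
        df.loc[2, "x"] = 5.0
        out = s.center_covariates(df, ["x"])
        assert np.isnan(out["x_within"].iloc[1])


def _toy_data(rng, m=3, irregular=True):
    rows = []
    day_sets = [[1, 2, 3, 5], [1, 4, 6], [2, 3, 7, 9, 10]] if irregular else None
    for i in range(m):
        days = day_sets[i % 3] if irregular else list(range(1, 7))
        for d in days:
            rows.append({"participant_id": f"P{i}", "day_index": d,
                         "time": float(d), "x": rng.normal(),
                         "steps": 10 + rng.normal() * 3})
    return pd.DataFrame(rows)


class TestLoglik:
    SPEC = MlmSpec(fixed_terms=("intercept", "time", "x"),
                   random_slope=True, ar1=True)
    PARAMS = {"beta": np.array([10.0, 0.5, -1.0]), "tau00": 4.0,
              "tau11": 0.2, "tau01": 0.3, "sigma2": 2.5, "rho": 0.35}

    def dense_oracle(self, df, params):
        total = 0.0
        G = np.array([[params["tau00"], params["tau01"]],
                      [params["tau01"], params["tau11"]]])
        for _, g in df.groupby("participant_id"):
            X = np.column_stack([np.ones(len(g)), g.time, g.x])
            Z = np.column_stack([np.ones(len(g)), g.time])
            t = g.day_index.to_numpy()
            R = params["rho"] ** np.abs(t[:, None] - t[None, :])
            V = Z @ G @ Z.T + params["sigma2"] * R
            total += stats.multivariate_normal.logpdf(
                g.steps, X @ params["beta"], V)
        return total

    def test_matches_dense_mvn_oracle(self, rng):
        df = _toy_data(rng)
        ll = mlm_loglik(self.PARAMS, df, self.SPEC)
        assert ll == pytest.approx(self.dense_oracle(df, self.PARAMS), abs=1e-8)

    def test_independent_case_closed_form(self, rng):
        df = _toy_data(rng)
        params = {"beta": np.array([10.0, 0.5, -1.0]), "tau00": 0.0,
                  "tau11": 0.0, "tau01": 0.0, "sigma2": 2.5, "rho": 0.0}
        spec = MlmSpec(fixed_terms=("intercept", "time", "x"))
        mu = params["beta"][0] + params["beta"][1] * df.time + params["beta"][2] * df.x
        closed = stats.norm.logpdf(df.steps, mu, np.sqrt(2.5)).sum()
        assert mlm_loglik(params, df, spec) == pytest.approx(closed, abs=1e-10)

    def test_participant_order_invariance(self, rng):
        df = _toy_data(rng)
        shuffled = pd.concat([g for _, g in df.groupby("participant_id")][::-1])
        a = mlm_loglik(self.PARAMS, df, self.SPEC)
        b = mlm_loglik(self.PARAMS, shuffled, self.SPEC)
        assert a == pytest.approx(b, abs=1e-10)

    def test_invalid_parameters(self, rng):
        df = _toy_data(rng)
        bad = dict(self.PARAMS, sigma2=-1.0)
        with pytest.raises(ValueError):
            mlm_loglik(bad, df, self.SPEC)
        with pytest.raises(ValueError):
            mlm_loglik(dict(self.PARAMS, rho=1.0), df, self.SPEC)


def _random_intercept_data(rng, m=12, n=30, tau=2.0, sigma=1.5, rho=0.0):
    rows = []
    for i in range(m):
        u = rng.normal(0, tau)
        e = simulate_ar1(n, rho, sigma**2, rng) if rho else rng.normal(0, sigma, n)
        x = rng.normal(size=n)
        for d in range(1, n + 1):
            rows.append({"participant_id": f"P{i}", "day_index": d,
                         "time": float(d), "x": x[d - 1],
                         "steps": 5 + 0.1 * d + 1.5 * x[d - 1] + u + e[d - 1]})
    return pd.DataFrame(rows)


class TestFitMlm:
    def test_degenerate_matches_ols(self):
        # seed chosen so the tau00 ML estimate lands on the zero boundary,
        # where the mixed model must collapse to pooled OLS
        df = _random_intercept_data(np.random.default_rng(1), m=10, n=20, tau=0.0)
        spec = MlmSpec(fixed_terms=("intercept", "time", "x"))
        fit = fit_mlm(df, spec)
        ols = fit_ols(df["steps"], df[["time", "x"]])
        for term in ("intercept", "time", "x"):
            assert fit.fixed[term].B == pytest.approx(ols.terms[term].B, rel=1e-4)
        assert fit.tau00 < 1e-6 * fit.sigma2
        assert fit.boundary

    def test_matches_statsmodels_mixedlm(self, rng):
        df = _random_intercept_data(rng)
        spec = MlmSpec(fixed_terms=("intercept", "time", "x"))
        fit = fit_mlm(df, spec)
        X = sm.add_constant(df[["time", "x"]])
        ml = MixedLM(df["steps"], X, groups=df["participant_id"]).fit(reml=False)
        assert fit.minus2ll == pytest.approx(-2 * ml.llf, abs=1e-4)
        for term, smname in (("intercept", "const"), ("time", "time"), ("x", "x")):
            assert fit.fixed[term].B == pytest.approx(ml.fe_params[smname], rel=1e-5)
        assert fit.ml_variance["tau00"] == pytest.approx(
            float(ml.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.ml_variance["sigma2"] == pytest.approx(ml.scale, rel=1e-3)
        # inference quantities come from the REML refit
        reml = MixedLM(df["steps"], X, groups=df["participant_id"]).fit(reml=True)
        for term, smname in (("intercept", "const"), ("time", "time"), ("x", "x")):
            assert fit.fixed[term].SE == pytest.approx(reml.bse_fe[smname], rel=1e-3)
        assert fit.tau00 == pytest.approx(float(reml.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2 == pytest.approx(reml.scale, rel=1e-3)

    def test_matches_direct_dense_optimization(self, rng):
        """Independent oracle: optimize the dense MVN likelihood directly."""
        df = _random_intercept_data(rng, m=6, n=10)
        spec = MlmSpec(fixed_terms=("intercept", "x"))
        fit = fit_mlm(df, spec)

        groups = [g for _, g in df.groupby("participant_id")]

        def neg_ll(par):
            b0, b1, log_tau, log_sig = par
            total = 0.0
            for g in groups:
                n = len(g)
                V = np.exp(log_tau) * np.ones((n, n)) + np.exp(log_sig) * np.eye(n)
                mu = b0 + b1 * g.x.to_numpy()
                total += stats.multivariate_normal.logpdf(g.steps, mu, V)
            return -total

        res = optimize.minimize(neg_ll, [5.0, 1.0, 1.0, 0.5], method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-12,
                                         "xatol": 1e-10})
        assert fit.minus2ll == pytest.approx(2 * res.fun, abs=1e-3)
        assert fit.fixed["x"].B == pytest.approx(res.x[1], rel=1e-3)
        assert fit.ml_variance["tau00"] == pytest.approx(np.exp(res.x[2]), rel=1e-2)

    def test_optimum_beats_truth(self, rng):
        df = _random_intercept_data(rng, rho=0.3)
        spec = MlmSpec(fixed_terms=("intercept", "time", "x"), ar1=True)
        fit = fit_mlm(df, spec)
        truth_ll = mlm_loglik(
            {"beta": np.array([5.0, 0.1, 1.5]), "tau00": 4.0, "tau11": 0.0,
             "tau01": 0.0, "sigma2": 1.5**2, "rho": 0.3}, df, spec)
        assert fit.minus2ll <= -2 * truth_ll + 1e-6

    def test_fit_consistent_with_public_loglik(self, rng):
        df = _random_intercept_data(rng, rho=0.2)
        spec = MlmSpec(fixed_terms=("intercept", "time", "x"),
                       random_slope=True, ar1=True)
        fit = fit_mlm(df, spec)
        ll = mlm_loglik({"beta": fit.beta(), **fit.ml_variance}, df, spec)
        assert fit.minus2ll == pytest.approx(-2 * ll, abs=1e-6)

    def test_rho_fixed_at_zero_reproduces_ar1_free_model(self, rng):
        df = _random_intercept_data(rng)
        base = MlmSpec(fixed_terms=("intercept", "time", "x"), random_slope=True)
        fixed = MlmSpec(fixed_terms=("intercept", "time", "x"),
                        random_slope=True, ar1=True, fix_rho=0.0)
        fit5 = fit_mlm(df, base)
        fit6 = fit_mlm(df, fixed)
        assert fit6.minus2ll == pytest.approx(fit5.minus2ll, abs=1e-8)
        for term in fit5.fixed:
            assert fit6.fixed[term].B == pytest.approx(fit5.fixed[term].B, rel=1e-8)

    def test_rho_recovery_on_ar1_data(self, rng):
        df = _random_intercept_data(rng, m=60, n=40, rho=0.4)
        fit = fit_mlm(df, MlmSpec(fixed_terms=("intercept", "time", "x"), ar1=True))
        assert fit.rho == pytest.approx(0.4, abs=0.06)

    def test_needs_two_participants(self, rng):
        df = _random_intercept_data(rng, m=1)
        with pytest.raises(ValueError):
            fit_mlm(df, MlmSpec(fixed_terms=("intercept",)))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
def test_ar1_model_cross_checked_against_r_nlme(tmp_path, rng):
    """Likelihood-level cross-check against nlme::lme with corCAR1 residuals."""
    df = _random_intercept_data(rng, m=20, n=25, rho=0.3)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(nlme))
        d <- read.csv("{csv}")
        m <- lme(steps ~ time + x, random = ~1 | participant_id,
                 correlation = corCAR1(form = ~ day_index | participant_id),
                 data = d, method = "ML")
        v <- VarCorr(m)
        cat(as.numeric(logLik(m)), fixef(m), as.numeric(v[1,1]),
            m$sigma^2, coef(m$modelStruct$corStruct, unconstrained = FALSE), "\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=300)
    assert out.returncode == 0, out.stderr
    r_ll, b0, b1, b2, r_tau, r_sig2, r_rho = map(float, out.stdout.split())
    spec = MlmSpec(fixed_terms=("intercept", "time", "x"), ar1=True)
    # evaluating our likelihood at R's estimates must reproduce R's logLik
    ll_at_r = mlm_loglik({"beta": np.array([b0, b1, b2]), "tau00": r_tau,
                          "sigma2": r_sig2, "rho": r_rho}, df, spec)
    assert ll_at_r == pytest.approx(r_ll, abs=1e-4)
    # and our own optimum should agree with R's fit
    fit = fit_mlm(df, spec)
    assert fit.minus2ll == pytest.approx(-2 * r_ll, abs=1e-3)
    assert fit.ml_variance["rho"] == pytest.approx(r_rho, abs=1e-3)
    assert fit.fixed["x"].B == pytest.approx(b2, rel=1e-4)


class TestDevianceAndSummaries:
    def _stub(self, m2ll, k, n=400):
        return MlmFit(minus2ll=m2ll, n_params=k, n_obs=n, n_participants=15)

    def test_identical_fits(self):
        t = s.deviance_test(self._stub(100.0, 3), self._stub(100.0, 4))
        assert t.chi2 == 0.0 and t.P == pytest.approx(stats.chi2.sf(0, 1))

    def test_errors(self):
        with pytest.raises(ValueError):
            s.deviance_test(self._stub(100.0, 4), self._stub(90.0, 4))
        with pytest.raises(ValueError):
            s.deviance_test(self._stub(100.0, 3, n=400),
                            self._stub(90.0, 4, n=399))

    def test_icc_arithmetic(self):
        fit = MlmFit(tau00=2.0, sigma2=2.0)
        assert s.compute_icc(fit) == 0.5
        assert s.compute_icc(MlmFit(tau00=0.0, sigma2=1.0)) == 0.0
        with pytest.raises(ValueError):
            s.compute_icc(MlmFit(tau00=0.0, sigma2=0.0))

    def test_variance_explained(self):
        ref = MlmFit(tau00=4.0, sigma2=8.0)
        fit = MlmFit(tau00=4.0, sigma2=4.0)
        assert s.variance_explained(ref, fit, "within") == 0.5
        assert s.variance_explained(ref, ref, "between") == 0.0
        with pytest.raises(ValueError):
            s.variance_explained(MlmFit(sigma2=0.0), fit, "within")


class TestLadder:
    def test_frames_match_design_arithmetic(self, small_study):
        _, n_int, _ = prepare_frame(small_study.data, "intervention")
        _, n_pred, _ = prepare_frame(small_study.data, "predictor:self_efficacy")
        assert n_int == 465
        assert n_pred == 600

    def test_deviance_monotone_and_df_increments(self, small_study):
        res = run_ladder(small_study, mode="predictor:self_efficacy")
        m2lls = [f.minus2ll for f in res.fits]
        assert all(a >= b - 1e-6 for a, b in zip(m2lls, m2lls[1:]))
        kdiffs = [b.n_params - a.n_params for a, b in zip(res.fits, res.fits[1:])]
        assert kdiffs == [1, 2, 10, 2, 1]
        assert [t.df for t in res.tests[1:]] == kdiffs
        assert all(f.n_obs == res.n_used for f in res.fits)

    def test_intervention_ladder_terms(self, small_study):
        res = run_ladder(small_study, mode="intervention")
        assert "dmi" in res.final.fixed and "bf" in res.final.fixed
        assert res.final.spec.ar1
        assert 0 < res.icc < 1

    def test_null_icc_recovered_on_large_cohort(self, default_cfg):
        cfg = default_cfg.replace(n_participants=2000)
        ds = s.simulate_study(cfg, 314, missingness=False)
        sub = ds.data[ds.data.washout == 0].copy()
        sub["time"] = sub["day_index"].astype(float)
        fit = fit_mlm(sub, MlmSpec(fixed_terms=("intercept",)))
        assert s.compute_icc(fit) == pytest.approx(0.571, abs=0.02)

    def test_unknown_mode_rejected(self, small_study):
        with pytest.raises(ValueError):
            run_ladder(small_study, mode="bogus")
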