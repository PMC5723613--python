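import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from divebout.errors import FitError
from divebout.gam import (
    FactorTerm,
    GamSpec,
    Gaussian,
    LinearTerm,
    Poisson,
    RandomEffectTerm,
    SmoothTerm,
    Tweedie,
    compute_vif,
    fit_gam,
    predict,
    select_model,
)
from divebout.gam.model import _design


class TestGaussianExactness:
    def test_matches_brute_force_penalized_least_squares(self, rng):
        """At fixed smoothing the fit must equal the direct linear-algebra solve."""
        n = 80
        x = rng.uniform(0, 1, n)
        y = np.sin(6 * x) + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"y": y, "x": x})
        spec = GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=8)])
        lam = np.array([3.7])
        fit = fit_gam(spec, df, lambdas=lam)
        X, _s, _l, pens, _pl = _design(spec, df, fitting=True)
        # reproduce the internal penalty rescaling on the raw penalty
        sl, S_raw = None, None
        for slc, S in pens:
            sl, S_raw = slc, S
        Xb = X[:, sl]
        xs = float((Xb * Xb).sum()) / Xb.shape[1]
        ev = np.linalg.eigvalsh(S_raw)
        ss = float(ev[ev > ev.max() * 1e-9].mean())
        S_full = np.zeros((X.shape[1], X.shape[1]))
        S_full[sl, sl] = lam[0] * S_raw * (xs / ss)
        beta_oracle = np.linalg.solve(X.T @ X + S_full, X.T @ y)
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-6)

    def test_infinite_smoothing_recovers_straight_line_fit(self, rng):
        n = 200
        x = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=10)]), df,
                      lambdas=np.array([1e12]))
        coef = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fit.fitted(df), np.polyval(coef, x), atol=1e-4)

    def test_aic_matches_classical_closed_form_for_linear_model(self, rng):
        n = 120
        x = rng.uniform(0, 1, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Gaussian(), [LinearTerm("x")]), df)
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        sigma2 = (resid**2).mean()  # ML estimate
        aic_classical = n * np.log(2 * np.pi * sigma2) + n + 2 * 3  # beta0, beta1, sigma2
        assert fit.aic == pytest.approx(aic_classical, abs=1e-6)
        assert fit.edf_total == pytest.approx(2.0, abs=1e-8)


class TestPoisson:
    def test_intercept_only_recovers_mean(self, rng):
        y = rng.poisson(3.0, 300)
        fit = fit_gam(GamSpec("y", Poisson(), []), pd.DataFrame({"y": y}))
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-8)

    def test_all_zero_counts_handled(self):
        df = pd.DataFrame({"y": np.zeros(50)})
        fit = fit_gam(GamSpec("y", Poisson(), []), df)
        assert np.exp(fit.beta[0]) < 1e-4

    def test_penalized_deviance_path_non_increasing(self, rng):
        n = 300
        x = rng.uniform(0, 2, n)
        y = rng.poisson(np.exp(0.3 + 0.8 * np.sin(3 * x)))
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Poisson(), [SmoothTerm(("x",), k=8)]), df,
                      lambdas=np.array([1.0]))
        path = fit.penalized_deviance_path
        assert np.all(np.diff(path) <= 1e-6 * (np.abs(path[:-1]) + 1))

    def test_predictions_strictly_positive(self, rng):
        n = 200
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(-2 + x))
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Poisson(), [SmoothTerm(("x",), k=5)]), df)
        pr = predict(fit, df)
        assert (pr["fit"] > 0).all()


class TestRandomEffects:
    def test_huge_smoothing_shrinks_level_effects_to_zero(self, rng):
        g = np.repeat(np.arange(10), 20)
        y = rng.normal(0, 1, 200) + np.repeat(rng.normal(0, 2, 10), 20)
        df = pd.DataFrame({"y": y, "id": g.astype(str)})
        fit = fit_gam(GamSpec("y", Gaussian(), [RandomEffectTerm("id")]), df,
                      lambdas=np.array([1e12]))
        assert np.abs(fit.beta[1:]).max() < 1e-6

    def test_variance_component_recovered_within_20_percent(self, rng):
        L, m, sigma_b = 100, 20, 0.8
        g = np.repeat(np.arange(L), m)
        y = 2.0 + np.repeat(rng.normal(0, sigma_b, L), m) + rng.normal(0, 1.0, L * m)
        df = pd.DataFrame({"y": y, "id": g.astype(str)})
        fit = fit_gam(GamSpec("y", Gaussian(), [RandomEffectTerm("id")]), df)
        est = list(fit.variance_components().values())[0]
        assert abs(est - sigma_b**2) / sigma_b**2 < 0.2

    def test_unseen_level_predicts_with_zero_effect(self, rng):
        g = np.repeat(["a", "b", "c"], 30)
        y = rng.normal(0, 1, 90) + np.repeat([1.0, -1.0, 0.5], 30)
        df = pd.DataFrame({"y": y, "id": g})
        fit = fit_gam(GamSpec("y", Gaussian(), [RandomEffectTerm("id")]), df)
        pr = predict(fit, pd.DataFrame({"id": ["zzz"]}))
        assert pr["fit"].iloc[0] == pytest.approx(fit.beta[0])

    def test_single_level_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "id": ["a", "a"]})
        with pytest.raises(FitError):
            fit_gam(GamSpec("y", Gaussian(), [RandomEffectTerm("id")]), df)


class TestTensorSmooth:
    def test_additive_truth_matches_marginal_fit(self, rng):
        n = 400
        x1 = rng.uniform(0, 1, n)
        x2 = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x1) + rng.normal(0, 0.2, n)  # depends on x1 only
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        te = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x1", "x2"), k=(5, 5))]), df)
        cr = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x1",), k=5)]), df)
        rmse = np.sqrt(np.mean((te.fitted(df) - cr.fitted(df)) ** 2))
        assert rmse < 0.1
        # the x2-margin penalty null space keeps x2-linear terms, so the
        # smoothed-out tensor retains ~2*k1 df (mgcv shows the same)
        assert te.edf_total < 2 * 5 + 4


class TestDiagnostics:
    def test_vif_orthogonal_covariates(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        vif = compute_vif(X)
        assert np.allclose(vif, 1.0, atol=0.05)

    def test_vif_exact_collinearity_is_infinite(self, rng):
        x = rng.normal(size=100)
        vif = compute_vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vif).all()

    def test_vif_known_correlation(self, rng):
        n = 200_00
        a = rng.normal(size=n)
        b = 0.7 * a + np.sqrt(1 - 0.49) * rng.normal(size=n)
        vif = compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert vif["a"] == pytest.approx(1 / (1 - 0.49), rel=0.05)

    def test_select_model_ranks_and_breaks_ties_by_edf(self, rng):
        n = 150
        x = rng.uniform(0, 1, n)
        y = 1 + x + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "x": x})
        lin = fit_gam(GamSpec("y", Gaussian(), [LinearTerm("x")], label="lin"), df)
        smo = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=8)], label="smo"), df)
        table = select_model([lin, smo])
        assert table["aic"].is_monotonic_increasing
        assert set(table["label"]) == {"lin", "smo"}

    def test_select_model_mismatched_data_rejected(self, rng):
        df1 = pd.DataFrame({"y": rng.normal(size=50), "x": rng.uniform(size=50)})
        df2 = pd.DataFrame({"y": rng.normal(size=60), "x": rng.uniform(size=60)})
        f1 = fit_gam(GamSpec("y", Gaussian(), [LinearTerm("x")]), df1)
        f2 = fit_gam(GamSpec("y", Gaussian(), [LinearTerm("x")]), df2)
        with pytest.raises(FitError):
            select_model([f1, f2])

    def test_noise_smooth_rarely_selected_over_true_model(self, rng):
        """With the equal-support rule (delta AIC < 2 -> simpler structure), a
        pure-noise smooth is almost never selected.  A plain AIC comparison
        ties at ~chi-square(1) through the smooth's unpenalized linear null
        space, which is exactly what the equal-support rule absorbs."""
        from divebout.foraging import select_with_parsimony

        wins = 0
        n_sim = 60
        for _ in range(n_sim):
            n = 120
            x = rng.uniform(0, 1, n)
            z = rng.uniform(0, 1, n)  # pure noise covariate
            y = 1 + 2 * x + rng.normal(0, 0.4, n)
            df = pd.DataFrame({"y": y, "x": x, "z": z})
            base = fit_gam(GamSpec("y", Gaussian(), [LinearTerm("x")], label="base"), df)
            noisy = fit_gam(
                GamSpec("y", Gaussian(), [LinearTerm("x"), SmoothTerm(("z",), k=5)],
                        label="noisy"),
                df,
            )
            chosen, _ = select_with_parsimony({"base": base, "noisy": noisy})
            if chosen == "base":
                wins += 1
        assert wins >= 0.85 * n_sim


class TestPredict:
    def test_training_predictions_equal_fitted_values(self, rng):
        n = 100
        x = rng.uniform(0, 1, n)
        y = np.cos(4 * x) + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=8)]), df)
        pr = predict(fit, df)
        np.testing.assert_allclose(pr["fit"].to_numpy(), fit.fitted(df), atol=1e-10)

    def test_extrapolation_flagged(self, rng):
        n = 60
        x = rng.uniform(0, 1, n)
        df = pd.DataFrame({"y": np.sin(x), "x": x})
        fit = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=5)]), df)
        pr = predict(fit, pd.DataFrame({"x": [0.5, 2.0]}))
        assert not pr["extrapolated"].iloc[0]
        assert pr["extrapolated"].iloc[1]

    def test_interval_coverage_near_95_percent(self, rng):
        """Across-the-function coverage of the 95% band over replicates."""
        n, n_sim = 150, 200
        grid = pd.DataFrame({"x": np.linspace(0.05, 0.95, 15)})
        truth = np.sin(2 * np.pi * grid["x"].to_numpy())
        hits, total = 0, 0
        for _ in range(n_sim):
            x = rng.uniform(0, 1, n)
            y = np.sin(2 * np.pi * x) + rng.normal(0, 0.4, n)
            fit = fit_gam(
                GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=10)]),
                pd.DataFrame({"y": y, "x": x}),
            )
            pr = predict(fit, grid)
            hits += int(((pr["lo"] <= truth) & (truth <= pr["hi"])).sum())
            total += len(grid)
        coverage = hits / total
        assert 0.92 <= coverage <= 0.98


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestMgcvCrossCheck:
    def test_gaussian_smooth_matches_mgcv(self, tmp_path, rng):
        """Advisory oracle: fitted values agree closely with mgcv's ML fit."""
        n = 250
        x = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x) + 0.5 * x + rng.normal(0, 0.3, n)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_gam(GamSpec("y", Gaussian(), [SmoothTerm(("x",), k=10)]), df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fitted.csv"
        script = (
            "library(mgcv); d <- read.csv('%s');"
            "f <- gam(y ~ s(x, k=10, bs='cr'), data=d, method='ML');"
            "write.csv(data.frame(fit=fitted(f)), '%s', row.names=FALSE)" % (csv, out)
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)["fit"].to_numpy()
        ours = fit.fitted(df)
        assert np.corrcoef(ours, ref)[0, 1] > 0.999
        assert np.max(np.abs(ours - ref)) < 0.05


class TestSpecSerialization:
    def test_yaml_round_trip_preserves_structure(self, tmp_path):
        from divebout.gam import LinearByFactorTerm, Tweedie

        spec = GamSpec(
            "n_pce",
            Tweedie(p=1.05),
            [
                SmoothTerm(("duration_s", "max_depth_m"), k=(5, 5), by="class"),
                LinearByFactorTerm("seafloor_depth_m", "class"),
                FactorTerm("animal_id"),
                RandomEffectTerm("bout_id"),
            ],
            label="demo",
        )
        spec.to_yaml(tmp_path / "spec.yaml")
        back = GamSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.response == spec.response
        assert back.family.p == 1.05
        assert back.terms[0].covariates == ("duration_s", "max_depth_m")
        assert back.terms[0].by == "class"
        assert len(back.terms) == 4

    def test_fit_json_export(self, tmp_path, rng):
        import json

        y = rng.poisson(2.0, 100)
        fit = fit_gam(GamSpec("y", Poisson(), [], label="m0"), pd.DataFrame({"y": y}))
        fit.to_json(tmp_path / "fit.json")
        obj = json.loads((tmp_path / "fit.json").read_text())
        assert obj["label"] == "m0" and obj["family"] == "poisson"
        assert obj["aic"] == pytest.approx(fit.aic)


class TestTweedieGam:
    def test_intercept_only_recovers_mean(self, rng):
        y = rng.gamma(4, 20, 200)
        y[rng.uniform(size=200) < 0.1] = 0.0
        df = pd.DataFrame({"y": y})
        fit = fit_gam(GamSpec("y", Tweedie(p=1.05), []), df)
        assert np.exp(fit.beta[0]) == pytest.approx(y.mean(), rel=1e-3)
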