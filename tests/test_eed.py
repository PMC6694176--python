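"""Censored maximum likelihood, AIC family selection, bootstrap, exceedance."""

import json
import math
import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy import integrate, stats

import nestrisk as nr
from nestrisk.eed import (
    FAMILIES,
    CensoredSample,
    _dist,
    bootstrap_params,
    censored_loglik,
    fit_censored,
    select_family,
)


def exact(values):
    return [CensoredSample(kind="exact", value=float(v)) for v in values]


class TestCensoredLoglik:
    def test_all_exact_equals_iid_loglik(self, small_censored):
        data = [s for s in small_censored if s.kind == "exact"]
        params = (0.1, 0.9)
        ll = censored_loglik(params, "lognormal", data)
        ref = sum(stats.lognorm(0.9, scale=math.exp(0.1)).logpdf(s.value) for s in data)
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_left_censored_exponential_closed_form(self):
        lam, b = 0.7, 1.3
        data = [CensoredSample(kind="left", bound=b), CensoredSample(kind="exact", value=2.0)]
        ll = censored_loglik((lam,), "exponential", data)
        ref = math.log(1 - math.exp(-lam * b)) + math.log(lam) - lam * 2.0
        assert ll == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("family,params", [
        ("lognormal", (0.2, 0.8)),
        ("gamma", (1.7, 1.2)),
        ("weibull", (1.4, 2.1)),
        ("exponential", (0.9,)),
    ])
    def test_matches_quadrature_oracle(self, family, params, small_censored):
        """Censored terms equal numerical integration of the pdf over each region."""
        d = _dist(family, params)
        ref = 0.0
        for s in small_censored:
            if s.kind == "exact":
                ref += d.logpdf(s.value)
            elif s.kind == "left":
                mass, _ = integrate.quad(d.pdf, 0, s.bound)
                ref += math.log(mass)
            else:
                mass, _ = integrate.quad(d.pdf, s.lo, s.hi)
                ref += math.log(mass)
        assert censored_loglik(params, family, small_censored) == pytest.approx(
            ref, abs=1e-6
        )

    def test_zero_mass_region_returns_sentinel(self):
        # Weibull with tiny scale: interval far in the tail has zero mass.
        data = [CensoredSample(kind="interval", lo=1e6, hi=2e6),
                CensoredSample(kind="exact", value=1.0)]
        ll = censored_loglik((2.0, 1e-3), "weibull", data)
        assert ll <= -1e290

    def test_unknown_family_rejected(self, small_censored):
        with pytest.raises(ValueError, match="family"):
            censored_loglik((1.0,), "normal", small_censored)


class TestFitCensored:
    def test_uncensored_lognormal_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0.4, 1.1, 150)
        fit = fit_censored(exact(x), "lognormal", method="numeric")
        logs = np.log(x)
        assert fit.params[0] == pytest.approx(logs.mean(), abs=1e-6)
        assert fit.params[1] == pytest.approx(
            math.sqrt(np.mean((logs - logs.mean()) ** 2)), abs=1e-6
        )

    def test_two_point_exponential_rate_is_inverse_mean(self):
        fit = fit_censored(exact([1.0, 1.0]), "exponential")
        assert fit.params[0] == pytest.approx(1.0, abs=1e-9)

    def test_fitted_params_maximize_likelihood(self, small_censored):
        fit = fit_censored(small_censored, "gamma")
        ll = censored_loglik(fit.params, "gamma", small_censored)
        for eps in (0.97, 1.03):
            worse = (fit.params[0] * eps, fit.params[1])
            assert censored_loglik(worse, "gamma", small_censored) <= ll + 1e-9
            worse = (fit.params[0], fit.params[1] * eps)
            assert censored_loglik(worse, "gamma", small_censored) <= ll + 1e-9

    def test_aic_identity(self, small_censored):
        for family, k in [("lognormal", 2), ("exponential", 1)]:
            fit = fit_censored(small_censored, family)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, rel=1e-12)

    def test_gamma_recovery_under_left_censoring(self):
        """Shape recovered within +-0.3 of truth across seeds at 30% censoring."""
        true_shape, true_rate = 2.0, 1.0
        lod = float(stats.gamma(true_shape, scale=1 / true_rate).ppf(0.3))
        shapes = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.gamma(true_shape, 1 / true_rate, 200)
            data = [
                CensoredSample(kind="exact", value=float(v)) if v >= lod
                else CensoredSample(kind="left", bound=lod)
                for v in x
            ]
            shapes.append(fit_censored(data, "gamma").params[0])
        assert abs(float(np.median(shapes)) - true_shape) < 0.3

    def test_refuses_zero_quantified(self):
        data = [CensoredSample(kind="left", bound=0.05)] * 28 + [
            CensoredSample(kind="interval", lo=0.05, hi=0.15)
        ]
        with pytest.raises(nr.CannotFitEED, match="cannot fit EED"):
            fit_censored(data, "lognormal")

    def test_refuses_single_observation(self):
        with pytest.raises(nr.CannotFitEED):
            fit_censored(exact([1.0]), "lognormal")

    def test_warns_on_sparse_information(self):
        data = exact([1.0, 2.0]) + [CensoredSample(kind="left", bound=0.1)] * 20
        with pytest.warns(UserWarning, match="weakly determined"):
            fit_censored(data, "lognormal")

    def test_r_fitdistrplus_agrees_on_censored_lognormal(self, tmp_path):
        """Independent oracle: the censored MLE matches fitdistrcens (R)."""
        rng = np.random.default_rng(11)
        x = rng.lognormal(0.3, 0.9, 40)
        lod, loq = 0.6, 1.2
        rows = []
        data = []
        for v in x:
            if v < lod:
                rows.append(("NA", lod))
                data.append(CensoredSample(kind="left", bound=lod))
            elif v < loq:
                rows.append((lod, loq))
                data.append(CensoredSample(kind="interval", lo=lod, hi=loq))
            else:
                rows.append((v, v))
                data.append(CensoredSample(kind="exact", value=float(v)))
        fit = fit_censored(data, "lognormal")
        csv = tmp_path / "cens.csv"
        csv.write_text("left,right\n" + "\n".join(f"{l},{r}" for l, r in rows))
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(fitdistrplus))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            f <- fitdistcens(d, "lnorm")
            cat(jsonlite::toJSON(list(mu=unname(f$estimate["meanlog"]),
                                      sigma=unname(f$estimate["sdlog"]))))
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv)],
            capture_output=True, text=True, check=True,
        )
        ref = json.loads(out.stdout)
        assert fit.params[0] == pytest.approx(ref["mu"][0], abs=2e-4)
        assert fit.params[1] == pytest.approx(ref["sigma"][0], abs=2e-4)


class TestSelectFamily:
    def test_lognormal_selected_on_large_lognormal_sample(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0.0, 1.0, 1000)
        assert select_family(exact(x)).family == "lognormal"

    def test_exponential_beats_gamma_on_nested_data(self):
        """Gamma nests the exponential, so its loglik is never lower; on
        exponential data the gain is typically < 1 (half a chi-square) and the
        parameter count makes exponential win the AIC on most draws."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            data = exact(rng.exponential(1.0, 400))
            fg = fit_censored(data, "gamma")
            fe = fit_censored(data, "exponential")
            assert fg.loglik >= fe.loglik - 1e-6
            fit = select_family(data, families=("gamma", "exponential"))
            wins += fit.family == "exponential"
        assert wins >= 7

    def test_single_candidate_returned_unchanged(self, small_censored):
        fit = select_family(small_censored, families=("weibull",))
        assert fit.family == "weibull"

    def test_selection_recovers_generating_family_at_scale(self):
        """AIC picks the truth >80% of the time for well-separated families."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            x = rng.lognormal(0.0, 1.0, 500)
            best = select_family(exact(x), families=("lognormal", "exponential"))
            hits += best.family == "lognormal"
        assert hits >= 9


class TestBootstrap:
    def test_single_iteration_degenerate(self, small_censored):
        boot = bootstrap_params(small_censored, "lognormal", n_iter=1, seed=0)
        assert boot.params.shape[0] + boot.n_failed == 1

    def test_seed_determinism(self, small_censored):
        a = bootstrap_params(small_censored, "lognormal", n_iter=25, seed=123)
        b = bootstrap_params(small_censored, "lognormal", n_iter=25, seed=123)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.n_failed == b.n_failed

    def test_different_seeds_differ(self, small_censored):
        a = bootstrap_params(small_censored, "lognormal", n_iter=25, seed=1)
        b = bootstrap_params(small_censored, "lognormal", n_iter=25, seed=2)
        assert not np.array_equal(a.params, b.params)

    def test_param_ci_orientation(self, small_censored):
        fit = fit_censored(small_censored, "lognormal")
        fit = nr.with_bootstrap(fit, small_censored, n_iter=100, seed=9)
        ci = fit.param_ci()
        assert ci.shape == (2, 2)
        assert np.all(ci[:, 0] <= ci[:, 1])


class TestExceedance:
    def test_lognormal_median_benchmark_gives_half(self):
        fit = nr.EEDFit(family="lognormal", params=(0.0, 1.0), loglik=0.0,
                        aic=0.0, n_exact=10, n_left=0, n_interval=0)
        res = nr.exceedance(fit, benchmark_ng_g=1.0, translocation=1.0)
        assert res.probability == pytest.approx(0.5, abs=1e-12)

    def test_half_at_fitted_median_for_every_family(self, small_censored):
        for family in FAMILIES:
            fit = fit_censored(small_censored, family)
            assert fit.sf(fit.median()) == pytest.approx(0.5, abs=1e-9)

    def test_probability_tends_to_one_for_tiny_benchmark(self, small_censored):
        fit = fit_censored(small_censored, "lognormal")
        assert nr.exceedance(fit, 1e-12).probability > 0.999

    def test_monotone_in_benchmark_and_translocation(self, small_censored):
        fit = fit_censored(small_censored, "gamma")
        benches = [0.01, 0.1, 1.0, 10.0]
        probs = [nr.exceedance(fit, b).probability for b in benches]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        ts = [0.1, 0.25, 0.5, 1.0]
        probs_t = [nr.exceedance(fit, 1.0, translocation=t).probability for t in ts]
        assert all(a <= b for a, b in zip(probs_t, probs_t[1:]))
        assert all(0 <= p <= 1 for p in probs + probs_t)

    def test_acceptable_flag_follows_threshold(self, small_censored):
        fit = fit_censored(small_censored, "lognormal")
        res = nr.exceedance(fit, 1.0, risk_threshold=0.9999)
        assert res.acceptable == (res.probability < 0.9999)

    def test_translocation_domain(self, small_censored):
        fit = fit_censored(small_censored, "lognormal")
        with pytest.raises(ValueError):
            nr.exceedance(fit, 1.0, translocation=0.0)


class TestHazen:
    def test_published_formula_n4(self):
        np.testing.assert_allclose(nr.hazen_positions(4), [0.125, 0.375, 0.625, 0.875])

    def test_single_point(self):
        np.testing.assert_allclose(nr.hazen_positions(1), [0.5])

    def test_empty(self):
        assert nr.hazen_positions(0).size == 0

    def test_increasing_and_symmetric(self):
        for n in (2, 5, 29, 82):
            p = nr.hazen_positions(n)
            assert np.all(np.diff(p) > 0)
            np.testing.assert_allclose(p + p[::-1], np.ones(n))

    def test_censored_points_ranked_by_interval_midpoint(self, small_censored):
        pts = nr.empirical_points(small_censored)
        assert np.all(np.diff(pts["midpoint"]) >= 0)
        left = pts[pts["kind"] == "left"]
        assert np.allclose(left["midpoint"], left["hi"] / 2)


class TestRunRiskAssessment:
    @pytest.fixture(scope="class")
    def results(self, request):
        presets = nr.study_like_presets()
        obs = []
        for name in ("cucurbita_clothianidin", "cucurbita_imidacloprid",
                     "cucurbita_thiamethoxam"):
            obs.extend(nr.gen_residues(presets[name]).observations)
        ds = nr.ResidueDataset.from_observations(obs)
        profile = nr.build_exposure_profile()
        return nr.run_risk_assessment(
            ds, profile, nr.table1_endpoints(), n_boot=50, seed=7,
        )

    def test_one_row_per_combination(self, results):
        ok = results[results["status"] != ""]
        fitted = results[~results["status"].str.startswith("not assessed")]
        # 2 fittable analytes x 2 scenarios x 2 endpoint kinds x 5 translocations
        assert len(fitted) == 2 * 2 * 2 * 5

    def test_chronic_exceeds_acute(self, results):
        fitted = results[~results["status"].str.startswith("not assessed")]
        piv = fitted.pivot_table(
            index=["analyte", "endpoint_kind", "translocation"],
            columns="scenario", values="exceedance",
        )
        assert (piv["chronic"] >= piv["acute"]).all()

    def test_surrogate_exceeds_geomean(self, results):
        fitted = results[~results["status"].str.startswith("not assessed")]
        piv = fitted.pivot_table(
            index=["analyte", "scenario", "translocation"],
            columns="endpoint_kind", values="exceedance",
        )
        assert (piv["solitary_surrogate"] >= piv["hb_geomean"]).all()

    def test_unfittable_analyte_reported_not_dropped(self, results):
        thia = results[results["analyte"] == "thiamethoxam"]
        assert len(thia) == 1
        assert thia.iloc[0]["status"].startswith("not assessed")

    def test_determinism_for_fixed_seed(self):
        presets = nr.study_like_presets()
        ds = nr.gen_residues(presets["cucurbita_clothianidin"])
        profile = nr.build_exposure_profile()
        kwargs = dict(n_boot=30, seed=11, translocations=(0.5, 1.0))
        a = nr.run_risk_assessment(ds, profile, nr.table1_endpoints(), **kwargs)
        b = nr.run_risk_assessment(ds, profile, nr.table1_endpoints(), **kwargs)
        assert a.equals(b)
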