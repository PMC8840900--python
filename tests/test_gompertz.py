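"""Spatial Gompertz model: likelihood pieces, Laplace accuracy, fitting, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from forestbird.errors import ComparisonError, DataError
from forestbird.gompertz import (
    FixedEffects,
    GompertzModelSpec,
    RandomFields,
    Z_95,
    _ar1_precision,
    _context_from_samples,
    _default_start,
    _obs_terms,
    fit_model,
    joint_nll,
    linear_predictor,
    marginal_nll,
    observation_nll,
    response_curve,
    select_quadratic,
    significance,
    trim_extremes,
)
from forestbird.matern import KnotMesh, build_knot_mesh, matern_correlation


def _fx(T=1, **kw):
    defaults = dict(beta=np.full(T, 10.0), gamma1=0.0, sigma_m2=0.5,
                    log_kappa=-3.0, rho_eps=0.4, sigma_omega2=0.3, sigma_eps2=0.1)
    defaults.update(kw)
    return FixedEffects(**defaults)


class TestObservationModel:
    def test_gamma_density_example(self):
        # shape 2, scale 1 -> mu = 2, sigma_m2 = 0.5; density at b=2 is 2e^-2
        nll = observation_nll(b=2.0, d=2.0, a=1.0, sigma_m2=0.5, family="gamma")
        assert np.isclose(nll[0], -np.log(2 * np.exp(-2)), atol=1e-10)
        # cross-check against scipy's gamma pdf
        assert np.isclose(nll[0], -gamma_dist.logpdf(2.0, a=2.0, scale=1.0))

    def test_finite_for_positive_dispersion_and_sharpens(self):
        vals = [observation_nll(5.0, 5.0, 1.0, s2, "gamma")[0] for s2 in (0.5, 0.1, 0.01)]
        assert all(np.isfinite(vals))
        assert vals[0] > vals[1] > vals[2]  # density spikes at b = mu as s2 -> 0

    def test_gamma_rejects_zero_b(self):
        with pytest.raises(DataError):
            observation_nll(0.0, 1.0, 1.0, 0.5, "gamma")

    def test_lognormal_mean_matches_a_d(self):
        rng = np.random.default_rng(8)
        a, d, s2 = 0.031, 3e4, 0.3
        draws = np.exp(rng.normal(np.log(a * d) - s2 / 2, np.sqrt(s2), size=200_000))
        assert np.isclose(draws.mean(), a * d, rtol=0.01)
        # and the nll corresponds to that generative law
        nll = observation_nll(a * d, d, a, s2, family="lognormal")
        from scipy.stats import lognorm
        expect = -lognorm.logpdf(a * d, s=np.sqrt(s2), scale=np.exp(np.log(a * d) - s2 / 2))
        assert np.isclose(nll[0], expect)

    @pytest.mark.parametrize("family,obs_var", [("gamma", "cv"), ("gamma", "absolute"),
                                                ("lognormal", "cv")])
    def test_derivatives_match_finite_differences(self, family, obs_var):
        b = np.array([1.5, 4.0, 0.8])
        log_mu = np.array([0.3, 1.2, -0.1])
        h = 1e-6
        _, d1, d2 = _obs_terms(b, log_mu, 0.4, family, obs_var)
        for j in range(3):
            e = np.zeros(3); e[j] = h
            np_, _, _ = _obs_terms(b, log_mu + e, 0.4, family, obs_var)
            nm_, _, _ = _obs_terms(b, log_mu - e, 0.4, family, obs_var)
            assert np.isclose((np_ - nm_)[j] / (2 * h), d1[j], rtol=1e-5)
            _, d1p, _ = _obs_terms(b, log_mu + e, 0.4, family, obs_var)
            _, d1m, _ = _obs_terms(b, log_mu - e, 0.4, family, obs_var)
            assert np.isclose((d1p - d1m)[j] / (2 * h), d2[j], rtol=1e-4, atol=1e-8)


class TestLinearPredictor:
    def test_all_zero_effects(self):
        eta = linear_predictor(_fx(beta=np.array([10.0])), None, {"tit": 0.0})
        assert eta[0] == 10.0

    def test_reported_finland_scale_example(self):
        # beta = 10.315, gamma1 = 0.025, tit at +1 SD -> 10.340
        fx = _fx(beta=np.array([10.315]), gamma1=0.025)
        eta = linear_predictor(fx, None, {"tit": 1.0})
        assert np.isclose(eta[0], 10.340)

    def test_inactive_covariate_ignored(self):
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 covariate_set=("tit",))
        fx = _fx(beta=np.array([10.0]), gamma1=0.1, gamma2=5.0)
        eta = linear_predictor(fx, None, {"tit": 1.0, "tit2": 1.0}, spec=spec)
        assert np.isclose(eta[0], 10.1)

    def test_fields_add(self):
        fields = RandomFields(omega=np.array([0.5]), epsilon=np.array([[0.25]]))
        eta = linear_predictor(_fx(beta=np.array([1.0])), fields, {}, 0, 0)
        assert np.isclose(eta[0], 1.75)


def _one_knot_samples(rng, fx, n, T, spec):
    X = rng.normal(size=n)
    years = rng.integers(0, T, size=n)
    mesh = KnotMesh(knot_coords=np.zeros((1, 2)), assignment=np.zeros(n, dtype=int))
    mu = spec.area * np.exp(fx.beta[years] + fx.gamma1 * X)
    b = rng.gamma(1 / fx.sigma_m2, mu * fx.sigma_m2)
    samples = pd.DataFrame({"b": b, "year": 2001 + years, "tit": X})
    return samples, mesh


class TestJointNll:
    def test_single_knot_matches_scalar_ar1(self):
        """At x = 1 the MVN field terms collapse to a hand-written scalar AR(1)."""
        rng = np.random.default_rng(3)
        T, n = 4, 25
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 n_knots=1, covariate_set=("tit",))
        fx = _fx(T=T, gamma1=0.15)
        samples, mesh = _one_knot_samples(rng, fx, n, T, spec)
        omega = np.array([0.2])
        eps = rng.normal(size=(T, 1)) * 0.3
        got = joint_nll(fx, RandomFields(omega, eps), samples, mesh, spec)

        # scalar oracle
        year_idx = samples["year"].to_numpy() - 2001
        eta = fx.beta[year_idx] + omega[0] + eps[year_idx, 0] \
            + fx.gamma1 * samples["tit"].to_numpy()
        obs = observation_nll(samples["b"].to_numpy(), np.exp(eta), spec.area,
                              fx.sigma_m2).sum()
        def norm_nll(v, m, s2):
            return 0.5 * np.log(2 * np.pi * s2) + (v - m) ** 2 / (2 * s2)
        prior = norm_nll(omega[0], 0.0, fx.sigma_omega2)
        s1 = fx.sigma_eps2 / (1 - fx.rho_eps ** 2)
        prior += norm_nll(eps[0, 0], 0.0, s1)
        for t in range(1, T):
            prior += norm_nll(eps[t, 0], fx.rho_eps * eps[t - 1, 0], fx.sigma_eps2)
        assert np.isclose(got, obs + prior, rtol=1e-10)

    def test_rho_zero_years_independent(self):
        """With ρε = 0 the ε years factorize: joint equals the sum over per-year terms."""
        T = 3
        M, logdet = _ar1_precision(T, 0.0, 0.25, "stationary")
        np.testing.assert_allclose(M, np.eye(T) / 0.25)
        assert np.isclose(logdet, -T * np.log(0.25))

    def test_zero_fields_reduce_to_normalizers(self):
        rng = np.random.default_rng(9)
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 n_knots=1, covariate_set=("tit",))
        fx = _fx(T=2)
        samples, mesh = _one_knot_samples(rng, fx, 10, 2, spec)
        z = RandomFields(np.zeros(1), np.zeros((2, 1)))
        got = joint_nll(fx, z, samples, mesh, spec)
        obs = observation_nll(samples["b"].to_numpy(), np.exp(
            fx.beta[samples["year"].to_numpy() - 2001]
            + fx.gamma1 * samples["tit"].to_numpy()), spec.area, fx.sigma_m2).sum()
        s1 = fx.sigma_eps2 / (1 - fx.rho_eps ** 2)
        normalizers = 0.5 * np.log(2 * np.pi * fx.sigma_omega2) \
            + 0.5 * np.log(2 * np.pi * s1) + 0.5 * np.log(2 * np.pi * fx.sigma_eps2)
        assert np.isclose(got, obs + normalizers, rtol=1e-10)


class TestLaplaceAccuracy:
    def test_lognormal_matches_closed_form(self):
        """Laplace is exact for a linear-Gaussian model (lognormal family in logs)."""
        rng = np.random.default_rng(21)
        x, T, n = 5, 3, 40
        coords = rng.uniform(0, 100, size=(x, 2))
        knot = rng.integers(0, x, size=n)
        years = rng.integers(0, T, size=n)
        mesh = KnotMesh(knot_coords=coords, assignment=knot)
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 family="lognormal", n_knots=x, covariate_set=("tit",))
        fx = _fx(T=T, gamma1=0.2, log_kappa=-2.5)
        X = rng.normal(size=n)
        b = rng.lognormal(mean=np.log(spec.area) + fx.beta[years], sigma=0.5)
        samples = pd.DataFrame({"b": b, "year": 2001 + years, "tit": X})
        lap = marginal_nll(fx, samples, mesh, spec)

        # closed-form marginal: y = log b ~ MVN(mean, Z Sigma_u Z' + s2 I)
        R = matern_correlation(mesh, fx.log_kappa)
        rho, se2 = fx.rho_eps, fx.sigma_eps2
        ar_cov = np.array([[se2 / (1 - rho ** 2) * rho ** abs(t - s)
                            for s in range(T)] for t in range(T)])
        Sigma_u = np.zeros((x + T * x, x + T * x))
        Sigma_u[:x, :x] = fx.sigma_omega2 * R
        Sigma_u[x:, x:] = np.kron(ar_cov, R)
        Z = np.zeros((n, x + T * x))
        Z[np.arange(n), knot] = 1.0
        Z[np.arange(n), x + years * x + knot] = 1.0
        V = Z @ Sigma_u @ Z.T + fx.sigma_m2 * np.eye(n)
        mean = np.log(spec.area) + fx.beta[years] + fx.gamma1 * X - fx.sigma_m2 / 2
        y = np.log(b)
        sign, logdetV = np.linalg.slogdet(V)
        resid = y - mean
        closed = 0.5 * (n * np.log(2 * np.pi) + logdetV
                        + resid @ np.linalg.solve(V, resid)) + np.sum(np.log(b))
        assert np.isclose(lap, closed, atol=1e-6)

    def test_gamma_one_knot_matches_quadrature(self):
        """1-knot gamma toy: Laplace vs adaptive quadrature over the scalar field sum."""
        rng = np.random.default_rng(42)
        n, T = 1000, 1
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 n_knots=1, covariate_set=("tit",))
        fx = _fx(T=T, gamma1=0.2, beta=np.array([9.5]), sigma_m2=0.4,
                 sigma_omega2=0.3, sigma_eps2=0.1, rho_eps=0.4)
        X = rng.normal(size=n)
        mu = spec.area * np.exp(fx.beta[0] + 0.3 + fx.gamma1 * X)
        b = rng.gamma(1 / fx.sigma_m2, mu * fx.sigma_m2)
        samples = pd.DataFrame({"b": b, "year": 2001, "tit": X})
        mesh = KnotMesh(knot_coords=np.zeros((1, 2)), assignment=np.zeros(n, dtype=int))
        lap = marginal_nll(fx, samples, mesh, spec)

        # omega + eps ~ N(0, s2_tot) exactly, so the marginal is a 1-D integral
        s2_tot = fx.sigma_omega2 + fx.sigma_eps2 / (1 - fx.rho_eps ** 2)
        def integrand(u):
            nll, _, _ = _obs_terms(b, np.log(spec.area) + fx.beta[0] + u
                                   + fx.gamma1 * X, fx.sigma_m2, "gamma", "cv")
            return np.exp(lap - np.sum(nll) - u * u / (2 * s2_tot)) \
                / np.sqrt(2 * np.pi * s2_tot)
        s = np.sqrt(s2_tot)
        val, err = quad(integrand, -8 * s, 8 * s, limit=200, epsabs=1e-12, epsrel=1e-12)
        oracle = lap - np.log(val)
        assert err < 1e-8
        assert np.isclose(lap, oracle, atol=1e-4)

    def test_degenerate_variances_approach_fixed_effects_likelihood(self):
        rng = np.random.default_rng(77)
        spec = GompertzModelSpec(include_quadratic=False, include_pc=False,
                                 n_knots=1, covariate_set=("tit",))
        fx_small = _fx(T=2, gamma1=0.1, sigma_omega2=1e-8, sigma_eps2=1e-8, rho_eps=0.0)
        samples, mesh = _one_knot_samples(rng, fx_small, 30, 2, spec)
        lap = marginal_nll(fx_small, samples, mesh, spec)
        eta = fx_small.beta[samples["year"].to_numpy() - 2001] \
            + fx_small.gamma1 * samples["tit"].to_numpy()
        fixed_only = observation_nll(samples["b"].to_numpy(), np.exp(eta),
                                     spec.area, fx_small.sigma_m2).sum()
        assert np.isclose(lap, fixed_only, atol=1e-3)


class TestAnalyticGradient:
    @pytest.mark.parametrize("family", ["gamma", "lognormal"])
    def test_matches_central_differences(self, family, tiny_dataset):
        cfg, ds = tiny_dataset
        spec = GompertzModelSpec(include_quadratic=True, include_pc=True,
                                 family=family, n_knots=cfg.n_knots, area=cfg.area)
        ctx = _context_from_samples(ds.samples, ds.mesh, spec)
        rng = np.random.default_rng(1)
        th = _default_start(ctx) + rng.normal(scale=0.05, size=len(_default_start(ctx)))
        _, g = ctx.marginal_and_grad(th)

        def cold_marginal(t):
            ctx.warm[:] = 0.0  # deterministic oracle, no warm-start hysteresis
            return ctx.marginal(t)

        for j in rng.choice(len(th), size=6, replace=False):
            h = 1e-4 * max(1.0, abs(th[j]))
            tp = th.copy(); tp[j] += h
            tm = th.copy(); tm[j] -= h
            fd = (cold_marginal(tp) - cold_marginal(tm)) / (2 * h)
            assert np.isclose(g[j], fd, rtol=5e-4, atol=1e-6)


class TestFitAndInference:
    def test_fit_smoke_and_aic_identity(self, tiny_dataset):
        cfg, ds = tiny_dataset
        fit = fit_model(ds.samples, ds.mesh, cfg.spec(), seed=0)
        assert fit.converged
        assert np.isclose(fit.aic, 2 * fit.n_params + 2 * fit.nll, rtol=1e-12)
        assert np.all(fit.d_hat > 0)
        assert fit.d_hat.shape == (cfg.n_knots, cfg.n_years)
        # empirical-Bayes fields have matching dimensions
        assert fit.fields.omega.shape == (cfg.n_knots,)
        assert fit.fields.epsilon.shape == (cfg.n_years, cfg.n_knots)

    def test_significance_rule(self):
        sig, ci = significance(0.025, 0.0102)
        assert sig and ci[0] > 0
        assert not significance(0.0, 1.0)[0]
        # CI endpoint exactly at zero: the closed interval encompasses zero
        sig, _ = significance(Z_95 * 1.0, 1.0)
        assert not sig

    def test_select_quadratic_rule(self, tiny_dataset):
        cfg, ds = tiny_dataset
        lin_spec = GompertzModelSpec(include_quadratic=False, include_pc=True,
                                     n_knots=cfg.n_knots, area=cfg.area)
        quad_spec = GompertzModelSpec(include_quadratic=True, include_pc=True,
                                      n_knots=cfg.n_knots, area=cfg.area)
        fit_lin = fit_model(ds.samples, ds.mesh, lin_spec, seed=0)
        fit_quad = fit_model(ds.samples, ds.mesh, quad_spec, seed=0)
        chosen = select_quadratic(fit_lin, fit_quad)
        g2 = fit_quad.fixed.gamma2
        sig = abs(g2) > Z_95 * fit_quad.se["gamma2"]
        if fit_quad.aic < fit_lin.aic and sig:
            assert chosen is fit_quad
        else:
            assert chosen is fit_lin

    def test_select_quadratic_demands_same_data(self, tiny_dataset):
        cfg, ds = tiny_dataset
        fit1 = fit_model(ds.samples, ds.mesh, cfg.spec(), seed=0, compute_se=False)
        other = ds.samples.copy()
        other["b"] = other["b"] * 1.5
        fit2 = fit_model(other, ds.mesh, cfg.spec(), seed=0, compute_se=False)
        with pytest.raises(ComparisonError):
            select_quadratic(fit1, fit2)

    def test_response_curve(self, tiny_dataset):
        cfg, ds = tiny_dataset
        fit = fit_model(ds.samples, ds.mesh, cfg.spec(), seed=0)
        grid = np.linspace(-2, 2, 11)
        c1 = response_curve(fit, grid, n_draws=500, seed=3)
        c2 = response_curve(fit, grid, n_draws=500, seed=3)
        pd.testing.assert_frame_equal(c1, c2)  # seeded determinism
        assert np.all(c1["lo"] <= c1["median"]) and np.all(c1["median"] <= c1["hi"])
        # band width grows away from the centre for a quadratic fit
        width = (c1["hi"] - c1["lo"]).to_numpy()
        assert width[0] > width[len(grid) // 2]
        assert width[-1] > width[len(grid) // 2]

    def test_response_curve_zero_cov_collapses(self, tiny_dataset):
        cfg, ds = tiny_dataset
        fit = fit_model(ds.samples, ds.mesh, cfg.spec(), seed=0)
        fit.fixed_cov = np.zeros_like(fit.fixed_cov)
        c = response_curve(fit, np.linspace(-1, 1, 5), n_draws=200, seed=0)
        np.testing.assert_allclose(c["lo"], c["log_d"], atol=1e-12)
        np.testing.assert_allclose(c["hi"], c["log_d"], atol=1e-12)


class TestTrimExtremes:
    def test_counts(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"b": rng.lognormal(size=40), "year": 2001})
        lo, hi = np.quantile(df["b"], [0.025, 0.975])
        expect = int(((df["b"] >= lo) & (df["b"] <= hi)).sum())
        assert len(trim_extremes(df, 0.025)) == expect == 38

    def test_zero_fraction_identity(self):
        df = pd.DataFrame({"b": [1.0, 2.0, 3.0]})
        assert trim_extremes(df, 0.0) is df

    def test_constant_b_unchanged(self):
        df = pd.DataFrame({"b": np.ones(20)})
        assert len(trim_extremes(df, 0.025)) == 20
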