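import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from yawnscope import inference as inf
from yawnscope.errors import NonNestedModelsError


def fisher_bruteforce(a, b, c, d):
    """Float enumeration oracle, structured differently from the implementation."""
    r1, r2, n1 = a + b, c + d, a + c
    p_obs = stats.hypergeom.pmf(a, r1 + r2, r1, n1)
    total = 0.0
    for a2 in range(max(0, n1 - r2), min(r1, n1) + 1):
        p = stats.hypergeom.pmf(a2, r1 + r2, r1, n1)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_published_examples(self):
        assert round(inf.fisher_exact_2x2(2, 23, 0, 39), 3) == 0.149
        assert round(inf.fisher_exact_2x2(4, 21, 5, 34), 3) == 0.728
        assert inf.fisher_exact_2x2(2, 23, 35, 4) < 0.001
        assert inf.fisher_exact_2x2(7, 18, 0, 39) < 0.001

    def test_symmetry_under_row_swap(self):
        assert inf.fisher_exact_2x2(3, 7, 5, 2) == pytest.approx(
            inf.fisher_exact_2x2(5, 2, 3, 7), abs=1e-15)

    def test_all_zero_table_warns(self):
        with pytest.warns(UserWarning):
            assert inf.fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            inf.fisher_exact_2x2(-1, 2, 3, 4)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 21, size=4))
        if a + b == 0 or c + d == 0:
            return
        got = inf.fisher_exact_2x2(a, b, c, d)
        assert got == pytest.approx(fisher_bruteforce(a, b, c, d), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, size=4))
            if a + b == 0 or c + d == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert inf.fisher_exact_2x2(a, b, c, d) == pytest.approx(p, abs=1e-9)


def make_gaussian(rng, n_g=11, per=28, beta_sex=-0.3, tau=0.4):
    g = np.repeat(np.arange(n_g), per)
    sex = rng.integers(0, 2, size=n_g)[g]
    u = rng.normal(0, tau, size=n_g)
    y = 1.0 + beta_sex * sex + u[g] + rng.normal(0, 0.5, size=n_g * per)
    return pd.DataFrame({"log_dur": y, "sex": np.where(sex == 1, "male", "female"),
                         "g": g.astype(str)})


class TestFitMixedGaussian:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        hits = 0
        reps = 40
        for _ in range(reps):
            d = make_gaussian(rng)
            fit = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("sex",), "g"), d)
            est, se = fit.params["sex[male]"], fit.bse["sex[male]"]
            if abs(est - (-0.3)) <= 2 * se:
                hits += 1
        # sex varies between groups only; with 11 group levels the +/-2 SE
        # interval has t-like (not normal) coverage, ~92% rather than 95%
        assert hits >= int(0.9 * reps)

    def test_zero_variance_boundary(self):
        rng = np.random.default_rng(3)
        d = make_gaussian(rng, tau=0.0)
        fit = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("sex",), "g"), d)
        # boundary case: tau2 near 0 relative to the ~0.25 residual variance
        assert fit.group_var < 0.02

    def test_vif_reported(self):
        rng = np.random.default_rng(4)
        d = make_gaussian(rng)
        d["x2"] = rng.normal(size=len(d))
        fit = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("sex", "x2"), "g"), d)
        assert all(v >= 1.0 for v in fit.vif.values())

    def test_degenerate_response_rejected(self):
        d = pd.DataFrame({"y": [1.0] * 20, "g": (["a"] * 10) + (["b"] * 10)})
        with pytest.raises(ValueError):
            inf.fit_mixed(inf.ModelSpec("y", "gaussian", (), "g"), d)


class TestFitMixedBinomial:
    def test_null_z_scores_central(self):
        rng = np.random.default_rng(77)
        zs = []
        for _ in range(40):
            n_g, per = 8, 20
            g = np.repeat(np.arange(n_g), per)
            x = rng.normal(size=n_g * per)
            y = (rng.random(n_g * per) < 0.5).astype(float)
            d = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
            fit = inf.fit_mixed(inf.ModelSpec("y", "binomial", ("x",), "g"), d)
            zs.append(fit.params["x"] / fit.bse["x"])
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.5
        assert np.mean(np.abs(zs) > 1.96) < 0.2

    def test_recovers_strong_effect(self):
        rng = np.random.default_rng(10)
        estimates = []
        for _ in range(5):
            n_g, per = 10, 40
            g = np.repeat(np.arange(n_g), per)
            x = rng.normal(size=n_g * per)
            u = rng.normal(0, 0.5, size=n_g)
            eta = 0.2 + 1.5 * x + u[g]
            y = (rng.random(n_g * per) < 1 / (1 + np.exp(-eta))).astype(float)
            d = pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})
            fit = inf.fit_mixed(inf.ModelSpec("y", "binomial", ("x",), "g"), d)
            assert fit.params["x"] > 0
            estimates.append(fit.params["x"])
        assert np.mean(estimates) == pytest.approx(1.5, abs=0.35)


class TestLRT:
    def test_model_vs_itself(self):
        rng = np.random.default_rng(6)
        d = make_gaussian(rng)
        fit = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("sex",), "g"), d)
        test = inf.lrt(fit, fit)
        assert test.chi2 == 0.0 and test.p == 1.0

    def test_matches_closed_form_ols_deviance(self):
        """With tau2 = 0 the mixed LRT reduces to the OLS deviance difference."""
        rng = np.random.default_rng(8)
        n = 200
        g = np.repeat(np.arange(2), n // 2).astype(str)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        d = pd.DataFrame({"y": y, "x": x, "g": g})
        full = inf.fit_mixed(inf.ModelSpec("y", "gaussian", ("x",), "g"), d)
        red = inf.fit_mixed(inf.ModelSpec("y", "gaussian", (), "g"), d)
        test = inf.lrt(full, red)
        # closed-form ML deviance difference between nested OLS models
        X1 = np.column_stack([np.ones(n), x])
        X0 = np.ones((n, 1))
        rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
        rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
        expected = n * math.log(rss0 / rss1)
        assert test.chi2 == pytest.approx(expected, abs=0.05)
        assert test.df == 1

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(9)
        d = make_gaussian(rng)
        d["x2"] = rng.normal(size=len(d))
        f1 = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("sex",), "g"), d)
        f2 = inf.fit_mixed(inf.ModelSpec("log_dur", "gaussian", ("x2",), "g"), d)
        with pytest.raises(NonNestedModelsError):
            inf.lrt(f1, f2)

    def test_p_monotone_in_chi2(self):
        chis = np.linspace(0, 30, 50)
        ps = stats.chi2.sf(chis, 3)
        assert np.all(np.diff(ps) <= 0)


def range_cdf_oracle(r, m):
    """P(range of m iid standard normals <= r) by 1-D quadrature."""
    def integrand(z):
        return m * stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - r)) ** (m - 1)
    val, _ = integrate.quad(integrand, -12, 12, epsabs=1e-12, epsrel=1e-12)
    return val


def balanced_fit(m=4, sigma2_over_n=0.04, t_values=(1.0, 2.0, 2.5)):
    """Synthetic FitResult mimicking a balanced one-way layout."""
    names = [f"cond[L{i}]" for i in range(1, m)]
    V = sigma2_over_n * (np.eye(m - 1) + np.ones((m - 1, m - 1)))
    se = math.sqrt(2 * sigma2_over_n)
    params = pd.Series([t * se for t in t_values], index=names)
    spec = inf.ModelSpec("y", "gaussian", ("cond",), "g")
    return inf.FitResult(
        spec=spec, params=params, bse=pd.Series(np.sqrt(np.diag(V)), index=names),
        cov_params=pd.DataFrame(V, index=names, columns=names),
        loglik=0.0, group_var=0.0, n_obs=m * 10, n_groups=5, converged=True,
    )


class TestTukey:
    def test_identical_groups_all_p_near_one(self):
        fit = balanced_fit(t_values=(0.01, -0.02, 0.015))
        out = inf.tukey_pairwise(fit, "cond", ref_level="L0")
        assert np.all(out["p_adj"] > 0.99)

    def test_six_contrasts_for_four_levels(self):
        fit = balanced_fit()
        out = inf.tukey_pairwise(fit, "cond", ref_level="L0")
        assert len(out) == 6

    def test_matches_independent_range_integration(self):
        """Balanced design: adjusted p must equal 1 - P(range <= |t|*sqrt(2))."""
        fit = balanced_fit(t_values=(1.2, 2.4, 0.7))
        out = inf.tukey_pairwise(fit, "cond", ref_level="L0")
        for _, row in out.iterrows():
            expected = 1.0 - range_cdf_oracle(abs(row["t_ratio"]) * math.sqrt(2), 4)
            assert row["p_adj"] == pytest.approx(expected, abs=1e-6)

    def test_estimates_consistent_with_coefficients(self):
        fit = balanced_fit(t_values=(1.0, 2.0, 3.0))
        out = inf.tukey_pairwise(fit, "cond", ref_level="L0").set_index("contrast")
        est = fit.params
        assert out.loc["L1 - L2", "estimate"] == pytest.approx(
            est["cond[L1]"] - est["cond[L2]"])
        assert out.loc["L0 - L1", "estimate"] == pytest.approx(-est["cond[L1]"])

    def test_two_levels_falls_back_to_z_test(self):
        names = ["cond[B]"]
        V = pd.DataFrame([[0.04]], index=names, columns=names)
        fit = inf.FitResult(
            spec=inf.ModelSpec("y", "gaussian", ("cond",), "g"),
            params=pd.Series([0.4], index=names),
            bse=pd.Series([0.2], index=names), cov_params=V,
            loglik=0.0, group_var=0.0, n_obs=20, n_groups=4, converged=True)
        with pytest.warns(UserWarning):
            out = inf.tukey_pairwise(fit, "cond", ref_level="A")
        assert out["p_adj"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)
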