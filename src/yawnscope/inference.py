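"""Shared statistical machinery: exact tests, mixed models, LRT, Tukey contrasts.

Both model families are fit by maximum likelihood (not REML), so
likelihood-ratio tests on fixed effects are valid.  Gaussian
random-intercept models use the exact one-dimensional profile likelihood;
binomial random-intercept models use Gauss-Hermite marginal maximum
likelihood.  Both have been cross-checked numerically against lme4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, NonNestedModelsError

# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided) by exact integer enumeration


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ``[[a, b], [c, d]]``.

    p is the sum of hypergeometric probabilities of all tables with the same
    margins whose probability is <= that of the observed table.  Comparisons
    use exact integer weights, so there is no floating-point tie ambiguity.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        warnings.warn("all-zero table: p = 1", stacklevel=2)
        return 1.0
    r1, r2, n1 = a + b, c + d, a + c
    observed = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(r1 + r2, n1)
    acc = 0
    for a2 in range(max(0, n1 - r2), min(r1, n1) + 1):
        w = math.comb(r1, a2) * math.comb(r2, n1 - a2)
        if w <= observed:
            acc += w
    return acc / total


# ---------------------------------------------------------------------------
# model specification and fit result containers


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one random-intercept model."""

    response: str
    distribution: str  # "gaussian" | "binomial"
    fixed_effects: tuple[str, ...]
    group: str  # grouping column (may be a combined pair id)

    def __post_init__(self):
        if self.distribution not in ("gaussian", "binomial"):
            raise ValueError(f"unknown distribution: {self.distribution}")


@dataclass
class FitResult:
    """Estimates, likelihood and diagnostics of one mixed-model fit."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    group_var: float
    n_obs: int
    n_groups: int
    converged: bool
    vif: dict[str, float] = field(default_factory=dict)
    r2_marginal: float = float("nan")
    r2_conditional: float = float("nan")

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    def summary_frame(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame({
            "coeff": self.params,
            "se": self.bse,
            "z": z,
            "p_wald": 2 * stats.norm.sf(np.abs(z)),
        })


def build_design(data: pd.DataFrame, fixed_effects: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for categorical columns.

    Categorical levels are sorted; the first is the reference.  Dummy columns
    are named ``col[level]`` so factor levels can be recovered downstream.
    """
    cols = {"Intercept": np.ones(len(data))}
    for col in fixed_effects:
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float).to_numpy()
        else:
            cols[col] = s.astype(float).to_numpy()
    return pd.DataFrame(cols, index=data.index)


def _vif(X: pd.DataFrame) -> dict[str, float]:
    out: dict[str, float] = {}
    cols = [c for c in X.columns if c != "Intercept"]
    for c in cols:
        others = [o for o in cols if o != c] + ["Intercept"]
        y = X[c].to_numpy()
        A = X[others].to_numpy()
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sst = np.sum((y - y.mean()) ** 2)
        if sst <= 0:
            out[c] = float("inf")
            continue
        r2 = 1 - np.sum(resid**2) / sst
        out[c] = float(1.0 / max(1 - r2, 1e-12))
    return out


# ---------------------------------------------------------------------------
# fitting


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fit of a random-intercept model.

    Rows with missing response, fixed-effect or group values are dropped.
    Non-convergence raises :class:`ConvergenceError` rather than returning a
    silently broken fit.
    """
    cols = [spec.response, spec.group, *spec.fixed_effects]
    d = data[cols].dropna().reset_index(drop=True)
    if d[spec.group].nunique() < 2:
        raise ValueError("need >= 2 grouping levels")
    y = d[spec.response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("degenerate response: no variation")
    X = build_design(d, spec.fixed_effects)
    groups, group_idx = np.unique(d[spec.group].astype(str), return_inverse=True)

    if spec.distribution == "gaussian":
        fit = _fit_gaussian(spec, y, X, d[spec.group].astype(str))
    else:
        fit = _fit_binomial(spec, y, X, group_idx, len(groups))
    fit.vif = _vif(X)
    fit.n_obs = len(d)
    fit.n_groups = len(groups)
    return fit


def _gaussian_profile(theta, y, Xn, group_idx, n_groups, group_sizes):
    """Profile out beta and sigma2 at fixed theta = tau2/sigma2.

    With V_j = I + theta * 11', V_j^{-1} = I - c_j 11' where
    c_j = theta / (1 + theta * n_j); everything reduces to group sums.
    """
    n = len(y)
    c = theta / (1.0 + theta * group_sizes)
    SX = np.zeros((n_groups, Xn.shape[1]))
    np.add.at(SX, group_idx, Xn)
    Sy = np.bincount(group_idx, weights=y, minlength=n_groups)
    A = Xn.T @ Xn - (SX * c[:, None]).T @ SX
    b = Xn.T @ y - SX.T @ (c * Sy)
    beta = np.linalg.solve(A, b)
    r = y - Xn @ beta
    Sr = np.bincount(group_idx, weights=r, minlength=n_groups)
    q = float(r @ r - np.sum(c * Sr**2))
    sigma2 = q / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) \
        - 0.5 * float(np.sum(np.log1p(theta * group_sizes)))
    return ll, beta, sigma2, A


def _fit_gaussian(spec, y, X, groups) -> FitResult:
    """ML fit of a Gaussian random-intercept model via the 1-D profile
    likelihood in theta = tau2/sigma2 (beta and sigma2 are closed-form given
    theta), so nested fits always have coherent likelihoods."""
    Xn = X.to_numpy()
    names = list(X.columns)
    codes, group_idx = np.unique(groups.to_numpy(), return_inverse=True)
    n_groups = len(codes)
    group_sizes = np.bincount(group_idx).astype(float)

    def negll(log_theta):
        return -_gaussian_profile(np.exp(log_theta), y, Xn, group_idx,
                                  n_groups, group_sizes)[0]

    best_lt = None
    res = optimize.minimize_scalar(negll, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover - bounded Brent is very robust
        raise ConvergenceError("profile-likelihood optimization failed")
    ll_theta0, *_ = _gaussian_profile(0.0, y, Xn, group_idx, n_groups, group_sizes)
    theta = float(np.exp(res.x))
    if ll_theta0 >= -res.fun:  # boundary: no between-group variance
        theta = 0.0
    ll, beta, sigma2, A = _gaussian_profile(theta, y, Xn, group_idx,
                                            n_groups, group_sizes)
    cov = pd.DataFrame(sigma2 * np.linalg.inv(A), index=names, columns=names)
    tau2 = theta * sigma2
    var_fixed = float(np.var(Xn @ beta))
    denom = var_fixed + tau2 + sigma2
    return FitResult(
        spec=spec, params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=cov, loglik=float(ll), group_var=tau2,
        n_obs=len(y), n_groups=n_groups, converged=True,
        r2_marginal=var_fixed / denom, r2_conditional=(var_fixed + tau2) / denom,
    )


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2 * np.pi)  # weights for N(0,1) expectation


def _binomial_negloglik(theta, y, X, group_idx, n_groups):
    beta, sigma = theta[:-1], abs(theta[-1])
    eta = X @ beta
    # n_groups x n_nodes matrix of group log-likelihood contributions
    u = sigma * _GH_NODES  # random-intercept values at quadrature nodes
    lin = eta[:, None] + u[None, :]
    logp = -np.logaddexp(0.0, -lin)
    log1mp = -np.logaddexp(0.0, lin)
    obs = y[:, None] * logp + (1 - y[:, None]) * log1mp
    per_group = np.zeros((n_groups, len(u)))
    np.add.at(per_group, group_idx, obs)
    m = per_group.max(axis=1, keepdims=True)
    lik = np.log(np.exp(per_group - m) @ _GH_WEIGHTS) + m[:, 0]
    return -float(lik.sum())


def _fit_binomial(spec, y, X, group_idx, n_groups) -> FitResult:
    Xn = X.to_numpy()
    names = list(X.columns)
    k = Xn.shape[1]
    # start from the plain logistic fit
    beta0 = _plain_logistic(y, Xn)
    theta0 = np.concatenate([beta0, [0.5]])
    obj = lambda th: _binomial_negloglik(th, y, Xn, group_idx, n_groups)
    res = optimize.minimize(obj, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    if not (res.success or res.status == 2):  # status 2: precision loss at optimum
        raise ConvergenceError(f"binomial GLMM optimizer failed: {res.message}")
    theta = res.x
    hess = _numerical_hessian(obj, theta)
    cov_full = _safe_inverse(hess)
    cov = pd.DataFrame(cov_full[:k, :k], index=names, columns=names)
    params = pd.Series(theta[:k], index=names)
    sigma2 = float(theta[-1] ** 2)
    var_fixed = float(np.var(Xn @ theta[:k]))
    denom = var_fixed + sigma2 + np.pi**2 / 3  # logit-link residual variance
    return FitResult(
        spec=spec, params=params, bse=pd.Series(np.sqrt(np.abs(np.diag(cov))), index=names),
        cov_params=cov, loglik=-float(res.fun), group_var=sigma2,
        n_obs=len(y), n_groups=n_groups, converged=True,
        r2_marginal=var_fixed / denom, r2_conditional=(var_fixed + sigma2) / denom,
    )


def _plain_logistic(y, X):
    beta = np.zeros(X.shape[1])
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p) + 1e-9
        z = eta + (y - p) / W
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X + 1e-8 * np.eye(X.shape[1]), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            ) / eps**2
    return H


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# likelihood-ratio test


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if not set(reduced.params.index) <= set(full.params.index):
        raise NonNestedModelsError(
            "reduced model's fixed effects are not a subset of the full model's"
        )
    if reduced.n_obs != full.n_obs:
        raise NonNestedModelsError("models were fit on different numbers of rows")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-6:
        raise NonNestedModelsError(f"full model has lower likelihood (chi2={chi2:.3g})")
    chi2 = max(chi2, 0.0)
    df = full.n_fixed - reduced.n_fixed
    if df < 0:
        raise NonNestedModelsError("reduced model has more parameters than full")
    if df == 0:
        # identical specifications: chi2 is 0 and the test is vacuous
        return LRTResult(chi2=chi2, df=0, p=1.0)
    return LRTResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Tukey-style familywise-adjusted pairwise contrasts


def _max_abs_t_cdf(c: float, R: np.ndarray, df: float, seed: int = 0) -> float:
    """P(max_i |T_i| <= c) for contrasts with correlation R.

    Exchangeable pairwise-contrast structure (balanced one-way Tukey family)
    is evaluated exactly through the studentized-range distribution; any
    other structure falls back to quasi-Monte-Carlo multivariate-normal /
    multivariate-t integration (accuracy ~1e-4, seeded).
    """
    K = R.shape[0]
    m = int(round((1 + math.sqrt(1 + 8 * K)) / 2))
    if m * (m - 1) // 2 == K:
        expected = _tukey_correlation(m)
        if np.max(np.abs(np.abs(R) - np.abs(expected))) < 1e-8:
            q = c * math.sqrt(2)
            dof = df if np.isfinite(df) else 1e7
            return float(stats.studentized_range.cdf(q, m, dof))
    rng = np.random.default_rng(seed)
    n_draw = 400_000
    L = np.linalg.cholesky(R + 1e-10 * np.eye(K))
    Z = rng.standard_normal((n_draw, K)) @ L.T
    if np.isfinite(df):
        s = np.sqrt(rng.chisquare(df, size=n_draw) / df)
        Z = Z / s[:, None]
    return float(np.mean(np.all(np.abs(Z) <= c, axis=1)))


def _tukey_correlation(m: int) -> np.ndarray:
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    C = np.zeros((len(pairs), m))
    for k, (i, j) in enumerate(pairs):
        C[k, i], C[k, j] = 1.0, -1.0
    cov = C @ C.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def tukey_pairwise(
    fit: FitResult, factor: str, df: float = np.inf, ref_level: str | None = None
) -> pd.DataFrame:
    """All pairwise contrasts of a categorical fixed effect, familywise-adjusted.

    Levels are recovered from the ``factor[level]`` dummy columns; the
    reference level (name supplied via ``ref_level``) has estimate 0.
    Returns one row per pair with the adjusted p computed from the joint
    max-|T| distribution.  With fewer than 3 levels a plain two-sided z/t-test
    is used (with a warning).
    """
    prefix = f"{factor}["
    dummy_cols = [c for c in fit.params.index if c.startswith(prefix)]
    if not dummy_cols:
        raise ValueError(f"no dummy columns found for factor {factor!r}")
    levels = [c[len(prefix):-1] for c in dummy_cols]
    ref_name = ref_level if ref_level is not None else f"<{factor} ref>"
    m = len(levels) + 1

    est = np.concatenate([[0.0], fit.params[dummy_cols].to_numpy()])
    V = np.zeros((m, m))
    V[1:, 1:] = fit.cov_params.loc[dummy_cols, dummy_cols].to_numpy()

    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    C = np.zeros((len(pairs), m))
    for k, (i, j) in enumerate(pairs):
        C[k, i], C[k, j] = 1.0, -1.0
    diffs = C @ est
    cov_c = C @ V @ C.T
    se = np.sqrt(np.diag(cov_c))
    t_ratio = diffs / se
    names = [
        f"{ref_name if i == 0 else levels[i - 1]} - {ref_name if j == 0 else levels[j - 1]}"
        for i, j in pairs
    ]

    if m < 3:
        warnings.warn("fewer than 3 levels: plain z-test, no familywise adjustment",
                      stacklevel=2)
        if np.isfinite(df):
            p_adj = 2 * stats.t.sf(np.abs(t_ratio), df)
        else:
            p_adj = 2 * stats.norm.sf(np.abs(t_ratio))
    else:
        R = cov_c / np.outer(se, se)
        p_adj = np.array([1.0 - _max_abs_t_cdf(abs(t), R, df) for t in t_ratio])
    return pd.DataFrame({
        "contrast": names, "estimate": diffs, "se": se,
        "t_ratio": t_ratio, "p_adj": np.clip(p_adj, 0.0, 1.0),
    })
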