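"""Inferential layer: summary-statistic t-tests, Yates-corrected G-tests,
random-intercept logistic regression, and AICc model ranking.

The two-sample t-test works directly from printed group summaries
(mean, standard error, n), reconstructing the group standard deviations as
``sd = se * sqrt(n)``.  Pooled variance is the default because equal-variance
degrees of freedom ``n1 + n2 - 2`` match how such comparisons are usually
reported; Welch's unequal-variance form is available.

The random-intercept logistic model

    logit P(y_ij = 1) = x_ij' beta + u_i,   u_i ~ N(0, sigma^2)

is fitted by maximising the marginal likelihood, with the per-group integral
over u_i evaluated by adaptive Gauss-Hermite quadrature (nodes recentred on
each group's posterior mode and rescaled by its curvature).  The variance is
optimised on the sigma >= 0 boundary-respecting scale, and a fit is flagged
singular when the estimated variance collapses to the boundary - the standard
symptom of a random effect with (near-)unique group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

logger = logging.getLogger(__name__)

SINGULAR_VAR_TOL = 1e-6


class SeparationError(RuntimeError):
    """Complete (or quasi-complete) separation: a covariate perfectly
    predicts the outcome and the MLE diverges."""


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.se <= 0:
            raise ValueError("standard error must be positive")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


def t_test_from_summary(g1: GroupSummary, g2: GroupSummary,
                        variant: str = "pooled") -> TestResult:
    """Two-sample two-tailed t-test from (mean, SE, n) group summaries."""
    if variant == "pooled":
        sp2 = (((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2)
               / (g1.n + g2.n - 2))
        se_diff = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        df = g1.n + g2.n - 2
    elif variant == "welch":
        a = g1.se ** 2
        b = g2.se ** 2
        se_diff = np.sqrt(a + b)
        df = (a + b) ** 2 / (a ** 2 / (g1.n - 1) + b ** 2 / (g2.n - 1))
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (g1.mean - g2.mean) / se_diff
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), f"t-test ({variant})")


def g_test_yates(table) -> TestResult:
    """G-test of independence on a 2x2 table with Yates continuity correction.

    Observed counts are moved 0.5 toward their expected values, clamped so
    they never cross them; G = 2 sum O' ln(O'/E) on 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal total")
    exp = row * col / total
    shift = np.clip(exp - obs, -0.5, 0.5)  # 0.5 toward expected, never past it
    adj = obs + shift
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(adj > 0, adj * np.log(adj / exp), 0.0)
    g = 2.0 * float(terms.sum())
    g = max(g, 0.0)
    p = float(sps.chi2.sf(g, 1))
    return TestResult(g, 1.0, p, "G-test (Yates)")


# ---------------------------------------------------------------------------
# random-intercept logistic regression


@dataclass
class MixedLogitFit:
    """Results of a random-intercept logistic fit."""

    params: np.ndarray           # fixed-effect coefficients
    bse: np.ndarray              # standard errors (observed information)
    zvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: float                # random-intercept variance
    loglike: float
    n_obs: int
    k_params: int                # fixed effects + variance component
    aicc: float
    singular: bool
    exog_names: list[str] = field(default_factory=list)
    name: str = "mixed-logit"

    def summary(self) -> str:
        lines = [f"Random-intercept logistic regression ({self.name})",
                 f"  n_obs = {self.n_obs}, logLik = {self.loglike:.3f}, "
                 f"AICc = {self.aicc:.3f}",
                 f"  random-intercept variance = {self.sigma2:.4g}"
                 + ("  [singular fit]" if self.singular else ""),
                 f"  {'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}"]
        for name, b, s, z, p in zip(self.exog_names, self.params, self.bse,
                                    self.zvalues, self.pvalues):
            lines.append(f"  {name:<16}{b:>10.4f}{s:>10.4f}{z:>8.2f}{p:>10.3g}")
        return "\n".join(lines)


def _group_loglik(beta, sigma, y, X, group_idx, n_groups, nodes, weights):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature."""
    eta0 = X @ beta
    if sigma < 1e-8:
        ll = y * eta0 - np.logaddexp(0.0, eta0)
        return float(ll.sum())
    # posterior mode and curvature per group (Newton on u)
    u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta0 + u[group_idx]
        mu = special.expit(eta)
        grad = np.bincount(group_idx, weights=y - mu, minlength=n_groups) \
            - u / sigma ** 2
        hess = -np.bincount(group_idx, weights=mu * (1 - mu),
                            minlength=n_groups) - 1.0 / sigma ** 2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[group_idx]
    mu = special.expit(eta)
    curv = np.bincount(group_idx, weights=mu * (1 - mu), minlength=n_groups) \
        + 1.0 / sigma ** 2
    s = 1.0 / np.sqrt(curv)                      # per-group scale
    # nodes: (n_groups, n_nodes)
    uq = u[:, None] + np.sqrt(2.0) * s[:, None] * nodes[None, :]
    # log integrand at each node
    eta_q = eta0[:, None] + uq[group_idx]
    ll_obs = y[:, None] * eta_q - np.logaddexp(0.0, eta_q)
    ll_grp = np.zeros((n_groups, len(nodes)))
    np.add.at(ll_grp, group_idx, ll_obs)
    ll_grp += (-0.5 * (uq / sigma) ** 2 - 0.5 * np.log(2 * np.pi * sigma ** 2))
    # adaptive GH: integral = sqrt(2) * s * sum_k w_k e^{z_k^2} f(u_k)
    logw = np.log(weights) + nodes ** 2
    log_int = special.logsumexp(ll_grp + logw[None, :], axis=1) \
        + 0.5 * np.log(2.0) + np.log(s)
    return float(log_int.sum())


def fit_logistic_random_intercept(outcomes, exog, groups, quad_points: int = 25,
                                  exog_names: list[str] | None = None,
                                  name: str = "mixed-logit") -> MixedLogitFit:
    """Fit logit P(y=1) = X beta + u_group, u ~ N(0, sigma^2).

    outcomes : binary array (n,)
    exog : design matrix (n, p), including the intercept column
    groups : group labels (n,) for the random intercept
    quad_points : Gauss-Hermite nodes for the marginal integral

    Raises SeparationError on (quasi-)complete separation, RuntimeError on
    non-convergence.
    """
    y = np.asarray(outcomes, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("exog and outcomes length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    nodes, weights = np.polynomial.hermite.hermgauss(quad_points)
    p = X.shape[1]

    def negll(theta):
        beta, sigma = theta[:p], abs(theta[p])
        return -_group_loglik(beta, sigma, y, X, codes, n_groups, nodes, weights)

    theta0 = np.zeros(p + 1)
    theta0[p] = 0.5
    res = optimize.minimize(negll, theta0, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-7})
    if not res.success and res.status != 2:  # 2: precision loss near optimum
        raise RuntimeError(f"mixed-logit optimiser failed: {res.message}\n{res}")
    beta = res.x[:p]
    sigma = abs(res.x[p])
    if np.any(np.abs(beta) > 15.0):
        j = int(np.argmax(np.abs(beta)))
        label = (exog_names[j] if exog_names and j < len(exog_names)
                 else f"column {j}")
        raise SeparationError(
            f"complete separation suspected: coefficient for {label} diverged")

    # observed information for the fixed effects (numerical Hessian)
    def nll_beta(b):
        return -_group_loglik(b, sigma, y, X, codes, n_groups, nodes, weights)

    h = 1e-4 * np.maximum(1.0, np.abs(beta))
    H = np.zeros((p, p))
    f0 = nll_beta(beta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = nll_beta(beta + ei + ej)
            fpm = nll_beta(beta + ei - ej)
            fmp = nll_beta(beta - ei + ej)
            fmm = nll_beta(beta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    z = np.where(bse > 0, beta / bse, np.nan)
    pvals = 2.0 * sps.norm.sf(np.abs(z))

    ll = -res.fun
    k = p + 1  # fixed effects + variance component
    n = y.size
    return MixedLogitFit(
        params=beta, bse=bse, zvalues=z, pvalues=pvals,
        sigma2=float(sigma ** 2), loglike=float(ll), n_obs=n, k_params=k,
        aicc=aicc(float(ll), k, n), singular=bool(sigma ** 2 <= SINGULAR_VAR_TOL),
        exog_names=exog_names or [f"x{i}" for i in range(p)], name=name)


def fit_logistic_random_intercept_lme4(outcomes, exog, groups,
                                       exog_names=None, rscript="Rscript"):
    """Cross-validation adapter: the same model via R's lme4::glmer.

    Returns (params, sigma2).  Requires an R installation with lme4; used in
    tests to corroborate the native quadrature fit, never as the primary
    implementation.
    """
    import subprocess
    import tempfile
    from pathlib import Path

    y = np.asarray(outcomes, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    names = exog_names or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["y"] = y
    df["grp"] = np.asarray(groups)
    rhs = " + ".join(n for n in names if n != "intercept") or "1"
    with tempfile.TemporaryDirectory() as td:
        csv = Path(td) / "d.csv"
        out = Path(td) / "out.txt"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ {rhs} + (1 | grp), data = d, family = binomial,
                   nAGQ = 25)
        co <- fixef(m)
        s2 <- as.numeric(VarCorr(m)$grp[1])
        writeLines(c(paste(co, collapse=","), as.character(s2)), "{out}")
        """
        rfile = Path(td) / "fit.R"
        rfile.write_text(script)
        subprocess.run([rscript, str(rfile)], check=True, capture_output=True)
        lines = out.read_text().splitlines()
    params = np.array([float(v) for v in lines[0].split(",")])
    return params, float(lines[1])


# ---------------------------------------------------------------------------
# model selection


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def rank_models(fits: list[MixedLogitFit]) -> pd.DataFrame:
    """AICc ranking table with ΔAICc and a within-2 tie flag.

    A parameter in a larger model is reported 'uninformative' (flagged, not
    removed) when the model sits within 2 ΔAICc of a smaller one and the
    added coefficients all have |z| < 2.
    """
    rows = []
    for f in fits:
        rows.append({"model": f.name, "k": f.k_params, "loglik": f.loglike,
                     "aicc": f.aicc, "singular": f.singular})
    tab = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].iloc[0]
    tab["within_2"] = tab["delta_aicc"] < 2.0
    by_name = {f.name: f for f in fits}
    flags = []
    for _, row in tab.iterrows():
        f = by_name[row["model"]]
        smaller = [g for g in fits if g.k_params < f.k_params]
        uninformative = False
        if smaller and row["delta_aicc"] < 2.0:
            best_small = min(g.aicc for g in smaller)
            if f.aicc - best_small > -2.0:
                extra_z = np.abs(f.zvalues[1:])  # beyond the intercept
                uninformative = bool(len(extra_z) and np.all(extra_z < 2.0))
        flags.append(uninformative)
    tab["uninformative_flag"] = flags
    return tab
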