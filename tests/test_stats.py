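"""Summary t-tests, Yates G-test, mixed logit and AICc ranking."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit

from stormcross.stats import (GroupSummary, MixedLogitFit, SeparationError,
                              aicc, fit_logistic_random_intercept,
                              fit_logistic_random_intercept_lme4, g_test_yates,
                              rank_models, t_test_from_summary)


# ---------------------------------------------------------------------------
# t-test from summaries


def test_pooled_t_reproduces_field_comparison():
    # total migration distance: 11,012 +/- 72.4 (n=14) vs 8,404 +/- 76.0 (n=13)
    r = t_test_from_summary(GroupSummary(11012.0, 72.4, 14),
                            GroupSummary(8404.0, 76.0, 13))
    assert r.statistic == pytest.approx(24.9, abs=0.1)
    assert r.df == 25
    assert r.p_value < 0.001


def test_equal_means_give_zero_statistic():
    g = GroupSummary(10.0, 1.0, 12)
    r = t_test_from_summary(g, GroupSummary(10.0, 2.0, 8))
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(1.0)


def _raw_with_moments(mean, sd, n, rng):
    """Raw sample with exactly the requested mean and sd."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


@pytest.mark.parametrize("variant", ["pooled", "welch"])
def test_summary_t_matches_raw_data_oracle(variant, rng):
    for _ in range(20):
        n1, n2 = int(rng.integers(3, 40)), int(rng.integers(3, 40))
        m1, m2 = rng.normal(0, 10, 2)
        s1, s2 = rng.uniform(0.5, 5.0, 2)
        x1 = _raw_with_moments(m1, s1, n1, rng)
        x2 = _raw_with_moments(m2, s2, n2, rng)
        g1 = GroupSummary(m1, s1 / np.sqrt(n1), n1)
        g2 = GroupSummary(m2, s2 / np.sqrt(n2), n2)
        r = t_test_from_summary(g1, g2, variant)
        o = sps.ttest_ind(x1, x2, equal_var=(variant == "pooled"))
        assert r.statistic == pytest.approx(o.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(o.pvalue, abs=1e-10)


def test_group_summary_validation():
    with pytest.raises(ValueError):
        GroupSummary(1.0, 0.5, 1)
    with pytest.raises(ValueError):
        GroupSummary(1.0, 0.0, 5)


# ---------------------------------------------------------------------------
# G-test with Yates correction


def _g_oracle(table):
    """Independently coded brute-force G with continuity correction."""
    o = [[float(v) for v in row] for row in table]
    r = [sum(row) for row in o]
    c = [o[0][j] + o[1][j] for j in range(2)]
    n = sum(r)
    g = 0.0
    for i in range(2):
        for j in range(2):
            e = r[i] * c[j] / n
            adj = o[i][j]
            if adj > e:
                adj = max(adj - 0.5, e)
            elif adj < e:
                adj = min(adj + 0.5, e)
            if adj > 0:
                g += adj * np.log(adj / e)
    return 2.0 * g


def test_g_perfect_independence():
    r = g_test_yates([[10, 10], [10, 10]])
    assert r.statistic == 0.0
    assert r.p_value == pytest.approx(1.0)
    assert r.df == 1


def test_g_matches_oracle_on_field_table():
    r = g_test_yates([[3, 23], [13, 8]])
    assert r.df == 1
    assert r.statistic == pytest.approx(_g_oracle([[3, 23], [13, 8]]), abs=1e-12)


def test_g_degenerate_diagonal_is_finite():
    r = g_test_yates([[0, 10], [10, 0]])
    assert np.isfinite(r.statistic)
    assert r.statistic > 0


def test_g_matches_oracle_on_random_tables(rng):
    for _ in range(1000):
        t = rng.integers(0, 40, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        assert g_test_yates(t).statistic == pytest.approx(
            _g_oracle(t), abs=1e-10)


def test_g_rejects_bad_tables():
    with pytest.raises(ValueError):
        g_test_yates([[0, 0], [5, 5]])
    with pytest.raises(ValueError):
        g_test_yates([[-1, 2], [3, 4]])


# ---------------------------------------------------------------------------
# mixed logit


def _simulate(rng, G=40, m=25, beta=(-0.3, -1.5), sigma2=0.5):
    u = rng.normal(0.0, np.sqrt(sigma2), G) if sigma2 > 0 else np.zeros(G)
    grp = np.repeat(np.arange(G), m)
    x = rng.binomial(1, 0.5, G * m).astype(float)
    eta = beta[0] + beta[1] * x + u[grp]
    y = rng.binomial(1, expit(eta))
    X = np.column_stack([np.ones(G * m), x])
    return y, X, grp


def test_zero_variance_reduces_to_plain_logistic(rng):
    import statsmodels.api as sm
    y, X, grp = _simulate(rng, sigma2=0.0)
    fit = fit_logistic_random_intercept(y, X, grp)
    oracle = sm.Logit(y, X).fit(disp=0)
    assert fit.singular
    assert np.max(np.abs(fit.params - oracle.params)) < 1e-4
    assert fit.loglike == pytest.approx(oracle.llf, abs=1e-4)


def test_near_unique_groups_give_singular_fit():
    # an identity-like random intercept (two observations per level, no true
    # between-level variance) collapses to the boundary
    local = np.random.default_rng(0)
    y, X, _ = _simulate(local, G=30, m=2, sigma2=0.0)
    ids = np.arange(len(y)) // 2
    fit = fit_logistic_random_intercept(y, X, ids)
    assert fit.singular
    assert fit.sigma2 <= 1e-6


def test_quadrature_converged(rng):
    y, X, grp = _simulate(rng)
    f20 = fit_logistic_random_intercept(y, X, grp, quad_points=20)
    f50 = fit_logistic_random_intercept(y, X, grp, quad_points=50)
    assert abs(f20.loglike - f50.loglike) < 1e-6


def test_complete_separation_raises():
    rng = np.random.default_rng(5)
    grp = np.repeat(np.arange(10), 10)
    x = rng.binomial(1, 0.5, 100).astype(float)
    y = x.copy()  # x separates y perfectly
    X = np.column_stack([np.ones(100), x])
    with pytest.raises((SeparationError, RuntimeError)):
        fit_logistic_random_intercept(y, X, grp, exog_names=["intercept", "x"])


def test_parameter_recovery_short(rng):
    """Small replicate suite; the full 200-replicate run lives in acceptance."""
    est = []
    for _ in range(25):
        y, X, grp = _simulate(rng)
        est.append(fit_logistic_random_intercept(y, X, grp,
                                                 quad_points=15).params[1])
    assert abs(np.mean(est) + 1.5) < 0.15


def test_lme4_adapter_agrees_on_fixture():
    rng = np.random.default_rng(99)
    y, X, grp = _simulate(rng, G=30, m=20)
    fit = fit_logistic_random_intercept(y, X, grp,
                                        exog_names=["intercept", "x"])
    params, sigma2 = fit_logistic_random_intercept_lme4(
        y, X, grp, exog_names=["intercept", "x"])
    assert np.max(np.abs(fit.params - params)) < 0.02
    assert fit.sigma2 == pytest.approx(sigma2, abs=0.1)


def test_summary_renders():
    rng = np.random.default_rng(11)
    y, X, grp = _simulate(rng, G=20, m=10)
    fit = fit_logistic_random_intercept(y, X, grp,
                                        exog_names=["intercept", "population"])
    text = fit.summary()
    assert "population" in text and "AICc" in text


# ---------------------------------------------------------------------------
# AICc and ranking


def test_aicc_closed_form():
    assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12.0 / 7.0)
    assert aicc(-10.0, 0, 10) == pytest.approx(20.0)  # k = 0: no correction
    assert aicc(-10.0, 2, 10**9) == pytest.approx(24.0, abs=1e-6)  # n -> inf
    with pytest.raises(ValueError):
        aicc(-10.0, 5, 6)


def _fake_fit(name, loglik, k, n=100, z=(0.5,)):
    zarr = np.array((3.0,) + tuple(z))
    return MixedLogitFit(
        params=zarr, bse=np.ones_like(zarr), zvalues=zarr,
        pvalues=np.full_like(zarr, 0.5), sigma2=0.1, loglike=loglik,
        n_obs=n, k_params=k, aicc=aicc(loglik, k, n), singular=False,
        exog_names=["intercept"] + [f"x{i}" for i in range(len(z))], name=name)


def test_rank_models_orders_and_flags():
    null = _fake_fit("null", -60.0, 2)
    weak = _fake_fit("null+x", -59.8, 3, z=(0.4,))   # uninformative extra param
    strong = _fake_fit("null+y", -50.0, 3, z=(4.0,))
    tab = rank_models([null, weak, strong])
    assert list(tab["model"])[0] == "null+y"
    assert tab["delta_aicc"].iloc[0] == 0.0
    weak_row = tab[tab.model == "null+x"].iloc[0]
    assert not weak_row["within_2"]
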