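"""Core numerics: links, moments, likelihood, information."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from evrtest import (
    BivariateSample,
    DegenerateDataError,
    ModelSpec,
    ParamVector,
    TestConfig,
    all_group_moments,
    bivariate_normal_loglik,
    coefficient_covariance,
    fisher_inverse,
    fisher_link,
    fit_saturated,
    group_moments,
    heev_ratio,
    sample_bivariate_normal,
    saturated_loglik,
    slope_from_correlation,
)
from evrtest.model_core import loglik_and_score


# ---------------------------------------------------------------------------
# links
# ---------------------------------------------------------------------------


@settings(derandomize=True, max_examples=200)
@given(st.floats(-0.999, 0.999))
def test_fisher_link_roundtrip(rho):
    assert fisher_inverse(fisher_link(rho)) == pytest.approx(rho, abs=1e-12)


@pytest.mark.parametrize(
    "eta, rho",
    [(0.0, 0.0), (1.0986, 0.5), (1.7346, 0.7), (0.2007, 0.1)],
)
def test_fisher_inverse_correlation_mapping(eta, rho):
    # the link values used throughout the simulation designs map onto the
    # stated correlations at z = 1
    assert fisher_inverse(eta) == pytest.approx(rho, abs=1e-4)


def test_fisher_link_domain():
    with pytest.raises(ValueError):
        fisher_link(1.0)
    with pytest.raises(ValueError):
        fisher_link(-1.2)


# ---------------------------------------------------------------------------
# group moments
# ---------------------------------------------------------------------------


def _cat_sample(x, y, labels=None):
    n = len(x)
    labels = labels if labels is not None else ["a"] * n
    return BivariateSample(np.asarray(x, float), np.asarray(y, float),
                           np.array(labels, dtype=object), kind="categorical")


def test_group_moments_orthogonal_balanced():
    s = _cat_sample([0, 0, 1, 1], [0, 1, 0, 1])
    g = group_moments(s, "a")
    assert g.r == pytest.approx(0.0, abs=1e-15)
    assert g.sd_x == pytest.approx(0.5)   # ML (divisor n) convention
    assert g.sd_y == pytest.approx(0.5)


def test_group_moments_collinear_is_degenerate():
    s = _cat_sample([1, 2, 3, 4], [1, 2, 3, 4])
    with pytest.raises(DegenerateDataError):
        group_moments(s, "a")


def test_group_moments_small_group_and_zero_variance():
    with pytest.raises(DegenerateDataError):
        group_moments(_cat_sample([1, 2, 3], [0, 1, 0]), "a")
    with pytest.raises(DegenerateDataError, match="zero variance in x"):
        group_moments(_cat_sample([2, 2, 2, 2], [0, 1, 0, 2]), "a")


def test_group_moments_duplication_invariance():
    x = [0.3, -1.2, 0.8, 2.0, -0.4]
    y = [1.0, 0.2, -0.6, 1.4, 0.0]
    g1 = group_moments(_cat_sample(x, y), "a")
    g3 = group_moments(_cat_sample(x * 3, y * 3), "a")
    assert g3.sd_x == pytest.approx(g1.sd_x, rel=1e-12)
    assert g3.sd_y == pytest.approx(g1.sd_y, rel=1e-12)
    assert g3.r == pytest.approx(g1.r, rel=1e-12)


def test_group_moments_recover_population():
    # sigma_x^2 = 2, sigma_y^2 = 8, sigma_xy = 2 => rho = 0.5
    n = 10_000
    xy = sample_bivariate_normal(n, (0, 0, 2.0, 8.0, 2.0), seed=4)
    g = group_moments(_cat_sample(xy[:, 0], xy[:, 1]), "a")
    assert g.r == pytest.approx(0.5, abs=3 * 0.75 / np.sqrt(n))
    assert g.sd_x == pytest.approx(np.sqrt(2), rel=0.05)


# ---------------------------------------------------------------------------
# elementary identities
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "rho, sy, sx, expected",
    [
        (0.5, np.sqrt(8), np.sqrt(2), 1.0),
        (0.0, 3.1, 0.2, 0.0),
        (0.45, 2.0, 1.0, 0.9),
    ],
)
def test_slope_from_correlation(rho, sy, sx, expected):
    assert slope_from_correlation(rho, sy, sx) == pytest.approx(expected)


def test_slope_from_correlation_rejects_nonpositive_sd():
    with pytest.raises(ValueError):
        slope_from_correlation(0.5, -1.0, 1.0)


def test_heev_ratio_cases():
    assert heev_ratio(0.3, 0.3, 2.0, 2.0).satisfied
    chk = heev_ratio(0.45, 0.45, 4.0, 1.0)
    assert chk.lhs == pytest.approx(4.0) and chk.rhs == pytest.approx(1.0)
    assert not chk.satisfied
    chk = heev_ratio(0.8, 0.0, 1.0, 0.36)
    assert chk.lhs == pytest.approx(chk.rhs, rel=1e-12) and chk.satisfied


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_loglik_single_observation_closed_form():
    s = BivariateSample([0.0], [0.0], [0.0], kind="continuous")
    spec = ModelSpec.continuous(np.array([0.0]))
    params = ParamVector(np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2))
    assert bivariate_normal_loglik(params, spec, s) == pytest.approx(-np.log(2 * np.pi))


def test_loglik_independence_factorization():
    rng = np.random.default_rng(0)
    n = 50
    z = rng.standard_normal(n)
    x = rng.standard_normal(n) * 1.7 + 0.3
    y = rng.standard_normal(n) * 0.6 - 1.0
    s = BivariateSample(x, y, z, kind="continuous")
    spec = ModelSpec.continuous(z)
    params = ParamVector(
        delta_x=np.array([np.log(1.5), 0.1]),
        delta_y=np.array([np.log(0.5), -0.2]),
        delta_r=np.zeros(2),
        gamma_x=np.array([0.3, 0.0]),
        gamma_y=np.array([-1.0, 0.1]),
    )
    sx = np.exp(params.delta_x[0] + params.delta_x[1] * z)
    sy = np.exp(params.delta_y[0] + params.delta_y[1] * z)
    expect = np.sum(stats.norm.logpdf(x, 0.3, sx)) + np.sum(
        stats.norm.logpdf(y, -1.0 + 0.1 * z, sy)
    )
    assert bivariate_normal_loglik(params, spec, s) == pytest.approx(expect, rel=1e-12)


def test_loglik_saturated_equals_moment_profile(two_group_sample):
    groups = all_group_moments(two_group_sample)
    fit = fit_saturated(groups)
    spec = ModelSpec.categorical(list(two_group_sample.moderator), groups[0].label)
    ll = bivariate_normal_loglik(fit.params, spec, two_group_sample)
    assert ll == pytest.approx(saturated_loglik(groups), abs=1e-8)


def test_loglik_numerical_optimum_matches_closed_form(two_group_sample):
    groups = all_group_moments(two_group_sample)
    fit = fit_saturated(groups)
    spec = ModelSpec.categorical(list(two_group_sample.moderator), groups[0].label)
    p0 = fit.params.pack()

    def neg(p):
        ll, g = loglik_and_score(ParamVector.unpack(p, spec), spec, two_group_sample)
        return -ll, -g

    res = optimize.minimize(neg, p0 + 0.1, jac=True, method="L-BFGS-B",
                            options={"ftol": 1e-15, "gtol": 1e-10, "maxiter": 2000})
    assert -res.fun == pytest.approx(fit.loglik, abs=1e-6)


# ---------------------------------------------------------------------------
# observed information
# ---------------------------------------------------------------------------


def _saturated_fd_cov(seed, rho, n=10_000):
    cov = rho * 1.0
    xy1 = sample_bivariate_normal(n, (0, 0, 1, 1, cov), seed=seed)
    xy2 = sample_bivariate_normal(n, (0, 0, 1, 1, cov), seed=seed + 1)
    x = np.concatenate([xy1[:, 0], xy2[:, 0]])
    y = np.concatenate([xy1[:, 1], xy2[:, 1]])
    labs = np.array(["a"] * n + ["b"] * n, dtype=object)
    s = BivariateSample(x, y, labs, kind="categorical")
    groups = all_group_moments(s)
    fit = fit_saturated(groups)
    spec = ModelSpec.categorical(list(labs), "a")
    cov_fd = coefficient_covariance(fit.params, spec, s)
    return groups, fit, cov_fd


def test_covariance_log_sd_oracle_independent_case():
    n = 10_000
    groups, fit, cov = _saturated_fd_cov(seed=10, rho=0.0, n=n)
    names = list(fit.names)
    i = names.index("dx:(intercept)")
    # classical asymptotic variance of a log-SD is 1/(2n)
    assert cov[i, i] == pytest.approx(1.0 / (2 * n), rel=0.10)


def test_covariance_log_sd_cross_oracle_correlated_case():
    n = 10_000
    groups, fit, cov = _saturated_fd_cov(seed=20, rho=0.6, n=n)
    names = list(fit.names)
    i, j = names.index("dx:(intercept)"), names.index("dy:(intercept)")
    r = groups[0].r
    # asymptotic covariance of the two log-SDs of a bivariate normal
    assert cov[i, j] == pytest.approx(r**2 / (2 * n), rel=0.10)
    # delta-method variance of theta_hat
    var_theta = (
        cov[names.index("dy:[b]"), names.index("dy:[b]")]
        + cov[names.index("dx:[b]"), names.index("dx:[b]")]
        - 2 * cov[names.index("dy:[b]"), names.index("dx:[b]")]
    )
    expect = (1 - groups[0].r**2) / n + (1 - groups[1].r**2) / n
    assert var_theta == pytest.approx(expect, rel=0.10)


def test_analytic_information_matches_finite_differences(two_group_sample):
    # the closed-form saturated covariance used by the fast paths agrees
    # with the finite-difference observed information on real data
    groups = all_group_moments(two_group_sample)
    fit = fit_saturated(groups)
    spec = ModelSpec.categorical(list(two_group_sample.moderator), groups[0].label)
    cov_fd = coefficient_covariance(fit.params, spec, two_group_sample)
    scale = np.abs(fit.vcov) + 1e-10
    assert np.max(np.abs(cov_fd - fit.vcov) / scale) < 1e-3


def test_testconfig_validation_and_df():
    with pytest.raises(ValueError):
        TestConfig(alpha=0.0)
    with pytest.raises(ValueError):
        TestConfig(critical_value_family="cauchy")
    cfg = TestConfig(critical_value_family="t")
    assert cfg.dof((70, 70)) == 136
    assert cfg.critical_value((70, 70)) == pytest.approx(
        stats.t.ppf(0.975, 136)
    )
    assert TestConfig().dof((70, 70)) is None
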