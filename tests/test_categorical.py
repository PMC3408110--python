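"""Categorical EVR testing and the constrained model-comparison engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from evrtest import (
    TestConfig,
    all_group_moments,
    build_scenario,
    evr_joint_test,
    evr_test,
    fit_constrained,
    fit_saturated,
    lr_compare,
    moderation_report,
    sample_scenario,
    theta_variance,
)

from conftest import gm


# ---------------------------------------------------------------------------
# saturated fit
# ---------------------------------------------------------------------------


def test_saturated_identical_groups_zero_indicators():
    g = gm("a", 50, 1.3, 0.8, 0.4)
    h = gm("b", 50, 1.3, 0.8, 0.4)
    fit = fit_saturated([g, h])
    assert fit.params.delta_x[1] == pytest.approx(0.0, abs=1e-14)
    assert fit.params.delta_y[1] == pytest.approx(0.0, abs=1e-14)
    assert fit.params.delta_r[1] == pytest.approx(0.0, abs=1e-14)


def test_saturated_indicator_is_log_sd_ratio():
    fit = fit_saturated([gm("a", 40, 1.0, 1.0, 0.2), gm("b", 40, 1.0, 2.0, 0.2)])
    assert fit.params.delta_y[1] == pytest.approx(np.log(2.0), rel=1e-12)
    assert fit.params.delta_x[1] == pytest.approx(0.0, abs=1e-14)


def test_saturated_requires_two_groups():
    with pytest.raises(ValueError):
        fit_saturated([gm("a", 40, 1.0, 1.0, 0.2)])


# ---------------------------------------------------------------------------
# the EVR Wald test
# ---------------------------------------------------------------------------


def test_evr_identity_case():
    g = gm("a", 80, 1.1, 2.3, 0.35)
    h = gm("b", 80, 1.1, 2.3, 0.35)
    res = evr_test([g, h], "a", "b")
    assert res.theta_hat == 0.0
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_evr_variance_ratio_four_gives_log_two():
    # doubling sd_y doubles the SD ratio: theta = log 2 = 0.6931, the same
    # value the continuous designs attach to a variance-ratio ratio of 4
    res = evr_test([gm("a", 100, 1.0, 1.0, 0.3), gm("b", 100, 1.0, 2.0, 0.3)], "a", "b")
    assert res.theta_hat == pytest.approx(0.6931, abs=1e-4)
    assert res.ci_exp_theta[0] == pytest.approx(np.exp(res.ci_theta[0]), rel=1e-12)
    assert res.ci_exp_theta[1] == pytest.approx(np.exp(res.ci_theta[1]), rel=1e-12)


def test_evr_se_equals_delta_method(two_group_sample):
    groups = all_group_moments(two_group_sample)
    res = evr_test(groups, groups[0].label, groups[1].label)
    assert res.se == pytest.approx(
        np.sqrt(theta_variance(groups[0], groups[1])), rel=1e-8
    )


def test_evr_errors():
    g = gm("a", 50, 1, 1, 0.1)
    h = gm("b", 50, 1, 1, 0.1)
    with pytest.raises(ValueError):
        evr_test([g, h], "a", "a")
    with pytest.raises(KeyError):
        evr_test([g, h], "a", "zzz")


@settings(derandomize=True, max_examples=60)
@given(
    sdx1=st.floats(0.2, 5.0), sdy1=st.floats(0.2, 5.0), r1=st.floats(-0.9, 0.9),
    sdx2=st.floats(0.2, 5.0), sdy2=st.floats(0.2, 5.0), r2=st.floats(-0.9, 0.9),
)
def test_exp_theta_equals_slope_ratio_over_corr_ratio(sdx1, sdy1, r1, sdx2, sdy2, r2):
    # exp(theta) = (beta_2 / beta_1) / (r_2 / r_1) exactly, on any data
    if abs(r1) < 1e-3 or abs(r2) < 1e-3:
        return
    g = gm("a", 50, sdx1, sdy1, r1)
    h = gm("b", 50, sdx2, sdy2, r2)
    res = evr_test([g, h], "a", "b")
    rhs = (h.slope_y_on_x / g.slope_y_on_x) / (h.r / g.r)
    assert res.exp_theta == pytest.approx(rhs, rel=1e-10)


def test_evr_antisymmetry():
    g = gm("a", 60, 1.2, 0.7, 0.5)
    h = gm("b", 90, 0.9, 1.8, 0.2)
    ab = evr_test([g, h], "a", "b")
    ba = evr_test([g, h], "b", "a")
    assert ba.theta_hat == pytest.approx(-ab.theta_hat, rel=1e-12)
    assert ba.ci_exp_theta[0] == pytest.approx(1.0 / ab.ci_exp_theta[1], rel=1e-10)
    assert ba.ci_exp_theta[1] == pytest.approx(1.0 / ab.ci_exp_theta[0], rel=1e-10)


def test_evr_scale_equivariance():
    g = gm("a", 60, 1.2, 0.7, 0.5)
    h = gm("b", 90, 0.9, 1.8, 0.2)
    base = evr_test([g, h], "a", "b")
    # scaling y in the target group by c shifts theta by exactly log c
    c = 3.7
    h_scaled = gm("b", 90, 0.9, 1.8 * c, 0.2)
    res = evr_test([g, h_scaled], "a", "b")
    assert res.theta_hat == pytest.approx(base.theta_hat + np.log(c), rel=1e-12)
    # shared rescaling of every group's x and y leaves theta unchanged
    g2 = gm("a", 60, 1.2 * 2.5, 0.7 * 0.4, 0.5)
    h2 = gm("b", 90, 0.9 * 2.5, 1.8 * 0.4, 0.2)
    res2 = evr_test([g2, h2], "a", "b")
    assert res2.theta_hat == pytest.approx(base.theta_hat, abs=1e-12)
    assert res2.se == pytest.approx(base.se, rel=1e-12)


def test_joint_theta_test_reduces_to_pairwise():
    g = gm("a", 60, 1.2, 0.7, 0.5)
    h = gm("b", 90, 0.9, 1.8, 0.2)
    pair = evr_test([g, h], "a", "b")
    joint = evr_joint_test([g, h], "a")
    assert joint["df"] == 1
    assert joint["chi2"] == pytest.approx(pair.statistic**2, rel=1e-10)
    j3 = evr_joint_test([g, h, gm("c", 70, 1.0, 1.0, 0.0)], "a")
    assert j3["df"] == 2


# ---------------------------------------------------------------------------
# constrained fits
# ---------------------------------------------------------------------------


def test_hov_x_inactive_when_x_moments_equal():
    g = gm("a", 80, 1.4, 1.0, 0.3)
    h = gm("b", 80, 1.4, 2.0, 0.5)
    sat = fit_saturated([g, h])
    hov = fit_constrained([g, h], {"HOV_X"})
    assert hov.loglik == pytest.approx(sat.loglik, abs=1e-7)


def test_evr_constraint_recovers_common_ratio():
    # both groups share variance ratio 2; the group SDs themselves differ
    spec = build_scenario("1", 2, sizes=(5000, 5000))
    s = sample_scenario(spec, seed=21)
    groups = all_group_moments(s)
    fit = fit_constrained(groups, {"EVR"})
    # the shared indicator offset equals the common log sd_x ratio
    truth = 0.5 * np.log(2.0 / 1.0)
    assert fit.params.delta_x[1] == pytest.approx(truth, abs=0.05)
    assert fit.params.delta_x[1] == pytest.approx(fit.params.delta_y[1], rel=1e-8)
    assert fit.loglik <= fit_saturated(groups).loglik + 1e-8


def test_equal_rho_recovers_common_correlation(sem_groups):
    fit = fit_constrained(sem_groups, {"EQUAL_RHO"})
    rho = np.tanh(fit.params.delta_r[0] / 2.0)
    assert rho == pytest.approx(0.45, abs=0.06)
    assert fit.params.delta_r[1] == pytest.approx(0.0, abs=1e-10)


def test_constraint_validation():
    g = gm("a", 50, 1, 1, 0.1)
    h = gm("b", 50, 1, 1, 0.1)
    with pytest.raises(ValueError):
        fit_constrained([g, h], {"NOPE"})
    with pytest.raises(ValueError):
        fit_constrained([g, h], {"EQUAL_SLOPE", "EQUAL_RHO"})


def test_equal_slope_and_equal_rho_match_profile_oracles(two_group_sample):
    # the general engine agrees with the independent profile-likelihood
    # closed forms used by the Monte-Carlo fast path
    from evrtest.simulation import _profile_equal_rho, _profile_equal_slope

    groups = all_group_moments(two_group_sample)
    st_ = {
        "n": np.array([float(g.n) for g in groups]),
        "Sxx": np.array([[g.sd_x**2] for g in groups]),
        "Syy": np.array([[g.sd_y**2] for g in groups]),
        "Sxy": np.array([[g.r * g.sd_x * g.sd_y] for g in groups]),
    }
    sat = fit_saturated(groups)
    chi_r, rho, _ = _profile_equal_rho(st_)
    chi_s, beta, _ = _profile_equal_slope(st_)
    fr = fit_constrained(groups, {"EQUAL_RHO"})
    fs = fit_constrained(groups, {"EQUAL_SLOPE"})
    assert 2 * (sat.loglik - fr.loglik) == pytest.approx(chi_r[0], abs=1e-6)
    assert 2 * (sat.loglik - fs.loglik) == pytest.approx(chi_s[0], abs=1e-6)
    assert fs.meta["beta"] == pytest.approx(beta[0], abs=1e-6)


# ---------------------------------------------------------------------------
# likelihood-ratio comparisons
# ---------------------------------------------------------------------------


def test_lr_identical_fits(sem_groups):
    sat = fit_saturated(sem_groups)
    cmp = lr_compare(sat, sat)
    assert cmp.chi2 == 0.0 and cmp.df == 0 and cmp.p_value == 1.0


def test_lr_df_counts_constraints(sem_groups):
    sat = fit_saturated(sem_groups)
    assert lr_compare(fit_constrained(sem_groups, {"EVR"}), sat).df == 1
    assert lr_compare(fit_constrained(sem_groups, {"EQUAL_RHO"}), sat).df == 1
    assert lr_compare(fit_constrained(sem_groups, {"HOV_X", "EVR"}), sat).df == 2


def test_lr_wald_asymptotic_agreement():
    spec = build_scenario("2", 1, sizes=(10_000, 10_000))
    s = sample_scenario(spec, seed=33)
    groups = all_group_moments(s)
    sat = fit_saturated(groups)
    evr = fit_constrained(groups, {"EVR"})
    cmp = lr_compare(evr, sat)
    wald = evr_test(groups, groups[0].label, groups[1].label)
    assert abs(cmp.chi2 - wald.statistic**2) / max(cmp.chi2, 1e-12) < 0.05


def test_lr_rejects_non_nested_and_foreign_data(sem_groups):
    hov = fit_constrained(sem_groups, {"HOV_X"})
    eqr = fit_constrained(sem_groups, {"EQUAL_RHO"})
    with pytest.raises(ValueError):
        lr_compare(hov, eqr)  # neither constraint set contains the other
    other = [gm("control", 300, 1, 1, 0.2), gm("video", 300, 1, 2, 0.2)]
    with pytest.raises(ValueError):
        lr_compare(fit_constrained(other, {"EVR"}), fit_saturated(sem_groups))


# ---------------------------------------------------------------------------
# the moderation report and the two-condition example pattern
# ---------------------------------------------------------------------------


def test_moderation_report_structure(sem_groups):
    rep = moderation_report(sem_groups, base="control")
    assert {"groups", "theta_tests", "correlation_tests", "lr_ladder"} <= set(rep)
    assert rep["lr_ladder"]["baseline"] in ("HOV_X", "saturated")
    assert len(rep["lr_ladder"]["steps"]) == 3
    assert rep["theta_tests"][0]["test_category"] == "video"


def test_identical_population_report_is_quiet():
    spec = build_scenario("1", 1, sizes=(400, 400))
    s = sample_scenario(spec, seed=8)
    rep = moderation_report(all_group_moments(s))
    for t in rep["theta_tests"] + rep["correlation_tests"]:
        assert t["p_value"] > 1e-4
    for step in rep["lr_ladder"]["steps"]:
        assert step["p_value"] > 1e-4


def test_two_condition_example_pattern():
    """Polarization example: doubling sd_y with unchanged correlation must
    show slope moderation (in opposite directions for y-on-x vs x-on-y),
    a decisively rejected EVR hypothesis, and retained equal correlations."""
    reps = 60
    evr_reject = eqrho_retain = signflip = 0
    for i in range(reps):
        s = sample_scenario(build_scenario("sem_example"), seed=1000 + i)
        groups = all_group_moments(s)
        by = {g.label: g for g in groups}
        ordered = [by["control"], by["video"]]
        sat = fit_saturated(ordered)
        evr = lr_compare(fit_constrained(ordered, {"EVR"}), sat)
        eqr = lr_compare(fit_constrained(ordered, {"EQUAL_RHO"}), sat)
        evr_reject += evr.p_value < 0.001
        eqrho_retain += eqr.p_value > 0.05
        signflip += (
            by["video"].slope_y_on_x > by["control"].slope_y_on_x
            and by["video"].slope_x_on_y < by["control"].slope_x_on_y
        )
    assert evr_reject == reps
    assert signflip == reps
    assert eqrho_retain >= int(0.9 * reps)
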