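"""EVR testing and constrained model comparison for categorical moderators.

The saturated multi-group bivariate-normal model has a closed-form ML
solution (the per-group sample moments), so the Wald test of equal
variance ratios needs no iteration: with the log-link SD submodels the
contrast for category i against the base category is

    theta_i = (log sd_y,i - log sd_x,i) - (log sd_y,base - log sd_x,base)

with var(theta_i) read off the saturated coefficient covariance, which is
exactly (1 - r_base^2)/n_base + (1 - r_i^2)/n_i.  exp(theta_i) estimates
the ratio of the slope ratio to the correlation ratio, so theta_i = 0 is
precisely the condition under which slope moderation and correlation
moderation coincide.

Restricted models (homogeneous x or y variance, equal variance ratios,
equal correlations, equal slopes) are fitted by maximum likelihood on the
group sufficient statistics and compared by likelihood-ratio chi-square,
mirroring multi-group structural-equation model comparisons.  The
equal-slope constraint is nonlinear in this parameterization (rho_i =
beta * sd_x,i / sd_y,i) and gets its own reparameterized fit so that all
comparisons share one likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .model_core import (
    ConvergenceError,
    GroupMoments,
    ModelFit,
    ModelSpec,
    ParamVector,
    RHO_CLAMP,
    TWO_PI,
    TestConfig,
    fisher_link,
    group_parameter_covariance,
    packed_names,
    saturated_loglik,
)

__all__ = [
    "SUPPORTED_CONSTRAINTS",
    "EVRTestResult",
    "WaldTestResult",
    "LRComparison",
    "fit_saturated",
    "fit_constrained",
    "evr_test",
    "evr_joint_test",
    "correlation_test",
    "lr_compare",
    "moderation_report",
    "theta_variance",
]

SUPPORTED_CONSTRAINTS = frozenset(
    {"HOV_X", "HOV_Y", "EVR", "EQUAL_RHO", "EQUAL_SLOPE"}
)


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EVRTestResult:
    """Wald test of theta = 0 (equal variance ratios) for one contrast."""

    theta_hat: float
    se: float
    statistic: float
    p_value: float
    ci_theta: tuple
    ci_exp_theta: tuple
    base_category: object
    test_category: object
    alpha: float

    @property
    def exp_theta(self) -> float:
        return float(np.exp(self.theta_hat))

    def to_dict(self) -> dict:
        return {
            "base_category": self.base_category,
            "test_category": self.test_category,
            "theta_hat": self.theta_hat,
            "exp_theta": self.exp_theta,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci_theta": list(self.ci_theta),
            "ci_exp_theta": list(self.ci_exp_theta),
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class WaldTestResult:
    """Generic single-coefficient Wald test (estimate, SE, z, p, CI)."""

    estimate: float
    se: float
    statistic: float
    p_value: float
    ci: tuple
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci": list(self.ci),
        }


@dataclass(frozen=True)
class LRComparison:
    """Likelihood-ratio chi-square between nested fits on the same data."""

    chi2: float
    df: int
    p_value: float
    restricted_fit: ModelFit
    full_fit: ModelFit

    def to_dict(self) -> dict:
        return {
            "constraints_restricted": sorted(self.restricted_fit.spec.constraints),
            "constraints_full": sorted(self.full_fit.spec.constraints),
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
        }


# ---------------------------------------------------------------------------
# closed-form saturated fit
# ---------------------------------------------------------------------------


def _coding_matrix(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + indicator coding Z and its inverse (delta = Zinv @ group values)."""
    Z = np.zeros((k, k))
    Z[:, 0] = 1.0
    for i in range(1, k):
        Z[i, i] = 1.0
    Zinv = np.zeros((k, k))
    Zinv[0, 0] = 1.0
    for i in range(1, k):
        Zinv[i, i] = 1.0
        Zinv[i, 0] = -1.0
    return Z, Zinv


def _group_spec(groups: Sequence[GroupMoments], constraints=frozenset()) -> ModelSpec:
    labels = [g.label for g in groups]
    return ModelSpec.categorical(labels, labels[0], constraints)


def _group_values(groups: Sequence[GroupMoments]) -> dict:
    return {
        "mux": np.array([g.mean_x for g in groups]),
        "muy": np.array([g.mean_y for g in groups]),
        "ax": np.array([np.log(g.sd_x) for g in groups]),
        "ay": np.array([np.log(g.sd_y) for g in groups]),
        "c": np.array([fisher_link(g.r) for g in groups]),
        "n": np.array([g.n for g in groups], dtype=float),
        "Sxx": np.array([g.sd_x**2 for g in groups]),
        "Syy": np.array([g.sd_y**2 for g in groups]),
        "Sxy": np.array([g.r * g.sd_x * g.sd_y for g in groups]),
    }


def _coef_cov_from_variable_cov(
    groups: Sequence[GroupMoments], var_cov: np.ndarray
) -> np.ndarray:
    """Map a covariance over per-group values (mux, muy, ax, ay, c — each a
    k-vector, variable-major) into intercept+indicator coefficient space,
    adding the exact per-group mean blocks."""
    k = len(groups)
    _, Zinv = _coding_matrix(k)
    full = np.zeros((5 * k, 5 * k))
    full[2 * k :, 2 * k :] = var_cov
    for i, g in enumerate(groups):
        block = group_parameter_covariance(g)[:2, :2]
        idx = np.array([i, k + i])
        full[np.ix_(idx, idx)] = block
    A = np.kron(np.eye(5), Zinv)
    return A @ full @ A.T


def fit_saturated(groups: Sequence[GroupMoments]) -> ModelFit:
    """Unrestricted multi-group fit, solved in closed form from moments.

    The first group in the sequence is the base category of the
    intercept + indicator coding.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    _, Zinv = _coding_matrix(k)
    v = _group_values(groups)
    params = ParamVector(
        delta_x=Zinv @ v["ax"],
        delta_y=Zinv @ v["ay"],
        delta_r=Zinv @ v["c"],
        gamma_x=Zinv @ v["mux"],
        gamma_y=Zinv @ v["muy"],
    )
    var_cov = np.zeros((3 * k, 3 * k))
    for i, g in enumerate(groups):
        block = group_parameter_covariance(g)[2:, 2:]
        idx = np.array([i, k + i, 2 * k + i])
        var_cov[np.ix_(idx, idx)] = block
    spec = _group_spec(groups)
    fit = ModelFit(
        params=params,
        loglik=saturated_loglik(groups),
        vcov=_coef_cov_from_variable_cov(groups, var_cov),
        n_free=5 * k,
        converged=True,
        spec=spec,
        names=packed_names(spec),
        meta={"groups": tuple(groups), "base": groups[0].label, "engine": "closed-form"},
    )
    return fit


# ---------------------------------------------------------------------------
# the EVR Wald test
# ---------------------------------------------------------------------------


def theta_variance(base: GroupMoments, target: GroupMoments) -> float:
    """Delta-method variance of theta_hat: (1-r_b^2)/n_b + (1-r_t^2)/n_t.

    Identical to the saturated-fit information variance; kept as an
    independent closed form for cross-checking and fast simulation.
    """
    return (1.0 - base.r**2) / base.n + (1.0 - target.r**2) / target.n


def _order_for_base(groups: Sequence[GroupMoments], base) -> list[GroupMoments]:
    by_label = {g.label: g for g in groups}
    if base not in by_label:
        raise KeyError(f"base category {base!r} not among groups")
    return [by_label[base]] + [g for g in groups if g.label != base]


def evr_test(
    groups: Sequence[GroupMoments],
    base,
    target,
    config: TestConfig = TestConfig(),
) -> EVRTestResult:
    """Wald test of equal variance ratios between ``target`` and ``base``.

    theta_hat and its standard error come from the saturated fit's
    coefficient covariance; the CI for exp(theta) — the slope-ratio to
    correlation-ratio comparison — exponentiates the theta CI endpoints.
    """
    if base == target:
        raise ValueError("base and target categories must differ")
    ordered = _order_for_base(groups, base)
    labels = [g.label for g in ordered]
    if target not in labels:
        raise KeyError(f"target category {target!r} not among groups")
    fit = fit_saturated(ordered)
    tname = f"[{target}]"
    theta = float(fit.params.delta_y[labels.index(target)]
                  - fit.params.delta_x[labels.index(target)])
    var = (
        fit.coef_cov(f"dy:{tname}", f"dy:{tname}")
        + fit.coef_cov(f"dx:{tname}", f"dx:{tname}")
        - 2.0 * fit.coef_cov(f"dy:{tname}", f"dx:{tname}")
    )
    se = float(np.sqrt(var))
    stat = theta / se
    sizes = (ordered[0].n, ordered[labels.index(target)].n)
    p = config.p_value(stat, sizes)
    crit = config.critical_value(sizes)
    lo, hi = theta - crit * se, theta + crit * se
    return EVRTestResult(
        theta_hat=theta,
        se=se,
        statistic=float(stat),
        p_value=float(p),
        ci_theta=(float(lo), float(hi)),
        ci_exp_theta=(float(np.exp(lo)), float(np.exp(hi))),
        base_category=base,
        test_category=target,
        alpha=config.alpha,
    )


def evr_joint_test(
    groups: Sequence[GroupMoments], base, config: TestConfig = TestConfig()
) -> dict:
    """Joint Wald chi-square over all theta contrasts against ``base``.

    An explicit extension beyond the pairwise formulation: it pools the
    k - 1 contrasts into one chi-square with df = k - 1.
    """
    ordered = _order_for_base(groups, base)
    k = len(ordered)
    if k < 2:
        raise ValueError("need at least 2 groups")
    thetas = np.array(
        [g.log_variance_ratio - ordered[0].log_variance_ratio for g in ordered[1:]]
    )
    v0 = (1.0 - ordered[0].r**2) / ordered[0].n
    V = np.full((k - 1, k - 1), v0)
    for i, g in enumerate(ordered[1:]):
        V[i, i] += (1.0 - g.r**2) / g.n
    chi2 = float(thetas @ np.linalg.solve(V, thetas))
    df = k - 1
    return {
        "kind": "joint Wald chi-square over theta contrasts (extension)",
        "base_category": base,
        "chi2": chi2,
        "df": df,
        "p_value": float(stats.chi2.sf(chi2, df)),
    }


def correlation_test(
    base: GroupMoments, target: GroupMoments, config: TestConfig = TestConfig()
) -> WaldTestResult:
    """Wald test of equal correlations on the Fisher-link scale.

    The estimate is the Fisher-link difference 2*atanh(r_t) - 2*atanh(r_b);
    its ML variance is 4/n per group (the familiar Fisher-z result with
    divisor n rather than n - 3).
    """
    est = fisher_link(target.r) - fisher_link(base.r)
    se = float(np.sqrt(4.0 / base.n + 4.0 / target.n))
    stat = est / se
    sizes = (base.n, target.n)
    p = config.p_value(stat, sizes)
    crit = config.critical_value(sizes)
    return WaldTestResult(
        estimate=float(est),
        se=se,
        statistic=float(stat),
        p_value=float(p),
        ci=(float(est - crit * se), float(est + crit * se)),
        label=f"fisher-link correlation difference [{target.label}] vs [{base.label}]",
    )


# ---------------------------------------------------------------------------
# constrained maximum likelihood on group sufficient statistics
# ---------------------------------------------------------------------------


def _group_loglik_terms(v: dict, ax, ay, c):
    """Log-likelihood and per-group scores wrt (ax, ay, c) at sample means."""
    rho = np.clip(np.tanh(np.asarray(c) / 2.0), -RHO_CLAMP, RHO_CLAMP)
    k = 1.0 - rho**2
    u = v["Sxx"] * np.exp(-2.0 * ax)
    w = v["Sxy"] * np.exp(-ax - ay)
    vv = v["Syy"] * np.exp(-2.0 * ay)
    n = v["n"]
    ll = n * (
        -np.log(TWO_PI) - ax - ay - 0.5 * np.log(k)
        - (u - 2.0 * rho * w + vv) / (2.0 * k)
    )
    g_ax = n * ((u - rho * w) / k - 1.0)
    g_ay = n * ((vv - rho * w) / k - 1.0)
    g_c = n * (rho + w - rho * (u - 2.0 * rho * w + vv) / k) / 2.0
    return ll, g_ax, g_ay, g_c, rho, k


def _linear_map(k: int, cons: frozenset) -> tuple[np.ndarray, list]:
    """Transformation v_var = T @ free for the linear equality constraints.

    v_var stacks (ax_1..k, ay_1..k, c_1..k).  Returns T and free names.
    """
    entries: list[tuple[int, int, float]] = []
    names: list[str] = []

    def new_col(name: str) -> int:
        names.append(name)
        return len(names) - 1

    if "HOV_X" in cons:
        cx = new_col("ax")
        xcols = [cx] * k
    else:
        xcols = [new_col(f"ax_{i}") for i in range(k)]
    for i in range(k):
        entries.append((i, xcols[i], 1.0))

    if "HOV_Y" in cons:
        cy = new_col("ay")
        for i in range(k):
            entries.append((k + i, cy, 1.0))
    elif "EVR" in cons:
        cy = new_col("ay_base")
        for i in range(k):
            entries.append((k + i, cy, 1.0))
            if i > 0:
                entries.append((k + i, xcols[i], 1.0))
                entries.append((k + i, xcols[0], -1.0))
    else:
        for i in range(k):
            entries.append((k + i, new_col(f"ay_{i}"), 1.0))

    if "EQUAL_RHO" in cons:
        cc = new_col("c")
        for i in range(k):
            entries.append((2 * k + i, cc, 1.0))
    else:
        for i in range(k):
            entries.append((2 * k + i, new_col(f"c_{i}"), 1.0))

    T = np.zeros((3 * k, len(names)))
    for r, c, val in entries:
        T[r, c] += val
    return T, names


def _optimize(fun_grad, x0, label: str):
    res = optimize.minimize(
        fun_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
    )
    if not np.all(np.isfinite(res.x)) or np.max(np.abs(res.jac)) > 1e-5:
        jitter = 0.05 * np.cos(np.arange(len(x0)) + 1.0)
        res2 = optimize.minimize(
            fun_grad, x0 + jitter, jac=True, method="L-BFGS-B",
            options={"maxiter": 4000, "ftol": 1e-15, "gtol": 1e-10},
        )
        if res2.fun <= res.fun:
            res = res2
        if not np.all(np.isfinite(res.x)) or np.max(np.abs(res.jac)) > 1e-4:
            raise ConvergenceError(
                f"{label}: optimizer failed (iters={res.nit}, "
                f"|grad|_inf={np.max(np.abs(res.jac)):.3g}, status={res.message})"
            )
    return res


def _fd_free_covariance(neg_ll_grad, x, n_total: float) -> np.ndarray:
    m = len(x)
    H = np.empty((m, m))
    for j in range(m):
        h = 1e-6 * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        _, gp = neg_ll_grad(xp)
        _, gm = neg_ll_grad(xm)
        H[:, j] = (gp - gm) / (2.0 * h)
    info = n_total * (H + H.T) / 2.0  # neg_ll is scaled by 1/n_total
    return np.linalg.inv(info)


def fit_constrained(
    groups: Sequence[GroupMoments],
    constraints,
    base=None,
) -> ModelFit:
    """ML fit of the multi-group model under named equality constraints.

    Supported constraints: ``HOV_X``/``HOV_Y`` (homogeneous x / y SD),
    ``EVR`` (equal variance ratios: the i>1 log-SD indicator coefficients
    equal between the x and y submodels), ``EQUAL_RHO`` (one correlation),
    ``EQUAL_SLOPE`` (one y-on-x slope, imposed through the nonlinear
    reparameterization rho_i = beta * sd_x,i / sd_y,i so every comparison
    shares the same likelihood).  Linear combinations are allowed;
    ``EQUAL_SLOPE`` combines with the homogeneity constraints only.
    """
    cons = frozenset(str(c).upper() for c in constraints)
    unknown = cons - SUPPORTED_CONSTRAINTS
    if unknown:
        raise ValueError(f"unsupported constraints: {sorted(unknown)}")
    if base is not None:
        groups = _order_for_base(groups, base)
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not cons:
        return fit_saturated(groups)
    if "EQUAL_SLOPE" in cons and (cons & {"EVR", "EQUAL_RHO"}):
        raise ValueError(
            "EQUAL_SLOPE may only be combined with HOV_X/HOV_Y; "
            "jointly with EVR or EQUAL_RHO the combination is not supported"
        )

    k = len(groups)
    v = _group_values(groups)
    n_total = float(v["n"].sum())

    if "EQUAL_SLOPE" in cons:
        fit = _fit_equal_slope_groups(groups, v, cons, n_total)
    else:
        fit = _fit_linear_groups(groups, v, cons, n_total)
    return fit


def _fit_linear_groups(groups, v, cons, n_total) -> ModelFit:
    k = len(groups)
    T, free_names = _linear_map(k, cons)
    v_sat = np.concatenate([v["ax"], v["ay"], v["c"]])
    x0, *_ = np.linalg.lstsq(T, v_sat, rcond=None)

    def neg_ll_grad(free):
        vv = T @ free
        ll, g_ax, g_ay, g_c, _, _ = _group_loglik_terms(v, vv[:k], vv[k : 2 * k], vv[2 * k :])
        g = np.concatenate([g_ax, g_ay, g_c])
        return -np.sum(ll) / n_total, -(T.T @ g) / n_total

    res = _optimize(neg_ll_grad, x0, f"constrained fit {sorted(cons)}")
    vv = T @ res.x
    ax, ay, c = vv[:k], vv[k : 2 * k], vv[2 * k :]
    loglik = -res.fun * n_total

    cov_free = _fd_free_covariance(neg_ll_grad, res.x, n_total)
    var_cov = T @ cov_free @ T.T

    _, Zinv = _coding_matrix(k)
    params = ParamVector(
        delta_x=Zinv @ ax, delta_y=Zinv @ ay, delta_r=Zinv @ c,
        gamma_x=Zinv @ v["mux"], gamma_y=Zinv @ v["muy"],
    )
    spec = _group_spec(groups, cons)
    return ModelFit(
        params=params,
        loglik=float(loglik),
        vcov=_coef_cov_from_variable_cov(groups, var_cov),
        n_free=2 * k + len(free_names),
        converged=True,
        spec=spec,
        names=packed_names(spec),
        meta={
            "groups": tuple(groups),
            "base": groups[0].label,
            "engine": "constrained-ml",
            "free_names": tuple(free_names),
        },
    )


def _fit_equal_slope_groups(groups, v, cons, n_total) -> ModelFit:
    k = len(groups)
    share_x = "HOV_X" in cons
    share_y = "HOV_Y" in cons
    nx = 1 if share_x else k
    ny = 1 if share_y else k

    def unpack(free):
        beta = free[0]
        ax = np.repeat(free[1], k) if share_x else free[1 : 1 + k]
        ay = np.repeat(free[1 + nx], k) if share_y else free[1 + nx : 1 + nx + k]
        return beta, ax, ay

    def neg_ll_grad(free):
        beta, ax, ay = unpack(free)
        ratio = np.exp(ax - ay)
        rho = np.clip(beta * ratio, -RHO_CLAMP, RHO_CLAMP)
        c = 2.0 * np.arctanh(rho)
        ll, g_ax, g_ay, g_c, rho_used, kk = _group_loglik_terms(v, ax, ay, c)
        # chain rule: d c / d rho = 2 / (1 - rho^2); rho depends on beta, ax, ay
        interior = np.abs(beta * ratio) < RHO_CLAMP
        g_rho = np.where(interior, g_c * 2.0 / kk, 0.0)
        g_beta = np.sum(g_rho * ratio)
        g_ax_tot = g_ax + g_rho * rho_used
        g_ay_tot = g_ay - g_rho * rho_used
        parts = [np.array([g_beta])]
        parts.append(np.array([np.sum(g_ax_tot)]) if share_x else g_ax_tot)
        parts.append(np.array([np.sum(g_ay_tot)]) if share_y else g_ay_tot)
        return -np.sum(ll) / n_total, -np.concatenate(parts) / n_total

    w0 = v["n"]
    beta0 = float(np.sum(w0 * v["Sxy"]) / np.sum(w0 * v["Sxx"]))
    ax0 = [0.5 * np.log(np.sum(w0 * v["Sxx"]) / np.sum(w0))] if share_x else list(v["ax"])
    ay0 = [0.5 * np.log(np.sum(w0 * v["Syy"]) / np.sum(w0))] if share_y else list(v["ay"])
    x0 = np.array([beta0] + ax0 + ay0)

    res = _optimize(neg_ll_grad, x0, f"equal-slope fit {sorted(cons)}")
    beta, ax, ay = unpack(res.x)
    rho = np.clip(beta * np.exp(ax - ay), -RHO_CLAMP, RHO_CLAMP)
    c = 2.0 * np.arctanh(rho)
    loglik = -res.fun * n_total

    cov_free = _fd_free_covariance(neg_ll_grad, res.x, n_total)
    # propagate to (ax, ay, c) space by the delta method for reporting
    J = np.zeros((3 * k, len(res.x)))
    ratio = np.exp(ax - ay)
    kk = 1.0 - rho**2
    for i in range(k):
        jx = 1 if share_x else 1 + i
        jy = 1 + nx if share_y else 1 + nx + i
        J[i, jx] = 1.0
        J[k + i, jy] = 1.0
        dc_drho = 2.0 / kk[i]
        J[2 * k + i, 0] = dc_drho * ratio[i]
        J[2 * k + i, jx] += dc_drho * rho[i]
        J[2 * k + i, jy] -= dc_drho * rho[i]
    var_cov = J @ cov_free @ J.T

    _, Zinv = _coding_matrix(k)
    params = ParamVector(
        delta_x=Zinv @ ax, delta_y=Zinv @ ay, delta_r=Zinv @ c,
        gamma_x=Zinv @ v["mux"], gamma_y=Zinv @ v["muy"],
    )
    spec = _group_spec(groups, cons)
    return ModelFit(
        params=params,
        loglik=float(loglik),
        vcov=_coef_cov_from_variable_cov(groups, var_cov),
        n_free=2 * k + len(res.x),
        converged=True,
        spec=spec,
        names=packed_names(spec),
        meta={
            "groups": tuple(groups),
            "base": groups[0].label,
            "engine": "equal-slope-ml",
            "beta": float(beta),
        },
    )


# ---------------------------------------------------------------------------
# likelihood-ratio comparison
# ---------------------------------------------------------------------------


def _same_data(a: ModelFit, b: ModelFit) -> bool:
    ga, gb = a.meta.get("groups"), b.meta.get("groups")
    if ga is None or gb is None or len(ga) != len(gb):
        return False
    for x, y in zip(ga, gb):
        if x.label != y.label or x.n != y.n:
            return False
        vals = ("mean_x", "mean_y", "sd_x", "sd_y", "r")
        if not all(np.isclose(getattr(x, f), getattr(y, f), rtol=1e-9) for f in vals):
            return False
    return True


def lr_compare(restricted: ModelFit, full: ModelFit) -> LRComparison:
    """Chi-square difference test between nested fits on the same groups."""
    if not _same_data(restricted, full):
        raise ValueError("fits were not computed on the same data")
    if not full.spec.constraints <= restricted.spec.constraints:
        raise ValueError(
            "models are not nested: the restricted fit must carry every "
            "constraint of the full fit"
        )
    df = full.n_free - restricted.n_free
    if df < 0:
        raise ValueError("restricted model has more free coefficients than full")
    chi2 = 2.0 * (full.loglik - restricted.loglik)
    if chi2 < -1e-6 * max(1.0, abs(full.loglik)):
        raise ValueError(
            f"negative chi-square ({chi2:.3g}): fits are not nested or did not converge"
        )
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRComparison(float(chi2), int(df), p, restricted, full)


# ---------------------------------------------------------------------------
# the full moderation report
# ---------------------------------------------------------------------------


def moderation_report(
    groups: Sequence[GroupMoments],
    config: TestConfig = TestConfig(),
    base=None,
) -> dict:
    """Moments, slopes in both directions, EVR tests, and the LR ladder.

    The ladder starts from the saturated model, imposes homogeneity of the
    x SDs first when the sample x moments are compatible with it (LR p >=
    alpha), and then adds one substantive constraint at a time (EVR, equal
    slopes, equal correlations), reporting each chi-square difference
    against the baseline.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if base is None:
        base = groups[0].label
    ordered = _order_for_base(groups, base)
    base_g = ordered[0]

    group_rows = []
    for g in ordered:
        group_rows.append(
            {
                "label": g.label,
                "n": g.n,
                "mean_x": g.mean_x,
                "mean_y": g.mean_y,
                "sd_x": g.sd_x,
                "sd_y": g.sd_y,
                "r": g.r,
                "slope_y_on_x": g.slope_y_on_x,
                "slope_x_on_y": g.slope_x_on_y,
                "variance_ratio": (g.sd_y / g.sd_x) ** 2,
            }
        )

    theta_tests = [
        evr_test(ordered, base, g.label, config).to_dict() for g in ordered[1:]
    ]
    corr_tests = [
        correlation_test(base_g, g, config).to_dict() for g in ordered[1:]
    ]

    sat = fit_saturated(ordered)
    hov_x = fit_constrained(ordered, {"HOV_X"})
    hov_cmp = lr_compare(hov_x, sat)
    use_hov = hov_cmp.p_value >= config.alpha
    baseline = hov_x if use_hov else sat
    base_cons = baseline.spec.constraints

    ladder = {
        "baseline": "HOV_X" if use_hov else "saturated",
        "hov_x_check": hov_cmp.to_dict(),
        "steps": [],
    }
    for extra in ("EVR", "EQUAL_SLOPE", "EQUAL_RHO"):
        rfit = fit_constrained(ordered, set(base_cons) | {extra})
        ladder["steps"].append(lr_compare(rfit, baseline).to_dict())

    report = {
        "base_category": base,
        "groups": group_rows,
        "theta_tests": theta_tests,
        "correlation_tests": corr_tests,
        "lr_ladder": ladder,
        "config": {
            "alpha": config.alpha,
            "critical_value_family": config.critical_value_family,
        },
    }
    if len(ordered) > 2:
        report["joint_theta_test"] = evr_joint_test(ordered, base, config)
    return report
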