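"""Monte-Carlo harness: rejection rates, power, and estimation bias.

``run_simulation`` draws R replicate data sets from a
:class:`~evrtest.samplers.ScenarioSpec`, applies the requested tests at
the configured alpha, and reports rejection proportions with their
binomial Monte-Carlo standard errors sqrt(p (1 - p) / R).

Categorical scenarios use the closed forms of the saturated model, so a
replicate costs a handful of moment computations:

* ``theta`` — Wald test of equal variance ratios (group 2 vs group 1);
* ``delta_r`` — Wald test of equal correlations on the Fisher-link scale;
* ``lr_equal_slope`` / ``lr_equal_rho`` — likelihood-ratio chi-square of
  the equal-slope / equal-correlation restriction against the saturated
  model, with the restricted likelihood profiled analytically (a scalar
  fixed-point in the shared slope, a scalar Newton step in the shared
  correlation) and vectorized across replicates.

Continuous scenarios are fitted with the batched Fisher-scoring engine;
``theta1`` and ``delta_r1`` are Wald tests from the observed-information
covariance, and coefficient bias (mean estimate minus truth) is recorded.

Reproducibility: replicate i uses ``numpy.random.default_rng(seed + i)``,
so any single replicate can be regenerated in isolation and aggregates do
not depend on execution order.  Non-converged replicates are excluded
from the rates and counted; an aggregate error is raised when they reach
5% of the requested replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .continuous import fit_batch
from .model_core import TestConfig
from .samplers import (
    ContinuousCoeffs,
    ScenarioSpec,
    _sample_group,
    sample_continuous_scenario,
)

__all__ = ["SimulationResult", "run_simulation", "bias_sweep", "mc_se"]

log = logging.getLogger("evrtest")

_CAT_TESTS = ("theta", "delta_r", "lr_equal_slope", "lr_equal_rho")
_CONT_TESTS = ("theta1", "delta_r1")


def mc_se(p: float, reps: int) -> float:
    """Binomial Monte-Carlo standard error sqrt(p (1 - p) / reps)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return float(np.sqrt(p * (1.0 - p) / reps))


@dataclass
class SimulationResult:
    """Aggregate of one Monte-Carlo cell."""

    scenario: ScenarioSpec
    reps: int
    alpha: float
    rejection_rates: dict = field(default_factory=dict)
    mc_se: dict = field(default_factory=dict)
    bias: dict = field(default_factory=dict)
    bias_mc_se: dict = field(default_factory=dict)
    failures: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario.name,
            "reps": self.reps,
            "alpha": self.alpha,
            "seed": self.seed,
            "rejection_rates": dict(self.rejection_rates),
            "mc_se": dict(self.mc_se),
            "bias": dict(self.bias),
            "bias_mc_se": dict(self.bias_mc_se),
            "failures": self.failures,
        }


# ---------------------------------------------------------------------------
# categorical machinery (vectorized over replicates)
# ---------------------------------------------------------------------------


def _collect_categorical_stats(spec: ScenarioSpec, reps: int, seed: int) -> dict:
    """Per-replicate ML moments of every group: arrays of shape (k, reps)."""
    k = len(spec.groups)
    n = np.array([g.n for g in spec.groups], dtype=float)
    Sxx = np.empty((k, reps))
    Syy = np.empty((k, reps))
    Sxy = np.empty((k, reps))
    for i in range(reps):
        rng = np.random.default_rng(seed + i)
        for gi, pop in enumerate(spec.groups):
            xy = _sample_group(pop, spec.skew, rng)
            x = xy[:, 0] - xy[:, 0].mean()
            y = xy[:, 1] - xy[:, 1].mean()
            Sxx[gi, i] = np.mean(x * x)
            Syy[gi, i] = np.mean(y * y)
            Sxy[gi, i] = np.mean(x * y)
    return {"n": n, "Sxx": Sxx, "Syy": Syy, "Sxy": Sxy}


def _profile_equal_rho(st: dict):
    """Common-correlation profile likelihood: solve the scalar score
    sum_i n_i [ -rho/(1-rho^2) + r_i/(1 - rho r_i) ] = 0 by Newton."""
    n = st["n"][:, None]
    r = st["Sxy"] / np.sqrt(st["Sxx"] * st["Syy"])
    z = np.sum(n * np.arctanh(r), axis=0) / np.sum(n)
    rho = np.tanh(z)
    ok = np.ones(rho.shape, dtype=bool)
    for _ in range(60):
        k = 1.0 - rho**2
        f = np.sum(n * (-rho / k + r / (1.0 - rho * r)), axis=0)
        fp = np.sum(
            n * (-(1.0 + rho**2) / k**2 + r**2 / (1.0 - rho * r) ** 2), axis=0
        )
        step = np.where(fp != 0.0, f / fp, 0.0)
        step = np.clip(step, -0.2, 0.2)
        rho = np.clip(rho - step, -0.9999, 0.9999)
        if np.max(np.abs(f)) < 1e-10 * np.sum(n):
            break
    k = 1.0 - rho**2
    resid = np.sum(n * (-rho / k + r / (1.0 - rho * r)), axis=0)
    ok = np.abs(resid) < 1e-6 * np.sum(n)
    chi2 = 2.0 * np.sum(
        n * (-0.5 * np.log1p(-(r**2)) - 0.5 * np.log(k) + np.log(1.0 - rho * r)),
        axis=0,
    )
    return np.maximum(chi2, 0.0), rho, ok


def _profile_equal_slope(st: dict):
    """Common-slope profile likelihood via the exact ML fixed point
    beta = sum_i w_i Sxy_i / sum_i w_i Sxx_i with w_i = n_i / sigma_e_i^2."""
    n = st["n"][:, None]
    Sxx, Syy, Sxy = st["Sxx"], st["Syy"], st["Sxy"]
    beta = np.sum(n * Sxy, axis=0) / np.sum(n * Sxx, axis=0)
    ok = np.ones(beta.shape, dtype=bool)
    for _ in range(200):
        se2 = Syy - 2.0 * beta * Sxy + beta**2 * Sxx
        w = n / se2
        new = np.sum(w * Sxy, axis=0) / np.sum(w * Sxx, axis=0)
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < 1e-13:
            break
    se2 = Syy - 2.0 * beta * Sxy + beta**2 * Sxx
    ok = np.all(se2 > 0, axis=0)
    r2 = Sxy**2 / (Sxx * Syy)
    chi2 = np.sum(n * np.log(se2 / (Syy * (1.0 - r2))), axis=0)
    return np.maximum(chi2, 0.0), beta, ok


def _categorical_rates(spec, reps, config, tests, seed):
    st = _collect_categorical_stats(spec, reps, seed)
    n = st["n"]
    r = st["Sxy"] / np.sqrt(st["Sxx"] * st["Syy"])
    sizes = (int(n[0]), int(n[1]))
    crit = config.critical_value(sizes)
    chi2_crit = stats.chi2.ppf(1.0 - config.alpha, len(spec.groups) - 1)

    rates: dict = {}
    ses: dict = {}
    failures = np.zeros(reps, dtype=bool)
    reject: dict = {}

    if "theta" in tests:
        theta = 0.5 * (
            np.log(st["Syy"][1] / st["Sxx"][1]) - np.log(st["Syy"][0] / st["Sxx"][0])
        )
        se = np.sqrt((1.0 - r[0] ** 2) / n[0] + (1.0 - r[1] ** 2) / n[1])
        reject["theta"] = np.abs(theta / se) > crit
    if "delta_r" in tests:
        est = 2.0 * (np.arctanh(r[1]) - np.arctanh(r[0]))
        se = np.sqrt(4.0 / n[0] + 4.0 / n[1])
        reject["delta_r"] = np.abs(est / se) > crit
    if "lr_equal_slope" in tests:
        chi2, _, ok = _profile_equal_slope(st)
        failures |= ~ok
        reject["lr_equal_slope"] = chi2 > chi2_crit
    if "lr_equal_rho" in tests:
        chi2, _, ok = _profile_equal_rho(st)
        failures |= ~ok
        reject["lr_equal_rho"] = chi2 > chi2_crit

    good = ~failures
    m = int(good.sum())
    for name, rej in reject.items():
        p = float(np.mean(rej[good]))
        rates[name] = p
        ses[name] = mc_se(p, m)
    return rates, ses, {}, {}, int(failures.sum())


# ---------------------------------------------------------------------------
# continuous machinery (batched fits)
# ---------------------------------------------------------------------------


def _continuous_rates(spec, reps, config, tests, seed, chunk):
    need_vcov = bool(set(tests) & set(_CONT_TESTS))
    N = spec.n_obs
    crit = config.critical_value(((N - 10 + 2),)) if config.critical_value_family == "t" \
        else config.critical_value(None)

    rej = {t: [] for t in tests}
    dr0_all, dr1_all, th1_all = [], [], []
    failures = 0
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        X = np.empty((b, N))
        Y = np.empty((b, N))
        Z = np.empty((b, N))
        for i in range(b):
            rng = np.random.default_rng(seed + done + i)
            s = sample_continuous_scenario(N, spec.coeffs, rng, spec.skew)
            X[i], Y[i], Z[i] = s.x, s.y, s.moderator
        fit = fit_batch(X, Y, Z, compute_vcov=need_vcov)
        good = fit.converged
        failures += int((~good).sum())
        if "theta1" in tests:
            stat = fit.theta1[good] / fit.se_theta1[good]
            rej["theta1"].append(np.abs(stat) > crit)
        if "delta_r1" in tests:
            stat = fit.coef("dr1")[good] / fit.se_dr1[good]
            rej["delta_r1"].append(np.abs(stat) > crit)
        dr0_all.append(fit.coef("dr0")[good])
        dr1_all.append(fit.coef("dr1")[good])
        th1_all.append(fit.theta1[good])
        done += b

    rates, ses = {}, {}
    for t in tests:
        v = np.concatenate(rej[t]) if rej[t] else np.array([], bool)
        p = float(np.mean(v)) if v.size else float("nan")
        rates[t] = p
        ses[t] = mc_se(p, max(v.size, 1))

    dr0 = np.concatenate(dr0_all)
    dr1 = np.concatenate(dr1_all)
    th1 = np.concatenate(th1_all)
    true_dr0 = spec.coeffs.delta_r[0]
    true_dr1 = spec.coeffs.delta_r[1]
    true_th1 = spec.coeffs.theta1
    # correlation-scale effect: the change in rho from z = 0 to z = 1
    drho = np.tanh((dr0 + dr1) / 2.0) - np.tanh(dr0 / 2.0)
    true_drho = np.tanh((true_dr0 + true_dr1) / 2.0) - np.tanh(true_dr0 / 2.0)
    bias = {
        "delta_r1": float(np.mean(dr1) - true_dr1),
        "theta1": float(np.mean(th1) - true_th1),
        "delta_rho": float(np.mean(drho) - true_drho),
    }
    bias_se = {
        "delta_r1": float(np.std(dr1, ddof=1) / np.sqrt(len(dr1))),
        "theta1": float(np.std(th1, ddof=1) / np.sqrt(len(th1))),
        "delta_rho": float(np.std(drho, ddof=1) / np.sqrt(len(drho))),
    }
    return rates, ses, bias, bias_se, failures


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def run_simulation(
    scenario: ScenarioSpec,
    reps: int,
    config: TestConfig = TestConfig(),
    tests=None,
    seed: int | None = None,
    chunk: int = 4000,
) -> SimulationResult:
    """Estimate rejection rates (and, for continuous cells, bias) by
    Monte Carlo.  ``seed`` overrides the scenario's stored seed."""
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful Monte-Carlo cell")
    master = seed if seed is not None else (scenario.seed or 0)
    if tests is None:
        tests = _CAT_TESTS[:2] if scenario.kind == "categorical" else _CONT_TESTS
    tests = tuple(tests)
    valid = _CAT_TESTS if scenario.kind == "categorical" else _CONT_TESTS
    unknown = set(tests) - set(valid)
    if unknown:
        raise ValueError(f"unknown tests for {scenario.kind} scenario: {sorted(unknown)}")

    if scenario.kind == "categorical":
        rates, ses, bias, bias_se, failures = _categorical_rates(
            scenario, reps, config, tests, master
        )
    else:
        rates, ses, bias, bias_se, failures = _continuous_rates(
            scenario, reps, config, tests, master, chunk
        )

    if failures:
        log.warning(
            "%d/%d replicates failed to converge and were excluded", failures, reps
        )
    if failures >= 0.05 * reps:
        raise RuntimeError(
            f"{failures}/{reps} replicates failed to converge (>= 5%)"
        )
    return SimulationResult(
        scenario=scenario,
        reps=reps,
        alpha=config.alpha,
        rejection_rates=rates,
        mc_se=ses,
        bias=bias,
        bias_mc_se=bias_se,
        failures=failures,
        seed=master,
    )


def bias_sweep(
    size_grid,
    delta_r1_grid,
    theta1_grid,
    reps: int,
    config: TestConfig = TestConfig(),
    seed: int = 0,
    delta_r0: float = 0.0,
) -> dict:
    """Mean estimation bias of dr1-hat and theta1-hat over a design grid.

    Cell populations put the variance-ratio moderation entirely in y
    (delta_x1 = 0, delta_y1 = theta1) with correlation intercept
    ``delta_r0``; z ~ N(0, 1).  Cell c uses master seed
    ``seed + 100000 * (c + 1)`` so cells never share replicate streams.
    """
    sizes = list(size_grid)
    dr1s = list(delta_r1_grid)
    th1s = list(theta1_grid)
    if not (sizes and dr1s and th1s):
        raise ValueError("all three grids must be nonempty")
    cells = []
    cell_index = 0
    for N in sizes:
        for dr1 in dr1s:
            for th1 in th1s:
                coeffs = ContinuousCoeffs(
                    delta_x=(0.0, 0.0),
                    delta_y=(0.0, float(th1)),
                    delta_r=(float(delta_r0), float(dr1)),
                )
                spec = ScenarioSpec(
                    kind="continuous", coeffs=coeffs, n_obs=int(N),
                    name=f"sweep.N{N}.dr1_{dr1}.th1_{th1}",
                )
                res = run_simulation(
                    spec, reps, config, tests=(),
                    seed=seed + 100_000 * (cell_index + 1),
                )
                cells.append(
                    {
                        "N": int(N),
                        "delta_r1": float(dr1),
                        "theta1": float(th1),
                        "bias_delta_r1": res.bias["delta_r1"],
                        "bias_theta1": res.bias["theta1"],
                        "bias_delta_rho": res.bias["delta_rho"],
                        "se_bias_delta_r1": res.bias_mc_se["delta_r1"],
                        "se_bias_theta1": res.bias_mc_se["theta1"],
                        "se_bias_delta_rho": res.bias_mc_se["delta_rho"],
                        "failures": res.failures,
                    }
                )
                cell_index += 1

    out = {"cells": cells, "reps_per_cell": reps}
    for key in ("delta_r1", "theta1", "delta_rho"):
        i = int(np.argmax([abs(c[f"bias_{key}"]) for c in cells]))
        out[f"max_abs_bias_{key}"] = abs(cells[i][f"bias_{key}"])
        out[f"max_abs_bias_{key}_se"] = cells[i][f"se_bias_{key}"]
        out[f"max_abs_bias_{key}_cell"] = {
            k: cells[i][k] for k in ("N", "delta_r1", "theta1")
        }
    return out
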