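"""Seeded generators and declarative simulation scenarios.

Two families of populations are supported:

* categorical — k moderator categories, each a bivariate normal (or
  bivariate skew-normal) with its own variances and covariance;
* continuous — z ~ N(0, 1) and (x, y) | z bivariate normal with
  log-linear SD submodels and a Fisher-link correlation submodel in z.

Skewed margins use the Azzalini skew-normal with shape ``lambda``:
density 2 phi(x) Phi(lambda x).  Bivariate dependence between two
skew-normal margins is induced by the shared-latent construction

    X = d|W| + sqrt(1 - d^2) U,   Y = d|W| + sqrt(1 - d^2) V,

with W standard normal, (U, V) bivariate normal with latent correlation
chosen so that corr(X, Y) hits the scenario target, and d =
lambda / sqrt(1 + lambda^2).  Both margins are then exactly skew-normal,
and an affine rescale maps them onto the scenario's means and SDs.

``build_scenario`` exposes the named simulation-study designs (tables
"1"–"7" and "sem_example") so the Monte-Carlo harness and the acceptance
checks draw from a single registry of populations.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .model_core import BivariateSample

__all__ = [
    "GroupPopulation",
    "ContinuousCoeffs",
    "ScenarioSpec",
    "SkewSpec",
    "skew_normal_pdf",
    "sn_mean",
    "sn_sd",
    "sn_skewness",
    "skew_latent_corr",
    "sample_bivariate_normal",
    "sample_bivariate_skew_normal",
    "sample_continuous_scenario",
    "sample_scenario",
    "build_scenario",
    "scenario_to_file",
    "scenario_from_file",
    "validate_scenario",
]

_MIN_ONE_MINUS_RHO2 = 1e-10


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPopulation:
    """One moderator category's bivariate population."""

    label: object
    n: int
    var_x: float
    var_y: float
    cov_xy: float
    mean_x: float = 0.0
    mean_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("group size must be at least 4")
        if not (self.var_x > 0 and self.var_y > 0):
            raise ValueError("variances must be positive")
        if 1.0 - self.rho**2 < _MIN_ONE_MINUS_RHO2:
            raise ValueError(
                "covariance matrix numerically singular: |rho| too close to 1"
            )

    @property
    def rho(self) -> float:
        return self.cov_xy / np.sqrt(self.var_x * self.var_y)

    @property
    def slope_y_on_x(self) -> float:
        return self.cov_xy / self.var_x

    @property
    def slope_x_on_y(self) -> float:
        return self.cov_xy / self.var_y

    @property
    def resid_var_y(self) -> float:
        """Error variance when y is regressed on x: var_y (1 - rho^2)."""
        return self.var_y * (1.0 - self.rho**2)

    @property
    def variance_ratio(self) -> float:
        return self.var_y / self.var_x


@dataclass(frozen=True)
class ContinuousCoeffs:
    """Coefficients of the continuous-moderator population model."""

    delta_x: tuple = (0.0, 0.0)
    delta_y: tuple = (0.0, 0.0)
    delta_r: tuple = (0.0, 0.0)
    gamma_x: tuple = (0.0, 0.0)
    gamma_y: tuple = (0.0, 0.0)

    @property
    def theta1(self) -> float:
        return self.delta_y[1] - self.delta_x[1]


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation cell (population + sizes + skew + seed)."""

    kind: str                              # "categorical" | "continuous"
    groups: tuple = ()                     # GroupPopulation's (categorical)
    coeffs: ContinuousCoeffs | None = None
    n_obs: int | None = None               # total N (continuous)
    skew: float = 0.0                      # Azzalini shape lambda, 0 = normal
    seed: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "categorical" and len(self.groups) < 2:
            raise ValueError("categorical scenario needs >= 2 groups")
        if self.kind == "continuous":
            if self.coeffs is None or self.n_obs is None or self.n_obs < 4:
                raise ValueError("continuous scenario needs coeffs and n_obs >= 4")
        if self.skew < 0:
            raise ValueError("skew shape lambda must be >= 0")


@dataclass(frozen=True)
class SkewSpec:
    """Azzalini shape lambda and the derived latent loading delta."""

    lam: float

    @property
    def delta(self) -> float:
        d = self.lam / np.sqrt(1.0 + self.lam**2)
        if not abs(d) < 1:
            raise ValueError("invalid shape: |delta| must be < 1")
        return d


# ---------------------------------------------------------------------------
# skew-normal pieces
# ---------------------------------------------------------------------------


def skew_normal_pdf(x, lam: float):
    """Standard Azzalini skew-normal density 2 phi(x) Phi(lambda x)."""
    from scipy import stats

    x = np.asarray(x, float)
    out = 2.0 * stats.norm.pdf(x) * stats.norm.cdf(lam * x)
    return float(out) if out.ndim == 0 else out


def sn_mean(lam: float) -> float:
    d = SkewSpec(lam).delta
    return d * np.sqrt(2.0 / np.pi)


def sn_sd(lam: float) -> float:
    d = SkewSpec(lam).delta
    return float(np.sqrt(1.0 - 2.0 * d**2 / np.pi))


def sn_skewness(lam: float) -> float:
    """Closed-form skewness of the standard skew-normal."""
    d = SkewSpec(lam).delta
    m = d * np.sqrt(2.0 / np.pi)
    return float((4.0 - np.pi) / 2.0 * m**3 / (1.0 - m**2) ** 1.5)


def skew_latent_corr(lam: float, target_corr: float) -> float:
    """Latent (U, V) correlation giving corr(X, Y) = target under the
    shared-latent construction.  Raises if the target is unreachable for
    this shape."""
    d = SkewSpec(lam).delta
    if d == 0.0:
        rho_uv = float(target_corr)
    else:
        m2 = 1.0 - 2.0 * d**2 / np.pi          # marginal variance
        shared = d**2 * (1.0 - 2.0 / np.pi)    # cov contributed by |W|
        rho_uv = float((target_corr * m2 - shared) / (1.0 - d**2))
    if not abs(rho_uv) < 1.0:
        raise ValueError(
            f"target correlation {target_corr} unreachable with shape "
            f"lambda={lam}: latent correlation {rho_uv:.3f} out of range"
        )
    return rho_uv


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def sample_bivariate_normal(n: int, moments, seed=None) -> np.ndarray:
    """(n, 2) draws from a bivariate normal.

    ``moments`` is (mean_x, mean_y, var_x, var_y, cov_xy); the covariance
    matrix must be numerically positive definite.
    """
    mean_x, mean_y, var_x, var_y, cov_xy = (float(v) for v in moments)
    if not (var_x > 0 and var_y > 0):
        raise ValueError("variances must be positive")
    rho = cov_xy / np.sqrt(var_x * var_y)
    if 1.0 - rho**2 < _MIN_ONE_MINUS_RHO2:
        raise ValueError("covariance matrix numerically singular")
    rng = _rng(seed)
    e = rng.standard_normal((n, 2))
    x = mean_x + np.sqrt(var_x) * e[:, 0]
    y = mean_y + np.sqrt(var_y) * (rho * e[:, 0] + np.sqrt(1.0 - rho**2) * e[:, 1])
    return np.column_stack([x, y])


def sample_bivariate_skew_normal(n: int, lam: float, latent_corr: float, seed=None) -> np.ndarray:
    """(n, 2) draws with standard skew-normal margins of shape ``lam``.

    ``latent_corr`` is the correlation of the latent normal pair (U, V) in
    the shared-latent construction; use :func:`skew_latent_corr` to aim at
    a target corr(X, Y).
    """
    if not abs(latent_corr) < 1:
        raise ValueError("|latent_corr| must be < 1")
    d = SkewSpec(lam).delta
    rng = _rng(seed)
    w = np.abs(rng.standard_normal(n))
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    u = e1
    v = latent_corr * e1 + np.sqrt(1.0 - latent_corr**2) * e2
    root = np.sqrt(1.0 - d**2)
    return np.column_stack([d * w + root * u, d * w + root * v])


def _sample_group(pop: GroupPopulation, lam: float, rng) -> np.ndarray:
    if lam == 0.0:
        return sample_bivariate_normal(
            pop.n, (pop.mean_x, pop.mean_y, pop.var_x, pop.var_y, pop.cov_xy), rng
        )
    rho_uv = skew_latent_corr(lam, pop.rho)
    raw = sample_bivariate_skew_normal(pop.n, lam, rho_uv, rng)
    m, s = sn_mean(lam), sn_sd(lam)
    std = (raw - m) / s
    x = pop.mean_x + np.sqrt(pop.var_x) * std[:, 0]
    y = pop.mean_y + np.sqrt(pop.var_y) * std[:, 1]
    return np.column_stack([x, y])


def sample_continuous_scenario(
    n: int, coeffs: ContinuousCoeffs, seed=None, skew: float = 0.0
) -> BivariateSample:
    """Draw z ~ N(0, 1) and (x, y) | z from the link-function population."""
    rng = _rng(seed)
    z = rng.standard_normal(n)
    dx, dy, dr = coeffs.delta_x, coeffs.delta_y, coeffs.delta_r
    gx, gy = coeffs.gamma_x, coeffs.gamma_y
    sx = np.exp(dx[0] + dx[1] * z)
    sy = np.exp(dy[0] + dy[1] * z)
    rho = np.tanh((dr[0] + dr[1] * z) / 2.0)
    mux = gx[0] + gx[1] * z
    muy = gy[0] + gy[1] * z
    if skew == 0.0:
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        x = mux + sx * e1
        y = muy + sy * (rho * e1 + np.sqrt(1.0 - rho**2) * e2)
    else:
        d = SkewSpec(skew).delta
        m2 = 1.0 - 2.0 * d**2 / np.pi
        shared = d**2 * (1.0 - 2.0 / np.pi)
        rho_uv = (rho * m2 - shared) / (1.0 - d**2)
        if np.any(np.abs(rho_uv) >= 1.0):
            raise ValueError(
                "target correlation path unreachable under the shared-latent "
                f"skew construction (lambda={skew})"
            )
        w = np.abs(rng.standard_normal(n))
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        root = np.sqrt(1.0 - d**2)
        u = e1
        v = rho_uv * e1 + np.sqrt(1.0 - rho_uv**2) * e2
        m, s = sn_mean(skew), sn_sd(skew)
        x = mux + sx * (d * w + root * u - m) / s
        y = muy + sy * (d * w + root * v - m) / s
    return BivariateSample(x, y, z, kind="continuous")


def sample_scenario(spec: ScenarioSpec, seed=None) -> BivariateSample:
    """Draw one data set from a scenario (categorical or continuous)."""
    rng = _rng(spec.seed if seed is None else seed)
    if spec.kind == "continuous":
        return sample_continuous_scenario(spec.n_obs, spec.coeffs, rng, spec.skew)
    xs, ys, labs = [], [], []
    for pop in spec.groups:
        xy = _sample_group(pop, spec.skew, rng)
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
        labs.extend([pop.label] * pop.n)
    return BivariateSample(
        np.concatenate(xs), np.concatenate(ys), np.array(labs, dtype=object),
        kind="categorical",
    )


# ---------------------------------------------------------------------------
# the scenario registry (simulation-study designs)
# ---------------------------------------------------------------------------

_SQ = np.sqrt
_R_HALF2 = 1.0 / _SQ(2.0)      # rho = 1/sqrt(2)

# per-condition group variance pairs; covariance rules give the designs'
# constant-correlation or constant-slope structure
_T1_VARS = [((1.0, 2.0), (1.0, 2.0)), ((1.0, 2.0), (2.0, 4.0)), ((1.0, 2.0), (4.0, 8.0))]
_T23_VARY2 = [3.0, 4.0, 8.0]
_T4_BETA2 = [0.61, 0.71, 1.00]
_T5_RHO2 = [0.41, 0.35, 0.25, 0.17]
_T67_DR0 = [0.0, 0.5, 1.0]

_SIZES_T1 = [(70, 70), (45, 155), (90, 180)]
_SIZES_T2 = [(70, 70), (40, 100), (140, 140), (80, 200)]


def _cat_spec(name, pops, skew=0.0) -> ScenarioSpec:
    return ScenarioSpec(kind="categorical", groups=tuple(pops), skew=skew, name=name)


def build_scenario(
    table_id,
    condition_index: int = 1,
    sizes: Sequence[int] | None = None,
    skew: float | None = None,
) -> ScenarioSpec:
    """Return the population for a named simulation design cell.

    ``table_id`` is one of "1"–"7" or "sem_example"; ``condition_index`` is
    the 1-based column of the design (for "6"/"7" it selects the
    correlation intercept).  ``sizes`` gives the group sizes (categorical;
    default the design's first row) or (N,) for the continuous designs
    (default 70).  ``skew`` selects the Azzalini shape for design "1"
    (default 0 = normal; "7" is fixed at 2).
    """
    tid = str(table_id)
    j = condition_index - 1

    if tid == "1":
        if not 0 <= j < len(_T1_VARS):
            raise KeyError(f"design 1 has conditions 1..{len(_T1_VARS)}")
        lam = 0.0 if skew is None else float(skew)
        n1, n2 = sizes if sizes is not None else _SIZES_T1[0]
        (vx1, vy1), (vx2, vy2) = _T1_VARS[j]
        pops = [
            GroupPopulation("g1", n1, vx1, vy1, _R_HALF2 * _SQ(vx1 * vy1)),
            GroupPopulation("g2", n2, vx2, vy2, _R_HALF2 * _SQ(vx2 * vy2)),
        ]
        return _cat_spec(f"design1.c{condition_index}", pops, lam)

    if tid in ("2", "3"):
        if not 0 <= j < len(_T23_VARY2):
            raise KeyError(f"design {tid} has conditions 1..{len(_T23_VARY2)}")
        n1, n2 = sizes if sizes is not None else _SIZES_T2[0]
        vy2 = _T23_VARY2[j]
        if tid == "2":   # moderated slopes, constant correlation 0.5
            cov2 = 0.5 * _SQ(2.0 * vy2)
        else:            # moderated correlations, constant slope 0.5
            cov2 = 1.0
        pops = [
            GroupPopulation("g1", n1, 2.0, 2.0, 1.0),
            GroupPopulation("g2", n2, 2.0, vy2, cov2),
        ]
        return _cat_spec(f"design{tid}.c{condition_index}", pops)

    if tid == "4":       # constant correlation 0.5, slope 0.5 vs beta2
        if not 0 <= j < len(_T4_BETA2):
            raise KeyError(f"design 4 has conditions 1..{len(_T4_BETA2)}")
        n1, n2 = sizes if sizes is not None else _SIZES_T2[0]
        b2 = _T4_BETA2[j]
        pops = [
            GroupPopulation("g1", n1, 1.0, 1.0, 0.5),
            GroupPopulation("g2", n2, 1.0, (2.0 * b2) ** 2, b2),
        ]
        return _cat_spec(f"design4.c{condition_index}", pops)

    if tid == "5":       # constant slope 0.5, correlation 0.5 vs rho2
        if not 0 <= j < len(_T5_RHO2):
            raise KeyError(f"design 5 has conditions 1..{len(_T5_RHO2)}")
        n1, n2 = sizes if sizes is not None else _SIZES_T2[0]
        r2 = _T5_RHO2[j]
        sy2 = 0.5 / r2
        pops = [
            GroupPopulation("g1", n1, 1.0, 1.0, 0.5),
            GroupPopulation("g2", n2, 1.0, sy2**2, 0.5),
        ]
        return _cat_spec(f"design5.c{condition_index}", pops)

    if tid in ("6", "7"):
        if not 0 <= j < len(_T67_DR0):
            raise KeyError(f"design {tid} has conditions 1..{len(_T67_DR0)}")
        n = int(sizes[0]) if sizes is not None else 70
        lam = 2.0 if tid == "7" else 0.0
        coeffs = ContinuousCoeffs(
            delta_x=(0.0, 0.5), delta_y=(0.0, 0.5), delta_r=(_T67_DR0[j], 0.0)
        )
        return ScenarioSpec(
            kind="continuous", coeffs=coeffs, n_obs=n, skew=lam,
            name=f"design{tid}.c{condition_index}",
        )

    if tid in ("sem_example", "sem"):
        n = int(sizes[0]) if sizes is not None else 300
        n2 = int(sizes[1]) if sizes is not None and len(sizes) > 1 else n
        pops = [
            GroupPopulation("video", n, 1.0, 4.0, 0.45 * 2.0),
            GroupPopulation("control", n2, 1.0, 1.0, 0.45),
        ]
        return _cat_spec("sem_example", pops)

    raise KeyError(f"unknown design id {table_id!r}")


def validate_scenario(spec: ScenarioSpec) -> dict:
    """Self-check: recompute each group's derived quantities from the raw
    (var_x, var_y, cov_xy) and confirm the design's structural promises
    (constant correlation / slope / variance ratio where the design claims
    one).  Returns the derived table for inspection."""
    out = {"name": spec.name, "groups": []}
    if spec.kind == "continuous":
        c = spec.coeffs
        out["theta1"] = c.theta1
        out["rho_at_z1"] = float(np.tanh((c.delta_r[0] + c.delta_r[1]) / 2.0))
        return out
    for pop in spec.groups:
        rho = pop.rho
        beta = pop.slope_y_on_x
        if not np.isclose(beta, rho * _SQ(pop.var_y / pop.var_x), rtol=1e-9):
            raise AssertionError("slope identity beta = rho * sd_y/sd_x violated")
        if not np.isclose(
            pop.resid_var_y, pop.var_y - pop.cov_xy**2 / pop.var_x, rtol=1e-9
        ):
            raise AssertionError("error-variance identity violated")
        out["groups"].append(
            {
                "label": pop.label,
                "n": pop.n,
                "rho": rho,
                "beta_y": beta,
                "resid_var_y": pop.resid_var_y,
                "variance_ratio": pop.variance_ratio,
            }
        )
    return out


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------


def scenario_to_file(spec: ScenarioSpec, path) -> None:
    path = Path(path)
    d = asdict(spec)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def scenario_from_file(path) -> ScenarioSpec:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix.lower() in (".yaml", ".yml") else json.loads(text)
    groups = tuple(GroupPopulation(**g) for g in d.get("groups", ()))
    coeffs = d.get("coeffs")
    if coeffs is not None:
        coeffs = ContinuousCoeffs(
            **{k: tuple(v) for k, v in coeffs.items()}
        )
    return ScenarioSpec(
        kind=d["kind"], groups=groups, coeffs=coeffs,
        n_obs=d.get("n_obs"), skew=d.get("skew", 0.0),
        seed=d.get("seed"), name=d.get("name", ""),
    )
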