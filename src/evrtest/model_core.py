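"""Bivariate-normal substrate for moderation analysis.

The statistical object throughout the package is a pair of continuous
variables (X, Y) whose joint distribution, conditional on a moderator Z,
is bivariate normal with moderator-dependent moments.  The moments are
tied to Z through three link-function submodels,

    log sigma_x(z) = D_x(z) . delta_x
    log sigma_y(z) = D_y(z) . delta_y
    log[(1 + rho(z)) / (1 - rho(z))] = D_r(z) . delta_r        (Fisher link)

plus (as a modelling convenience, since the likelihood needs them) mean
submodels mu_x(z) = D_m(z) . gamma_x and mu_y(z) = D_m(z) . gamma_y.  For a
categorical moderator the design rows are an intercept plus indicator
columns; for a continuous moderator they are an intercept plus z.

The quantity of scientific interest is the variance-ratio contrast

    theta = delta_y - delta_x        (elementwise, excluding intercepts)

because exp(theta) equals the ratio of slope ratios to correlation ratios
between moderator states: slopes and correlations are equivalently
moderated iff theta = 0 (equal variance ratios, "EVR").

Everything in this module is deliberately exact or analytic: closed-form
moment estimators with the ML (divisor-n) convention, the exact bivariate
normal log-likelihood under the links, its analytic score, and the observed
information for coefficient covariances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TWO_PI",
    "RHO_CLAMP",
    "DegenerateDataError",
    "NumericError",
    "SingularInformationError",
    "ConvergenceError",
    "BivariateSample",
    "GroupMoments",
    "ModelSpec",
    "ParamVector",
    "ModelFit",
    "TestConfig",
    "group_moments",
    "all_group_moments",
    "fisher_link",
    "fisher_inverse",
    "slope_from_correlation",
    "heev_ratio",
    "HeevCheck",
    "bivariate_normal_loglik",
    "loglik_and_score",
    "coefficient_covariance",
    "variance_information",
    "group_parameter_covariance",
    "saturated_loglik",
]

TWO_PI = 2.0 * np.pi
#: correlations are clamped to +/- (1 - 1e-10) inside the likelihood so the
#: Fisher link cannot overflow at boundary samples
RHO_CLAMP = 1.0 - 1e-10
_LOG_SD_CLAMP = 40.0


class DegenerateDataError(ValueError):
    """A group or variable carries no usable variation (or too few rows)."""


class NumericError(FloatingPointError):
    """The log-likelihood became non-finite; the message names the row."""


class SingularInformationError(np.linalg.LinAlgError):
    """Observed information is singular.

    Usually caused by a collinear design matrix or an estimate on the
    boundary of the parameter space; reparameterize or drop columns.
    """


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge; carries a trace summary."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BivariateSample:
    """Paired observations (x, y) with a categorical or continuous moderator.

    Parameters
    ----------
    x, y : array-like of float, same length, no missing values.
    moderator : array-like
        Group labels (``kind="categorical"``) or real values
        (``kind="continuous"``).
    kind : {"categorical", "continuous"}
    """

    x: np.ndarray
    y: np.ndarray
    moderator: np.ndarray
    kind: str = "categorical"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown moderator kind {self.kind!r}")
        if self.kind == "continuous":
            z = np.asarray(self.moderator, dtype=float)
        else:
            z = np.asarray(self.moderator, dtype=object)
        if x.ndim != 1 or y.ndim != 1 or z.ndim != 1:
            raise ValueError("x, y and moderator must be one-dimensional")
        if not (len(x) == len(y) == len(z)):
            raise ValueError("x, y and moderator must have equal length")
        if len(x) < 1:
            raise ValueError("empty sample")
        for name, v in (("x", x), ("y", y)):
            if not np.all(np.isfinite(v)):
                i = int(np.flatnonzero(~np.isfinite(v))[0])
                raise ValueError(f"missing/non-finite value in {name} at row {i}")
        if self.kind == "continuous":
            if not np.all(np.isfinite(z)):
                i = int(np.flatnonzero(~np.isfinite(z))[0])
                raise ValueError(f"missing/non-finite moderator at row {i}")
        else:
            for i, lab in enumerate(z):
                if lab is None or (isinstance(lab, float) and np.isnan(lab)):
                    raise ValueError(f"missing moderator label at row {i}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "moderator", z)

    @property
    def n(self) -> int:
        return len(self.x)

    def labels(self) -> list:
        """Distinct categorical labels in order of first appearance."""
        if self.kind != "categorical":
            raise ValueError("labels() requires a categorical moderator")
        seen: dict = {}
        for lab in self.moderator:
            seen.setdefault(lab, None)
        return list(seen)

    def group(self, label) -> tuple[np.ndarray, np.ndarray]:
        mask = np.array([lab == label for lab in self.moderator], dtype=bool)
        if not mask.any():
            raise KeyError(f"no rows with moderator label {label!r}")
        return self.x[mask], self.y[mask]


@dataclass(frozen=True)
class GroupMoments:
    """Per-group sufficient statistics under the ML (divisor-n) convention."""

    label: object
    n: int
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    r: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be positive")
        if not (self.sd_x > 0 and self.sd_y > 0):
            raise DegenerateDataError("standard deviations must be positive")
        if not abs(self.r) < 1:
            raise DegenerateDataError("|r| must be < 1 (collinear group)")

    @property
    def slope_y_on_x(self) -> float:
        return slope_from_correlation(self.r, self.sd_y, self.sd_x)

    @property
    def slope_x_on_y(self) -> float:
        return slope_from_correlation(self.r, self.sd_x, self.sd_y)

    @property
    def log_variance_ratio(self) -> float:
        """log(sd_y / sd_x); group-level half-log variance ratio."""
        return float(np.log(self.sd_y) - np.log(self.sd_x))


def group_moments(sample: BivariateSample, label) -> GroupMoments:
    """ML moments (divisor n) of one moderator category.

    Raises
    ------
    DegenerateDataError
        If the group has fewer than 4 rows, a zero-variance variable, or a
        perfectly collinear (|r| = 1) configuration.
    """
    x, y = sample.group(label)
    n = len(x)
    if n < 4:
        raise DegenerateDataError(f"group {label!r} has n={n} < 4")
    mx, my = float(np.mean(x)), float(np.mean(y))
    vx = float(np.mean((x - mx) ** 2))
    vy = float(np.mean((y - my) ** 2))
    if vx <= 0:
        raise DegenerateDataError(f"zero variance in x for group {label!r}")
    if vy <= 0:
        raise DegenerateDataError(f"zero variance in y for group {label!r}")
    cxy = float(np.mean((x - mx) * (y - my)))
    r = cxy / np.sqrt(vx * vy)
    if not abs(r) < 1:
        raise DegenerateDataError(
            f"|r| = 1 in group {label!r}: x and y are collinear"
        )
    return GroupMoments(label, n, mx, my, float(np.sqrt(vx)), float(np.sqrt(vy)), r)


def all_group_moments(sample: BivariateSample) -> list[GroupMoments]:
    return [group_moments(sample, lab) for lab in sample.labels()]


# ---------------------------------------------------------------------------
# link functions and elementary identities
# ---------------------------------------------------------------------------


def fisher_link(rho: float) -> float:
    """Fisher link log((1 + rho)/(1 - rho)) = 2 atanh(rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1):
        raise ValueError("fisher_link requires |rho| < 1")
    out = 2.0 * np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def fisher_inverse(eta: float) -> float:
    """Exact inverse of :func:`fisher_link`: tanh(eta / 2)."""
    out = np.tanh(np.asarray(eta, dtype=float) / 2.0)
    return float(out) if out.ndim == 0 else out


def slope_from_correlation(rho: float, sd_y: float, sd_x: float) -> float:
    """Unstandardized regression slope beta_y = rho * sd_y / sd_x."""
    if not (sd_x > 0 and sd_y > 0):
        raise ValueError("standard deviations must be positive")
    return float(rho * sd_y / sd_x)


class HeevCheck(NamedTuple):
    lhs: float
    rhs: float
    satisfied: bool


def heev_ratio(
    rho_i: float,
    rho_j: float,
    var_yi: float,
    var_yj: float,
    rel_tol: float = 1e-9,
) -> HeevCheck:
    """Check the homogeneous-error-variance (HeEV) balance condition.

    Regression of Y on X has equal error variances in groups i and j exactly
    when var_yi / var_yj = (1 - rho_j^2)/(1 - rho_i^2).  Returns both sides
    and whether they agree within ``rel_tol``.  The condition is logically
    independent of equal variance ratios.
    """
    if not (abs(rho_i) < 1 and abs(rho_j) < 1):
        raise ValueError("correlations must satisfy |rho| < 1")
    if not (var_yi > 0 and var_yj > 0):
        raise ValueError("variances must be positive")
    lhs = var_yi / var_yj
    rhs = (1.0 - rho_j**2) / (1.0 - rho_i**2)
    satisfied = abs(lhs - rhs) <= rel_tol * max(abs(lhs), abs(rhs))
    return HeevCheck(float(lhs), float(rhs), bool(satisfied))


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Design matrices (and constraint tags) for the four submodels.

    All four design matrices share their row count; rows correspond either
    to observations (row-level fits) or to moderator categories
    (moment-level fits, where each group contributes one design row).
    """

    design_x: np.ndarray
    design_y: np.ndarray
    design_r: np.ndarray
    design_mean: np.ndarray
    names_x: tuple
    names_y: tuple
    names_r: tuple
    names_mean: tuple
    constraints: frozenset = frozenset()

    def __post_init__(self) -> None:
        mats = {
            "design_x": np.atleast_2d(np.asarray(self.design_x, float)),
            "design_y": np.atleast_2d(np.asarray(self.design_y, float)),
            "design_r": np.atleast_2d(np.asarray(self.design_r, float)),
            "design_mean": np.atleast_2d(np.asarray(self.design_mean, float)),
        }
        nrows = {m.shape[0] for m in mats.values()}
        if len(nrows) != 1:
            raise ValueError("design matrices must share their row count")
        for name, mat in mats.items():
            if not any(np.allclose(mat[:, j], 1.0) for j in range(mat.shape[1])):
                raise ValueError(f"{name} lacks an intercept column")
            object.__setattr__(self, name, mat)

    @property
    def n_rows(self) -> int:
        return self.design_x.shape[0]

    @property
    def n_coef(self) -> int:
        return (
            2 * self.design_mean.shape[1]
            + self.design_x.shape[1]
            + self.design_y.shape[1]
            + self.design_r.shape[1]
        )

    @classmethod
    def categorical(cls, labels: Sequence, base, constraints=frozenset()) -> "ModelSpec":
        """Intercept + indicator coding over observation rows."""
        labels = list(labels)
        cats = []
        for lab in labels:
            if lab not in cats:
                cats.append(lab)
        if base not in cats:
            raise ValueError(f"base category {base!r} not present")
        cats = [base] + [c for c in cats if c != base]
        cols = [np.ones(len(labels))]
        names = ["(intercept)"]
        for c in cats[1:]:
            cols.append(np.array([1.0 if lab == c else 0.0 for lab in labels]))
            names.append(f"[{c}]")
        design = np.column_stack(cols)
        names = tuple(names)
        return cls(design, design, design, design, names, names, names, names,
                   frozenset(constraints))

    @classmethod
    def continuous(cls, z: np.ndarray, constraints=frozenset()) -> "ModelSpec":
        """Intercept + linear-z coding; extra polynomial columns may be added
        by building the design by hand."""
        z = np.asarray(z, float)
        design = np.column_stack([np.ones_like(z), z])
        names = ("(intercept)", "z")
        return cls(design, design, design, design, names, names, names, names,
                   frozenset(constraints))


@dataclass(frozen=True)
class ParamVector:
    """Coefficients of the five submodels (means, log-SDs, Fisher-link rho)."""

    delta_x: np.ndarray
    delta_y: np.ndarray
    delta_r: np.ndarray
    gamma_x: np.ndarray
    gamma_y: np.ndarray

    def __post_init__(self) -> None:
        for name in ("delta_x", "delta_y", "delta_r", "gamma_x", "gamma_y"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite coefficient in {name}")
            object.__setattr__(self, name, v)

    def pack(self) -> np.ndarray:
        """Flatten in the canonical order gamma_x, gamma_y, delta_x, delta_y, delta_r."""
        return np.concatenate(
            [self.gamma_x, self.gamma_y, self.delta_x, self.delta_y, self.delta_r]
        )

    @staticmethod
    def unpack(vec: np.ndarray, spec: ModelSpec) -> "ParamVector":
        pm = spec.design_mean.shape[1]
        px = spec.design_x.shape[1]
        py = spec.design_y.shape[1]
        pr = spec.design_r.shape[1]
        if len(vec) != 2 * pm + px + py + pr:
            raise ValueError("packed vector length does not match spec")
        gx, gy = vec[:pm], vec[pm : 2 * pm]
        dx = vec[2 * pm : 2 * pm + px]
        dy = vec[2 * pm + px : 2 * pm + px + py]
        dr = vec[2 * pm + px + py :]
        return ParamVector(dx, dy, dr, gx, gy)


def packed_names(spec: ModelSpec) -> tuple:
    return tuple(
        [f"gx:{c}" for c in spec.names_mean]
        + [f"gy:{c}" for c in spec.names_mean]
        + [f"dx:{c}" for c in spec.names_x]
        + [f"dy:{c}" for c in spec.names_y]
        + [f"dr:{c}" for c in spec.names_r]
    )


@dataclass
class ModelFit:
    """A fitted model: coefficients, log-likelihood, covariance, bookkeeping."""

    params: ParamVector
    loglik: float
    vcov: np.ndarray
    n_free: int
    converged: bool
    spec: ModelSpec
    names: tuple = ()
    meta: dict = field(default_factory=dict)

    def coef_index(self, name: str) -> int:
        return self.names.index(name)

    def coef_cov(self, name_a: str, name_b: str) -> float:
        return float(self.vcov[self.coef_index(name_a), self.coef_index(name_b)])


@dataclass(frozen=True)
class TestConfig:
    """Hypothesis-test configuration.

    ``critical_value_family`` chooses between standard-normal critical
    values (large-sample ML default) and a t reference with
    df = sum(n_i - 2) over the two groups involved, the conventional
    independent-samples count; ``df_rule`` may override the latter.
    """

    __test__ = False  # not a test class, despite the name

    alpha: float = 0.05
    critical_value_family: str = "normal"
    df_rule: Callable[[Sequence[int]], float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.critical_value_family not in ("normal", "t"):
            raise ValueError("critical_value_family must be 'normal' or 't'")

    def dof(self, sizes: Sequence[int] | None) -> float | None:
        if self.critical_value_family == "normal":
            return None
        if self.df_rule is not None:
            return float(self.df_rule(sizes))
        if sizes is None:
            raise ValueError("t critical values need group sizes")
        return float(sum(n - 2 for n in sizes))

    def critical_value(self, sizes: Sequence[int] | None = None) -> float:
        from scipy import stats as _st

        df = self.dof(sizes)
        q = 1.0 - self.alpha / 2.0
        return float(_st.norm.ppf(q) if df is None else _st.t.ppf(q, df))

    def p_value(self, statistic: float, sizes: Sequence[int] | None = None) -> float:
        from scipy import stats as _st

        df = self.dof(sizes)
        a = np.abs(statistic)
        p = 2.0 * (_st.norm.sf(a) if df is None else _st.t.sf(a, df))
        return float(p) if np.ndim(p) == 0 else p


# ---------------------------------------------------------------------------
# the bivariate-normal log-likelihood under the links
# ---------------------------------------------------------------------------


def _link_values(params: ParamVector, spec: ModelSpec):
    a = np.clip(spec.design_x @ params.delta_x, -_LOG_SD_CLAMP, _LOG_SD_CLAMP)
    b = np.clip(spec.design_y @ params.delta_y, -_LOG_SD_CLAMP, _LOG_SD_CLAMP)
    c = spec.design_r @ params.delta_r
    rho = np.clip(np.tanh(c / 2.0), -RHO_CLAMP, RHO_CLAMP)
    mux = spec.design_mean @ params.gamma_x
    muy = spec.design_mean @ params.gamma_y
    return mux, muy, a, b, rho


def _row_logliks(params: ParamVector, spec: ModelSpec, sample: BivariateSample):
    mux, muy, a, b, rho = _link_values(params, spec)
    sx, sy = np.exp(a), np.exp(b)
    p = (sample.x - mux) / sx
    q = (sample.y - muy) / sy
    k = 1.0 - rho**2
    quad = (p**2 - 2.0 * rho * p * q + q**2) / (2.0 * k)
    return -np.log(TWO_PI) - a - b - 0.5 * np.log(k) - quad


def bivariate_normal_loglik(
    params: ParamVector, spec: ModelSpec, sample: BivariateSample
) -> float:
    """Exact bivariate-normal log-likelihood with link-function submodels.

    Positivity of the SDs and |rho| < 1 hold automatically through the log
    and Fisher links.
    """
    if spec.n_rows != sample.n:
        raise ValueError("spec rows do not match the sample")
    rows = _row_logliks(params, spec, sample)
    if not np.all(np.isfinite(rows)):
        i = int(np.flatnonzero(~np.isfinite(rows))[0])
        raise NumericError(f"non-finite log-density at row {i}")
    return float(np.sum(rows))


def loglik_and_score(
    params: ParamVector, spec: ModelSpec, sample: BivariateSample
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its analytic gradient in packed coefficient order."""
    mux, muy, a, b, rho = _link_values(params, spec)
    sx, sy = np.exp(a), np.exp(b)
    p = (sample.x - mux) / sx
    q = (sample.y - muy) / sy
    k = 1.0 - rho**2
    Q = p**2 - 2.0 * rho * p * q + q**2
    rows = -np.log(TWO_PI) - a - b - 0.5 * np.log(k) - Q / (2.0 * k)
    s_mux = (p - rho * q) / (k * sx)
    s_muy = (q - rho * p) / (k * sy)
    s_a = -1.0 + p * (p - rho * q) / k
    s_b = -1.0 + q * (q - rho * p) / k
    s_c = (rho + p * q - Q * rho / k) / 2.0
    grad = np.concatenate(
        [
            spec.design_mean.T @ s_mux,
            spec.design_mean.T @ s_muy,
            spec.design_x.T @ s_a,
            spec.design_y.T @ s_b,
            spec.design_r.T @ s_c,
        ]
    )
    return float(np.sum(rows)), grad


def coefficient_covariance(
    params: ParamVector,
    spec: ModelSpec,
    sample: BivariateSample,
    step: float = 1e-5,
) -> np.ndarray:
    """Observed-information covariance of the free coefficients.

    Central finite differences of the analytic score give the Hessian; the
    covariance is the inverse of the negative (symmetrized) Hessian.  Meant
    to be evaluated at a local maximum of the log-likelihood.
    """
    p0 = params.pack()
    m = len(p0)
    H = np.empty((m, m))
    for j in range(m):
        h = step * (1.0 + abs(p0[j]))
        pp, pm = p0.copy(), p0.copy()
        pp[j] += h
        pm[j] -= h
        _, gp = loglik_and_score(ParamVector.unpack(pp, spec), spec, sample)
        _, gm = loglik_and_score(ParamVector.unpack(pm, spec), spec, sample)
        H[:, j] = (gp - gm) / (2.0 * h)
    info = -(H + H.T) / 2.0
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(
            "singular observed information: check for collinear design "
            "columns or an estimate on the parameter-space boundary"
        ) from exc
    if np.linalg.cond(info) > 1e12:
        raise SingularInformationError(
            "ill-conditioned observed information: check for collinear "
            "design columns or an estimate on the parameter-space boundary"
        )
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# closed forms for the per-group (saturated) model
# ---------------------------------------------------------------------------


def variance_information(rho: float | np.ndarray) -> np.ndarray:
    """Per-observation Fisher information of (log sd_x, log sd_y, fisher(rho)).

    The symmetric 3x3 block; the mean parameters are information-orthogonal
    to it.  Derived from the bivariate-normal score moments; validated in
    the test suite against a finite-difference Hessian.
    """
    rho = np.asarray(rho, float)
    k = 1.0 - rho**2
    I = np.empty(rho.shape + (3, 3))
    I[..., 0, 0] = I[..., 1, 1] = (2.0 - rho**2) / k
    I[..., 0, 1] = I[..., 1, 0] = -(rho**2) / k
    I[..., 0, 2] = I[..., 2, 0] = -rho / 2.0
    I[..., 1, 2] = I[..., 2, 1] = -rho / 2.0
    I[..., 2, 2] = (1.0 + rho**2) / 4.0
    return I


def group_parameter_covariance(m: GroupMoments) -> np.ndarray:
    """Asymptotic covariance of (mu_x, mu_y, log sd_x, log sd_y, fisher coef).

    Evaluated at the group's own ML estimates; equals the inverse observed
    information of the saturated fit (for the saturated bivariate normal the
    observed and expected information coincide at the MLE because the
    Hessian depends on the data only through moments that the MLE matches).
    """
    cov = np.zeros((5, 5))
    cov[0, 0] = m.sd_x**2
    cov[1, 1] = m.sd_y**2
    cov[0, 1] = cov[1, 0] = m.r * m.sd_x * m.sd_y
    cov[2:, 2:] = np.linalg.inv(variance_information(m.r))
    return cov / m.n


def saturated_loglik(groups: Sequence[GroupMoments]) -> float:
    """Maximized log-likelihood of the unrestricted multi-group model.

    At the MLE every group's standardized quadratic form collapses to a
    constant, leaving sum_i n_i [-log(2 pi) - log(sd_x sd_y) - 0.5 log(1 -
    r^2) - 1].
    """
    total = 0.0
    for g in groups:
        total += g.n * (
            -np.log(TWO_PI)
            - np.log(g.sd_x * g.sd_y)
            - 0.5 * np.log1p(-g.r**2)
            - 1.0
        )
    return float(total)
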