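"""Detection-function fitting for line-transect distance sampling.

Implements maximum-likelihood fitting of the two standard detection
keys, half-normal ``g(x) = exp(-x^2 / 2 sigma^2)`` and hazard-rate
``g(x) = 1 - exp(-(x/sigma)^-b)``, with observation-level covariates
entering the scale on the log link, ``sigma(z) = exp(b0 + sum b_j z_j)``
(the conditional-likelihood MCDS formulation).  Null models may carry
cosine series adjustments instead of covariates.

The conditional likelihood of the observed perpendicular distances is

    L = prod_i g(x_i | z_i) / mu(z_i),   mu(z) = int_0^w g(u | z) du,

with ``mu`` the effective (half-)strip width (ESW) and ``w`` the
truncation distance.  Model choice is by AIC; absolute fit is screened
with a Cramér–von Mises test on the fitted (conditional) CDFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

HALF_NORMAL = "half_normal"
HAZARD_RATE = "hazard_rate"

#: candidate covariates understood by the design-matrix builder
KNOWN_COVARIATES = ("obs", "size", "wind_speed", "vessel")

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)

_JITTER_SEED = 20190109  # fixed: restarts are part of the deterministic contract


class FitError(RuntimeError):
    """Raised when a detection fit fails to converge."""


@dataclass(frozen=True)
class DetectionModel:
    """Specification of a detection-function model."""

    key: str
    formula: tuple[str, ...] = ()
    w_m: float = 7000.0
    adjustment_orders: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.key not in (HALF_NORMAL, HAZARD_RATE):
            raise ValueError(f"unknown key {self.key!r}")
        if self.w_m <= 0:
            raise ValueError("truncation width must be positive")
        unknown = set(self.formula) - set(KNOWN_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if self.formula and self.adjustment_orders:
            raise ValueError("series adjustments are for null models only")

    @property
    def label(self) -> str:
        f = " + ".join(self.formula) if self.formula else "1"
        adj = (
            f" + cos({','.join(map(str, self.adjustment_orders))})"
            if self.adjustment_orders
            else ""
        )
        return f"{self.key}~{f}{adj}"


@dataclass
class DetectionFit:
    """A converged detection-function fit."""

    model: DetectionModel
    params: np.ndarray
    param_names: list[str]
    loglik: float
    aic: float
    n: int
    esw_m: np.ndarray  # per-observation effective strip width mu_i
    p: np.ndarray  # per-observation detectability p_i = mu_i / w
    pa: float  # average detectability
    se_pa: float
    vcov: np.ndarray
    distances_m: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)
    cvm_stat: float = float("nan")
    cvm_p: float = float("nan")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def summary(self) -> dict:
        return {
            "key": self.model.key,
            "formula": self.model.label,
            "n": self.n,
            "loglik": self.loglik,
            "aic": self.aic,
            "pa": self.pa,
            "se_pa": self.se_pa,
            "cvm_stat": self.cvm_stat,
            "cvm_p": self.cvm_p,
            "params": dict(zip(self.param_names, self.params.tolist())),
        }


# ---------------------------------------------------------------------------
# key functions


def g_half_normal(x, sigma):
    """Half-normal detection probability ``exp(-x^2 / 2 sigma^2)``."""
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    return np.exp(-(x**2) / (2.0 * np.square(sigma)))


def g_hazard_rate(x, sigma, b):
    """Hazard-rate detection probability ``1 - exp(-(x/sigma)^-b)``.

    The limit at x=0 is 1, taken as the defined value.  Shape ``b``
    controls the width of the shoulder.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(sigma) <= 0) or np.any(np.asarray(b) <= 0):
        raise ValueError("sigma and b must be positive")
    with np.errstate(divide="ignore", over="ignore"):
        t = np.power(x / sigma, -np.asarray(b, dtype=float))
    out = -np.expm1(-t)
    return np.where(x == 0, 1.0, out)


def _log_g(x, sigma, key, b=None):
    """log g(x); numerically safe for extreme arguments."""
    x = np.asarray(x, dtype=float)
    if key == HALF_NORMAL:
        return -(x**2) / (2.0 * np.square(sigma))
    with np.errstate(divide="ignore", over="ignore"):
        t = np.power(x / sigma, -b)
    small = t < 1e-8
    with np.errstate(divide="ignore"):
        out = np.where(
            small,
            np.log(np.maximum(t, 1e-300)),  # g ~ t as t -> 0
            np.log(-np.expm1(-np.minimum(t, 700.0))),
        )
    return np.where(x == 0, 0.0, out)


def _cosine_factor(x, w, orders, coefs):
    """Series adjustment factor (1 + sum a_m cos(m pi x / w)) / (1 + sum a_m)."""
    x = np.asarray(x, dtype=float)
    num = np.ones_like(x)
    for m, a in zip(orders, coefs):
        num = num + a * np.cos(m * np.pi * x / w)
    return num / (1.0 + np.sum(coefs))


def detection_probability(model: DetectionModel, x, sigma, b=None, adj_coefs=()):
    """Evaluate g(x) for a model with given scale (and shape/adjustments)."""
    if model.key == HALF_NORMAL:
        g = g_half_normal(x, sigma)
    else:
        g = g_hazard_rate(x, sigma, b)
    if model.adjustment_orders:
        g = g * _cosine_factor(x, model.w_m, model.adjustment_orders, np.asarray(adj_coefs))
    return g


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(
    sightings: pd.DataFrame, formula: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the log-scale linear predictor.

    Continuous covariates: ``wind_speed`` enters raw (m/s), ``size`` as
    the natural log of group size.  ``obs`` and ``vessel`` are
    categorical with treatment coding, reference level the
    alphabetically first.  A categorical with a single level is dropped
    with a warning.
    """
    cols = [np.ones(len(sightings))]
    names = ["(intercept)"]
    for cov in formula:
        if cov == "wind_speed":
            cols.append(sightings["wind_speed_ms"].to_numpy(dtype=float))
            names.append("wind_speed")
        elif cov == "size":
            cols.append(np.log(sightings["group_size"].to_numpy(dtype=float)))
            names.append("log_size")
        elif cov in ("obs", "vessel"):
            src = "observer" if cov == "obs" else "vessel"
            levels = sorted(sightings[src].astype(str).unique())
            if len(levels) < 2:
                warnings.warn(
                    f"covariate {cov!r} has a single level and was dropped",
                    stacklevel=2,
                )
                continue
            for level in levels[1:]:
                cols.append((sightings[src].astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        else:  # pragma: no cover - guarded by DetectionModel
            raise ValueError(f"unknown covariate {cov!r}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# ESW / quadrature


def effective_strip_width(
    model: DetectionModel, sigma, b=None, adj_coefs=()
) -> np.ndarray | float:
    """ESW ``mu = int_0^w g(u) du`` by 64-node Gauss-Legendre quadrature.

    ``sigma`` may be a scalar or an array (per observation); the result
    has matching shape.  Values lie in (0, w].
    """
    w = model.w_m
    u = 0.5 * w * (_GL_NODES + 1.0)  # nodes on [0, w]
    wt = 0.5 * w * _GL_WEIGHTS
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    g = detection_probability(model, u[None, :], sig[:, None], b=b, adj_coefs=adj_coefs)
    mu = g @ wt
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise FitError("quadrature produced a non-finite or non-positive ESW")
    mu = np.minimum(mu, w)
    return float(mu[0]) if np.isscalar(sigma) else mu


# ---------------------------------------------------------------------------
# likelihood machinery


def _unpack(theta, model: DetectionModel, n_beta: int):
    i = 0
    b = None
    if model.key == HAZARD_RATE:
        b = np.exp(theta[0])
        i = 1
    beta = theta[i : i + n_beta]
    adj = theta[i + n_beta :]
    return b, beta, adj


def _adjustment_valid(model: DetectionModel, b, sigma0, adj) -> bool:
    """Check non-negativity of the adjusted g on a dense grid."""
    grid = np.linspace(0.0, model.w_m, 201)
    g = detection_probability(model, grid, sigma0, b=b, adj_coefs=adj)
    return bool(np.all(np.isfinite(g)) and np.min(g) >= -1e-12)


def _nll(theta, model, X, x, n_beta):
    BIG = 1e10  # finite penalty keeps L-BFGS-B finite-difference gradients clean
    b, beta, adj = _unpack(theta, model, n_beta)
    eta = X @ beta
    if np.any(eta > 50) or not np.all(np.isfinite(eta)):
        return BIG
    sigma = np.exp(eta)
    if model.adjustment_orders:
        if 1.0 + np.sum(adj) <= 1e-6 or not _adjustment_valid(model, b, sigma[0], adj):
            return BIG
        g = detection_probability(model, x, sigma, b=b, adj_coefs=adj)
        if np.any(g <= 0):
            return BIG
        log_g = np.log(g)
    else:
        log_g = _log_g(x, sigma, model.key, b)
    # ESW per unique scale value (cheap for null / categorical models)
    uniq, inv = np.unique(sigma, return_inverse=True)
    try:
        mu = effective_strip_width(model, uniq, b=b, adj_coefs=adj)
    except FitError:
        return BIG
    mu = np.atleast_1d(mu)[inv]
    val = -(np.sum(log_g) - np.sum(np.log(mu)))
    return val if np.isfinite(val) else BIG


def _initial_theta(model, x, n_beta):
    if model.key == HALF_NORMAL:
        s0 = np.sqrt(np.mean(x**2)) if np.mean(x**2) > 0 else model.w_m / 10
        theta = [np.log(max(s0, 1e-3))]
    else:
        s0 = max(np.median(x), 1e-3)
        theta = [np.log(2.0), np.log(s0)]
    theta += [0.0] * (n_beta - 1)
    theta += [0.0] * len(model.adjustment_orders)
    return np.asarray(theta, dtype=float)


def fit_detection(
    sightings: pd.DataFrame,
    key: str,
    formula: Sequence[str] = (),
    w_m: float = 7000.0,
    adjustment_orders: Sequence[int] = (),
    n_restarts: int = 5,
) -> DetectionFit:
    """Fit a detection function by maximum likelihood.

    ``sightings`` must carry ``perp_distance_m`` plus any covariate
    columns the formula needs.  The optimiser (L-BFGS-B) is run from a
    heuristic start and ``n_restarts`` jittered starts with a fixed
    jitter seed, so the fit is deterministic given the data.
    """
    model = DetectionModel(
        key=key, formula=tuple(formula), w_m=w_m,
        adjustment_orders=tuple(adjustment_orders),
    )
    x = sightings["perp_distance_m"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise FitError("need at least 2 distinct perpendicular distances")
    if np.any(x < 0) or np.any(x > w_m):
        raise ValueError("distances outside [0, w]; truncate first")

    X, names = build_design_matrix(sightings, model.formula)
    n_beta = X.shape[1]
    theta0 = _initial_theta(model, x, n_beta)

    rng = np.random.default_rng(_JITTER_SEED)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 0.3, size=theta0.size) for _ in range(n_restarts)
    ]
    best = None
    diagnostics = []
    for start in starts:
        res = optimize.minimize(
            _nll,
            start,
            args=(model, X, x, n_beta),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        diagnostics.append(res.message)
        if np.isfinite(res.fun) and res.fun < 1e9 and (
            best is None or res.fun < best.fun - 1e-10
        ):
            best = res
    if best is None:
        raise FitError(f"optimisation failed from all starts: {diagnostics}")

    theta = best.x
    loglik = -best.fun
    b, beta, adj = _unpack(theta, model, n_beta)
    sigma = np.exp(X @ beta)
    if np.exp(beta[0]) > 2 * w_m:
        warnings.warn(
            "fitted scale exceeds 2x the truncation width; the distance "
            "distribution shows no decline (boundary fit)",
            stacklevel=2,
        )

    mu = np.atleast_1d(effective_strip_width(model, sigma, b=b, adj_coefs=adj))
    p = mu / w_m

    param_names = (["log_shape"] if model.key == HAZARD_RATE else []) + names + [
        f"cos{m}" for m in model.adjustment_orders
    ]
    vcov = _numeric_vcov(theta, model, X, x, n_beta)
    fit = DetectionFit(
        model=model,
        params=theta,
        param_names=param_names,
        loglik=float(loglik),
        aic=float(2 * len(theta) - 2 * loglik),
        n=len(x),
        esw_m=mu,
        p=p,
        pa=float("nan"),
        se_pa=float("nan"),
        vcov=vcov,
        distances_m=x,
        design=X,
    )
    fit.pa, fit.se_pa = average_detectability(fit)
    fit.cvm_stat, fit.cvm_p = cvm_test(fit)
    return fit


def fit_with_adjustments(
    sightings: pd.DataFrame,
    key: str,
    cosine_orders: Sequence[int],
    w_m: float = 7000.0,
) -> DetectionFit:
    """Fit a covariate-free key with cosine series adjustments."""
    return fit_detection(
        sightings, key, formula=(), w_m=w_m, adjustment_orders=tuple(cosine_orders)
    )


def _numeric_vcov(theta, model, X, x, n_beta) -> np.ndarray:
    """Observed-information covariance by central-difference Hessian."""
    k = theta.size
    h = 1e-4 * (1.0 + np.abs(theta))
    H = np.empty((k, k))
    f0 = _nll(theta, model, X, x, n_beta)

    def f(t):
        v = _nll(t, model, X, x, n_beta)
        return v if v < 1e9 else f0 + 1e6

    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        return np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full((k, k), np.nan)


# ---------------------------------------------------------------------------
# derived quantities


def average_detectability(fit: DetectionFit) -> tuple[float, float]:
    """Average detectability ``P_a = n / sum_i 1/p_i`` with delta-method se.

    This is the Horvitz-Thompson-consistent estimate of the
    population-average detection probability within the truncated strip;
    with no covariates it reduces to ``mu / w`` exactly.
    """
    if np.any(fit.p <= 0):
        raise ValueError("non-positive detection probability")
    pa = fit.n / np.sum(1.0 / fit.p)

    model, X, x, n_beta = fit.model, fit.design, fit.distances_m, fit.design.shape[1]

    def pa_of(theta):
        b, beta, adj = _unpack(theta, model, n_beta)
        sigma = np.exp(X @ beta)
        mu = np.atleast_1d(effective_strip_width(model, sigma, b=b, adj_coefs=adj))
        return fit.n / np.sum(model.w_m / mu)

    h = 1e-5 * (1.0 + np.abs(fit.params))
    grad = np.empty(fit.params.size)
    for i in range(fit.params.size):
        e = np.zeros(fit.params.size); e[i] = h[i]
        grad[i] = (pa_of(fit.params + e) - pa_of(fit.params - e)) / (2 * h[i])
    var = float(grad @ fit.vcov @ grad)
    se = float(np.sqrt(var)) if var > 0 else float("nan")
    return float(pa), se


def conditional_cdf_values(fit: DetectionFit) -> np.ndarray:
    """PIT values ``u_i = F_i(x_i)`` under each observation's fitted CDF.

    ``F_i(x) = int_0^x g_i / mu_i``; under a correct model the u_i are
    iid uniform on (0, 1).
    """
    model = fit.model
    b, beta, adj = _unpack(fit.params, model, fit.design.shape[1])
    sigma = np.exp(fit.design @ beta)
    x = fit.distances_m
    # per-observation integral over [0, x_i]
    u = 0.5 * x[:, None] * (_GL_NODES[None, :] + 1.0)
    wt = 0.5 * x[:, None] * _GL_WEIGHTS[None, :]
    g = detection_probability(model, u, np.atleast_1d(sigma)[:, None], b=b, adj_coefs=adj)
    num = np.sum(g * wt, axis=1)
    return np.clip(num / fit.esw_m, 0.0, 1.0)


def cvm_test(fit: DetectionFit) -> tuple[float, float]:
    """Cramér–von Mises goodness-of-fit on the fitted conditional CDFs.

    The statistic is computed from the probability-integral transforms
    of the observed distances; the p-value uses the classical asymptotic
    distribution (no parameter-estimation correction — the screen is at
    p > 0.05 only).
    """
    if fit.n < 5:
        raise ValueError("Cramér–von Mises test needs at least 5 observations")
    u = conditional_cdf_values(fit)
    res = stats.cramervonmises(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def model_selection(fits: Sequence[DetectionFit]) -> pd.DataFrame:
    """AIC ranking of candidate fits on one dataset.

    Columns mirror the standard model-selection table: key, formula,
    CvM p-value, average detectability with se, and AIC difference to
    the best model, sorted ascending by AIC.
    """
    if not fits:
        raise ValueError("no fits supplied")
    ref = fits[0]
    for f in fits[1:]:
        if f.n != ref.n or f.model.w_m != ref.model.w_m or not np.array_equal(
            np.sort(f.distances_m), np.sort(ref.distances_m)
        ):
            raise ValueError("model selection requires fits on identical data")
    rows = [
        {
            "key": f.model.key,
            "formula": f.model.label,
            "n_params": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
            "cvm_p": f.cvm_p,
            "pa": f.pa,
            "se_pa": f.se_pa,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table


def plot_detection(fit: DetectionFit, ax=None, bins: int = 20):
    """Histogram of perpendicular distances with the fitted average g(x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = fit.distances_m
    w = fit.model.w_m
    ax.hist(x, bins=bins, range=(0, w), density=True, alpha=0.4, label="observed")
    grid = np.linspace(0, w, 200)
    b, beta, adj = _unpack(fit.params, fit.model, fit.design.shape[1])
    sigma = np.exp(fit.design @ beta)
    # average pdf over observed covariates
    g = detection_probability(
        fit.model, grid[None, :], np.atleast_1d(sigma)[:, None], b=b, adj_coefs=adj
    )
    pdf = np.mean(g / fit.esw_m[:, None], axis=0)
    ax.plot(grid, pdf, label="fitted")
    ax.set_xlabel("perpendicular distance (m)")
    ax.set_ylabel("density")
    ax.legend()
    return ax
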