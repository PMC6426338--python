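"""Generalized least squares with spatial correlation and window random effects.

The paired analyses need linear models whose residuals are correlated in
space: observations a few cells apart share unmodelled regional influences.
Residual correlation is modelled as a parametric function of the Euclidean
distance between observations in raw (longitude, latitude) degrees, with one
of five classical families (exponential, gaussian, rational quadratic,
spherical, linear) plus an independence reference.  The paired design adds a
random intercept per search window, entering the marginal covariance as a
constant ``variance_ratio`` (window variance over residual variance) between
observations of the same window.

Estimation profiles out the fixed effects and the residual variance, leaving
a 1- or 2-parameter likelihood in (range, variance_ratio) that is maximized
numerically (multi-start, log-transformed parameters).  REML is used for
reported coefficients and standard errors; ML log-likelihoods are kept on
every fit so AICc values are comparable across correlation structures with
identical fixed effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize, stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CorrelationStructure",
    "ModelFit",
    "ConvergenceError",
    "correlation_value",
    "build_covariance",
    "fit_gls",
    "fit_paired_model",
    "aicc",
    "select_structure",
    "select_paired_structure",
    "INDEPENDENCE",
]

FAMILIES = ("spherical", "linear", "rational_quadratic", "gaussian", "exponential", "independence")


class ConvergenceError(RuntimeError):
    """Raised when the covariance-parameter optimization fails outright."""


@dataclass(frozen=True)
class CorrelationStructure:
    """A named spatial correlation family with a range parameter in degrees."""

    family: str
    range: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family != "independence" and self.range is not None and self.range <= 0:
            raise ValueError("range must be positive")

    @property
    def has_range(self) -> bool:
        return self.family != "independence"

    def with_range(self, r: float) -> "CorrelationStructure":
        return CorrelationStructure(self.family, r)


INDEPENDENCE = CorrelationStructure("independence")


def correlation_value(structure: CorrelationStructure, d) -> np.ndarray:
    """Correlation at distance ``d`` (degrees) under a structure.

    All families equal 1 at zero distance and decay monotonically:
    exponential exp(−d/r); gaussian exp(−(d/r)²); rational quadratic
    1/(1+(d/r)²); spherical 1 − 1.5(d/r) + 0.5(d/r)³ inside the range, 0
    beyond; linear 1 − d/r inside the range, 0 beyond.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if structure.family == "independence":
        return np.where(d == 0, 1.0, 0.0)
    r = structure.range
    if r is None or r <= 0:
        raise ValueError("structure needs a positive range")
    h = d / r
    if structure.family == "exponential":
        return np.exp(-h)
    if structure.family == "gaussian":
        return np.exp(-(h**2))
    if structure.family == "rational_quadratic":
        return 1.0 / (1.0 + h**2)
    if structure.family == "spherical":
        return np.where(h < 1.0, 1.0 - 1.5 * h + 0.5 * h**3, 0.0)
    # linear
    return np.where(h < 1.0, 1.0 - h, 0.0)


def build_covariance(
    coords: np.ndarray,
    structure: CorrelationStructure,
    variance_ratio: float | None = None,
    window_ids: Sequence | None = None,
) -> np.ndarray:
    """Observation covariance up to the residual-variance scale.

    ``V = ratio·(same-window indicator) + C`` with
    ``C[i, j] = correlation(structure, ||coords_i − coords_j||)``; the
    diagonal is therefore ``1 + ratio``.  Coordinates are (lon, lat) degrees.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2) lon/lat")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    n = coords.shape[0]
    if structure.family == "independence":
        V = np.eye(n)
    else:
        D = squareform(pdist(coords))
        V = correlation_value(structure, D)
        np.fill_diagonal(V, 1.0)
    if variance_ratio is not None:
        if window_ids is None:
            raise ValueError("variance_ratio requires window_ids")
        w = np.asarray(window_ids)
        V = V + variance_ratio * (w[:, None] == w[None, :])
    return V


@dataclass
class ModelFit:
    """A fitted (mixed) GLS model.

    Coefficients, standard errors and 95% CIs come from the requested
    likelihood (REML by default); both ML and REML log-likelihoods are
    evaluated at the fitted covariance parameters so the fit can enter an
    AICc comparison.  ``k`` counts fixed effects, the correlation range,
    the window variance ratio when present, and the residual variance.
    """

    names: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci95: np.ndarray  # (p, 2)
    t_values: np.ndarray
    p_values: np.ndarray
    df: np.ndarray
    log_likelihood_ml: float
    log_likelihood_reml: float
    n: int
    k: int
    sigma2: float
    variance_ratio: float | None
    structure: CorrelationStructure
    residuals: np.ndarray
    fitted: np.ndarray
    method: str = "REML"
    converged: bool = True
    jitter: float = 0.0

    @property
    def log_likelihood(self) -> float:
        return self.log_likelihood_reml if self.method == "REML" else self.log_likelihood_ml

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood_ml, self.k, self.n)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def summary_dict(self) -> dict:
        return {
            "coefficients": {
                nm: {
                    "estimate": float(b),
                    "se": float(s),
                    "ci95": [float(lo), float(hi)],
                    "t": float(t),
                    "p": float(p),
                    "df": float(d),
                }
                for nm, b, s, (lo, hi), t, p, d in zip(
                    self.names,
                    self.coefficients,
                    self.standard_errors,
                    self.ci95,
                    self.t_values,
                    self.p_values,
                    self.df,
                )
            },
            "logLik_ML": self.log_likelihood_ml,
            "logLik_REML": self.log_likelihood_reml,
            "AICc": self.aicc,
            "n": self.n,
            "k": self.k,
            "sigma2": self.sigma2,
            "variance_ratio": self.variance_ratio,
            "structure": {"family": self.structure.family, "range": self.structure.range},
            "method": self.method,
            "converged": self.converged,
            "jitter": self.jitter,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.summary_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: −2·logLik + 2k + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# profiled likelihood machinery
# ---------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


class _Profile:
    """Profiled (RE)ML negative log-likelihood over covariance parameters.

    Distances and the window indicator are cached; each evaluation builds V,
    factorizes it, and profiles beta and sigma^2 in closed form.
    """

    def __init__(self, y, X, coords, structure, window_ids):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.structure = structure
        self.window_ids = None if window_ids is None else np.asarray(window_ids)
        coords = np.asarray(coords, dtype=float)
        self.D = squareform(pdist(coords)) if structure.has_range else None
        if self.window_ids is not None:
            self.B = (self.window_ids[:, None] == self.window_ids[None, :]).astype(float)
        else:
            self.B = None
        self.jitter_used = 0.0

    def _V(self, rng: float | None, ratio: float | None) -> np.ndarray:
        if self.structure.has_range:
            V = correlation_value(self.structure.with_range(rng), self.D)
            np.fill_diagonal(V, 1.0)
        else:
            V = np.eye(self.n)
        if ratio is not None:
            V = V + ratio * self.B
        return V

    def _chol(self, V: np.ndarray):
        jit = 0.0
        for attempt in range(6):
            try:
                L = linalg.cholesky(V if jit == 0 else V + jit * np.eye(self.n), lower=True)
                return L, jit
            except linalg.LinAlgError:
                jit = 1e-10 * 10.0**attempt * max(1.0, float(np.mean(np.diag(V))))
        return None, jit

    def loglik(self, rng, ratio, method: str) -> tuple[float, dict] | tuple[float, None]:
        L, jit = self._chol(self._V(rng, ratio))
        if L is None:
            return -np.inf, None
        n, p = self.n, self.p
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        Xw = linalg.solve_triangular(L, self.X, lower=True)
        yw = linalg.solve_triangular(L, self.y, lower=True)
        XtX = Xw.T @ Xw
        try:
            cF = linalg.cho_factor(XtX)
        except linalg.LinAlgError:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        beta = linalg.cho_solve(cF, Xw.T @ yw)
        r = yw - Xw @ beta
        rss = float(r @ r)
        if rss <= 0:
            rss = np.finfo(float).tiny
        if method == "ML":
            sigma2 = rss / n
            ll = -0.5 * (n * (_LOG2PI + np.log(sigma2) + 1.0) + logdetV)
        else:  # REML
            sigma2 = rss / (n - p)
            sign, logdetXtX = np.linalg.slogdet(XtX)
            ll = -0.5 * (
                (n - p) * (_LOG2PI + np.log(sigma2) + 1.0) + logdetV + logdetXtX
            )
        aux = {
            "beta": beta,
            "sigma2": sigma2,
            "XtX_chol": cF,
            "L": L,
            "jitter": jit,
            "rss": rss,
            "logdetV": logdetV,
        }
        return float(ll), aux


def _range_grid(D: np.ndarray) -> tuple[float, float, list[float]]:
    """Bounds and deterministic multi-start values for the range (log scale)."""
    pos = D[np.triu_indices_from(D, k=1)]
    pos = pos[pos > 0]
    if pos.size == 0:
        raise ValueError("all coordinates coincide; spatial range is unidentifiable")
    lo = max(float(np.min(pos)) * 1e-2, 1e-8)
    hi = float(np.max(pos)) * 10.0
    starts = [float(np.quantile(pos, q)) for q in (0.1, 0.5, 0.9)]
    return lo, hi, starts


def fit_gls(
    y,
    X,
    coords,
    structure: CorrelationStructure,
    *,
    method: str = "REML",
    names: Sequence[str] | None = None,
    window_ids: Sequence | None = None,
    df_map: dict | None = None,
    fixed_params: bool = False,
) -> ModelFit:
    """Fit a linear model with spatial residual correlation by (RE)ML.

    Parameters
    ----------
    y, X : array-like
        Response (n,) and design matrix (n, p); X must include the intercept
        column explicitly and be full rank.
    coords : array-like (n, 2)
        (lon, lat) of each observation in degrees.
    structure : CorrelationStructure
        Correlation family; its range (if any) is estimated unless
        ``fixed_params`` is true and a range is supplied.
    method : "REML" or "ML"
        Likelihood used for the covariance-parameter search and for the
        reported coefficient covariance.  Both log-likelihoods are evaluated
        at the solution.
    window_ids : optional grouping
        When given, a per-window random intercept is included via the
        variance ratio, estimated jointly with the range.
    df_map : optional dict
        Per-coefficient t degrees of freedom overriding the default n − p
        (the paired model uses the number of windows − 1 for the within-
        window contrast, matching the nested-design convention).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different lengths")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]

    prob = _Profile(y, X, coords, structure, window_ids)
    est_range = structure.has_range and not (fixed_params and structure.range is not None)
    est_ratio = window_ids is not None

    # --- optimize covariance parameters -----------------------------------
    rng_hat: float | None = structure.range if structure.has_range else None
    ratio_hat: float | None = None
    converged = True
    if est_range or est_ratio:
        if est_range:
            lo, hi, starts = _range_grid(prob.D)

        if est_range and est_ratio:
            def nll2(z):
                rng_v = max(float(np.exp(np.clip(z[0], -30, 30))), 1e-12)
                ratio_v = max(float(np.exp(np.clip(z[1], -30, 30))), 1e-12)
                ll, _ = prob.loglik(rng_v, ratio_v, method)
                return -ll

            best = None
            for s in starts:
                res = optimize.minimize(
                    nll2,
                    x0=[np.log(s), 0.0],
                    method="Nelder-Mead",
                    options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 500},
                )
                if best is None or res.fun < best.fun:
                    best = res
            converged = bool(best.success) and np.isfinite(best.fun)
            rng_hat = max(float(np.exp(np.clip(best.x[0], -30, 30))), 1e-12)
            ratio_hat = max(float(np.exp(np.clip(best.x[1], -30, 30))), 1e-12)
        elif est_range:
            def nll1(z):
                ll, _ = prob.loglik(np.exp(z), None, method)
                return -ll

            best_z, best_f = None, np.inf
            for s in starts:
                res = optimize.minimize_scalar(
                    nll1,
                    bounds=(np.log(lo), np.log(hi)),
                    method="bounded",
                    options={"xatol": 1e-12},
                )
                if res.fun < best_f:
                    best_z, best_f = float(res.x), float(res.fun)
                # bounded Brent ignores starts; one call suffices
                break
            converged = np.isfinite(best_f)
            rng_hat = float(np.exp(best_z))
        else:  # ratio only (independence + random effect)
            def nllr(z):
                ll, _ = prob.loglik(None, np.exp(z), method)
                return -ll

            res = optimize.minimize_scalar(
                nllr, bounds=(-14.0, 14.0), method="bounded", options={"xatol": 1e-13}
            )
            converged = np.isfinite(res.fun)
            ratio_hat = float(np.exp(res.x))
        if not converged:
            raise ConvergenceError(
                f"covariance-parameter optimization failed for {structure.family} "
                f"(range={rng_hat}, ratio={ratio_hat})"
            )
    elif structure.has_range and structure.range is None:
        raise ValueError("fixed_params requires a range on the structure")

    # --- final evaluation at the optimum ----------------------------------
    ll_req, aux = prob.loglik(rng_hat, ratio_hat, method)
    if aux is None:
        raise ConvergenceError("covariance not positive definite at the solution")
    other = "ML" if method == "REML" else "REML"
    ll_other, _ = prob.loglik(rng_hat, ratio_hat, other)
    ll_ml = ll_req if method == "ML" else ll_other
    ll_reml = ll_req if method == "REML" else ll_other

    beta = aux["beta"]
    # coefficient covariance uses the REML-style (n - p) variance whatever the
    # search likelihood, matching standard mixed-model software output
    sigma2_inf = aux["rss"] / (n - p)
    cov_beta = sigma2_inf * linalg.cho_solve(aux["XtX_chol"], np.eye(p))
    se = np.sqrt(np.diag(cov_beta))
    df = np.full(p, n - p, dtype=float)
    if df_map:
        for nm, d in df_map.items():
            df[names.index(nm)] = d
    t_vals = beta / se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df)
    ci = np.column_stack([beta - 1.96 * se, beta + 1.96 * se])

    fitted = X @ beta
    resid = y - fitted
    k = p + (1 if est_range or (structure.has_range and fixed_params) else 0)
    k += (1 if est_ratio else 0) + 1  # + residual variance

    fitted_structure = (
        structure.with_range(rng_hat) if structure.has_range else structure
    )
    return ModelFit(
        names=names,
        coefficients=beta,
        standard_errors=se,
        ci95=ci,
        t_values=t_vals,
        p_values=p_vals,
        df=df,
        log_likelihood_ml=ll_ml,
        log_likelihood_reml=ll_reml,
        n=n,
        k=k,
        sigma2=float(aux["sigma2"]),
        variance_ratio=ratio_hat,
        structure=fitted_structure,
        residuals=resid,
        fitted=fitted,
        method=method,
        converged=converged,
        jitter=float(aux["jitter"]),
    )


# ---------------------------------------------------------------------------
# the paired mixed model
# ---------------------------------------------------------------------------

def fit_paired_model(
    pairs,
    variable: str,
    structure: CorrelationStructure = INDEPENDENCE,
    *,
    method: str = "REML",
    min_windows: int = 10,
) -> ModelFit:
    """Mixed model comparing focal versus reference cells across windows.

    Each window contributes two observations of the variable's change (the
    reference cell's and the focal cell's).  Fixed effects are an intercept
    and a focal-cell indicator; a random intercept per window absorbs the
    shared local background, and residuals may carry a spatial correlation
    structure on each observation's own coordinates.  The focal-indicator
    coefficient (named ``cell_type``) estimates the effect of forest change
    on the variable; under the independence structure the model is exactly a
    paired t-test on focal − reference differences.
    """
    import pandas as pd

    from .pairing import pairs_to_frame

    if isinstance(pairs, pd.DataFrame):
        df_pairs = pairs
    else:
        df_pairs = pairs_to_frame(pairs)
    foc = df_pairs[f"{variable}_foc"]
    ref = df_pairs[f"{variable}_ref"]
    ok = foc.notna() & ref.notna()
    df_pairs = df_pairs[ok]
    m = len(df_pairs)
    if m < min_windows:
        raise ValueError(f"need at least {min_windows} windows with both members; got {m}")

    y = np.concatenate([df_pairs[f"{variable}_ref"].to_numpy(), df_pairs[f"{variable}_foc"].to_numpy()])
    cell_type = np.concatenate([np.zeros(m), np.ones(m)])
    X = np.column_stack([np.ones(2 * m), cell_type])
    coords = np.vstack(
        [
            df_pairs[["ref_lon", "ref_lat"]].to_numpy(),
            df_pairs[["focal_lon", "focal_lat"]].to_numpy(),
        ]
    )
    wid = np.concatenate([df_pairs["window_id"].to_numpy()] * 2)
    return fit_gls(
        y,
        X,
        coords,
        structure,
        method=method,
        names=["intercept", "cell_type"],
        window_ids=wid,
        df_map={"cell_type": m - 1, "intercept": m - 1},
    )


# ---------------------------------------------------------------------------
# structure selection
# ---------------------------------------------------------------------------

def select_structure(
    structures: Sequence[CorrelationStructure],
    fit_fn: Callable[[CorrelationStructure], ModelFit],
) -> list[ModelFit]:
    """Fit every candidate structure and rank by AICc (ascending, stable).

    ``fit_fn`` must fit identical fixed effects for every structure and use
    ML for the covariance search so the AICc values are comparable (pass
    ``method='ML'`` to the underlying fit).  Candidates that fail to converge
    are excluded with a warning; if all fail, an error is raised.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 candidate structures")
    fits = []
    for i, s in enumerate(structures):
        try:
            fits.append((i, fit_fn(s)))
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"candidate {s.family} excluded: {exc}")
    if not fits:
        raise ConvergenceError("no candidate structure converged")
    fits.sort(key=lambda t: (t[1].aicc, t[0]))  # stable on input order at ties
    return [f for _, f in fits]


def select_paired_structure(
    pairs,
    variable: str,
    structures: Sequence[CorrelationStructure],
    *,
    min_windows: int = 10,
) -> list[ModelFit]:
    """Rank candidate correlation structures for the paired mixed model."""
    return select_structure(
        structures,
        lambda s: fit_paired_model(pairs, variable, s, method="ML", min_windows=min_windows),
    )
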