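"""Maximum-likelihood estimation of covariance-structure models.

The discrepancy F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p is
minimized over the free parameters with an analytic gradient, a
multi-start quasi-Newton search (L-BFGS-B) and a final Newton polish on
the interior coordinates. T = (n - 1) F_min is referred to a chi-square
distribution with df = p(p+1)/2 - n_free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from ..errors import DataError, NumericDomainError
from .covariance import CovMatrix, implied_covariance, ml_discrepancy
from .effects import construct_reliability, standardize_params
from .model import ModelSpec
from .params import ParameterSet, build_template

_BIG = 1e10
_BOUND = 1e-10
_GRAD_TOL = 1e-8


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: ParameterSet
    standardized: ParameterSet | None
    standard_errors: dict[str, float | None]
    T: float
    df: int
    p_value: float | None
    rmsea: float | None
    cfi: float | None
    F_min: float
    converged: bool
    n: int
    construct_reliabilities: dict[str, float]
    S: CovMatrix
    warnings: list[str] = field(default_factory=list)
    heywood: list[str] = field(default_factory=list)
    grad_norm: float = float("nan")
    best_start: int = -1
    _hessian: np.ndarray | None = field(default=None, repr=False)

    def to_report(self) -> dict:
        """JSON-serializable report: estimates table, fit block,
        standardized block and reliabilities."""
        names = self.estimates.free_names()
        x = self.estimates.pack()
        table = []
        for name, est in zip(names, x):
            se = self.standard_errors.get(name)
            z = est / se if se else None
            pv = 2.0 * stats.norm.sf(abs(z)) if z is not None else None
            table.append({"parameter": name, "estimate": float(est),
                          "se": se, "z": z, "p": pv})
        std_block = None
        if self.standardized is not None:
            std_block = {
                name: float(val)
                for name, val in zip(names, self.standardized.pack())
            }
        return {
            "estimates": table,
            "fit": {"T": self.T, "df": self.df, "p_value": self.p_value,
                    "rmsea": self.rmsea, "cfi": self.cfi,
                    "F_min": self.F_min, "n": self.n,
                    "converged": self.converged},
            "standardized": std_block,
            "construct_reliabilities": self.construct_reliabilities,
            "warnings": self.warnings,
            "heywood": self.heywood,
        }


# ----------------------------------------------------------------------
# objective and analytic gradient
# ----------------------------------------------------------------------
def _objective(tpl: ParameterSet, s_values: np.ndarray, x: np.ndarray
               ) -> tuple[float, np.ndarray]:
    params = tpl.unpack(x)
    m = params.beta.shape[0]
    imb = np.eye(m) - params.beta
    try:
        c = linalg.inv(imb)
    except linalg.LinAlgError:
        return _BIG, np.zeros_like(x)
    mid = c @ params.psi @ c.T
    sigma = params.lam @ mid @ params.lam.T + np.diag(params.theta)
    sigma = (sigma + sigma.T) / 2.0
    try:
        cf = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        return _BIG, np.zeros_like(x)
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    sign_s, logdet_s = np.linalg.slogdet(s_values)
    sigma_inv = linalg.cho_solve(cf, np.eye(sigma.shape[0]))
    f = logdet_sigma + float(np.trace(sigma_inv @ s_values)) \
        - logdet_s - sigma.shape[0]

    # dF = tr(W dSigma), W = Sigma^-1 (Sigma - S) Sigma^-1
    w = sigma_inv @ (sigma - s_values) @ sigma_inv
    w = (w + w.T) / 2.0
    grad_lam = 2.0 * w @ params.lam @ mid
    g_mid = c.T @ params.lam.T @ w @ params.lam @ c
    grad_beta = 2.0 * g_mid @ params.psi @ c.T
    grad_theta = np.diag(w)

    tril = np.tril(tpl.psi_free)
    idx = np.nonzero(tril)
    psi_grad = np.where(np.asarray(idx[0]) == np.asarray(idx[1]),
                        g_mid[idx], 2.0 * g_mid[idx])
    grad = np.concatenate([
        grad_lam[tpl.lam_free],
        grad_beta[tpl.beta_free],
        psi_grad,
        grad_theta[tpl.theta_free],
    ])
    return float(f), grad


def _fd_hessian(grad_fn, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    k = x.size
    h_mat = np.empty((k, k))
    for i in range(k):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        h_mat[:, i] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return (h_mat + h_mat.T) / 2.0


def _start_vector(tpl: ParameterSet, S: CovMatrix) -> np.ndarray:
    """Documented default starts: loadings 0.7 (on the marker scale),
    paths 0, variances seeded from the sample diagonal."""
    spec = tpl.spec
    man_idx = {name: i for i, name in enumerate(spec.manifest_names)}
    lat_idx = {name: j for j, name in enumerate(spec.latent_names)}
    diag = np.diag(S.values)
    start = tpl.copy()

    marker = spec.identification == "marker-variable"
    for fname, inds in spec.factors:
        j = lat_idx[fname]
        base_var = diag[man_idx[inds[0]]]
        for ind in inds:
            i = man_idx[ind]
            if start.lam_free[i, j]:
                scale = 1.0 if marker else float(np.sqrt(diag[i]))
                start.lam[i, j] = 0.7 * scale
            if start.theta_free[i]:
                start.theta[i] = 0.5 * diag[i]
        if start.psi_free[j, j]:
            start.psi[j, j] = 0.5 * base_var
    for name in spec.observed_exogenous:
        j = lat_idx[name]
        if start.psi_free[j, j]:
            start.psi[j, j] = diag[man_idx[name]]
    if spec.second_order is not None:
        so, governed = spec.second_order
        j = lat_idx[so]
        if start.psi_free[j, j]:
            start.psi[j, j] = 0.5
    start.beta[tpl.beta_free] = 0.0
    return start.pack()


def fit(spec: ModelSpec, S: CovMatrix, n: int, *, n_starts: int = 5,
        seed: int = 0, compute_se: bool = True) -> FitResult:
    """Fit the model to a sample covariance matrix by maximum likelihood.

    Runs ``n_starts`` jittered starts, keeps the lowest discrepancy
    (ties broken by start index) and reports an honest convergence flag
    based on the projected-gradient max-norm.
    """
    if tuple(S.labels) != tuple(spec.manifest_names):
        raise DataError(
            "sample covariance labels do not match the model manifest "
            f"variables: {list(S.labels)} vs {list(spec.manifest_names)}")
    p = S.p
    if n <= p:
        raise DataError(f"need n > p observations (n={n}, p={p})")

    tpl = build_template(spec)
    n_free = tpl.n_free
    df = p * (p + 1) // 2 - n_free

    var_mask = tpl.variance_mask()
    bounds = [(_BOUND, None) if v else (None, None) for v in var_mask]
    lower = np.array([_BOUND if v else -np.inf for v in var_mask])

    def fun(x):
        return _objective(tpl, S.values, x)

    def grad_only(x):
        return fun(x)[1]

    x_default = _start_vector(tpl, S)
    best: tuple[float, int, np.ndarray] | None = None
    for k in range(n_starts):
        x0 = x_default.copy()
        if k > 0:
            rng = np.random.default_rng([seed, k])
            jitter = rng.standard_normal(x0.size)
            x0 = np.where(var_mask,
                          x0 * np.exp(0.3 * jitter),
                          x0 * (1.0 + 0.25 * jitter) + 0.05 * jitter)
            x0 = np.maximum(x0, lower)
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 4000, "ftol": 1e-14,
                                         "gtol": 1e-12})
        x_opt = _newton_polish(fun, res.x, lower)
        f_opt = fun(x_opt)[0]
        if best is None or f_opt < best[0] - 1e-14:
            best = (f_opt, k, x_opt)

    f_min, best_start, x_hat = best
    f_val, g = fun(x_hat)
    at_bound = var_mask & (x_hat <= 2.0 * _BOUND)
    kkt_free = ~(at_bound & (g > 0))
    grad_norm = float(np.max(np.abs(g[kkt_free]))) if kkt_free.any() else 0.0
    converged = grad_norm < _GRAD_TOL and f_val < _BIG / 2

    estimates = tpl.unpack(x_hat)
    names = estimates.free_names()
    heywood = [name for name, hit in zip(names, at_bound) if hit]
    warn_list = []
    if heywood:
        msg = f"Heywood case: variance(s) clamped at bound: {heywood}"
        warn_list.append(msg)
        warnings.warn(msg, stacklevel=2)

    T = (n - 1) * f_min
    p_value = rmsea = cfi = None
    standardized = None
    reliabilities: dict[str, float] = {}
    if converged:
        if df > 0:
            t_b, df_b = baseline_statistics(S, n)
            p_value, rmsea, cfi = fit_statistics(T, df, n, t_b, df_b)
        elif df == 0:
            p_value, rmsea, cfi = None, 0.0, 1.0
        standardized = standardize_params(estimates)
        reliabilities = _reliabilities(standardized)
    else:
        warn_list.append("non-convergence after all starts; fit indices "
                         "withheld")

    ses: dict[str, float | None] = {name: None for name in names}
    hessian = None
    if converged and compute_se:
        hessian = _fd_hessian(grad_only, x_hat) * (n - 1) / 2.0
        ses = _se_from_hessian(hessian, names, at_bound, warn_list)

    return FitResult(
        spec=spec, estimates=estimates, standardized=standardized,
        standard_errors=ses, T=float(max(T, 0.0)), df=df, p_value=p_value,
        rmsea=rmsea, cfi=cfi, F_min=float(max(f_min, 0.0)),
        converged=converged, n=n, construct_reliabilities=reliabilities,
        S=S, warnings=warn_list, heywood=heywood, grad_norm=grad_norm,
        best_start=best_start, _hessian=hessian,
    )


def _newton_polish(fun, x: np.ndarray, lower: np.ndarray,
                   max_iter: int = 25) -> np.ndarray:
    """Newton refinement with a finite-difference Hessian of the analytic
    gradient; respects the lower bounds on variances."""
    x = np.maximum(x, lower)
    f, g = fun(x)
    bounded = np.isfinite(lower)
    for _ in range(max_iter):
        at_bound = bounded & (x <= lower + _BOUND)
        active = at_bound & (g > 0)
        free = ~active
        if not free.any() or np.max(np.abs(g[free])) < 1e-11:
            break
        h_full = _fd_hessian(lambda z: fun(z)[1], x)
        h_sub = h_full[np.ix_(free, free)]
        try:
            step = linalg.solve(h_sub, -g[free], assume_a="sym")
        except linalg.LinAlgError:
            break
        d = np.zeros_like(x)
        d[free] = step
        g_norm = np.max(np.abs(g[free]))
        improved = False
        t = 1.0
        for _ in range(25):
            xn = np.maximum(x + t * d, lower)
            fn, gn = fun(xn)
            # near machine-precision minima f comparisons are noise, so a
            # clear gradient-norm drop also accepts the step
            if fn < f - 1e-16 or np.max(np.abs(gn[free])) < 0.5 * g_norm:
                x, f, g = xn, fn, gn
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return x


def _se_from_hessian(hessian: np.ndarray, names: tuple[str, ...],
                     at_bound: np.ndarray, warn_list: list[str]
                     ) -> dict[str, float | None]:
    ses: dict[str, float | None] = {name: None for name in names}
    try:
        cov = linalg.inv(hessian)
        diag = np.diag(cov)
        if np.any(diag[~at_bound] <= 0):
            raise linalg.LinAlgError("non-positive information diagonal")
        for i, name in enumerate(names):
            ses[name] = None if at_bound[i] else float(np.sqrt(diag[i]))
    except linalg.LinAlgError as exc:
        warn_list.append(f"standard errors withheld: singular observed "
                         f"information ({exc})")
    return ses


def baseline_statistics(S: CovMatrix, n: int) -> tuple[float, int]:
    """Independence-baseline chi-square and df. With free variances only
    the baseline MLE is diag(S), so T_b = -(n-1) ln|R| for the sample
    correlation matrix R."""
    p = S.p
    d = np.sqrt(np.diag(S.values))
    r = S.values / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise NumericDomainError("sample correlation matrix not positive "
                                 "definite")
    t_b = -(n - 1) * float(logdet)
    return t_b, p * (p - 1) // 2


def fit_statistics(T: float, df: int, n: int, T_baseline: float,
                   df_baseline: int) -> tuple[float, float, float]:
    """(p_value, rmsea, cfi) for a chi-square statistic against the
    independence baseline. RMSEA truncates to 0 when T <= df."""
    if df <= 0:
        raise NumericDomainError(f"fit indices undefined for df={df}")
    if df_baseline < df:
        raise NumericDomainError("baseline df must be >= model df")
    p_value = float(stats.chi2.sf(T, df))
    rmsea = float(np.sqrt(max(0.0, (T - df) / (df * (n - 1)))))
    num = max(T - df, 0.0)
    denom = max(T_baseline - df_baseline, T - df, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - num / denom
    return p_value, rmsea, float(min(max(cfi, 0.0), 1.0))


def standard_errors(fit_result: FitResult, S: CovMatrix | None = None,
                    n: int | None = None) -> dict[str, float | None]:
    """Standard errors from the inverse observed information (numerical
    Hessian of (n-1)/2 F_ML at the optimum)."""
    if not fit_result.converged:
        raise NumericDomainError("standard errors require a converged fit")
    S = S if S is not None else fit_result.S
    n = n if n is not None else fit_result.n
    tpl = build_template(fit_result.spec)
    x_hat = fit_result.estimates.pack()

    def grad_only(x):
        return _objective(tpl, S.values, x)[1]

    hessian = _fd_hessian(grad_only, x_hat) * (n - 1) / 2.0
    var_mask = tpl.variance_mask()
    at_bound = var_mask & (x_hat <= 2.0 * _BOUND)
    warn_list: list[str] = []
    ses = _se_from_hessian(hessian, fit_result.estimates.free_names(),
                           at_bound, warn_list)
    if warn_list:
        raise NumericDomainError(warn_list[0])
    return ses


def _reliabilities(standardized: ParameterSet) -> dict[str, float]:
    spec = standardized.spec
    man_idx = {name: i for i, name in enumerate(spec.manifest_names)}
    lat_idx = {name: j for j, name in enumerate(spec.latent_names)}
    out: dict[str, float] = {}
    for fname, inds in spec.factors:
        if len(inds) < 2:
            continue
        j = lat_idx[fname]
        lam = [standardized.lam[man_idx[i], j] for i in inds]
        theta = [standardized.theta[man_idx[i]] for i in inds]
        out[fname] = construct_reliability(lam, theta)
    return out
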