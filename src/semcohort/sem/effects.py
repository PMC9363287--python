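"""Standardized solutions, mediation effects, reliabilities and factor
scores derived from a fitted (or constructed) parameter set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from ..errors import DataError, NumericDomainError
from .covariance import CovMatrix, implied_covariance, latent_transform
from .params import ParameterSet


def standardize_params(params: ParameterSet) -> ParameterSet:
    """Rescale a solution so every latent and manifest variable has unit
    variance.

    Loadings become correlations-with-factor, path coefficients become
    standardized betas, psi off-diagonals become correlations and psi
    diagonals of endogenous latents become unexplained-variance
    fractions. Idempotent, and invariant to which indicator carried the
    scale (marker choice).
    """
    c = latent_transform(params)
    latent_var = np.diag(c @ params.psi @ c.T).copy()
    if np.any(latent_var <= 0):
        raise NumericDomainError("zero or negative model-implied latent "
                                 "variance; cannot standardize")
    sigma = implied_covariance(params.spec, params)
    man_sd = np.sqrt(np.diag(sigma.values))
    lat_sd = np.sqrt(latent_var)

    out = params.copy()
    out.lam = params.lam * lat_sd[None, :] / man_sd[:, None]
    out.beta = params.beta * lat_sd[None, :] / lat_sd[:, None]
    out.psi = params.psi / np.outer(lat_sd, lat_sd)
    out.theta = params.theta / man_sd**2
    return out


def standardize(fit) -> ParameterSet:
    """Standardized solution of a :class:`FitResult` (or ParameterSet)."""
    params = getattr(fit, "estimates", fit)
    return standardize_params(params)


@dataclass
class IndirectEffects:
    """Per-chain products of directed coefficients plus their sum."""

    source: str
    target: str
    chains: dict[tuple[str, ...], float]
    total: float
    note: str | None = None


def indirect_effects(fit, source: str, target: str,
                     standardized: bool = True) -> IndirectEffects:
    """Indirect effects of ``source`` on ``target``: the product of
    coefficients along every directed chain of length >= 2, and their
    sum. A direct edge source -> target is not an indirect effect."""
    params = getattr(fit, "standardized", None) if standardized else None
    if params is None:
        params = getattr(fit, "estimates", fit)
        if standardized:
            params = standardize_params(params)
    spec = params.spec
    lat = list(spec.latent_names)
    if source not in lat or target not in lat:
        raise DataError(f"unknown latent {source!r} or {target!r}")
    idx = {name: j for j, name in enumerate(lat)}
    children: dict[str, list[str]] = {name: [] for name in lat}
    for src, tgt in spec.edges:
        children[src].append(tgt)

    chains: dict[tuple[str, ...], float] = {}

    def walk(node: str, path: list[str], product: float) -> None:
        for nxt in children[node]:
            coef = float(params.beta[idx[nxt], idx[node]])
            if nxt == target:
                if len(path) >= 2:  # at least one intermediate node
                    chains[tuple(path + [nxt])] = product * coef
            else:
                walk(nxt, path + [nxt], product * coef)

    walk(source, [source], 1.0)
    total = float(sum(chains.values()))
    note = None if chains else f"no indirect path from {source} to {target}"
    return IndirectEffects(source, target, chains, total, note)


def construct_reliability(loadings, errors) -> float:
    """Composite reliability (sum lam)^2 / ((sum lam)^2 + sum theta) from
    standardized loadings and error variances."""
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(errors, dtype=float)
    if lam.size == 0:
        raise DataError("empty indicator list")
    if lam.shape != theta.shape:
        raise DataError("loadings and errors must have the same length")
    num = float(lam.sum()) ** 2
    return num / (num + float(theta.sum()))


def factor_scores(fit, data: pd.DataFrame,
                  center: pd.Series | None = None,
                  own_indicators: bool = False) -> pd.DataFrame:
    """Regression-method (Thomson) factor scores.

    ``scores = Cov(eta, y) S^-1 (y - ybar)`` with S the sample covariance
    the model was fitted to. ``center`` overrides the centering means
    (e.g. baseline means applied to a follow-up slice). With
    ``own_indicators=True`` each first-order factor is scored from its
    own indicator block only, which avoids cross-factor bleed when
    scores are compared between occasions or arms.
    """
    params = fit.estimates
    spec = params.spec
    s_matrix: CovMatrix = fit.S
    c = latent_transform(params)
    cov_eta_y = c @ params.psi @ c.T @ params.lam.T  # (m, p)

    needed = (list({i for _, inds in spec.factors for i in inds})
              if own_indicators else list(spec.manifest_names))
    missing = [col for col in needed if col not in data.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    sub = data[[c_ for c_ in spec.manifest_names
                if c_ in data.columns]].astype(float).dropna()

    def center_of(cols: list[str]) -> np.ndarray:
        if center is None:
            return sub[cols].mean(axis=0).to_numpy()
        return np.asarray([center[c_] for c_ in cols], dtype=float)

    man_pos = {name: i for i, name in enumerate(spec.manifest_names)}
    lat_pos = {name: j for j, name in enumerate(spec.latent_names)}

    if own_indicators:
        out = {}
        for fname, inds in spec.factors:
            cols = list(inds)
            rows = [man_pos[c_] for c_ in cols]
            s_block = s_matrix.values[np.ix_(rows, rows)]
            a_block = cov_eta_y[lat_pos[fname], rows]
            try:
                w = linalg.solve(s_block, a_block, assume_a="pos")
            except linalg.LinAlgError as exc:
                raise NumericDomainError(
                    f"singular covariance block for {fname}: {exc}") from exc
            centered = sub[cols].to_numpy() - center_of(cols)[None, :]
            out[fname] = centered @ w
        return pd.DataFrame(out, index=sub.index)

    cols = list(spec.manifest_names)
    try:
        weights = linalg.solve(s_matrix.values, cov_eta_y.T,
                               assume_a="pos")  # (p, m)
    except linalg.LinAlgError as exc:
        raise NumericDomainError(f"singular sample covariance: {exc}") from exc
    centered = sub[cols].to_numpy() - center_of(cols)[None, :]
    scores = centered @ weights
    return pd.DataFrame(scores, index=sub.index,
                        columns=list(spec.latent_names))
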