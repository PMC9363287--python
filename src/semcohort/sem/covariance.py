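"""Covariance matrices: sample containers, model-implied composition and
the maximum-likelihood discrepancy function."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from ..errors import ModelStructureError, NumericDomainError
from .model import ModelSpec
from .params import ParameterSet


@dataclass
class CovMatrix:
    """Labelled symmetric covariance matrix, optionally with the number
    of observations it summarizes."""

    labels: tuple[str, ...]
    values: np.ndarray
    n: int | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise NumericDomainError(
                f"covariance matrix shape {self.values.shape} does not match "
                f"{p} labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise NumericDomainError("covariance matrix is not symmetric")
        if np.any(np.diag(self.values) <= 0):
            raise NumericDomainError("covariance diagonal must be positive")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def p(self) -> int:
        return len(self.labels)

    @classmethod
    def from_data(cls, data: pd.DataFrame, columns: list[str] | None = None
                  ) -> "CovMatrix":
        cols = list(columns) if columns is not None else list(data.columns)
        sub = data[cols].astype(float)
        values = np.cov(sub.to_numpy(), rowvar=False, ddof=1)
        return cls(tuple(cols), np.atleast_2d(values), n=len(sub))

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.values, index=self.labels,
                             columns=self.labels)
        frame.to_csv(path, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, n: int | None = None) -> "CovMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(tuple(frame.columns), frame.to_numpy(dtype=float), n=n)


def latent_transform(params: ParameterSet) -> np.ndarray:
    """(I - B)^-1 over the latent coefficient matrix."""
    m = params.beta.shape[0]
    imb = np.eye(m) - params.beta
    try:
        return linalg.inv(imb)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded below
        raise ModelStructureError(f"singular (I - B): {exc}") from exc


def implied_covariance(spec: ModelSpec, params: ParameterSet) -> CovMatrix:
    """Model-implied covariance  Sigma = Lam C Psi C' Lam' + Theta  with
    C = (I - B)^-1."""
    m = params.beta.shape[0]
    if abs(linalg.det(np.eye(m) - params.beta)) < 1e-12:
        raise ModelStructureError("singular (I - B); check path coefficients")
    c = latent_transform(params)
    mid = c @ params.psi @ c.T
    sigma = params.lam @ mid @ params.lam.T + np.diag(params.theta)
    sigma = (sigma + sigma.T) / 2.0
    return CovMatrix(spec.manifest_names, sigma)


def ml_discrepancy(S: CovMatrix, Sigma: CovMatrix) -> float:
    """F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (non-negative, zero
    iff S == Sigma)."""
    if S.labels != Sigma.labels:
        raise NumericDomainError("covariance labels differ between S and "
                                 "Sigma")
    p = S.p
    try:
        c_sig, low = linalg.cho_factor(Sigma.values, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericDomainError(
            f"implied covariance not positive definite: {exc}") from exc
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c_sig))))
    sign_s, logdet_s = np.linalg.slogdet(S.values)
    if sign_s <= 0:
        raise NumericDomainError("sample covariance not positive definite")
    trace = float(np.trace(linalg.cho_solve((c_sig, low), S.values)))
    f = logdet_sigma + trace - logdet_s - p
    return max(float(f), 0.0) if abs(f) < 1e-12 else float(f)
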