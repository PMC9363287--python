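"""Parameter container for covariance-structure models.

The model is held in four matrices over ``p`` manifest and ``m`` latent
variables:

* ``lam``   (p, m)  indicator loadings (observed-exogenous rows fixed 1),
* ``beta``  (m, m)  directed latent coefficients, ``beta[target, source]``
  (structural paths and second-order loadings),
* ``psi``   (m, m)  symmetric exogenous (co)variances and disturbances,
* ``theta`` (p,)    measurement-error variances.

Boolean masks of the same shapes mark the free entries; fixed entries are
never touched by :meth:`ParameterSet.unpack`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelSpec


@dataclass
class ParameterSet:
    spec: ModelSpec
    lam: np.ndarray
    beta: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    lam_free: np.ndarray
    beta_free: np.ndarray
    psi_free: np.ndarray
    theta_free: np.ndarray
    _free_names: tuple[str, ...] = field(default=(), repr=False)

    # ------------------------------------------------------------------
    # flat-vector view
    # ------------------------------------------------------------------
    @property
    def n_free(self) -> int:
        return int(self.lam_free.sum() + self.beta_free.sum()
                   + np.tril(self.psi_free).sum() + self.theta_free.sum())

    def pack(self) -> np.ndarray:
        tril = np.tril(self.psi_free)
        return np.concatenate([
            self.lam[self.lam_free],
            self.beta[self.beta_free],
            self.psi[tril],
            self.theta[self.theta_free],
        ])

    def unpack(self, vec: np.ndarray) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free values, "
                             f"got {vec.shape}")
        out = self.copy()
        i = 0
        k = int(self.lam_free.sum())
        out.lam[self.lam_free] = vec[i:i + k]
        i += k
        k = int(self.beta_free.sum())
        out.beta[self.beta_free] = vec[i:i + k]
        i += k
        tril = np.tril(self.psi_free)
        k = int(tril.sum())
        out.psi[tril] = vec[i:i + k]
        lower = np.tril(out.psi, -1)
        out.psi = np.diag(np.diag(out.psi)) + lower + lower.T
        i += k
        k = int(self.theta_free.sum())
        out.theta[self.theta_free] = vec[i:i + k]
        return out

    def copy(self) -> "ParameterSet":
        return replace(
            self,
            lam=self.lam.copy(), beta=self.beta.copy(),
            psi=self.psi.copy(), theta=self.theta.copy(),
            lam_free=self.lam_free.copy(), beta_free=self.beta_free.copy(),
            psi_free=self.psi_free.copy(), theta_free=self.theta_free.copy(),
        )

    def free_names(self) -> tuple[str, ...]:
        if self._free_names:
            return self._free_names
        man = self.spec.manifest_names
        lat = self.spec.latent_names
        names: list[str] = []
        for i, j in zip(*np.nonzero(self.lam_free)):
            names.append(f"lambda:{man[i]}~{lat[j]}")
        for i, j in zip(*np.nonzero(self.beta_free)):
            names.append(f"beta:{lat[i]}<-{lat[j]}")
        for i, j in zip(*np.nonzero(np.tril(self.psi_free))):
            names.append(f"psi:{lat[i]}~~{lat[j]}")
        for (i,) in zip(*np.nonzero(self.theta_free)):
            names.append(f"theta:{man[i]}")
        object.__setattr__(self, "_free_names", tuple(names))
        return self._free_names

    def variance_mask(self) -> np.ndarray:
        """Boolean mask over the flat vector marking variance parameters
        (psi diagonal and theta), which are bound below at zero."""
        parts = [
            np.zeros(int(self.lam_free.sum()), dtype=bool),
            np.zeros(int(self.beta_free.sum()), dtype=bool),
        ]
        tril = np.tril(self.psi_free)
        idx = np.nonzero(tril)
        parts.append(np.asarray(idx[0]) == np.asarray(idx[1]))
        parts.append(np.ones(int(self.theta_free.sum()), dtype=bool))
        return np.concatenate(parts)

    # ------------------------------------------------------------------
    # named views (reporting convenience)
    # ------------------------------------------------------------------
    def first_order_loadings(self) -> np.ndarray:
        cols = [self.spec.latent_names.index(f)
                for f in self.spec.first_order_names]
        return self.lam[:, cols]

    def second_order_loadings(self) -> np.ndarray:
        if self.spec.second_order is None:
            return np.zeros(0)
        name, governed = self.spec.second_order
        j = self.spec.latent_names.index(name)
        rows = [self.spec.latent_names.index(g) for g in governed]
        return self.beta[rows, j]

    def path_coefficients(self) -> dict[str, float]:
        lat = self.spec.latent_names
        return {f"{t}<-{s}": float(self.beta[lat.index(t), lat.index(s)])
                for s, t in self.spec.paths}

    def exogenous_variances(self) -> dict[str, float]:
        lat = self.spec.latent_names
        return {name: float(self.psi[lat.index(name), lat.index(name)])
                for name in self.spec.exogenous_latents}

    def disturbance_variances(self) -> dict[str, float]:
        lat = self.spec.latent_names
        return {name: float(self.psi[lat.index(name), lat.index(name)])
                for name in self.spec.endogenous_latents}

    def error_variances(self) -> dict[str, float]:
        return {name: float(self.theta[i])
                for i, name in enumerate(self.spec.manifest_names)}


def build_template(spec: ModelSpec) -> ParameterSet:
    """Construct the free/fixed parameter layout implied by ``spec`` and
    its identification rule, with neutral default values (loadings 0.7,
    paths 0, unit variances)."""
    p, m = spec.n_manifest, spec.n_latent
    man_idx = {name: i for i, name in enumerate(spec.manifest_names)}
    lat_idx = {name: j for j, name in enumerate(spec.latent_names)}
    marker = spec.identification == "marker-variable"

    lam = np.zeros((p, m))
    lam_free = np.zeros((p, m), dtype=bool)
    theta = np.full(p, 0.5)
    theta_free = np.ones(p, dtype=bool)
    beta = np.zeros((m, m))
    beta_free = np.zeros((m, m), dtype=bool)
    psi = np.eye(m)
    psi_free = np.zeros((m, m), dtype=bool)

    for fname, inds in spec.factors:
        j = lat_idx[fname]
        for k, ind in enumerate(inds):
            i = man_idx[ind]
            if marker and k == 0:
                lam[i, j] = 1.0
            else:
                lam[i, j] = 0.7
                lam_free[i, j] = True

    for name, fix in spec.fixed_error.items():
        i = man_idx[name]
        theta[i] = fix
        theta_free[i] = False

    for name in spec.observed_exogenous:
        i, j = man_idx[name], lat_idx[name]
        lam[i, j] = 1.0
        theta[i] = 0.0
        theta_free[i] = False

    if spec.second_order is not None:
        so, governed = spec.second_order
        j = lat_idx[so]
        for k, g in enumerate(governed):
            i = lat_idx[g]
            if marker and k == 0:
                beta[i, j] = 1.0
            else:
                beta[i, j] = 0.7
                beta_free[i, j] = True

    for src, tgt in spec.paths:
        beta[lat_idx[tgt], lat_idx[src]] = 0.0
        beta_free[lat_idx[tgt], lat_idx[src]] = True

    exo = spec.exogenous_latents
    for name in spec.latent_names:
        j = lat_idx[name]
        psi_free[j, j] = marker  # unit-latent-variance rule: fixed at 1
    for name in spec.observed_exogenous:
        # variance of an observed variable is a datum, never fixed at 1
        psi_free[lat_idx[name], lat_idx[name]] = True
    # exogenous latents covary freely under either rule
    for a in exo:
        for b in exo:
            if a != b:
                ja, jb = lat_idx[a], lat_idx[b]
                psi_free[ja, jb] = True
                psi[ja, jb] = 0.0

    return ParameterSet(spec, lam, beta, psi, theta,
                        lam_free, beta_free, psi_free, theta_free)
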