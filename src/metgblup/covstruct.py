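"""Residual covariance structures for multi-environment trials.

A single trait scored in ``l`` environments is treated as ``l`` correlated
traits; the per-line residual vector has an ``l x l`` covariance matrix R0
which can take one of four shapes:

``IDV``
    homogeneous diagonal, sigma^2 * I — one parameter.
``IDH``
    heterogeneous diagonal, diag(sigma_1^2 .. sigma_l^2) — ``l`` parameters.
``ANT1``
    first-order antedependence: heterogeneous standard deviations with
    adjacent (lag-1) correlations whose products give the longer-lag
    correlations, Sigma_ij = sigma_i sigma_j prod_{k=min}^{max-1} rho_k.
    ``2l - 1`` parameters; its inverse is tridiagonal.
``US``
    unstructured symmetric positive-definite matrix — ``l(l+1)/2``
    parameters.

Each structure also has a smooth bijection to an unconstrained real vector
(log variances, Fisher-z correlations, log-Cholesky for US) so optimizers
and samplers can move freely without leaving the positive-definite cone.
The same log-Cholesky transform serves the unstructured genetic covariance
G0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import StructureError

KINDS = ("US", "IDH", "IDV", "ANT1")


def param_count(kind: str, l: int, covariances_only: bool = False) -> int:
    """Number of free parameters of a residual structure over ``l`` environments.

    ``covariances_only=True`` counts only the off-diagonal entries of US
    (a convention that appears in parts of the literature); the default
    counts every free entry, variances included.
    """
    if l < 1:
        raise StructureError(f"need at least one environment, got l={l}")
    if kind == "IDV":
        return 1
    if kind == "IDH":
        return l
    if kind == "ANT1":
        return 2 * l - 1
    if kind == "US":
        return l * (l - 1) // 2 if covariances_only else l * (l + 1) // 2
    raise StructureError(f"unknown covariance kind {kind!r}")


@dataclass(frozen=True)
class ResidualStructure:
    """A parameterized residual covariance R0.

    Canonical parameter order:

    - IDV: ``[sigma2]``
    - IDH: ``[sigma2_1, ..., sigma2_l]``
    - ANT1: ``[sd_1, ..., sd_l, rho_1, ..., rho_{l-1}]`` (standard
      deviations, then adjacent correlations)
    - US: lower triangle of the covariance matrix in row-major order
      ``[s11, s21, s22, s31, s32, s33, ...]``
    """

    kind: str
    n_env: int
    params: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise StructureError(f"unknown covariance kind {self.kind!r}")
        p = np.asarray(self.params, dtype=float)
        object.__setattr__(self, "params", p)
        expected = param_count(self.kind, self.n_env)
        if p.shape != (expected,):
            raise StructureError(
                f"{self.kind} over l={self.n_env} needs {expected} parameters, "
                f"got shape {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise StructureError("non-finite structure parameters")
        if self.kind in ("IDV", "IDH") and np.any(p <= 0):
            raise StructureError("variances must be strictly positive")
        if self.kind == "ANT1":
            l = self.n_env
            if np.any(p[:l] <= 0):
                raise StructureError("ANT1 standard deviations must be positive")
            if np.any(np.abs(p[l:]) >= 1):
                raise StructureError("ANT1 adjacent correlations must lie in (-1, 1)")

    @property
    def matrix(self) -> np.ndarray:
        return build_covariance(self)

    def to_dict(self) -> dict:
        """Flat config-block form, e.g. {kind: ANT1, sigma: [...], rho: [...]}."""
        l, p = self.n_env, self.params
        if self.kind == "IDV":
            return {"kind": "IDV", "sigma2": float(p[0])}
        if self.kind == "IDH":
            return {"kind": "IDH", "sigma2": [float(v) for v in p]}
        if self.kind == "ANT1":
            return {
                "kind": "ANT1",
                "sigma": [float(v) for v in p[:l]],
                "rho": [float(v) for v in p[l:]],
            }
        return {"kind": "US", "lower": [float(v) for v in p]}

    @classmethod
    def from_dict(cls, d: dict, n_env: int | None = None) -> "ResidualStructure":
        kind = d["kind"]
        if kind == "IDV":
            return cls("IDV", n_env or 1, np.atleast_1d(np.asarray(d["sigma2"], float)))
        if kind == "IDH":
            p = np.asarray(d["sigma2"], float)
            return cls("IDH", len(p), p)
        if kind == "ANT1":
            sig = np.asarray(d["sigma"], float)
            rho = np.asarray(d["rho"], float)
            return cls("ANT1", len(sig), np.concatenate([sig, rho]))
        if kind == "US":
            p = np.asarray(d["lower"], float)
            l = int(round((np.sqrt(8 * len(p) + 1) - 1) / 2))
            return cls("US", l, p)
        raise StructureError(f"unknown covariance kind {kind!r}")


def _us_from_lower(params: np.ndarray, l: int) -> np.ndarray:
    m = np.zeros((l, l))
    idx = np.tril_indices(l)
    m[idx] = params
    m = m + np.tril(m, -1).T
    return m


def _us_to_lower(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(m.shape[0])]


def build_covariance(rs: ResidualStructure) -> np.ndarray:
    """Materialize R0 as a dense ``l x l`` matrix."""
    l, p = rs.n_env, rs.params
    if rs.kind == "IDV":
        return p[0] * np.eye(l)
    if rs.kind == "IDH":
        return np.diag(p)
    if rs.kind == "ANT1":
        sd, rho = p[:l], p[l:]
        # lag-1 correlations multiply out to the longer lags
        corr = np.eye(l)
        for i in range(l):
            for j in range(i + 1, l):
                corr[i, j] = corr[j, i] = np.prod(rho[i:j])
        return np.outer(sd, sd) * corr
    m = _us_from_lower(p, l)
    # PD check via Cholesky; US free entries need not form a valid covariance
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        raise StructureError("US parameters do not form a positive-definite matrix")
    return m


def inverse_covariance(rs: ResidualStructure) -> np.ndarray:
    """Exact inverse of R0; tridiagonal for ANT1."""
    l, p = rs.n_env, rs.params
    if rs.kind == "IDV":
        return np.eye(l) / p[0]
    if rs.kind == "IDH":
        return np.diag(1.0 / p)
    m = build_covariance(rs)
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0 or not np.isfinite(logdet):
        raise StructureError(f"{rs.kind} covariance is singular")
    return np.linalg.inv(m)


# ---------------------------------------------------------------------------
# unconstrained parameterizations
# ---------------------------------------------------------------------------


def spd_to_log_chol(m: np.ndarray) -> np.ndarray:
    """Log-Cholesky vector of an SPD matrix: log diagonal, free off-diagonal,
    in row-major lower-triangle order."""
    L = np.linalg.cholesky(m)
    out = L[np.tril_indices(m.shape[0])].copy()
    k = np.cumsum(np.arange(1, m.shape[0] + 1)) - 1  # diagonal positions
    out[k] = np.log(np.diag(L))
    return out


def log_chol_to_spd(v: np.ndarray, l: int) -> np.ndarray:
    L = np.zeros((l, l))
    L[np.tril_indices(l)] = v
    np.fill_diagonal(L, np.exp(np.diag(L)))
    return L @ L.T


def unconstrained_transform(rs: ResidualStructure) -> np.ndarray:
    """Map a valid structure to an unconstrained real vector (bijective)."""
    l, p = rs.n_env, rs.params
    if rs.kind == "IDV":
        return np.log(p)
    if rs.kind == "IDH":
        return np.log(p)
    if rs.kind == "ANT1":
        return np.concatenate([np.log(p[:l]), np.arctanh(p[l:])])
    return spd_to_log_chol(build_covariance(rs))


def inverse_transform(v: np.ndarray, kind: str, l: int) -> ResidualStructure:
    """Map an unconstrained vector back to a valid structure."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise StructureError("non-finite unconstrained parameters")
    if v.shape != (param_count(kind, l),):
        raise StructureError(
            f"{kind} over l={l} needs {param_count(kind, l)} unconstrained "
            f"parameters, got shape {v.shape}"
        )
    if kind in ("IDV", "IDH"):
        return ResidualStructure(kind, l, np.exp(v))
    if kind == "ANT1":
        # tanh saturates to +-1.0 in floats for |z| > ~19; keep inside (-1, 1)
        rho = np.clip(np.tanh(v[l:]), -1 + 1e-12, 1 - 1e-12)
        return ResidualStructure(kind, l, np.concatenate([np.exp(v[:l]), rho]))
    return ResidualStructure(kind, l, _us_to_lower(log_chol_to_spd(v, l)))


def validate_genetic_covariance(G0: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    """Symmetrize and check positive definiteness (after jitter) of G0."""
    G0 = np.asarray(G0, dtype=float)
    if G0.ndim != 2 or G0.shape[0] != G0.shape[1]:
        raise StructureError("G0 must be square")
    if np.max(np.abs(G0 - G0.T)) > 1e-8 * max(1.0, np.max(np.abs(G0))):
        raise StructureError("G0 is not symmetric")
    G0 = 0.5 * (G0 + G0.T)
    w = np.linalg.eigvalsh(G0)
    if w.min() < -jitter * max(1.0, w.max()):
        raise StructureError("G0 is not positive semi-definite")
    return G0
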