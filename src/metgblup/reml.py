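"""REML estimation of variance components for all three MET models.

The restricted log-likelihood is maximized by quasi-Newton (L-BFGS-B with
safeguarded line search) over an unconstrained reparameterization of the
variance components: log-Cholesky for the unstructured G0, log variances
and Fisher-z correlations for the residual structures. Positive
definiteness is therefore enforced by parameterization, never by
rejection.

Initialization follows the per-environment univariate fits: the G0 start
is diagonal in the univariate genetic variances with off-diagonals at
half the geometric mean, and R0 starts from the univariate residual
variances. The same univariate fits also supply the prior scales of the
Bayesian sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .covstruct import (
    ResidualStructure,
    inverse_transform,
    log_chol_to_spd,
    param_count,
    spd_to_log_chol,
    unconstrained_transform,
)
from .exceptions import ModelError, NumericalError, StructureError
from .grm import KinshipMatrix
from .models import (
    FitResult,
    METDesign,
    RotatedSolver,
    VarianceComponents,
    build_covariance,
)

__all__ = [
    "REMLResult",
    "reml_fit",
    "init_from_univariate",
    "univariate_components",
    "assemble_init",
]

logger = logging.getLogger("metgblup.reml")


@dataclass
class REMLResult:
    vc_hat: VarianceComponents
    loglik: float
    converged: bool
    n_iter: int
    fit: FitResult

    def __repr__(self):
        return (
            f"REMLResult(model={self.vc_hat.model}, R0={self.vc_hat.R0.kind}, "
            f"loglik={self.loglik:.4f}, converged={self.converged}, "
            f"n_iter={self.n_iter})"
        )


# ---------------------------------------------------------------------------
# packing between VarianceComponents and unconstrained vectors
# ---------------------------------------------------------------------------


def _pack(vc: VarianceComponents) -> np.ndarray:
    if vc.model == 1:
        return np.concatenate(
            [spd_to_log_chol(vc.G0), unconstrained_transform(vc.R0)]
        )
    if vc.model == 2:
        return np.concatenate(
            [
                np.log([vc.sigma_g2, vc.sigma_v2]),
                unconstrained_transform(vc.R0),
            ]
        )
    return np.log([vc.sigma_g2, vc.R0.params[0]])


def _unpack(theta: np.ndarray, model: int, kind: str, l: int) -> VarianceComponents:
    if model == 1:
        ng = l * (l + 1) // 2
        G0 = log_chol_to_spd(theta[:ng], l)
        R0 = inverse_transform(theta[ng:], kind, l)
        return VarianceComponents(1, R0, G0=G0)
    if model == 2:
        sg2, sv2 = np.exp(theta[:2])
        R0 = inverse_transform(theta[2:], kind, l)
        return VarianceComponents(2, R0, sigma_g2=sg2, sigma_v2=sv2)
    sg2, se2 = np.exp(theta)
    return VarianceComponents(
        3, ResidualStructure("IDV", 1, np.array([se2])), sigma_g2=sg2
    )


def _n_theta(model: int, kind: str, l: int) -> int:
    if model == 1:
        return l * (l + 1) // 2 + param_count(kind, l)
    if model == 2:
        return 2 + param_count(kind, l)
    return 2


# ---------------------------------------------------------------------------
# univariate warm start
# ---------------------------------------------------------------------------


def _univariate_fit(y: np.ndarray, lines: list[str], K: KinshipMatrix) -> tuple[float, float]:
    """Model 3 REML on one environment; returns (sigma_g2, sigma_e2)."""
    design = METDesign(
        3, list(lines), ["E"], y[:, None], np.ones((len(lines), 1), bool),
        np.ones((1, 1)),
    )
    vy = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
    if vy <= 1e-12:
        logger.warning("degenerate environment (constant phenotype); halving variance")
        vy = max(vy, 1e-6)
        return vy / 2, vy / 2
    solver = RotatedSolver(design, K.subset(list(lines)))

    def nll(theta):
        sg2, se2 = np.exp(theta)
        try:
            return -solver.reml_loglik(
                np.array([[sg2]]), np.array([[se2]])
            )
        except NumericalError:
            return 1e10

    res = optimize.minimize(
        nll, np.log([vy / 2, vy / 2]), method="L-BFGS-B",
        options={"maxiter": 200},
    )
    sg2, se2 = np.exp(res.x)
    return float(sg2), float(se2)


def univariate_components(design: METDesign, K: KinshipMatrix):
    """Per-environment univariate (sigma_g^2, sigma_e^2) REML estimates."""
    l = design.n_env
    sg2 = np.empty(l)
    se2 = np.empty(l)
    for e in range(l):
        idx = np.where(design.obs_mask[:, e])[0]
        if idx.size < 3:
            raise ModelError(f"environment {design.env_ids[e]} has < 3 observations")
        lines = [design.line_ids[i] for i in idx]
        sg2[e], se2[e] = _univariate_fit(design.y_cells[idx, e], lines, K)
    return np.maximum(sg2, 1e-8), np.maximum(se2, 1e-8)


def assemble_init(
    model: int, sg2: np.ndarray, se2: np.ndarray, structure_kind: str = "US"
) -> VarianceComponents:
    """Starting values from univariate components: G0 diagonal in the
    univariate genetic variances with off-diagonals at half the geometric
    mean; R0 from the univariate residual variances, per structure kind."""
    if model == 1:
        G0 = 0.5 * np.sqrt(np.outer(sg2, sg2))
        np.fill_diagonal(G0, sg2)
        R0 = _residual_init(structure_kind, se2)
        return VarianceComponents(1, R0, G0=G0)
    if model == 2:
        if structure_kind not in ("IDV", "IDH"):
            structure_kind = "IDV"
        R0 = _residual_init(structure_kind, se2)
        m = float(np.mean(sg2))
        return VarianceComponents(2, R0, sigma_g2=0.5 * m, sigma_v2=0.5 * m)
    return VarianceComponents(
        3,
        ResidualStructure("IDV", 1, np.array([float(np.mean(se2))])),
        sigma_g2=float(np.mean(sg2)),
    )


def init_from_univariate(
    design: METDesign,
    K: KinshipMatrix,
    structure_kind: str = "US",
) -> VarianceComponents:
    """Starting values from independent per-environment univariate fits."""
    sg2, se2 = univariate_components(design, K)
    return assemble_init(design.model, sg2, se2, structure_kind)


def _residual_init(kind: str, se2: np.ndarray) -> ResidualStructure:
    l = se2.size
    if kind == "IDV":
        return ResidualStructure("IDV", l, np.array([float(np.mean(se2))]))
    if kind == "IDH":
        return ResidualStructure("IDH", l, se2.copy())
    if kind == "ANT1":
        return ResidualStructure(
            "ANT1", l, np.concatenate([np.sqrt(se2), np.zeros(l - 1)])
        )
    return ResidualStructure("US", l, np.diag(se2)[np.tril_indices(l)])


# ---------------------------------------------------------------------------
# main fit
# ---------------------------------------------------------------------------


def reml_fit(
    design: METDesign,
    K: KinshipMatrix,
    structure_kind: str = "US",
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> REMLResult:
    """Maximize the restricted likelihood over the model's variance
    components; returns the best point found even when not converged
    (flagged in ``converged``)."""
    l = design.n_env
    model = design.model
    if model == 3:
        structure_kind = "IDV"
    if model == 2 and structure_kind not in ("IDV", "IDH"):
        raise ModelError("Model 2 residuals are IDV or IDH")
    if design.n_obs < _n_theta(model, structure_kind, l) + design.p:
        raise ModelError("fewer observations than parameters to estimate")
    if init is None:
        init = init_from_univariate(design, K, structure_kind)
    if init.model != model or init.R0.kind != structure_kind:
        raise ModelError("init does not match the requested model/structure")

    solver = RotatedSolver(design, K)
    theta0 = _pack(init)
    n_eval = {"count": 0}

    def nll(theta):
        n_eval["count"] += 1
        try:
            with np.errstate(all="ignore"):  # line search probes singular corners
                vc = _unpack(theta, model, structure_kind, l)
                val = solver.reml_loglik(vc.effective_G0(), build_covariance(vc.R0))
        except (NumericalError, StructureError, np.linalg.LinAlgError, FloatingPointError):
            return 1e10
        if not np.isfinite(val):
            return 1e10
        return -val

    f0 = nll(theta0)
    if f0 >= 1e10:
        raise ModelError("restricted likelihood is not finite at the initial values")

    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-5},
    )
    theta_hat = res.x if res.fun <= f0 else theta0
    vc_hat = _unpack(theta_hat, model, structure_kind, l)
    ll = -min(res.fun, f0)
    converged = bool(res.success)
    if not converged:
        logger.warning("REML did not converge: %s", res.message)
    fit = solver.solve(vc_hat)
    return REMLResult(vc_hat, float(ll), converged, int(res.nit), fit)
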