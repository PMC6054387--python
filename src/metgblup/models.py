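"""Mixed-model assembly and solution for multi-environment trials.

Three models, all sharing the additive genomic relationship matrix K:

- **Model 1** (multivariate): the trait in each environment is a separate
  correlated trait; ``vec(u) ~ N(0, G0 (x) K)`` with unstructured G0 and
  residual covariance ``R0 (x) I`` where R0 is US, IDH, IDV or ANT1.
- **Model 2** (main effect + G-by-E): ``y = X beta + Z u + W v + eps`` with
  ``u ~ N(0, sigma_g^2 K)``, ``v ~ N(0, sigma_v^2 I (x) K)``; the implied
  per-environment genetic covariance is compound-symmetric,
  ``sigma_g^2 J + sigma_v^2 I``, making Model 2 a special case of Model 1.
- **Model 3** (univariate): one environment at a time,
  ``u ~ N(0, sigma_g^2 K)``, ``eps ~ N(0, sigma_e^2 I)``.

Observations are stacked environment-major (all lines of environment 1,
then 2, ...). Unobserved cells are dropped from the rows.

Two interchangeable solvers are provided. The default works in the
eigenbasis of K, where the marginal covariance of a fully-observed trial
decouples into n independent l x l blocks ``d_k G0 + R0``; missing cells
enter through an exact low-rank (deleted-cell) correction. A dense
Henderson mixed-model-equation solver is kept as a direct reference; both
return the same BLUEs/BLUPs (the MME solution equals the joint-Gaussian
conditional mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covstruct import (
    ResidualStructure,
    build_covariance,
    validate_genetic_covariance,
)
from .exceptions import ModelError, NumericalError
from .grm import KinshipMatrix

__all__ = [
    "METDesign",
    "VarianceComponents",
    "FitResult",
    "build_design",
    "solve_mme",
    "restricted_loglik",
    "heritability",
    "genomic_correlation",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class METDesign:
    """Observed MET layout: which (line, env) cells carry a phenotype, the
    cell values, and the per-environment fixed-effect row.

    ``X_env`` has one row per environment; because none of the three models
    uses line-level covariates, the fixed-effect row of an observation
    depends on its environment only.
    """

    model: int
    line_ids: list[str]
    env_ids: list[str]
    y_cells: np.ndarray  # n x l, NaN where unobserved
    obs_mask: np.ndarray  # n x l bool
    X_env: np.ndarray  # l x p

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_env(self) -> int:
        return len(self.env_ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())

    @property
    def p(self) -> int:
        return self.X_env.shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Environment-major observation vector y, incidence X, and the
        (line, env) index of every row."""
        ys, Xs, cells = [], [], []
        for e in range(self.n_env):
            idx = np.where(self.obs_mask[:, e])[0]
            ys.append(self.y_cells[idx, e])
            Xs.append(np.tile(self.X_env[e], (idx.size, 1)))
            cells.append(np.stack([idx, np.full(idx.size, e)], axis=1))
        return np.concatenate(ys), np.vstack(Xs), np.vstack(cells).astype(int)

    def subset_lines(self, keep: list[str]) -> "METDesign":
        idx = [self.line_ids.index(s) for s in keep]
        return METDesign(
            self.model,
            list(keep),
            list(self.env_ids),
            self.y_cells[idx],
            self.obs_mask[idx],
            self.X_env,
        )


def build_design(
    phenotypes: pd.DataFrame,
    line_ids: list[str],
    model: int,
    env_ids: list[str] | None = None,
) -> METDesign:
    """Build a model design from a long phenotype table (line, env, value).

    Rows with a missing value mark unobserved cells, as do absent (line,
    env) combinations. Fixed effects: Model 1 has one intercept per
    environment; Model 2 a grand mean plus sum-to-zero environment effects;
    Model 3 a single intercept (and requires a single environment).
    """
    if model not in (1, 2, 3):
        raise ModelError(f"unknown model {model}")
    ph = phenotypes.copy()
    required = {"line", "env", "value"}
    if not required.issubset(ph.columns):
        raise ModelError(f"phenotype table needs columns {sorted(required)}")
    ph["line"] = ph["line"].astype(str)
    ph["env"] = ph["env"].astype(str)
    if env_ids is None:
        env_ids = list(dict.fromkeys(ph["env"]))
    unknown_env = set(ph["env"]) - set(env_ids)
    if unknown_env:
        raise ModelError(f"unknown environment labels {sorted(unknown_env)}")
    unknown_line = set(ph["line"]) - set(line_ids)
    if unknown_line:
        raise ModelError(f"phenotype lines not in line_ids: {sorted(unknown_line)[:5]}")
    dup = ph.duplicated(subset=["line", "env"])
    if dup.any():
        first = ph.loc[dup, ["line", "env"]].iloc[0]
        raise ModelError(f"duplicate record for line={first['line']} env={first['env']}")

    n, l = len(line_ids), len(env_ids)
    if model == 3 and l != 1:
        raise ModelError("Model 3 is univariate: build one design per environment")
    li = {s: i for i, s in enumerate(line_ids)}
    ei = {s: e for e, s in enumerate(env_ids)}
    y = np.full((n, l), np.nan)
    for _, row in ph.iterrows():
        y[li[row["line"]], ei[row["env"]]] = row["value"]
    mask = ~np.isnan(y)
    if model == 1:
        X_env = np.eye(l)
    elif model == 2:
        # grand mean + sum-to-zero environment deviations (identifiable)
        H = np.zeros((l, l - 1))
        H[: l - 1] += np.eye(l - 1)
        H[l - 1] = -1.0
        X_env = np.hstack([np.ones((l, 1)), H])
    else:
        X_env = np.ones((1, 1))
    return METDesign(model, list(line_ids), list(env_ids), y, mask, X_env)


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """Variance parameters of one of the three models.

    Model 1 carries ``G0`` (unstructured l x l) and ``R0``. Model 2 carries
    ``sigma_g2``, ``sigma_v2`` and an IDV or IDH ``R0``. Model 3 carries
    ``sigma_g2`` and an IDV ``R0`` holding sigma_e^2.
    """

    model: int
    R0: ResidualStructure
    G0: np.ndarray | None = None
    sigma_g2: float | None = None
    sigma_v2: float | None = None

    def __post_init__(self):
        if self.model == 1:
            if self.G0 is None:
                raise ModelError("Model 1 needs G0")
            self.G0 = validate_genetic_covariance(self.G0)
            if self.G0.shape[0] != self.R0.n_env:
                raise ModelError("G0 and R0 disagree on the number of environments")
        elif self.model == 2:
            if self.sigma_g2 is None or self.sigma_v2 is None:
                raise ModelError("Model 2 needs sigma_g2 and sigma_v2")
            if self.sigma_g2 < 0 or self.sigma_v2 < 0:
                raise ModelError("variances must be non-negative")
            if self.R0.kind not in ("IDV", "IDH"):
                raise ModelError("Model 2 residuals are IDV or IDH")
        elif self.model == 3:
            if self.sigma_g2 is None:
                raise ModelError("Model 3 needs sigma_g2")
            if self.R0.kind != "IDV" or self.R0.n_env != 1:
                raise ModelError("Model 3 residual is a single variance (IDV, l=1)")
        else:
            raise ModelError(f"unknown model {self.model}")

    @property
    def n_env(self) -> int:
        return self.R0.n_env

    @property
    def sigma_e2(self):
        """Residual variance(s): scalar for IDV, per-env vector for IDH."""
        R0m = build_covariance(self.R0)
        d = np.diag(R0m)
        return float(d[0]) if self.R0.kind == "IDV" else d

    def effective_G0(self) -> np.ndarray:
        """Per-environment genetic covariance implied by the model."""
        l = self.n_env
        if self.model == 1:
            return self.G0
        if self.model == 2:
            return self.sigma_g2 * np.ones((l, l)) + self.sigma_v2 * np.eye(l)
        return np.array([[self.sigma_g2]])


def heritability(vc: VarianceComponents, env: int = 0) -> float:
    """Per-environment SNP heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
    (G0_ee / (G0_ee + R0_ee) in the multivariate model)."""
    G0 = vc.effective_G0()
    R0 = build_covariance(vc.R0)
    total = G0[env, env] + R0[env, env]
    if total <= 0:
        raise ModelError("zero total variance")
    return float(G0[env, env] / total)


def genomic_correlation(vc: VarianceComponents) -> np.ndarray:
    """Between-environment genomic correlation matrix from G0."""
    G0 = vc.effective_G0()
    d = np.diag(G0)
    if np.any(d <= 0):
        raise ModelError("zero genetic variance in some environment")
    s = np.sqrt(d)
    return G0 / np.outer(s, s)


@dataclass
class FitResult:
    """Solution of the mixed model at fixed variance components."""

    beta_hat: np.ndarray
    u_hat: np.ndarray  # n x l (Model 1) or n (Models 2-3)
    v_hat: np.ndarray | None  # n x l (Model 2 only)
    gebv: np.ndarray  # n x l per-environment genomic values
    loglik: float
    line_ids: list[str]
    env_ids: list[str]

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gebv, index=self.line_ids, columns=self.env_ids)

    def to_json_dict(self) -> dict:
        return {
            "beta_hat": [float(b) for b in self.beta_hat],
            "loglik": float(self.loglik),
            "env_ids": list(self.env_ids),
        }


# ---------------------------------------------------------------------------
# eigenbasis engine
# ---------------------------------------------------------------------------


class RotatedSolver:
    """Shared computational core for the marginal (GLS) formulation.

    In the eigenbasis K = U diag(d) U', a fully-observed trial has marginal
    covariance blocks ``Sigma_k = d_k G0_eff + R0`` over independent l-vectors.
    Missing cells are handled exactly by deleting rows of the balanced
    system: with A = V_full^-1 and D the deleted index set,

        V_obs^-1 = A_OO - A_OD (A_DD)^-1 A_DO,
        log|V_obs| = log|V_full| + log|A_DD|,

    and A applied to any padded vector stays cheap blockwise. The object is
    built once per (design, K) and evaluated many times at different
    variance components, which is what REML optimization needs.
    """

    def __init__(self, design: METDesign, K: KinshipMatrix):
        if K.n_lines != design.n_lines or list(K.line_ids) != list(design.line_ids):
            raise ModelError("kinship and design disagree on lines")
        self.design = design
        n, l = design.n_lines, design.n_env
        self.n, self.l = n, l
        d, U = np.linalg.eigh(K.values)
        self.d = np.clip(d, 0.0, None)
        self.U = U
        y0 = np.where(design.obs_mask, design.y_cells, 0.0)
        self.Uy = U.T @ y0  # n x l (component k, env e)
        UM = U.T @ design.obs_mask.astype(float)  # n x l
        # rotated fixed effects: Xt[k, e, :] = UM[k, e] * X_env[e]
        self.Xt = UM[:, :, None] * design.X_env[None, :, :]
        self.p = design.p
        # deleted (unobserved) cells
        del_i, del_e = np.where(~design.obs_mask)
        self.m = del_i.size
        self.del_e = del_e
        self.Ud = U[del_i, :].T.copy()  # n x m (component k, deleted cell j)
        # deleted cells grouped by environment: correction blocks become GEMMs
        self._del_groups = [
            (e, np.where(del_e == e)[0]) for e in range(l) if (del_e == e).any()
        ]
        _, X_obs, _ = design.stacked()
        sign, self.logdet_XtX = np.linalg.slogdet(X_obs.T @ X_obs)
        if sign <= 0:
            raise NumericalError("fixed-effects incidence X is rank deficient")
        self.n_obs = design.n_obs
        # stacked RHS [y, X] in rotated space: (n, l, 1+p)
        self.RHS = np.concatenate([self.Uy[:, :, None], self.Xt], axis=2)

    # -- core pieces -------------------------------------------------------

    def _blocks(self, G0_eff: np.ndarray, R0m: np.ndarray) -> np.ndarray:
        return self.d[:, None, None] * G0_eff[None] + R0m[None]

    def _gram(self, Sig):
        """Gram matrix [y X]' V_obs^-1 [y X], log|V_obs| and solver state."""
        try:
            cho = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            raise NumericalError("marginal covariance block not positive definite")
        logdet = 2.0 * float(np.sum(np.log(np.diagonal(cho, axis1=1, axis2=2))))
        c = self.RHS.shape[2]
        Cinv = np.linalg.inv(Sig)  # (n, l, l)
        s = Cinv @ self.RHS  # (n, l, 1+p)
        M = self.RHS.reshape(-1, c).T @ s.reshape(-1, c)
        state = {"s": s, "Cinv": Cinv}
        if self.m:
            # sD[j, c] = sum_k Ud[k, j] * s[k, e_j, c], blocked by env
            sD = np.empty((self.m, c))
            for e, idx in self._del_groups:
                sD[idx] = self.Ud[:, idx].T @ s[:, e, :]
            ADD = np.empty((self.m, self.m))
            for a, ia in self._del_groups:
                for b, ib in self._del_groups:
                    ADD[np.ix_(ia, ib)] = self.Ud[:, ia].T @ (
                        Cinv[:, a, b, None] * self.Ud[:, ib]
                    )
            try:
                cf = np.linalg.cholesky(ADD)
            except np.linalg.LinAlgError:
                raise NumericalError("deleted-cell correction block not PD")
            logdet += 2.0 * float(np.sum(np.log(np.diag(cf))))
            alpha = np.linalg.solve(ADD, sD)
            M = M - sD.T @ alpha
            state["ADD"] = ADD
        return M, logdet, state

    def reml_loglik(self, G0_eff: np.ndarray, R0m: np.ndarray) -> float:
        """Restricted log-likelihood (orthonormal-projection convention)."""
        Sig = self._blocks(G0_eff, R0m)
        M, logdet_V, _ = self._gram(Sig)
        XtViX = M[1:, 1:]
        XtViy = M[1:, 0]
        yViy = M[0, 0]
        sign, logdet_C = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise NumericalError("X' V^-1 X singular")
        beta = np.linalg.solve(XtViX, XtViy)
        quad = yViy - XtViy @ beta
        return -0.5 * (
            quad
            + logdet_V
            + logdet_C
            - self.logdet_XtX
            + (self.n_obs - self.p) * _LOG2PI
        )

    def gls(self, G0_eff: np.ndarray, R0m: np.ndarray):
        """GLS fixed effects and the rotated representation of the padded
        vector V_obs^-1 (y - X beta)."""
        Sig = self._blocks(G0_eff, R0m)
        M, logdet_V, state = self._gram(Sig)
        XtViX, XtViy, yViy = M[1:, 1:], M[1:, 0], M[0, 0]
        beta = np.linalg.solve(XtViX, XtViy)
        s = state["s"]
        s_r = s[:, :, 0] - s[:, :, 1:] @ beta  # V^-1 applied to padded residual
        if self.m:
            Cinv = state["Cinv"]
            sD = np.empty(self.m)
            for e, idx in self._del_groups:
                sD[idx] = self.Ud[:, idx].T @ s_r[:, e]
            alpha = np.linalg.solve(state["ADD"], sD)
            for e, idx in self._del_groups:
                s_r = s_r - Cinv[:, :, e] * (self.Ud[:, idx] @ alpha[idx])[:, None]
        quad = yViy - XtViy @ beta
        sign, logdet_C = np.linalg.slogdet(XtViX)
        ll = -0.5 * (
            quad
            + logdet_V
            + logdet_C
            - self.logdet_XtX
            + (self.n_obs - self.p) * _LOG2PI
        )
        return beta, s_r, ll

    def solve(self, vc: VarianceComponents) -> FitResult:
        """BLUE/BLUP at fixed variance components via the conditional mean."""
        G0_eff = vc.effective_G0()
        R0m = build_covariance(vc.R0)
        beta, s_r, ll = self.gls(G0_eff, R0m)
        d = self.d
        # u over all cells: (G0 (x) K) applied to the padded GLS residual
        g = (d[:, None] * s_r) @ G0_eff
        u_cells = self.U @ g  # n x l
        if vc.model == 1:
            return FitResult(
                beta, u_cells, None, u_cells, ll,
                list(self.design.line_ids), list(self.design.env_ids),
            )
        if vc.model == 2:
            u_main = self.U @ (vc.sigma_g2 * d * s_r.sum(axis=1))
            v = self.U @ (vc.sigma_v2 * d[:, None] * s_r)
            gebv = u_main[:, None] + v
            return FitResult(
                beta, u_main, v, gebv, ll,
                list(self.design.line_ids), list(self.design.env_ids),
            )
        u = u_cells[:, 0]
        return FitResult(
            beta, u, None, u_cells, ll,
            list(self.design.line_ids), list(self.design.env_ids),
        )

    def predict_new_lines(
        self, vc: VarianceComponents, K_cross: np.ndarray, beta, s_r
    ) -> np.ndarray:
        """GEBVs of lines absent from the design, from the cross-covariance
        block K_cross (n_new x n_train) with the training lines."""
        G0_eff = vc.effective_G0()
        t = self.U @ s_r  # padded V_obs^-1 residual back in line space
        return (K_cross @ t) @ G0_eff


# ---------------------------------------------------------------------------
# dense Henderson MME (reference path)
# ---------------------------------------------------------------------------


def _dense_mme(design: METDesign, vc: VarianceComponents, K: KinshipMatrix) -> FitResult:
    n, l = design.n_lines, design.n_env
    y, X, cells = design.stacked()
    N = y.size
    R0m = build_covariance(vc.R0)
    Rfull = np.kron(R0m, np.eye(n))
    flat = cells[:, 1] * n + cells[:, 0]
    R = Rfull[np.ix_(flat, flat)]
    Ri = np.linalg.inv(R)
    Kv = K.values
    w = np.linalg.eigvalsh(Kv)
    if w[0] < 1e-10 * max(1.0, w[-1]):
        Kv = Kv + 1e-8 * np.eye(n)
    Ki = np.linalg.inv(Kv)

    if vc.model in (1, 3):
        G0_eff = vc.effective_G0()
        q = n * l
        Z = np.zeros((N, q))
        Z[np.arange(N), flat] = 1.0
        try:
            Gi = np.kron(np.linalg.inv(G0_eff), Ki)
        except np.linalg.LinAlgError:
            raise NumericalError("genetic covariance block G0 (x) K is singular")
    else:
        q = n + n * l
        Z = np.zeros((N, q))
        Z[np.arange(N), cells[:, 0]] = 1.0  # u block
        Z[np.arange(N), n + flat] = 1.0  # v block
        Gi = np.zeros((q, q))
        Gi[:n, :n] = Ki / vc.sigma_g2
        Gi[n:, n:] = np.kron(np.eye(l), Ki) / vc.sigma_v2

    p = X.shape[1]
    C = np.zeros((p + q, p + q))
    C[:p, :p] = X.T @ Ri @ X
    C[:p, p:] = X.T @ Ri @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Ri @ Z + Gi
    rhs = np.concatenate([X.T @ Ri @ y, Z.T @ Ri @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError:
        raise NumericalError("singular mixed-model coefficient matrix")
    beta = sol[:p]
    if vc.model in (1, 3):
        u_cells = sol[p:].reshape(l, n).T
        ll = restricted_loglik(design, vc, K)
        if vc.model == 1:
            return FitResult(beta, u_cells, None, u_cells, ll,
                             list(design.line_ids), list(design.env_ids))
        return FitResult(beta, u_cells[:, 0], None, u_cells, ll,
                         list(design.line_ids), list(design.env_ids))
    u_main = sol[p : p + n]
    v = sol[p + n :].reshape(l, n).T
    ll = restricted_loglik(design, vc, K)
    return FitResult(beta, u_main, v, u_main[:, None] + v, ll,
                     list(design.line_ids), list(design.env_ids))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def solve_mme(
    design: METDesign,
    vc: VarianceComponents,
    K: KinshipMatrix,
    engine: str = "rotated",
) -> FitResult:
    """Solve the mixed model at fixed variance components.

    ``engine='rotated'`` (default) uses the eigenbasis conditional-mean
    formulation; ``engine='dense'`` assembles and solves the Henderson
    mixed-model equations directly. The two agree to numerical precision.
    """
    if vc.model != design.model:
        raise ModelError(
            f"variance components are for model {vc.model}, design is model {design.model}"
        )
    if vc.n_env != design.n_env:
        raise ModelError("variance components and design disagree on environments")
    if engine == "dense":
        return _dense_mme(design, vc, K)
    if engine != "rotated":
        raise ValueError(f"unknown engine {engine!r}")
    return RotatedSolver(design, K).solve(vc)


def restricted_loglik(
    design: METDesign, vc: VarianceComponents, K: KinshipMatrix
) -> float:
    """REML log-likelihood of the variance components given the design.

    Defined as the log-density of B'y ~ N(0, B'VB) where B is an orthonormal
    basis of the orthogonal complement of the fixed-effects column space and
    V = Z G Z' + R is the dense marginal covariance.
    """
    if vc.model != design.model or vc.n_env != design.n_env:
        raise ModelError("variance components do not match the design")
    solver = RotatedSolver(design, K)
    return solver.reml_loglik(vc.effective_G0(), build_covariance(vc.R0))
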