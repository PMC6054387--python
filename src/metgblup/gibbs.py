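"""Bayesian estimation of the MET models by Gibbs sampling.

The sampler works in the eigenbasis of K (K = U diag(d) U'): writing
``u = U diag(sqrt(d)) a`` the breeding-value prior becomes ``a_k ~ N(0, G0)``
independently over eigencomponents, so every full conditional factorizes
into small l-dimensional problems. Updates:

- (beta, a): Gaussian full conditionals (beta with a vague large-variance
  normal prior);
- G0 (Model 1): inverse-Wishart conjugate update; sigma_g^2, sigma_v^2
  (Models 2-3): scaled-inverse-chi-square updates;
- R0: inverse-Wishart for US, scaled-inverse-chi-square for IDV/IDH, and
  an adaptive Metropolis-within-Gibbs step on unconstrained coordinates
  for ANT1 (random-walk scale tuned toward 20-40% acceptance during
  burn-in);
- unobserved phenotype cells: data augmentation — each sweep they are
  drawn from their Gaussian full conditional, which keeps the completed
  trial balanced and lets held-out cells be predicted from a line's
  records in the other environments.

Priors follow common practice for multivariate GBLUP: inverse-Wishart
scale matrices diagonal in the per-environment univariate variance
estimates, weakly-informative degrees of freedom l + 1 (scalar variances:
scaled-inverse-chi-square with 3 df), and an essentially flat Gaussian
prior on fixed effects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .covstruct import (
    ResidualStructure,
    build_covariance,
    inverse_transform,
    unconstrained_transform,
)
from .exceptions import ModelError, PriorError
from .grm import KinshipMatrix
from .models import METDesign, VarianceComponents
from .reml import init_from_univariate

__all__ = ["PriorSpec", "PosteriorChain", "run_mcmc", "posterior_mode", "point_gebv"]

logger = logging.getLogger("metgblup.gibbs")


@dataclass
class PriorSpec:
    """Priors for the Bayesian path.

    ``G0_scale``/``R0_scale`` are the inverse-Wishart scale matrices
    (diagonal, from univariate variance estimates); ``var_df``/``var_scale``
    parameterize the scaled-inverse-chi-square priors used for scalar
    variances (IDV/IDH/ANT1 residual variances, sigma_g^2, sigma_v^2).
    ANT1 adjacent correlations have a uniform(-1, 1) prior.
    """

    n_env: int
    G0_scale: np.ndarray
    G0_df: float
    R0_scale: np.ndarray
    R0_df: float
    var_df: float = 3.0
    var_scale: np.ndarray | None = None  # per-env s0^2 for scalar variances
    beta_var: float = 1e8

    def __post_init__(self):
        l = self.n_env
        self.G0_scale = np.atleast_2d(np.asarray(self.G0_scale, float))
        self.R0_scale = np.atleast_2d(np.asarray(self.R0_scale, float))
        if self.G0_df <= l - 1 or self.R0_df <= l - 1:
            raise PriorError(f"inverse-Wishart df must exceed l-1 = {l - 1}")
        if np.linalg.eigvalsh(self.G0_scale)[0] <= 0:
            raise PriorError("G0 prior scale must be positive definite")
        if self.var_scale is None:
            self.var_scale = np.diag(self.R0_scale).copy()
        self.var_scale = np.atleast_1d(np.asarray(self.var_scale, float))
        if self.beta_var < 1e6:
            raise PriorError("beta prior variance must be vague (>= 1e6)")


def default_prior(design: METDesign, K: KinshipMatrix) -> PriorSpec:
    """Diagonal inverse-Wishart scales from per-environment univariate fits."""
    l = design.n_env
    uni = init_from_univariate(design, K, "IDH" if l > 1 else "IDV")
    if design.model == 1:
        g_diag = np.diag(uni.G0)
        e_diag = np.atleast_1d(uni.sigma_e2)
    elif design.model == 2:
        g_diag = np.full(l, uni.sigma_g2 + uni.sigma_v2)
        e_diag = np.atleast_1d(uni.sigma_e2)
        if e_diag.size == 1:
            e_diag = np.full(l, e_diag[0])
    else:
        g_diag = np.array([uni.sigma_g2])
        e_diag = np.array([uni.sigma_e2])
    return PriorSpec(
        n_env=l,
        G0_scale=np.diag(g_diag),
        G0_df=l + 1,
        R0_scale=np.diag(e_diag),
        R0_df=l + 1,
        var_scale=e_diag,
    )


@dataclass
class PosteriorChain:
    """Thinned posterior draws of variance parameters and GEBVs."""

    model: int
    structure_kind: str
    params: dict[str, np.ndarray]
    gebv_draws: np.ndarray  # (n_stored, n_lines, l)
    n_iter: int
    burnin: int
    thin: int
    seed: int
    line_ids: list[str]
    env_ids: list[str]
    acceptance_rate: float | None = None

    @property
    def n_stored(self) -> int:
        return self.gebv_draws.shape[0]

    def parameter(self, name: str) -> np.ndarray:
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}; have {sorted(self.params)}")
        return self.params[name]

    def G0_draws(self) -> np.ndarray:
        """(n_stored, l, l) genetic covariance draws."""
        l = len(self.env_ids)
        out = np.zeros((self.n_stored, l, l))
        for i in range(l):
            for j in range(i + 1):
                v = self.params[f"G0_{i + 1}_{j + 1}"]
                out[:, i, j] = out[:, j, i] = v
        return out


def _sample_invgamma(rng, df: float, ssq: float) -> float:
    # scaled-inverse-chi-square(df, ssq/df) draw
    return float(ssq / rng.chisquare(df))


def _logpdf_scaled_inv_chi2(x, nu, s2):
    # density of sigma^2 ~ nu*s2 / chi2_nu
    return (
        0.5 * nu * np.log(s2 * nu / 2.0)
        - np.log(x) * (nu / 2.0 + 1.0)
        - nu * s2 / (2.0 * x)
        - math.lgamma(nu / 2.0)
    )


class _Ant1Step:
    """Adaptive random-walk Metropolis update of ANT1 on unconstrained
    coordinates (log standard deviations, Fisher-z correlations)."""

    def __init__(self, l: int, prior: PriorSpec):
        self.l = l
        self.prior = prior
        self.scale = 0.1
        self.accepted = 0
        self.proposed = 0
        self.window_accepted = 0
        self.post_adapt_accepted = 0
        self.post_adapt_proposed = 0

    def log_target(self, theta: np.ndarray, S: np.ndarray, n: int) -> float:
        rs = inverse_transform(theta, "ANT1", self.l)
        R0 = build_covariance(rs)
        sign, logdet = np.linalg.slogdet(R0)
        if sign <= 0:
            return -np.inf
        ll = -0.5 * (n * logdet + np.trace(np.linalg.solve(R0, S)))
        sd = rs.params[: self.l]
        rho = rs.params[self.l :]
        var = sd**2
        nu, s2 = self.prior.var_df, self.prior.var_scale
        # prior on variances + Jacobian d sigma^2 / d log sd = 2 sigma^2
        lp = float(
            np.sum(_logpdf_scaled_inv_chi2(var, nu, s2) + np.log(2.0 * var))
        )
        # uniform(-1,1) on rho + Jacobian d rho / dz = 1 - rho^2
        lp += float(np.sum(np.log1p(-(rho**2))))
        return ll + lp

    def update(self, rs, S, n, rng, adapting: bool):
        theta = unconstrained_transform(rs)
        cur = self.log_target(theta, S, n)
        prop = theta + self.scale * rng.standard_normal(theta.size)
        new = self.log_target(prop, S, n)
        self.proposed += 1
        accept = np.log(rng.random()) < new - cur
        if not adapting:
            self.post_adapt_proposed += 1
            self.post_adapt_accepted += int(accept)
        if accept:
            self.accepted += 1
            self.window_accepted += 1
            theta = prop
        if adapting and self.proposed % 50 == 0:
            rate = self.window_accepted / 50.0
            if rate > 0.40:
                self.scale *= 1.3
            elif rate < 0.20:
                self.scale /= 1.3
            self.window_accepted = 0
        return inverse_transform(theta, "ANT1", self.l)


def _split_rhat(x: np.ndarray) -> float:
    n = x.size // 2
    a, b = x[:n], x[n : 2 * n]
    W = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    B = n * np.var([a.mean(), b.mean()], ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((W * (n - 1) / n + B / n) / W))


def run_mcmc(
    design: METDesign,
    K: KinshipMatrix,
    structure_kind: str = "US",
    prior: PriorSpec | None = None,
    n_iter: int = 10_000,
    burnin: int = 3_000,
    thin: int = 10,
    seed: int = 0,
    fix: dict | None = None,
) -> PosteriorChain:
    """Gibbs sampler for the model of ``design`` with residual structure
    ``structure_kind``; reproducible given ``seed``.

    ``fix`` freezes blocks at given values (keys among ``beta``, ``u``,
    ``G0``, ``sigma_g2``, ``sigma_v2``, ``R0``) and is meant for
    validating individual conditional updates against closed forms.
    """
    model = design.model
    l = design.n_env
    if n_iter <= burnin:
        raise ModelError("n_iter must exceed burnin")
    if model == 3:
        structure_kind = "IDV"
    if model == 2 and structure_kind not in ("IDV", "IDH"):
        raise ModelError("Model 2 residuals are IDV or IDH")
    if prior is None:
        prior = default_prior(design, K)
    if prior.n_env != l:
        raise PriorError("prior dimension does not match the design")
    fix = fix or {}
    rng = np.random.default_rng(seed)

    n = design.n_lines
    d_raw, U = np.linalg.eigh(K.values)
    d = np.clip(d_raw, 1e-12, None)
    sqd = np.sqrt(d)
    ux = U.T @ np.ones(n)
    X_env = design.X_env
    p = X_env.shape[1]
    obs = design.obs_mask
    miss_any = not obs.all()
    # group lines by missing pattern for vectorized augmentation
    patterns: dict[tuple, np.ndarray] = {}
    if miss_any:
        keys = [tuple(row) for row in obs]
        for i, k in enumerate(keys):
            if not all(k):
                patterns.setdefault(k, []).append(i)
        patterns = {k: np.array(v) for k, v in patterns.items()}

    # --- initial state -----------------------------------------------------
    col_mean = np.array(
        [
            np.nanmean(design.y_cells[:, e]) if obs[:, e].any() else 0.0
            for e in range(l)
        ]
    )
    y_complete = np.where(obs, design.y_cells, col_mean[None, :])
    beta = np.asarray(
        fix.get("beta", np.linalg.lstsq(X_env, col_mean, rcond=None)[0]), float
    )
    if model == 1:
        G0 = np.asarray(fix.get("G0", prior.G0_scale.copy()), float)
    else:
        sigma_g2 = float(fix.get("sigma_g2", prior.var_scale.mean()))
        sigma_v2 = float(fix.get("sigma_v2", prior.var_scale.mean()))
    if "R0" in fix:
        rs = fix["R0"]
    else:
        if structure_kind == "US":
            rs = ResidualStructure("US", l, prior.R0_scale[np.tril_indices(l)])
        elif structure_kind == "IDH":
            rs = ResidualStructure("IDH", l, prior.var_scale.copy())
        elif structure_kind == "ANT1":
            rs = ResidualStructure(
                "ANT1", l, np.concatenate([np.sqrt(prior.var_scale), np.zeros(l - 1)])
            )
        else:
            rs = ResidualStructure("IDV", l, np.array([float(prior.var_scale.mean())]))
    if "u" in fix:
        if model == 2:
            raise ModelError("freezing u is only supported for models 1 and 3")
        u_fixed = np.asarray(fix["u"], float)
        if u_fixed.ndim == 1:
            u_fixed = u_fixed[:, None]
        a = (U.T @ u_fixed) / sqd[:, None]
    else:
        a = np.zeros((n, l)) if model != 2 else None
    if model == 2 and "u" not in fix:
        a_u = np.zeros(n)
        a_v = np.zeros((n, l))
    ant1 = _Ant1Step(l, prior) if structure_kind == "ANT1" else None

    n_stored = int(np.ceil((n_iter - burnin) / thin))
    gebv_draws = np.empty((n_stored, n, l))
    store: dict[str, np.ndarray] = {}

    def store_names():
        names = [f"beta_{j + 1}" for j in range(p)]
        if model == 1:
            names += [
                f"G0_{i + 1}_{j + 1}" for i in range(l) for j in range(i + 1)
            ]
        else:
            names += ["sigma_g2"] + (["sigma_v2"] if model == 2 else [])
        if structure_kind == "US":
            names += [f"R0_{i + 1}_{j + 1}" for i in range(l) for j in range(i + 1)]
        elif structure_kind == "IDH":
            names += [f"R0_sigma2_{e + 1}" for e in range(l)]
        elif structure_kind == "ANT1":
            names += [f"R0_sd_{e + 1}" for e in range(l)]
            names += [f"R0_rho_{e + 1}" for e in range(l - 1)]
        else:
            names += ["R0_sigma2"]
        return names

    for name in store_names():
        store[name] = np.empty(n_stored)

    idx_store = 0
    for t in range(n_iter):
        R0m = build_covariance(rs)
        R0inv = np.linalg.inv(R0m)

        # current breeding values in line space (per-environment)
        if model == 2:
            u_cells = (U @ (sqd * a_u))[:, None] + U @ (sqd[:, None] * a_v)
        else:
            u_cells = U @ (sqd[:, None] * a)

        # (1) data augmentation of unobserved cells
        if miss_any:
            mean_cells = (X_env @ beta)[None, :] + u_cells
            for key, idx in patterns.items():
                o = np.array(key, bool)
                mlist = np.where(~o)[0]
                olist = np.where(o)[0]
                if olist.size:
                    Roo = R0m[np.ix_(olist, olist)]
                    Rmo = R0m[np.ix_(mlist, olist)]
                    A = np.linalg.solve(Roo, Rmo.T).T
                    cond_cov = R0m[np.ix_(mlist, mlist)] - A @ Rmo.T
                    eps_o = (design.y_cells[np.ix_(idx, olist)]
                             - mean_cells[np.ix_(idx, olist)])
                    mu = eps_o @ A.T
                else:
                    cond_cov = R0m[np.ix_(mlist, mlist)]
                    mu = np.zeros((idx.size, mlist.size))
                Lc = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(mlist.size))
                draw = mu + rng.standard_normal(mu.shape) @ Lc.T
                rows = np.repeat(idx, mlist.size)
                cols = np.tile(mlist, idx.size)
                y_complete[rows, cols] = (mean_cells[np.ix_(idx, mlist)] + draw).ravel()
        yt = U.T @ y_complete  # rotated completed data (n x l)

        # (2) fixed effects — collapsed over the breeding values, so that the
        # subsequent a-draw makes (beta, u) a joint Gaussian update; sampling
        # beta conditionally on u mixes poorly because the family-mean
        # eigencomponents of u are nearly confounded with the intercepts
        if "beta" not in fix:
            if "u" in fix:
                # u frozen: draw beta from its conditional given u
                resid_rot = yt - sqd[:, None] * a
                prec = n * (X_env.T @ R0inv @ X_env) + np.eye(p) / prior.beta_var
                rhs = X_env.T @ R0inv @ (resid_rot.T @ ux)
            else:
                if model == 1:
                    G0_eff = G0
                elif model == 2:
                    G0_eff = sigma_g2 * np.ones((l, l)) + sigma_v2 * np.eye(l)
                else:
                    G0_eff = np.array([[sigma_g2]])
                SigInv = np.linalg.inv(
                    d[:, None, None] * G0_eff[None] + R0m[None]
                )
                S1 = np.tensordot(ux**2, SigInv, axes=(0, 0))  # sum ux_k^2 Sig_k^-1
                tvec = np.einsum("k,kab,kb->a", ux, SigInv, yt)
                prec = X_env.T @ S1 @ X_env + np.eye(p) / prior.beta_var
                rhs = X_env.T @ tvec
            Lp = np.linalg.cholesky(prec)
            mean_b = np.linalg.solve(prec, rhs)
            beta = mean_b + np.linalg.solve(Lp.T, rng.standard_normal(p))

        # (3) breeding values
        z = yt - np.outer(ux, X_env @ beta)  # n x l
        if "u" not in fix:
            if model == 2:
                M = np.hstack([np.ones((l, 1)), np.eye(l)])  # maps (a_u, a_v)
                MR = M.T @ R0inv @ M  # (1+l) x (1+l)
                prior_prec = np.diag(
                    np.concatenate([[1.0 / sigma_g2], np.full(l, 1.0 / sigma_v2)])
                )
                P = prior_prec[None] + d[:, None, None] * MR[None]
                rhs = sqd[:, None] * (z @ (R0inv @ M))
                L = np.linalg.cholesky(P)
                mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
                noise = np.linalg.solve(
                    np.transpose(L, (0, 2, 1)),
                    rng.standard_normal((n, 1 + l, 1)),
                )[:, :, 0]
                b = mean + noise
                a_u, a_v = b[:, 0], b[:, 1:]
            else:
                G0inv = (
                    np.linalg.inv(G0) if model == 1 else np.array([[1.0 / sigma_g2]])
                )
                P = G0inv[None] + d[:, None, None] * R0inv[None]
                rhs = sqd[:, None] * (z @ R0inv)
                L = np.linalg.cholesky(P)
                mean = np.linalg.solve(P, rhs[:, :, None])[:, :, 0]
                noise = np.linalg.solve(
                    np.transpose(L, (0, 2, 1)), rng.standard_normal((n, l, 1))
                )[:, :, 0]
                a = mean + noise

        # (4) genetic (co)variances
        if model == 1 and "G0" not in fix:
            S = prior.G0_scale + a.T @ a
            G0 = stats.invwishart.rvs(df=prior.G0_df + n, scale=S, random_state=rng)
            G0 = np.atleast_2d(G0)
        elif model == 2:
            if "sigma_g2" not in fix:
                sigma_g2 = _sample_invgamma(
                    rng,
                    prior.var_df + n,
                    prior.var_df * float(prior.var_scale.mean()) + float(a_u @ a_u),
                )
            if "sigma_v2" not in fix:
                sigma_v2 = _sample_invgamma(
                    rng,
                    prior.var_df + n * l,
                    prior.var_df * float(prior.var_scale.mean())
                    + float(np.sum(a_v**2)),
                )
        elif model == 3 and "sigma_g2" not in fix:
            sigma_g2 = _sample_invgamma(
                rng,
                prior.var_df + n,
                prior.var_df * float(prior.var_scale.mean()) + float(np.sum(a**2)),
            )

        # (5) residual structure
        if "R0" not in fix:
            if model == 2:
                eps = z - sqd[:, None] * (a_u[:, None] + a_v)
            else:
                eps = z - sqd[:, None] * a
            if structure_kind == "US":
                S = prior.R0_scale + eps.T @ eps
                R0new = stats.invwishart.rvs(
                    df=prior.R0_df + n, scale=S, random_state=rng
                )
                rs = ResidualStructure("US", l, np.atleast_2d(R0new)[np.tril_indices(l)])
            elif structure_kind == "IDH":
                s2 = np.array(
                    [
                        _sample_invgamma(
                            rng,
                            prior.var_df + n,
                            prior.var_df * prior.var_scale[e]
                            + float(eps[:, e] @ eps[:, e]),
                        )
                        for e in range(l)
                    ]
                )
                rs = ResidualStructure("IDH", l, s2)
            elif structure_kind == "IDV":
                s2 = _sample_invgamma(
                    rng,
                    prior.var_df + n * l,
                    prior.var_df * float(prior.var_scale.mean())
                    + float(np.sum(eps**2)),
                )
                rs = ResidualStructure("IDV", l, np.array([s2]))
            else:
                rs = ant1.update(rs, eps.T @ eps, n, rng, adapting=t < burnin)

        # (6) store
        if t >= burnin and (t - burnin) % thin == 0:
            if model == 2:
                u_main = U @ (sqd * a_u)
                v = U @ (sqd[:, None] * a_v)
                gebv_draws[idx_store] = u_main[:, None] + v
            else:
                gebv_draws[idx_store] = U @ (sqd[:, None] * a)
            for j in range(p):
                store[f"beta_{j + 1}"][idx_store] = beta[j]
            if model == 1:
                for i in range(l):
                    for j in range(i + 1):
                        store[f"G0_{i + 1}_{j + 1}"][idx_store] = G0[i, j]
            else:
                store["sigma_g2"][idx_store] = sigma_g2
                if model == 2:
                    store["sigma_v2"][idx_store] = sigma_v2
            R0cur = build_covariance(rs)
            if structure_kind == "US":
                for i in range(l):
                    for j in range(i + 1):
                        store[f"R0_{i + 1}_{j + 1}"][idx_store] = R0cur[i, j]
            elif structure_kind == "IDH":
                for e in range(l):
                    store[f"R0_sigma2_{e + 1}"][idx_store] = rs.params[e]
            elif structure_kind == "ANT1":
                for e in range(l):
                    store[f"R0_sd_{e + 1}"][idx_store] = rs.params[e]
                for e in range(l - 1):
                    store[f"R0_rho_{e + 1}"][idx_store] = rs.params[l + e]
            else:
                store["R0_sigma2"][idx_store] = rs.params[0]
            idx_store += 1

    acc = None
    if ant1 is not None and ant1.post_adapt_proposed:
        acc = ant1.post_adapt_accepted / ant1.post_adapt_proposed
        if not 0.05 < acc < 0.8:
            logger.warning("ANT1 Metropolis acceptance rate %.2f outside (0.05, 0.8)", acc)
    for name in ("sigma_g2", "R0_sigma2", "G0_1_1"):
        if name in store and store[name].size >= 4:
            logger.debug("split R-hat %s: %.3f", name, _split_rhat(store[name]))

    return PosteriorChain(
        model=model,
        structure_kind=structure_kind,
        params=store,
        gebv_draws=gebv_draws,
        n_iter=n_iter,
        burnin=burnin,
        thin=thin,
        seed=seed,
        line_ids=list(design.line_ids),
        env_ids=list(design.env_ids),
        acceptance_rate=acc,
    )


def posterior_mode(chain: PosteriorChain, parameter: str) -> float:
    """Mode of a Gaussian-kernel density estimate (Silverman bandwidth)
    over the marginal draws of one parameter. Ties in the density grid
    resolve to the lower value."""
    x = chain.parameter(parameter)
    if x.size < 50:
        raise ModelError(f"need >= 50 stored draws for a mode, have {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 1024)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def point_gebv(chain: PosteriorChain) -> np.ndarray:
    """Posterior-mean GEBV per line x environment (u, plus v for Model 2)."""
    return chain.gebv_draws.mean(axis=0)
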