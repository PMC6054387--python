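"""Synthetic multi-environment-trial generator.

Emulates the generative model behind multivariate GBLUP: for line i and
environment e,

    y_ie = beta_e + u_ie + eps_ie,
    vec(u) ~ N(0, G0 (x) K),       eps rows iid ~ N(0, R0) across lines,

with K the additive genomic relationship matrix computed from simulated
biallelic dosages. Markers are drawn in linkage equilibrium (two Bernoulli
draws per marker, allele frequencies uniform on a configurable range); LD is
deliberately not emulated because GBLUP only consumes K. Missing phenotype
cells are missing completely at random, except that a line is never missing
in every environment (the pattern is re-drawn if it would be).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covstruct import ResidualStructure, build_covariance, validate_genetic_covariance
from .exceptions import ModelError
from .grm import KinshipMatrix, MarkerMatrix, compute_grm

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_genotypes",
    "simulate_met",
    "family_kinship",
    "met_config",
    "rice_like_config",
    "maize_like_config",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated MET.

    ``G0`` is the between-environment genetic covariance (trait units
    squared), ``residual_structure`` parameterizes R0, ``env_means`` the
    per-environment fixed means. Allele frequencies are uniform on
    ``allele_freq_range``; the default range mirrors a MAF >= 0.05 panel.
    """

    n_lines: int
    n_markers: int
    G0: np.ndarray
    residual_structure: ResidualStructure
    env_means: np.ndarray
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.G0 = validate_genetic_covariance(self.G0)
        self.env_means = np.atleast_1d(np.asarray(self.env_means, dtype=float))
        l = self.G0.shape[0]
        if self.residual_structure.n_env != l or self.env_means.shape != (l,):
            raise ModelError("G0, residual structure and env_means disagree on l")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.n_lines < 2 or self.n_markers < 1:
            raise ValueError("need n_lines >= 2 and n_markers >= 1")

    @property
    def n_env(self) -> int:
        return self.G0.shape[0]

    def heritability(self, env: int) -> float:
        """Implied per-environment SNP heritability G0_ee / (G0_ee + R0_ee)."""
        R0 = build_covariance(self.residual_structure)
        return self.G0[env, env] / (self.G0[env, env] + R0[env, env])


@dataclass
class SimResult:
    genotypes: MarkerMatrix
    kinship: KinshipMatrix
    phenotypes: pd.DataFrame  # columns line, env, value, observed
    true_u: np.ndarray  # n x l breeding values
    true_beta: np.ndarray
    true_G0: np.ndarray
    true_R0: ResidualStructure

    @property
    def observed_phenotypes(self) -> pd.DataFrame:
        """Long table of observed cells only (line, env, value)."""
        obs = self.phenotypes[self.phenotypes["observed"]]
        return obs[["line", "env", "value"]].reset_index(drop=True)


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    allele_freq_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> MarkerMatrix:
    """Unlinked biallelic dosages: per marker, p ~ U(range), dosage = sum of
    two Bernoulli(p) draws. Deterministic given the seed."""
    if n_lines < 2 or n_markers < 1:
        raise ValueError("need n_lines >= 2 and n_markers >= 1")
    lo, hi = allele_freq_range
    if not (0 < lo <= hi < 1):
        raise ValueError("allele_freq_range must lie inside (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_markers)
    dos = (rng.random((n_lines, n_markers)) < p).astype(float)
    dos += (rng.random((n_lines, n_markers)) < p).astype(float)
    lines = [f"L{i:04d}" for i in range(n_lines)]
    markers = [f"M{j:05d}" for j in range(n_markers)]
    return MarkerMatrix(dos, lines, markers)


def _draw_missing_mask(rng, n: int, l: int, frac: float) -> np.ndarray:
    """MCAR mask (True = missing); lines missing everywhere are re-drawn."""
    if frac == 0:
        return np.zeros((n, l), dtype=bool)
    for _ in range(1000):
        mask = rng.random((n, l)) < frac
        bad = mask.all(axis=1)
        if not bad.any():
            return mask
        # re-draw only the offending lines
        mask[bad] = rng.random((bad.sum(), l)) < frac
        if not mask.all(axis=1).any():
            return mask
    raise ModelError("could not draw a missing pattern leaving every line observed")


def simulate_met(cfg: SimConfig, kinship: KinshipMatrix | None = None) -> SimResult:
    """Simulate one MET under the multivariate model.

    If ``kinship`` is omitted, genotypes are simulated from ``cfg`` and K is
    their VanRaden GRM; otherwise the provided K is used and genotypes are
    still simulated for completeness of the result object.
    """
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(
        cfg.n_lines, cfg.n_markers, cfg.allele_freq_range, seed=rng.integers(2**31)
    )
    if kinship is None:
        kinship = compute_grm(geno)
    elif kinship.n_lines != cfg.n_lines:
        raise ModelError(
            f"kinship has {kinship.n_lines} lines, config says {cfg.n_lines}"
        )
    else:
        geno = MarkerMatrix(geno.dosages, list(kinship.line_ids), geno.marker_ids)

    n, l = cfg.n_lines, cfg.n_env
    K = kinship.values

    # matrix-normal draw: u = L_K Z L_G', so vec(u) (env-major) ~ N(0, G0 (x) K)
    if np.any(cfg.G0):
        Lk = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        Lg = np.linalg.cholesky(
            cfg.G0 + 1e-12 * np.trace(cfg.G0 + np.eye(l)) * np.eye(l)
        )
        u = Lk @ rng.standard_normal((n, l)) @ Lg.T
    else:  # no genetic variance at all: skip the O(n^3) factorization
        u = np.zeros((n, l))

    R0 = build_covariance(cfg.residual_structure)
    Lr = np.linalg.cholesky(R0 + 1e-14 * np.eye(l)) if np.any(R0) else np.zeros((l, l))
    eps = rng.standard_normal((n, l)) @ Lr.T

    y = cfg.env_means[None, :] + u + eps
    miss = _draw_missing_mask(rng, n, l, cfg.missing_fraction)
    return _assemble_result(cfg, geno, kinship, y, u, miss)


def _assemble_result(cfg, geno, kinship, y, u, miss) -> SimResult:
    n, l = cfg.n_lines, cfg.n_env

    env_ids = [f"E{e + 1}" for e in range(l)]
    rows = []
    for e in range(l):  # env-major stacking convention
        for i in range(n):
            rows.append(
                {
                    "line": kinship.line_ids[i],
                    "env": env_ids[e],
                    "value": y[i, e],
                    "observed": not miss[i, e],
                }
            )
    pheno = pd.DataFrame(rows)
    pheno.loc[~pheno["observed"], "value"] = np.nan
    return SimResult(
        genotypes=geno,
        kinship=kinship,
        phenotypes=pheno,
        true_u=u,
        true_beta=cfg.env_means.copy(),
        true_G0=cfg.G0.copy(),
        true_R0=cfg.residual_structure,
    )


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------


def family_kinship(
    n_lines: int, family_size: int = 30, within: float = 0.5
) -> KinshipMatrix:
    """Block kinship of unrelated families with constant within-family
    relatedness, emulating the large full-sib / doubled-haploid families of
    breeding panels. Strong relatedness is what identifies the split
    between genetic and residual covariance in real MET data."""
    if n_lines % family_size:
        raise ValueError("n_lines must be a multiple of family_size")
    K = np.full((n_lines, n_lines), 0.0)
    for f in range(n_lines // family_size):
        s = slice(f * family_size, (f + 1) * family_size)
        K[s, s] = within
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, [f"L{i:04d}" for i in range(n_lines)])


def met_config(
    h2,
    genomic_corr,
    n_lines: int = 300,
    n_markers: int = 1000,
    residual_kind: str = "IDH",
    seed: int = 0,
) -> SimConfig:
    """MET study conditions from per-environment heritabilities and a
    between-environment genomic correlation matrix.

    Genetic variances are fixed at 1 per environment; the heritability
    pattern is expressed through heterogeneous residual variances
    ``(1 - h2) / h2``, mirroring how real panels combine a common genetic
    scale with location-dependent noise.
    """
    h2 = np.asarray(h2, float)
    l = h2.size
    C = np.asarray(genomic_corr, float)
    rvar = (1.0 - h2) / h2
    if residual_kind == "IDH":
        rs = ResidualStructure("IDH", l, rvar)
    elif residual_kind == "IDV":
        rs = ResidualStructure("IDV", l, np.array([float(rvar.mean())]))
    else:
        raise ValueError("met_config residuals are IDH or IDV")
    return SimConfig(
        n_lines=n_lines,
        n_markers=n_markers,
        G0=C,
        residual_structure=rs,
        env_means=np.linspace(10.0, 10.0 + 2.0 * (l - 1), l),
        seed=seed,
    )


def rice_like_config(n_lines: int = 300, n_markers: int = 1000, seed: int = 0) -> SimConfig:
    """High between-environment genomic correlation with strongly varying
    heritability (0.71 / 0.47 / 0.24) — the weak-GxE regime."""
    corr = np.array([[1.0, 0.63, 0.77], [0.63, 1.0, 0.65], [0.77, 0.65, 1.0]])
    return met_config((0.71, 0.47, 0.24), corr, n_lines, n_markers, seed=seed)


def maize_like_config(n_lines: int = 300, n_markers: int = 1000, seed: int = 0) -> SimConfig:
    """Low genomic correlation (strong GxE) with heritabilities
    0.58 / 0.73 / 0.41."""
    corr = np.array([[1.0, 0.54, 0.30], [0.54, 1.0, 0.11], [0.30, 0.11, 1.0]])
    return met_config((0.58, 0.73, 0.41), corr, n_lines, n_markers, seed=seed)
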