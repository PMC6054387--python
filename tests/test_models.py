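"""Mixed-model solver tests against independent dense multivariate-normal
oracles: the BLUP must equal the joint-Gaussian conditional mean E[u|y], and
the restricted likelihood the log-density of the data projected onto the
orthogonal complement of the fixed-effects space."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from metgblup.covstruct import ResidualStructure, build_covariance
from metgblup.exceptions import ModelError
from metgblup.grm import KinshipMatrix
from metgblup.models import (
    VarianceComponents,
    build_design,
    genomic_correlation,
    heritability,
    restricted_loglik,
    solve_mme,
)

from .conftest import long_phenotypes, random_kinship, random_pd, random_structure


def dense_oracle(design, vc, K):
    """Brute-force conditional mean and projected REML likelihood from the
    explicit dense covariance V = G0 (x) K + R0 (x) I."""
    n, l = design.n_lines, design.n_env
    y, X, cells = design.stacked()
    flat = cells[:, 1] * n + cells[:, 0]
    Gfull = np.kron(vc.effective_G0(), K.values)
    Rfull = np.kron(build_covariance(vc.R0), np.eye(n))
    V = (Gfull + Rfull)[np.ix_(flat, flat)]
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = (Gfull[:, flat] @ (Vi @ (y - X @ beta))).reshape(l, n).T
    B = null_space(X.T)
    BVB = B.T @ V @ B
    z = B.T @ y
    _, ld = np.linalg.slogdet(BVB)
    ll = -0.5 * (
        z @ np.linalg.solve(BVB, z) + ld + (y.size - X.shape[1]) * np.log(2 * np.pi)
    )
    return beta, u, ll


def random_instance(kind, model, rng, n=7, l=3, drop=0.2):
    K = random_kinship(n, rng)
    if model == 1:
        vc = VarianceComponents(1, random_structure(kind, l, rng), G0=random_pd(l, rng))
    else:
        rs = random_structure(kind if kind in ("IDV", "IDH") else "IDV", l, rng)
        vc = VarianceComponents(2, rs, sigma_g2=0.8, sigma_v2=0.5)
    y = rng.standard_normal((n, l))
    ph = long_phenotypes(y, K.line_ids, [f"E{e}" for e in range(l)], drop, rng)
    design = build_design(ph, K.line_ids, model, env_ids=[f"E{e}" for e in range(l)])
    return design, vc, K


class TestSolveAgainstDenseOracle:
    @pytest.mark.parametrize("kind", ["US", "IDH", "IDV", "ANT1"])
    @pytest.mark.parametrize("model", [1, 2])
    def test_blup_equals_conditional_mean(self, kind, model, rng):
        design, vc, K = random_instance(kind, model, rng)
        beta_o, u_o, _ = dense_oracle(design, vc, K)
        fit = solve_mme(design, vc, K)
        assert np.allclose(fit.beta_hat, beta_o, atol=1e-8)
        assert np.allclose(fit.gebv, u_o, atol=1e-8)
        if model == 2:
            # GEBV decomposes into main effect plus interaction
            assert np.allclose(
                fit.gebv, fit.u_hat[:, None] + fit.v_hat, atol=1e-10
            )

    @pytest.mark.parametrize("kind", ["US", "IDH", "IDV", "ANT1"])
    def test_dense_mme_agrees_with_rotated_engine(self, kind, rng):
        design, vc, K = random_instance(kind, 1, rng)
        a = solve_mme(design, vc, K, engine="rotated")
        b = solve_mme(design, vc, K, engine="dense")
        assert np.allclose(a.beta_hat, b.beta_hat, atol=1e-8)
        assert np.allclose(a.gebv, b.gebv, atol=1e-7)

    def test_vanishing_genetic_variance_gives_gls_means(self, rng):
        n, l = 12, 2
        K = random_kinship(n, rng)
        vc = VarianceComponents(
            1,
            ResidualStructure("IDV", l, np.array([1.0])),
            G0=1e-12 * np.eye(l),
        )
        y = rng.standard_normal((n, l)) + np.array([5.0, -2.0])
        ph = long_phenotypes(y, K.line_ids, ["E0", "E1"])
        design = build_design(ph, K.line_ids, 1, env_ids=["E0", "E1"])
        fit = solve_mme(design, vc, K)
        assert np.max(np.abs(fit.u_hat)) < 1e-6
        assert np.allclose(fit.beta_hat, y.mean(axis=0), atol=1e-6)

    def test_gebv_shrinks_monotonically_with_residual_variance(self, rng):
        design, vc, K = random_instance("IDV", 1, rng, n=10)
        norms = []
        for c in (0.5, 2.0, 8.0, 32.0):
            vc_c = VarianceComponents(
                1, ResidualStructure("IDV", 3, c * vc.R0.params), G0=vc.G0
            )
            norms.append(np.linalg.norm(solve_mme(design, vc_c, K).gebv))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_model3_with_identity_kinship_is_ridge_regression(self, rng):
        n, sg2, se2 = 20, 1.3, 0.7
        K = KinshipMatrix(np.eye(n), [f"L{i}" for i in range(n)])
        y = rng.standard_normal(n)
        ph = long_phenotypes(y[:, None], K.line_ids, ["E"])
        design = build_design(ph, K.line_ids, 3, env_ids=["E"])
        vc = VarianceComponents(
            3, ResidualStructure("IDV", 1, np.array([se2])), sigma_g2=sg2
        )
        fit = solve_mme(design, vc, K)
        # ridge of centred y on line indicators, penalty se2/sg2
        lam = se2 / sg2
        beta_gls = y.mean()
        expected = (y - beta_gls) / (1 + lam)
        assert np.allclose(fit.u_hat, expected, atol=1e-8)

    def test_single_environment_model1_equals_model3(self, rng):
        n = 9
        K = random_kinship(n, rng)
        y = rng.standard_normal(n)
        ph = long_phenotypes(y[:, None], K.line_ids, ["E"])
        d1 = build_design(ph, K.line_ids, 1, env_ids=["E"])
        d3 = build_design(ph, K.line_ids, 3, env_ids=["E"])
        rs = ResidualStructure("IDV", 1, np.array([0.8]))
        vc1 = VarianceComponents(1, rs, G0=np.array([[1.1]]))
        vc3 = VarianceComponents(3, rs, sigma_g2=1.1)
        f1, f3 = solve_mme(d1, vc1, K), solve_mme(d3, vc3, K)
        assert np.allclose(f1.gebv, f3.gebv, atol=1e-10)
        assert f1.loglik == pytest.approx(f3.loglik, abs=1e-10)


class TestRestrictedLoglik:
    @pytest.mark.parametrize("kind", ["US", "IDH", "IDV", "ANT1"])
    @pytest.mark.parametrize("model", [1, 2])
    def test_matches_dense_projection_oracle(self, kind, model, rng):
        design, vc, K = random_instance(kind, model, rng, n=8)
        _, _, ll_o = dense_oracle(design, vc, K)
        assert restricted_loglik(design, vc, K) == pytest.approx(ll_o, abs=1e-8)

    def test_invariant_under_line_relabeling(self, rng):
        design, vc, K = random_instance("US", 1, rng, n=8, drop=0.0)
        ll = restricted_loglik(design, vc, K)
        perm = list(np.random.default_rng(3).permutation(8))
        ids = [K.line_ids[i] for i in perm]
        K2 = KinshipMatrix(K.values[np.ix_(perm, perm)], ids)
        design2 = build_design(
            long_phenotypes(design.y_cells[perm], ids, design.env_ids),
            ids, 1, env_ids=design.env_ids,
        )
        assert restricted_loglik(design2, vc, K2) == pytest.approx(ll, abs=1e-10)

    def test_scaling_change_of_variables(self, rng):
        # y -> c y with all variances -> c^2: the REML density (a density of
        # N_obs - p linearly projected data points) changes by -(N-p) log c
        design, vc, K = random_instance("IDH", 1, rng, n=8)
        c = 2.5
        ll = restricted_loglik(design, vc, K)
        design_c = build_design(
            long_phenotypes(c * design.y_cells, K.line_ids, design.env_ids),
            K.line_ids, 1, env_ids=design.env_ids,
        )
        # keep the same cells observed
        design_c.y_cells[~design.obs_mask] = np.nan
        design_c.obs_mask[:] = design.obs_mask
        vc_c = VarianceComponents(
            1,
            ResidualStructure("IDH", 3, c**2 * vc.R0.params),
            G0=c**2 * vc.G0,
        )
        ll_c = restricted_loglik(design_c, vc_c, K)
        expected = -(design.n_obs - design.p) * np.log(c)
        assert ll_c - ll == pytest.approx(expected, abs=1e-8)


class TestDesign:
    def test_model1_block_diagonal_intercepts(self):
        y = np.arange(6.0).reshape(3, 2)
        ph = long_phenotypes(y, ["a", "b", "c"], ["E1", "E2"])
        design = build_design(ph, ["a", "b", "c"], 1)
        _, X, _ = design.stacked()
        assert X.shape == (6, 2)
        assert np.array_equal(X[:3], np.tile([1.0, 0.0], (3, 1)))
        assert np.array_equal(X[3:], np.tile([0.0, 1.0], (3, 1)))

    def test_model2_fixed_effects_span_mean_plus_environments(self):
        # the unconstrained parameterization (grand mean + l environment
        # columns) has 1 + l columns and rank l; the sum-to-zero constrained
        # design spans exactly the same space
        y = np.zeros((4, 3))
        ph = long_phenotypes(y, list("abcd"), ["E1", "E2", "E3"])
        design = build_design(ph, list("abcd"), 2)
        unconstrained = np.hstack([np.ones((3, 1)), np.eye(3)])
        assert unconstrained.shape[1] == 1 + 3
        assert np.linalg.matrix_rank(unconstrained) == 3
        assert design.X_env.shape == (3, 3)
        combined = np.hstack([design.X_env, unconstrained])
        assert np.linalg.matrix_rank(combined) == np.linalg.matrix_rank(design.X_env)

    def test_missing_cell_dropped_from_rows_not_columns(self):
        y = np.arange(6.0).reshape(3, 2)
        ph = long_phenotypes(y, ["a", "b", "c"], ["E1", "E2"]).drop(index=2)
        design = build_design(ph, ["a", "b", "c"], 1)
        assert design.n_obs == 5
        yv, X, cells = design.stacked()
        assert len(yv) == 5
        assert design.n_lines == 3  # all lines keep a breeding value

    def test_duplicate_record_rejected(self):
        ph = pd.DataFrame(
            {"line": ["a", "a"], "env": ["E1", "E1"], "value": [1.0, 2.0]}
        )
        with pytest.raises(ModelError):
            build_design(ph, ["a"], 1)

    def test_unknown_environment_rejected(self):
        ph = pd.DataFrame({"line": ["a"], "env": ["E9"], "value": [1.0]})
        with pytest.raises(ModelError):
            build_design(ph, ["a"], 1, env_ids=["E1"])


class TestSummaries:
    @pytest.mark.parametrize(
        "sg2,se2,expected", [(1, 1, 0.5), (1e-12, 1, 0.0), (3, 1, 0.75)]
    )
    def test_heritability_formula(self, sg2, se2, expected):
        vc = VarianceComponents(
            3, ResidualStructure("IDV", 1, np.array([se2])), sigma_g2=sg2
        )
        assert heritability(vc, 0) == pytest.approx(expected, abs=1e-9)

    def test_genomic_correlation_unit_diagonal_and_known_value(self):
        G0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        vc = VarianceComponents(
            1, ResidualStructure("IDV", 2, np.array([1.0])), G0=G0
        )
        r = genomic_correlation(vc)
        assert np.allclose(np.diag(r), 1.0)
        assert r[0, 1] == pytest.approx(0.5)

    def test_genomic_correlation_bounded_by_one(self, rng):
        for _ in range(100):
            G0 = random_pd(3, rng, ridge=0.05)
            vc = VarianceComponents(
                1, ResidualStructure("IDV", 3, np.array([1.0])), G0=G0
            )
            assert np.max(np.abs(genomic_correlation(vc))) <= 1 + 1e-12
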