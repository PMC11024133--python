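import logging

import numpy as np
import pytest
from scipy.optimize import linprog, minimize

from spade.deconvolve import deconvolve_dataset, solve_simplex_lad
from spade.model import DomainAssignment, PipelineConfig
from spade.selection import SelectionResult


def lp_oracle(y, X):
    """Independent LP reformulation (inequality form): min sum t subject to
    t >= y - Xp, t >= Xp - y, p on the simplex."""
    M, k = X.shape
    # variables [p, t]
    c = np.r_[np.zeros(k), np.ones(M)]
    A_ub = np.block([[X, -np.eye(M)], [-X, -np.eye(M)]])
    b_ub = np.r_[y, -y]
    A_eq = np.r_[np.ones(k), np.zeros(M)][None, :]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=(0, None), method="highs")
    assert res.success
    return res.x[:k], res.fun


def nnls_simplex(y, X):
    """Quadratic-loss baseline: min ||y - Xp||^2 on the simplex (SLSQP)."""
    k = X.shape[1]
    res = minimize(
        lambda p: ((y - X @ p) ** 2).sum(),
        np.full(k, 1.0 / k),
        jac=lambda p: -2 * X.T @ (y - X @ p),
        bounds=[(0, None)] * k,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1}],
        method="SLSQP",
    )
    return res.x


class TestSolver:
    def test_identity_exact_representation(self):
        p, obj = solve_simplex_lad(np.array([0.7, 0.3]), np.eye(2))
        assert p == pytest.approx([0.7, 0.3], abs=1e-8)
        assert obj == pytest.approx(0.0, abs=1e-8)

    def test_pure_column_gives_unit_vector(self, rng):
        X = rng.uniform(0, 1, (20, 4))
        p, obj = solve_simplex_lad(X[:, 2], X)
        assert p == pytest.approx(np.eye(4)[2], abs=1e-6)
        assert obj == pytest.approx(0.0, abs=1e-8)

    def test_noise_free_mixture_recovered(self, rng):
        X = rng.uniform(0, 1, (50, 5))
        p_true = rng.dirichlet(np.ones(5))
        p, obj = solve_simplex_lad(X @ p_true, X)
        assert p == pytest.approx(p_true, abs=1e-4)
        p_lp, f_lp = lp_oracle(X @ p_true, X)
        assert obj == pytest.approx(f_lp, abs=1e-8)

    @pytest.mark.parametrize("method", ["lp", "auglag"])
    def test_solution_beats_random_simplex_candidates(self, method, rng):
        X = rng.uniform(0, 1, (30, 4))
        y = X @ rng.dirichlet(np.ones(4)) + rng.normal(0, 0.1, 30)
        p, obj = solve_simplex_lad(y, X, method=method)
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0, abs=1e-6)
        for _ in range(200):
            q = rng.dirichlet(np.ones(4))
            assert obj <= np.abs(y - X @ q).sum() + 1e-6

    def test_auglag_matches_lp_objective(self, rng):
        for _ in range(10):
            M = int(rng.integers(10, 60))
            k = int(rng.integers(2, 7))
            X = rng.uniform(0, 1, (M, k))
            y = X @ rng.dirichlet(np.ones(k)) + rng.normal(0, 0.05, M)
            _, f_lp = solve_simplex_lad(y, X, method="lp")
            _, f_al = solve_simplex_lad(y, X, method="auglag")
            assert f_al == pytest.approx(f_lp, abs=1e-5)

    def test_scale_equivariance(self, rng):
        X = rng.uniform(0, 1, (25, 3))
        y = X @ np.array([0.2, 0.3, 0.5]) + rng.normal(0, 0.05, 25)
        p1, f1 = solve_simplex_lad(y, X)
        p2, f2 = solve_simplex_lad(7.5 * y, 7.5 * X)
        assert p2 == pytest.approx(p1, abs=1e-6)
        assert f2 == pytest.approx(7.5 * f1, rel=1e-6)

    def test_column_permutation_permutes_solution(self, rng):
        X = rng.uniform(0, 1, (40, 5))
        y = X @ rng.dirichlet(np.ones(5))
        perm = [3, 1, 4, 0, 2]
        p1, _ = solve_simplex_lad(y, X)
        p2, _ = solve_simplex_lad(y, X[:, perm])
        assert p2 == pytest.approx(p1[perm], abs=1e-6)

    def test_zero_expression_returns_uniform(self, caplog, rng):
        X = rng.uniform(0, 1, (10, 4))
        with caplog.at_level(logging.WARNING, logger="spade"):
            p, obj = solve_simplex_lad(np.zeros(10), X)
        assert p == pytest.approx(np.full(4, 0.25))
        assert obj == pytest.approx(np.abs(X @ p).sum())
        assert "uniform" in caplog.text

    def test_empty_type_set_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            solve_simplex_lad(np.ones(3), np.ones((3, 0)))

    def test_l1_more_robust_to_outliers_than_l2(self, rng):
        """Corrupting a few genes with extreme values should hurt the
        absolute-loss fit far less than the quadratic-loss fit."""
        X = rng.uniform(0, 1, (100, 5))
        p_true = rng.dirichlet(np.ones(5))
        y = X @ p_true
        bad = rng.choice(100, size=5, replace=False)
        y_corrupt = y.copy()
        y_corrupt[bad] += rng.uniform(5, 10, size=5)
        p_l1, _ = solve_simplex_lad(y_corrupt, X)
        p_l2 = nnls_simplex(y_corrupt, X)
        mad_l1 = np.abs(p_l1 - p_true).mean()
        mad_l2 = np.abs(p_l2 - p_true).mean()
        assert mad_l1 < mad_l2


class TestDatasetDeconvolution:
    def _setup(self, rng, n_spots=6, K=4, M=40):
        from spade.model import SpatialDataset
        from spade.reference import SignatureMatrix

        values = rng.uniform(0.1, 1.0, (M, K))
        sig = SignatureMatrix(
            gene_ids=[f"g{i}" for i in range(M)],
            cell_types=[f"T{j}" for j in range(K)],
            values=values,
            provenance={f"g{i}": {"shared"} for i in range(M)},
        )
        P_true = rng.dirichlet(np.ones(K), size=n_spots)
        counts = (values / values.sum(0)) @ P_true.T
        spatial = SpatialDataset(
            gene_ids=sig.gene_ids,
            spot_ids=[f"s{i}" for i in range(n_spots)],
            counts=counts,
            coords=np.c_[np.arange(n_spots), np.zeros(n_spots)].astype(float),
        )
        domains = DomainAssignment(
            spot_ids=spatial.spot_ids, domain=np.zeros(n_spots, int), n_domains=1
        )
        return sig, spatial, domains, P_true

    def test_single_type_domain_forces_proportion_one(self, rng):
        sig, spatial, domains, _ = self._setup(rng)
        sel = SelectionResult(
            spot_ids=spatial.spot_ids, cell_types=sig.cell_types,
            binary=np.zeros((spatial.n_spots, 4), int),
            domain_sets={0: {"T2"}},
        )
        P = deconvolve_dataset(spatial, sig, sel, domains, PipelineConfig())
        assert np.array_equal(P.P[:, 2], np.ones(spatial.n_spots))
        assert np.array_equal(P.P[:, [0, 1, 3]], np.zeros((spatial.n_spots, 3)))

    def test_excluded_type_is_exactly_zero(self, rng):
        sig, spatial, domains, _ = self._setup(rng)
        sel = SelectionResult(
            spot_ids=spatial.spot_ids, cell_types=sig.cell_types,
            binary=np.zeros((spatial.n_spots, 4), int),
            domain_sets={0: {"T0", "T1", "T3"}},
        )
        P = deconvolve_dataset(spatial, sig, sel, domains, PipelineConfig())
        assert np.array_equal(P.P[:, 2], np.zeros(spatial.n_spots))
        assert np.allclose(P.P.sum(axis=1), 1.0, atol=1e-6)

    def test_noise_free_spots_recovered(self, rng):
        sig, spatial, domains, P_true = self._setup(rng)
        sel = SelectionResult(
            spot_ids=spatial.spot_ids, cell_types=sig.cell_types,
            binary=np.ones((spatial.n_spots, 4), int),
            domain_sets={0: set(sig.cell_types)},
        )
        P = deconvolve_dataset(spatial, sig, sel, domains, PipelineConfig())
        assert P.P == pytest.approx(P_true, abs=1e-4)

    def test_solver_error_names_spot(self, rng):
        sig, spatial, domains, _ = self._setup(rng)
        spatial.counts[3, 2] = np.inf
        sel = SelectionResult(
            spot_ids=spatial.spot_ids, cell_types=sig.cell_types,
            binary=np.ones((spatial.n_spots, 4), int),
            domain_sets={0: set(sig.cell_types)},
        )
        with pytest.raises(RuntimeError, match="s2"):
            deconvolve_dataset(spatial, sig, sel, domains, PipelineConfig())
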