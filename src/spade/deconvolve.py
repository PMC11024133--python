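"""Simplex-constrained least-absolute-deviation proportion estimation.

Per spot, the cell-type proportions p minimize the L1 residual

    sum_i | y_i - sum_{j in S} p_j x_ij |    s.t.  p_j >= 0,  sum p_j = 1,

where S is the cell-type set of the spot's spatial domain. The absolute
loss is preferred over the quadratic because it is far less sensitive to
outlying genes. The production solver is the exact linear-programming
reformulation (split residuals r+ and r-, solved with HiGHS), which
certifies global optimality of this convex problem; an augmented-Lagrangian
path with a smoothed absolute value is kept as an alternative backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize

from .model import DomainAssignment, PipelineConfig, SpatialDataset
from .reference import SignatureMatrix
from .selection import SelectionResult

logger = logging.getLogger("spade")

__all__ = ["ProportionMatrix", "solve_simplex_lad", "deconvolve_dataset"]


@dataclass
class ProportionMatrix:
    """Spot x cell-type proportions on the simplex, zero outside S_d."""

    spot_ids: list[str]
    cell_types: list[str]
    P: np.ndarray
    objective_value: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.objective_value = np.asarray(self.objective_value, dtype=float)
        if self.P.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("P dims inconsistent")
        if self.P.size:
            if self.P.min() < 0:
                raise ValueError("proportions must be non-negative")
            sums = self.P.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-6:
                raise ValueError("each spot's proportions must sum to 1")
        if self.objective_value.shape != (len(self.spot_ids),):
            raise ValueError("one objective value per spot required")


def _solve_lp(y: np.ndarray, X: np.ndarray, tol: float) -> np.ndarray:
    """Exact LP: min sum(r+ + r-) s.t. Xp + r+ - r- = y, sum p = 1, all >= 0."""
    M, k = X.shape
    c = np.concatenate([np.zeros(k), np.ones(2 * M)])
    A_eq = np.zeros((M + 1, k + 2 * M))
    A_eq[:M, :k] = X
    A_eq[:M, k : k + M] = np.eye(M)
    A_eq[:M, k + M :] = -np.eye(M)
    A_eq[M, :k] = 1.0
    b_eq = np.concatenate([y, [1.0]])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
        options={"primal_feasibility_tolerance": min(tol, 1e-8)},
    )
    if not res.success:
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    return res.x[:k]


def _solve_auglag(y: np.ndarray, X: np.ndarray, tol: float) -> np.ndarray:
    """Augmented-Lagrangian solve of the same problem.

    The nonsmooth |r| is replaced by sqrt(r^2 + delta^2) with delta driven
    toward 0 by continuation; the simplex equality constraint enters the
    augmented Lagrangian while p >= 0 is handled by bounds in the L-BFGS-B
    inner solves.
    """
    M, k = X.shape
    p = np.full(k, 1.0 / k)
    mu, rho = 0.0, 10.0
    for delta in (1e-3, 1e-5, 1e-7, 1e-9):

        def fun(pv: np.ndarray, d: float = delta) -> tuple[float, np.ndarray]:
            r = y - X @ pv
            sm = np.sqrt(r * r + d * d)
            h = pv.sum() - 1.0
            f = sm.sum() + mu * h + 0.5 * rho * h * h
            g = -X.T @ (r / sm) + (mu + rho * h)
            return f, g

        for _ in range(30):
            res = minimize(
                fun,
                p,
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * k,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
            )
            p = res.x
            h = p.sum() - 1.0
            if abs(h) < 1e-10:
                break
            mu += rho * h
            rho = min(rho * 2.0, 1e8)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return p


def solve_simplex_lad(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    method: str = "lp",
) -> tuple[np.ndarray, float]:
    """Solve one spot's LAD deconvolution on the probability simplex.

    Returns ``(p, objective)`` where the objective is the L1 residual at p.
    ``method`` is "lp" (exact, default) or "auglag". An all-zero y returns
    the uniform vector with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("y and X have inconsistent shapes")
    if X.shape[1] == 0:
        raise ValueError("empty cell-type set")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in LAD inputs")
    k = X.shape[1]
    if not y.any():
        logger.warning("all-zero spot expression; returning uniform proportions")
        p = np.full(k, 1.0 / k)
        return p, float(np.abs(X @ p).sum())
    if method == "lp":
        p = _solve_lp(y, X, tol)
    elif method == "auglag":
        p = _solve_auglag(y, X, tol)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if abs(s - 1.0) > 1e-6:
        raise RuntimeError(f"solver simplex violation: sum(p)={s}")
    p /= s
    return p, float(np.abs(y - X @ p).sum())


def deconvolve_dataset(
    spatial: SpatialDataset,
    signature: SignatureMatrix,
    selection: SelectionResult,
    domains: DomainAssignment,
    config: PipelineConfig,
) -> ProportionMatrix:
    """Estimate proportions for every spot, restricted to its domain's S_d."""
    from ._design import design_matrices

    Y, X = design_matrices(spatial, signature, config.normalization_mode)
    types = signature.cell_types
    type_idx = {t: j for j, t in enumerate(types)}
    n_spots, K = spatial.n_spots, len(types)
    P = np.zeros((n_spots, K))
    obj = np.empty(n_spots)
    cols_by_domain = {
        d: sorted(type_idx[t] for t in s) for d, s in selection.domain_sets.items()
    }
    deg_genes = None
    if config.markers_only:
        deg_genes = {
            g for g, flags in signature.provenance.items() if "deg" in flags
        }
    for s in range(n_spots):
        d = int(domains.domain[s])
        cols = cols_by_domain[d]
        rows = slice(None)
        if deg_genes is not None:
            rows = [i for i, g in enumerate(signature.gene_ids) if g in deg_genes]
            if not rows:
                rows = slice(None)
        try:
            p_sub, obj[s] = solve_simplex_lad(
                Y[rows, s], X[rows][:, cols], tol=config.solver_tolerance
            )
        except Exception as exc:
            raise RuntimeError(
                f"deconvolution failed at spot {spatial.spot_ids[s]!r}: {exc}"
            ) from exc
        P[s, cols] = p_sub
    return ProportionMatrix(
        spot_ids=spatial.spot_ids, cell_types=types, P=P, objective_value=obj
    )
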