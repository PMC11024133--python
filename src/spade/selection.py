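"""Per-domain cell-type selection.

Each spot's expression over the feature genes is regressed on the signature
columns with an L1 (Lasso) penalty — the objective is the residual sum of
squares plus lambda * sum_j |beta_j|, with lambda chosen by k-fold
cross-validation over genes-as-observations. A cell type whose coefficient
shrinks to zero is treated as absent at that spot. The spot x cell-type
coefficient matrix is then binarized by adaptive thresholding (each entry
compared to an FFT-computed local moving mean) and the per-spot calls are
aggregated into one cell-type set per spatial domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .model import DomainAssignment, PipelineConfig, SpatialDataset
from .reference import SignatureMatrix

logger = logging.getLogger("spade")

__all__ = [
    "CoefficientMatrix",
    "SelectionResult",
    "fit_spot_lasso",
    "adaptive_threshold",
    "adaptive_threshold_matrix",
    "aggregate_domain_selection",
    "select_cell_types",
]

#: coefficients with absolute value below this are snapped to exactly 0
COEF_SNAP = 1e-10

#: numeric guard for the strict beta > filtered comparison (FFT roundoff)
_TIE_GUARD = 1e-10


@dataclass
class CoefficientMatrix:
    """Spot x cell-type Lasso coefficients plus the penalty chosen per spot."""

    spot_ids: list[str]
    cell_types: list[str]
    beta: np.ndarray
    lambda_chosen: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.lambda_chosen = np.asarray(self.lambda_chosen, dtype=float)
        if self.beta.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("beta dims inconsistent")
        if self.lambda_chosen.shape != (len(self.spot_ids),):
            raise ValueError("one lambda per spot required")
        if (self.lambda_chosen <= 0).any():
            raise ValueError("lambda_chosen must be positive")


@dataclass
class SelectionResult:
    """Binary spot-level calls and the aggregated per-domain sets S_d."""

    spot_ids: list[str]
    cell_types: list[str]
    binary: np.ndarray
    domain_sets: dict[int, set[str]]

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=int)
        if self.binary.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("binary dims inconsistent")
        if not np.isin(self.binary, (0, 1)).all():
            raise ValueError("binary entries must be 0 or 1")
        for d, s in self.domain_sets.items():
            if not s:
                raise ValueError(f"domain {d} has an empty cell-type set")


def _default_grid(y: np.ndarray, X: np.ndarray, n: int, min_ratio: float) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to lambda_max*min_ratio.

    lambda_max = 2 * max|X^T y| is the smallest penalty under the
    RSS + lambda*||beta||_1 convention at which every coefficient is zero.
    """
    lam_max = 2.0 * np.abs(X.T @ y).max()
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n)


def fit_spot_lasso(
    y: np.ndarray,
    X: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
) -> tuple[np.ndarray, float]:
    """L1-penalized fit of one spot's expression on the signature columns.

    Minimizes ``sum_i (y_i - sum_j beta_j x_ij)^2 + lambda * sum_j |beta_j|``
    (no intercept). With a single grid value that lambda is used directly
    (lambda=0 reduces to ordinary least squares); otherwise lambda is chosen
    by k-fold cross-validation over genes-as-observations with folds from a
    seeded shuffle. ``rule`` is "1se" (default: the largest — sparsest —
    penalty whose mean CV squared error is within one standard error of the
    minimum, the convention used for coefficient extraction after
    cross-validated Lasso fits in glmnet) or "min" (the error-minimizing
    penalty). Coefficients with |beta| < 1e-10 are snapped to exactly 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("NaN in lasso inputs")
    M = y.shape[0]
    if X.shape[0] != M:
        raise ValueError("y and X have inconsistent gene dimension")
    if (np.abs(X).sum(axis=0) == 0).any():
        raise ValueError("signature has an all-zero column")
    # scikit-learn's Lasso minimizes (1/2n)*RSS + alpha*||beta||_1, so the
    # printed-penalty lambda maps to alpha = lambda / (2M)
    if lambda_grid is not None and np.asarray(lambda_grid).size == 1:
        lam = float(np.asarray(lambda_grid).ravel()[0])
        if lam == 0.0:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
        else:
            model = Lasso(
                alpha=lam / (2 * M), fit_intercept=False, max_iter=100000, tol=1e-10
            ).fit(X, y)
            beta = model.coef_.copy()
        beta[np.abs(beta) < COEF_SNAP] = 0.0
        return beta, lam if lam > 0 else COEF_SNAP
    if M < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} genes, got {M}")
    grid = (
        np.asarray(lambda_grid, dtype=float)
        if lambda_grid is not None
        else _default_grid(y, X, 50, 1e-4)
    )
    if (grid <= 0).any():
        raise ValueError("cross-validated lambda grid must be positive")
    alphas = np.sort(grid / (2 * M))[::-1]  # descending, for warm starts
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_mse = np.empty((cv_folds, alphas.size))
    for f, (train, test) in enumerate(cv.split(y)):
        # lasso_path fits no intercept, matching the printed objective
        _, coefs, _ = lasso_path(X[train], y[train], alphas=alphas)
        resid = y[test, None] - X[test] @ coefs
        fold_mse[f] = (resid**2).mean(axis=0)
    mean_mse = fold_mse.mean(axis=0)
    if rule == "min":
        pick = int(np.argmin(mean_mse))
    elif rule == "1se":
        best = int(np.argmin(mean_mse))
        se = fold_mse[:, best].std(ddof=1) / np.sqrt(cv_folds)
        # alphas descend, so the first index within one SE is the sparsest fit
        pick = int(np.flatnonzero(mean_mse <= mean_mse[best] + se)[0])
    else:
        raise ValueError(f"unknown lambda rule {rule!r}")
    model = Lasso(
        alpha=alphas[pick], fit_intercept=False, max_iter=100000, tol=1e-10
    ).fit(X, y)
    beta = model.coef_.copy()
    beta[np.abs(beta) < COEF_SNAP] = 0.0
    return beta, float(alphas[pick] * 2 * M)


def adaptive_threshold_matrix(
    beta: np.ndarray, window: tuple[int, int], return_filtered: bool = False
):
    """Binarize a coefficient matrix against its FFT-filtered local mean.

    Negative coefficients are clipped to 0 first. The filter is a uniform
    moving mean of the given odd window under symmetric (reflect) boundary
    padding, computed by FFT convolution; an entry becomes 1 iff it strictly
    exceeds its filtered value. Windows larger than the matrix are clamped
    (with a warning) to the nearest odd size that fits.
    """
    beta = np.clip(np.asarray(beta, dtype=float), 0.0, None)
    if beta.ndim != 2:
        raise ValueError("beta must be 2-D")
    wr, wc = int(window[0]), int(window[1])
    if wr % 2 == 0 or wc % 2 == 0 or wr < 1 or wc < 1:
        raise ValueError("window dims must be odd and >= 1")
    nr, nc = beta.shape

    def clamp(w: int, n: int) -> int:
        if w > n:
            w = n if n % 2 == 1 else n - 1
            w = max(w, 1)
            logger.warning("threshold window clamped to %d", w)
        return w

    wr, wc = clamp(wr, nr), clamp(wc, nc)
    padded = np.pad(beta, ((wr // 2, wr // 2), (wc // 2, wc // 2)), mode="symmetric")
    kernel = np.full((wr, wc), 1.0 / (wr * wc))
    filtered = fftconvolve(padded, kernel, mode="valid")
    # strict inequality with a tiny slack absorbing FFT roundoff, so exact
    # ties (e.g. a constant matrix) binarize to 0
    guard = _TIE_GUARD * (1.0 + np.abs(filtered))
    binary = (beta > filtered + guard).astype(int)
    if return_filtered:
        return binary, filtered
    return binary


def adaptive_threshold(
    coef: CoefficientMatrix,
    window: tuple[int, int],
    domains: DomainAssignment,
    coords: np.ndarray,
) -> np.ndarray:
    """Spot-level binary calls, filtering in (domain, row, col) spot order.

    Spots are sorted domain-major (then by array row and column) before the
    2-D filtering so the moving window's neighborhood is spatially
    meaningful and stays within domains; the returned binary matrix is in
    the original spot order.
    """
    if domains.spot_ids != coef.spot_ids:
        raise ValueError("coefficient and domain spot ids differ")
    coords = np.asarray(coords, dtype=float)
    order = np.lexsort((coords[:, 1], coords[:, 0], domains.domain))
    binary_sorted = adaptive_threshold_matrix(coef.beta[order, :], window)
    binary = np.empty_like(binary_sorted)
    binary[order, :] = binary_sorted
    return binary


def aggregate_domain_selection(
    binary: np.ndarray,
    domains: DomainAssignment,
    tau: float,
    coef: CoefficientMatrix,
) -> SelectionResult:
    """Aggregate spot-level calls into one cell-type set per domain.

    A type enters S_d when at least a fraction ``tau`` of the domain's spots
    call it. An empty S_d falls back to the single type with the largest
    mean coefficient in the domain (logged).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    binary = np.asarray(binary, dtype=int)
    cell_types = coef.cell_types
    domain_sets: dict[int, set[str]] = {}
    for d in range(domains.n_domains):
        spots = domains.spots_in(d)
        if spots.size == 0:
            raise ValueError(f"domain {d} contains no spots")
        frac = binary[spots, :].mean(axis=0)
        chosen = {cell_types[j] for j in np.flatnonzero(frac >= tau)}
        if not chosen:
            j = int(np.argmax(coef.beta[spots, :].mean(axis=0)))
            chosen = {cell_types[j]}
            logger.warning(
                "domain %d selected no cell type; falling back to %r",
                d,
                cell_types[j],
            )
        domain_sets[d] = chosen
    return SelectionResult(
        spot_ids=coef.spot_ids,
        cell_types=cell_types,
        binary=binary,
        domain_sets=domain_sets,
    )


def select_cell_types(
    spatial: SpatialDataset,
    signature: SignatureMatrix,
    domains: DomainAssignment,
    config: PipelineConfig,
) -> tuple[CoefficientMatrix, SelectionResult]:
    """Run the full selection stage for a dataset.

    Returns the per-spot coefficient matrix (with chosen penalties) and the
    thresholded/aggregated selection result.
    """
    from ._design import design_matrices

    Y, X = design_matrices(spatial, signature, config.normalization_mode)
    n_spots = spatial.n_spots
    beta = np.empty((n_spots, signature.n_types))
    lam = np.empty(n_spots)
    for s in range(n_spots):
        beta[s], lam[s] = fit_spot_lasso(
            Y[:, s],
            X,
            lambda_grid=config.lasso_lambda_grid,
            cv_folds=config.cv_folds,
            seed=config.rng_seed,
            rule=config.lasso_lambda_rule,
        )
    coef = CoefficientMatrix(
        spot_ids=spatial.spot_ids,
        cell_types=signature.cell_types,
        beta=beta,
        lambda_chosen=lam,
    )
    binary = adaptive_threshold(
        coef, config.threshold_window, domains, spatial.coords
    )
    selection = aggregate_domain_selection(
        binary, domains, config.domain_fraction_tau, coef
    )
    return coef, selection
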