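"""Core data containers shared across the pipeline.

The pipeline operates on three kinds of measured input — a spatial
transcriptomics dataset (genes x spots plus spot coordinates), an annotated
single-cell RNA-seq dataset (genes x cells plus per-cell labels), and an
optional partition of the spots into spatial domains — and one configuration
object holding every tunable knob and the single random seed that all
stochastic steps draw from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger("spade")

__all__ = [
    "SpatialDataset",
    "SingleCellDataset",
    "DomainAssignment",
    "PipelineConfig",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class SpatialDataset:
    """Gene x spot expression with per-spot array coordinates.

    ``counts`` may hold raw counts or normalized expression; it must be
    non-negative with shape ``(len(gene_ids), len(spot_ids))``. ``coords``
    follows the 0-based (row, col) array convention; pixel x/y inputs are
    mapped x->col, y->row at load time. ``histology_rgb`` is an optional
    per-spot mean RGB summary in [0, 255].
    """

    gene_ids: list[str]
    spot_ids: list[str]
    counts: np.ndarray
    coords: np.ndarray
    histology_rgb: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.spot_ids, "spot")
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.spot_ids)} spots)"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.coords.shape != (len(self.spot_ids), 2):
            raise ValueError("coords must have one (row, col) pair per spot")
        if self.histology_rgb is not None:
            self.histology_rgb = np.asarray(self.histology_rgb, dtype=float)
            if self.histology_rgb.shape != (len(self.spot_ids), 3):
                raise ValueError("histology_rgb must be spots x 3")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "SpatialDataset":
        """Return a new dataset restricted to ``gene_ids``, in that order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return SpatialDataset(
            gene_ids=list(gene_ids),
            spot_ids=self.spot_ids,
            counts=self.counts[rows, :],
            coords=self.coords,
            histology_rgb=self.histology_rgb,
        )


@dataclass
class SingleCellDataset:
    """Gene x cell counts with a cell-type and sample label per cell."""

    gene_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray
    cell_type: list[str]
    sample_id: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.cell_type = list(self.cell_type)
        self.sample_id = list(self.sample_id)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts dims inconsistent with gene/cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(self.cell_type) != len(self.cell_ids):
            raise ValueError("cell_type must have one label per cell")
        if any(not t for t in self.cell_type):
            raise ValueError("every cell needs a non-empty cell_type")
        if len(self.sample_id) != len(self.cell_ids):
            raise ValueError("sample_id must have one label per cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cell_types(self) -> list[str]:
        """Distinct cell-type labels in first-appearance order."""
        out: list[str] = []
        for t in self.cell_type:
            if t not in out:
                out.append(t)
        return out

    def subset_cells(self, mask: np.ndarray) -> "SingleCellDataset":
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        return SingleCellDataset(
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in keep],
            counts=self.counts[:, keep],
            cell_type=[self.cell_type[i] for i in keep],
            sample_id=[self.sample_id[i] for i in keep],
        )

    def subset_genes(self, mask: np.ndarray) -> "SingleCellDataset":
        mask = np.asarray(mask, dtype=bool)
        keep = np.flatnonzero(mask)
        return SingleCellDataset(
            gene_ids=[self.gene_ids[i] for i in keep],
            cell_ids=self.cell_ids,
            counts=self.counts[keep, :],
            cell_type=self.cell_type,
            sample_id=self.sample_id,
        )


@dataclass
class DomainAssignment:
    """One integer spatial-domain label per spot, contiguous from 0."""

    spot_ids: list[str]
    domain: np.ndarray
    n_domains: int

    def __post_init__(self) -> None:
        self.spot_ids = list(self.spot_ids)
        self.domain = np.asarray(self.domain, dtype=int)
        if self.domain.shape != (len(self.spot_ids),):
            raise ValueError("one domain label required per spot")
        labels = np.unique(self.domain)
        if self.n_domains < 1 or not np.array_equal(
            labels, np.arange(self.n_domains)
        ):
            raise ValueError(
                "domain labels must be contiguous integers 0..D-1; "
                f"got {labels.tolist()} with D={self.n_domains}"
            )

    def spots_in(self, d: int) -> np.ndarray:
        return np.flatnonzero(self.domain == d)


@dataclass
class PipelineConfig:
    """Tunable parameters for the full pipeline.

    ``lasso_lambda_grid=None`` means a per-spot grid of 50 log-spaced values
    from lambda_max (smallest penalty zeroing every coefficient) down to
    lambda_max * 1e-4. ``threshold_window`` is (spots, cell types) and must
    be odd in both dimensions. ``domain_fraction_tau`` is the fraction of a
    domain's spots that must individually select a cell type for it to enter
    the domain set. ``normalization_mode`` is "sum1" (spot vectors and
    signature columns scaled to unit sum over the feature genes) or "none".
    """

    lasso_lambda_grid: np.ndarray | None = None
    cv_folds: int = 10
    threshold_window: tuple[int, int] = (15, 1)
    domain_fraction_tau: float = 0.25
    solver_tolerance: float = 1e-8
    rng_seed: int = 0
    normalization_mode: str = "sum1"
    min_lfc: float = 0.25
    max_adj_p: float = 0.05
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-4
    lasso_lambda_rule: str = "1se"
    fallback_n_pcs: int = 50
    fallback_n_neighbors: int = 6
    fallback_coord_weight: float = 1.0
    pairwise_markers: bool = False
    markers_only: bool = False
    per_sample_mean: bool = False

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        wr, wc = self.threshold_window
        if wr < 1 or wc < 1 or wr % 2 == 0 or wc % 2 == 0:
            raise ValueError("threshold_window entries must be odd and >= 1")
        if not 0.0 <= self.domain_fraction_tau <= 1.0:
            raise ValueError("domain_fraction_tau must lie in [0, 1]")
        if self.normalization_mode not in ("sum1", "none"):
            raise ValueError("normalization_mode must be 'sum1' or 'none'")
        if self.lasso_lambda_rule not in ("1se", "min"):
            raise ValueError("lasso_lambda_rule must be '1se' or 'min'")
        if self.lasso_lambda_grid is not None:
            grid = np.asarray(self.lasso_lambda_grid, dtype=float)
            if grid.ndim != 1 or grid.size == 0 or (grid < 0).any():
                raise ValueError("lasso_lambda_grid must be non-negative 1-D")
            self.lasso_lambda_grid = grid

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, rng_seed=int(seed))
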