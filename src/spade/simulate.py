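"""Pseudo-spatial data generation with known ground truth.

A spot is a mixture of cells: for each spatial location the generator
(1) draws ground-truth cell-type proportions from a Dirichlet distribution
whose concentration vector is specific to the location's spatial domain
(zeros encode types absent from that domain), (2) allocates a fixed number
of cells to the types by largest-remainder rounding and samples that many
cells with replacement from an annotated scRNA-seq dataset, and
(3) sums the sampled cells' raw counts into the spot's gene expression
column. Optional multiplicative lognormal noise perturbs the counts.

A toy scRNA-seq generator (block-structured marker genes, Poisson counts)
provides a self-contained reference so the whole pipeline is exercisable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DomainAssignment, SingleCellDataset, SpatialDataset

__all__ = [
    "SimulationTruth",
    "make_domain_layout",
    "simulate_spatial_dataset",
    "make_toy_reference",
    "standard_benchmark",
    "largest_remainder_allocation",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulation: proportions, layout and parameters."""

    true_P: np.ndarray
    cell_types: list[str]
    domain_layout: DomainAssignment
    dirichlet_alpha: np.ndarray
    cells_per_spot: int
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.true_P = np.asarray(self.true_P, dtype=float)
        self.dirichlet_alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if self.cells_per_spot < 1:
            raise ValueError("cells_per_spot must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        sums = self.true_P.sum(axis=1)
        if self.true_P.size and np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("true proportions must sum to 1 per spot")

    def domain_type_sets(self) -> dict[int, set[str]]:
        """The cell types truly present (positive alpha) in each domain."""
        return {
            d: {
                self.cell_types[j]
                for j in np.flatnonzero(self.dirichlet_alpha[d] > 0)
            }
            for d in range(self.dirichlet_alpha.shape[0])
        }


def make_domain_layout(
    grid_rows: int, grid_cols: int, n_domains: int, seed: int = 0
) -> tuple[DomainAssignment, np.ndarray]:
    """Spots on an integer grid, contiguous horizontal bands per domain."""
    if n_domains > grid_rows:
        raise ValueError("n_domains cannot exceed grid_rows")
    coords = np.array(
        [(r, c) for r in range(grid_rows) for c in range(grid_cols)], dtype=float
    )
    spot_ids = [f"spot_{r}_{c}" for r in range(grid_rows) for c in range(grid_cols)]
    rows_per = grid_rows / n_domains
    domain = np.array(
        [min(int(r // rows_per), n_domains - 1) for r, _ in coords], dtype=int
    )
    return (
        DomainAssignment(spot_ids=spot_ids, domain=domain, n_domains=n_domains),
        coords,
    )


def largest_remainder_allocation(p: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``p``, summing exactly.

    Floors each share then hands the remaining units to the largest
    fractional remainders (ties broken by lower index).
    """
    p = np.asarray(p, dtype=float)
    shares = p * total
    base = np.floor(shares).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = shares - base
        order = np.lexsort((np.arange(len(p)), -remainders))
        base[order[:short]] += 1
    return base


def simulate_spatial_dataset(
    sc: SingleCellDataset,
    layout: DomainAssignment,
    coords: np.ndarray,
    alpha_per_domain: np.ndarray,
    cells_per_spot: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[SpatialDataset, SimulationTruth]:
    """Generate a pseudo-spatial dataset by aggregating sampled cells.

    ``alpha_per_domain`` is domains x K over ``sc``'s cell types in
    first-appearance order; zero entries encode absent types. The recorded
    ground truth is the Dirichlet draw itself, not the rounded allocation.
    With ``noise_sigma > 0`` every count is multiplied by an independent
    lognormal(0, sigma) factor and rounded to the nearest integer.
    """
    rng = np.random.default_rng(seed)
    types = sc.cell_types
    K = len(types)
    alpha_per_domain = np.asarray(alpha_per_domain, dtype=float)
    if alpha_per_domain.shape != (layout.n_domains, K):
        raise ValueError("alpha_per_domain must be domains x cell types")
    if (alpha_per_domain < 0).any():
        raise ValueError("alpha entries must be >= 0")
    labels = np.asarray(sc.cell_type)
    cells_by_type = {t: np.flatnonzero(labels == t) for t in types}
    for d in range(layout.n_domains):
        for j in np.flatnonzero(alpha_per_domain[d] > 0):
            if cells_by_type[types[j]].size == 0:
                raise ValueError(
                    f"cell type {types[j]!r} has positive alpha but no cells"
                )
    n_spots = len(layout.spot_ids)
    counts = np.zeros((sc.n_genes, n_spots))
    true_P = np.zeros((n_spots, K))
    sc_counts = np.asarray(sc.counts, dtype=float)
    for s in range(n_spots):
        alpha = alpha_per_domain[layout.domain[s]]
        pos = np.flatnonzero(alpha > 0)
        draw = rng.dirichlet(alpha[pos])
        draw /= draw.sum()  # guard float rounding (exact 1.0 when K_pos == 1)
        true_P[s, pos] = draw
        alloc = largest_remainder_allocation(draw, cells_per_spot)
        col = np.zeros(sc.n_genes)
        for jj, n_cells in zip(pos, alloc):
            if n_cells == 0:
                continue
            pool = cells_by_type[types[jj]]
            chosen = rng.integers(0, pool.size, size=n_cells)
            col += sc_counts[:, pool[chosen]].sum(axis=1)
        counts[:, s] = col
    if noise_sigma > 0:
        factors = rng.lognormal(mean=0.0, sigma=noise_sigma, size=counts.shape)
        counts = np.clip(np.rint(counts * factors), 0, None)
    spatial = SpatialDataset(
        gene_ids=sc.gene_ids,
        spot_ids=list(layout.spot_ids),
        counts=counts,
        coords=np.asarray(coords, dtype=float),
    )
    truth = SimulationTruth(
        true_P=true_P,
        cell_types=types,
        domain_layout=layout,
        dirichlet_alpha=alpha_per_domain,
        cells_per_spot=cells_per_spot,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return spatial, truth


def make_toy_reference(
    n_types: int = 6,
    markers_per_type: int = 30,
    shared_genes: int = 40,
    cells_per_type: int = 50,
    marker_rate: float = 8.0,
    background_rate: float = 0.2,
    shared_rate: float = 2.0,
    n_samples: int = 2,
    seed: int = 0,
) -> SingleCellDataset:
    """Toy annotated scRNA-seq dataset with block-structured markers.

    Each cell type owns ``markers_per_type`` genes expressed at
    ``marker_rate`` in its own cells and ``background_rate`` elsewhere;
    ``shared_genes`` housekeeping genes are expressed at ``shared_rate`` in
    every type. Counts are Poisson; every type has the same expected
    library size so cell-count and expression proportions coincide. This is
    a synthetic stand-in for a real annotated reference: it has none of the
    overdispersion, dropout or nested subtype structure of real scRNA-seq.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_types * markers_per_type + shared_genes
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    types = [f"T{j}" for j in range(n_types)]
    rates = np.full((n_genes, n_types), background_rate)
    for j in range(n_types):
        lo = j * markers_per_type
        rates[lo : lo + markers_per_type, j] = marker_rate
    rates[n_types * markers_per_type :, :] = shared_rate
    n_cells = n_types * cells_per_type
    lam = np.repeat(rates, cells_per_type, axis=1)
    counts = rng.poisson(lam)
    cell_type = [t for t in types for _ in range(cells_per_type)]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    sample_id = [f"sample{i % n_samples}" for i in range(n_cells)]
    return SingleCellDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        cell_type=cell_type,
        sample_id=sample_id,
    )


def default_alpha(n_domains: int, n_types: int) -> np.ndarray:
    """Domain concentration vectors: one dominant type plus two minors.

    Domain d gets alpha=5 on its dominant type (index 2d mod K), alpha=1 on
    the next two types cyclically, and 0 elsewhere — one dominant cell type
    per domain with a varying minor entourage.
    """
    alpha = np.zeros((n_domains, n_types))
    for d in range(n_domains):
        alpha[d, (2 * d) % n_types] = 5.0
        alpha[d, (2 * d + 1) % n_types] = 1.0
        alpha[d, (2 * d + 2) % n_types] = 1.0
    return alpha


def standard_benchmark(
    seed: int = 0,
    grid: tuple[int, int] = (20, 20),
    n_domains: int = 3,
    n_types: int = 6,
    cells_per_spot: int = 50,
    noise_sigma: float = 0.0,
) -> tuple[SingleCellDataset, SpatialDataset, SimulationTruth]:
    """The package's standard simulation benchmark.

    A 20x20 grid (400 spots) in 3 banded domains over a 6-type toy
    reference, 50 cells per spot, dominant-plus-minor Dirichlet
    concentrations; returns the reference, the pseudo-spatial dataset and
    the ground truth.
    """
    sc = make_toy_reference(n_types=n_types, seed=seed)
    layout, coords = make_domain_layout(grid[0], grid[1], n_domains, seed=seed)
    alpha = default_alpha(n_domains, n_types)
    spatial, truth = simulate_spatial_dataset(
        sc,
        layout,
        coords,
        alpha,
        cells_per_spot=cells_per_spot,
        noise_sigma=noise_sigma,
        seed=seed + 1,
    )
    return sc, spatial, truth
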