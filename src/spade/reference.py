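"""Signature-matrix construction from annotated scRNA-seq data.

The reference profile x_ij for gene i in cell type j is the mean
library-size-scaled expression over the cells labeled j. Feature genes are
those shared with the spatial data, user-supplied markers, or genes called
differentially expressed between cell types by a Wilcoxon rank-sum test
with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import SingleCellDataset

logger = logging.getLogger("spade")

__all__ = [
    "SignatureMatrix",
    "MarkerTestResult",
    "filter_cells_genes",
    "scale_by_library_size",
    "wilcoxon_rank_sum",
    "find_marker_genes",
    "build_signature",
]

#: largest combined group size for which the exact null distribution is used
EXACT_LIMIT = 12

#: pseudo-value added inside the log-fold-change
LFC_EPS = 1e-9


@dataclass
class MarkerTestResult:
    """One gene x cell-type differential-expression call."""

    gene_id: str
    cell_type: str
    statistic: float
    p_value: float
    adjusted_p: float
    log_fold_change: float


@dataclass
class SignatureMatrix:
    """Gene x cell-type mean scaled expression with per-gene provenance.

    ``provenance`` maps gene id -> subset of {"shared", "user_marker",
    "deg"}; every feature gene carries at least one flag.
    """

    gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray
    provenance: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("signature dims inconsistent")
        if self.values.size and self.values.min() < 0:
            raise ValueError("signature values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in signature")
        if len(self.cell_types) < 1:
            raise ValueError("signature needs at least one cell type")
        for g in self.gene_ids:
            if not self.provenance.get(g):
                raise ValueError(f"gene {g!r} carries no provenance flag")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


def filter_cells_genes(
    sc: SingleCellDataset, keep_types: set[str] | None = None
) -> SingleCellDataset:
    """Drop genes with zero total count and cells of unwanted types."""
    if keep_types is not None:
        mask = np.array([t in keep_types for t in sc.cell_type])
        n_drop = int((~mask).sum())
        if n_drop:
            logger.info("removed %d cell(s) outside keep_types", n_drop)
        sc = sc.subset_cells(mask)
        if sc.n_cells == 0:
            raise ValueError("keep_types removed every cell")
    totals = sc.counts.sum(axis=1)
    gene_mask = totals > 0
    if not gene_mask.any():
        raise ValueError("all genes have zero counts after filtering")
    if not gene_mask.all():
        logger.info("removed %d zero-count gene(s)", int((~gene_mask).sum()))
    return sc.subset_genes(gene_mask)


def scale_by_library_size(sc: SingleCellDataset) -> SingleCellDataset:
    """Scale every cell's counts by its library size so columns sum to 1.

    Cells with a zero total are dropped with a warning.
    """
    totals = sc.counts.sum(axis=0).astype(float)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropped %d zero-total cell(s)", int((~keep).sum()))
        sc = sc.subset_cells(keep)
        totals = totals[keep]
    scaled = sc.counts / totals[np.newaxis, :]
    return SingleCellDataset(
        gene_ids=sc.gene_ids,
        cell_ids=sc.cell_ids,
        counts=scaled,
        cell_type=sc.cell_type,
        sample_id=sc.sample_id,
    )


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test for two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most ``EXACT_LIMIT`` and there are no ties across the pooled sample;
    otherwise the normal approximation with tie and continuity correction.
    Returns ``(U, p)`` with U computed for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _rank_sum_pvalues(in_mat: np.ndarray, out_mat: np.ndarray) -> np.ndarray:
    """Vectorized one-vs-rest rank-sum p-values per gene (rows)."""
    n_genes = in_mat.shape[0]
    pvals = np.empty(n_genes)
    for i in range(n_genes):
        _, pvals[i] = wilcoxon_rank_sum(in_mat[i], out_mat[i])
    return pvals


def find_marker_genes(
    sc_scaled: SingleCellDataset,
    min_lfc: float = 0.25,
    max_adj_p: float = 0.05,
    pairwise: bool = False,
) -> list[MarkerTestResult]:
    """Detect differentially expressed genes per cell type.

    Default is one-vs-rest: for each cell type, every gene is tested with a
    two-sided rank-sum test of that type's cells against all other cells,
    p-values are BH-adjusted within the cell type, and genes with
    ``adjusted_p <= max_adj_p`` and natural-log fold change >= ``min_lfc``
    are reported. With ``pairwise=True`` a gene is reported for a type if it
    passes against ANY single other type. Types with fewer than 3 cells are
    excluded with a warning.
    """
    types = sc_scaled.cell_types
    labels = np.asarray(sc_scaled.cell_type)
    usable = []
    for t in types:
        if int((labels == t).sum()) < 3:
            logger.warning("cell type %r has < 3 cells; excluded from DEG tests", t)
        else:
            usable.append(t)
    if len(usable) < 2:
        raise ValueError("marker detection needs >= 2 cell types with >= 3 cells")
    X = np.asarray(sc_scaled.counts, dtype=float)
    results: list[MarkerTestResult] = []
    for t in usable:
        in_mask = labels == t
        in_mat = X[:, in_mask]
        mean_in = in_mat.mean(axis=1)
        if pairwise:
            best_p = np.ones(X.shape[0])
            best_lfc = np.full(X.shape[0], -np.inf)
            for other in usable:
                if other == t:
                    continue
                out_mat = X[:, labels == other]
                p = _rank_sum_pvalues(in_mat, out_mat)
                lfc = np.log(mean_in + LFC_EPS) - np.log(
                    out_mat.mean(axis=1) + LFC_EPS
                )
                better = p < best_p
                best_p = np.where(better, p, best_p)
                best_lfc = np.where(better, lfc, best_lfc)
            pvals, lfcs = best_p, best_lfc
        else:
            out_mat = X[:, ~in_mask]
            pvals = _rank_sum_pvalues(in_mat, out_mat)
            lfcs = np.log(mean_in + LFC_EPS) - np.log(
                out_mat.mean(axis=1) + LFC_EPS
            )
        adj = multipletests(pvals, method="fdr_bh")[1]
        for i, g in enumerate(sc_scaled.gene_ids):
            if adj[i] <= max_adj_p and lfcs[i] >= min_lfc:
                results.append(
                    MarkerTestResult(
                        gene_id=g,
                        cell_type=t,
                        statistic=float("nan"),
                        p_value=float(pvals[i]),
                        adjusted_p=float(adj[i]),
                        log_fold_change=float(lfcs[i]),
                    )
                )
    return results


def build_signature(
    sc_scaled: SingleCellDataset,
    spatial_genes: set[str],
    user_markers: set[str] | None = None,
    deg: list[MarkerTestResult] | None = None,
    per_sample_mean: bool = False,
) -> SignatureMatrix:
    """Assemble the gene x cell-type signature matrix.

    Feature genes satisfy any of: shared with the spatial data, listed as a
    user marker, or called as a DEG — then are intersected with
    ``spatial_genes`` so the downstream fits are well-posed. Each column is
    the mean scaled expression over cells of that type (with
    ``per_sample_mean`` the within-sample means are averaged across
    samples instead of pooling all cells).
    """
    user_markers = user_markers or set()
    deg_genes = {r.gene_id for r in (deg or [])}
    provenance: dict[str, set[str]] = {}
    feature: list[str] = []
    for g in sc_scaled.gene_ids:
        flags = set()
        if g in spatial_genes:
            flags.add("shared")
        if g in user_markers:
            flags.add("user_marker")
        if g in deg_genes:
            flags.add("deg")
        if not flags:
            continue
        if g not in spatial_genes:
            logger.info("gene %r excluded: absent from spatial data", g)
            continue
        provenance[g] = flags
        feature.append(g)
    missing_markers = user_markers - set(sc_scaled.gene_ids)
    for g in sorted(missing_markers):
        logger.info("user marker %r not in reference genes; ignored", g)
    if len(feature) < 2:
        raise ValueError("fewer than 2 feature genes; cannot build signature")

    types = sc_scaled.cell_types
    gene_idx = {g: i for i, g in enumerate(sc_scaled.gene_ids)}
    rows = [gene_idx[g] for g in feature]
    X = np.asarray(sc_scaled.counts, dtype=float)[rows, :]
    labels = np.asarray(sc_scaled.cell_type)
    samples = np.asarray(sc_scaled.sample_id)
    values = np.empty((len(feature), len(types)))
    for j, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has zero cells")
        if per_sample_mean:
            per_sample = [
                X[:, mask & (samples == s)].mean(axis=1)
                for s in np.unique(samples[mask])
            ]
            values[:, j] = np.mean(per_sample, axis=0)
        else:
            values[:, j] = X[:, mask].mean(axis=1)
    return SignatureMatrix(
        gene_ids=feature, cell_types=types, values=values, provenance=provenance
    )
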