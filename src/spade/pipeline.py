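"""End-to-end orchestration: reference -> domains -> selection -> deconvolution."""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

import numpy as np

from .deconvolve import ProportionMatrix, deconvolve_dataset
from .domains import assign_domains_fallback
from .model import DomainAssignment, PipelineConfig, SingleCellDataset, SpatialDataset
from .reference import (
    SignatureMatrix,
    build_signature,
    filter_cells_genes,
    find_marker_genes,
    scale_by_library_size,
)
from .selection import select_cell_types

logger = logging.getLogger("spade")

__all__ = ["run_pipeline", "build_reference"]


def build_reference(
    sc: SingleCellDataset,
    spatial_genes: set[str],
    config: PipelineConfig,
    user_markers: set[str] | None = None,
    keep_types: set[str] | None = None,
) -> SignatureMatrix:
    """Reference-construction stage: filter, scale, call markers, assemble."""
    sc = filter_cells_genes(sc, keep_types=keep_types)
    sc = scale_by_library_size(sc)
    deg = find_marker_genes(
        sc,
        min_lfc=config.min_lfc,
        max_adj_p=config.max_adj_p,
        pairwise=config.pairwise_markers,
    )
    return build_signature(
        sc,
        spatial_genes=spatial_genes,
        user_markers=user_markers,
        deg=deg,
        per_sample_mean=config.per_sample_mean,
    )


def _cross_sample_variance(
    sc_scaled: SingleCellDataset, gene_ids: Iterable[str]
) -> dict[str, float]:
    """Per-gene variance of within-(type, sample) means, reported in the run
    log for reference-quality diagnostics (the fits themselves are unweighted)."""
    idx = {g: i for i, g in enumerate(sc_scaled.gene_ids)}
    rows = [idx[g] for g in gene_ids if g in idx]
    X = np.asarray(sc_scaled.counts, dtype=float)[rows, :]
    labels = np.asarray(sc_scaled.cell_type)
    samples = np.asarray(sc_scaled.sample_id)
    means = []
    for t in sc_scaled.cell_types:
        for s in np.unique(samples[labels == t]):
            mask = (labels == t) & (samples == s)
            if mask.any():
                means.append(X[:, mask].mean(axis=1))
    var = np.var(np.stack(means, axis=1), axis=1) if means else np.zeros(len(rows))
    genes = [g for g in gene_ids if g in idx]
    return {g: float(v) for g, v in zip(genes, var)}


def run_pipeline(
    spatial: SpatialDataset,
    sc: SingleCellDataset,
    domains: DomainAssignment | None = None,
    config: PipelineConfig | None = None,
    n_domains: int | None = None,
    user_markers: set[str] | None = None,
    run_log_path: str | os.PathLike | None = None,
) -> tuple[ProportionMatrix, dict]:
    """Run reference construction, selection and deconvolution in order.

    If ``domains`` is None the fallback clusterer is invoked with
    ``n_domains``. Returns the proportion matrix and a run-log dict
    (gene counts after each filter, the per-spot penalty summary, and the
    per-domain cell-type sets); the log is also written to
    ``run_log_path`` as JSON when given.
    """
    config = config or PipelineConfig()
    log: dict = {"seed": config.rng_seed}
    try:
        sc_f = filter_cells_genes(sc)
        sc_scaled = scale_by_library_size(sc_f)
        if len(sc_scaled.cell_types) >= 2:
            deg = find_marker_genes(
                sc_scaled,
                min_lfc=config.min_lfc,
                max_adj_p=config.max_adj_p,
                pairwise=config.pairwise_markers,
            )
        else:
            logger.info("single cell type reference; skipping DEG detection")
            deg = []
        signature = build_signature(
            sc_scaled,
            spatial_genes=set(spatial.gene_ids),
            user_markers=user_markers,
            deg=deg,
            per_sample_mean=config.per_sample_mean,
        )
        log["genes"] = {
            "spatial": spatial.n_genes,
            "reference_after_zero_filter": sc_f.n_genes,
            "n_deg_calls": len(deg),
            "feature_genes": len(signature.gene_ids),
        }
        log["cross_sample_variance_mean"] = float(
            np.mean(list(_cross_sample_variance(sc_scaled, signature.gene_ids).values()))
        )
    except Exception as exc:
        raise RuntimeError(f"reference: {exc}") from exc

    try:
        if domains is None:
            if n_domains is None:
                raise ValueError("n_domains required when no domain labels given")
            domains = assign_domains_fallback(
                spatial,
                n_domains,
                seed=config.rng_seed,
                n_pcs=config.fallback_n_pcs,
                n_neighbors=config.fallback_n_neighbors,
                coord_weight=config.fallback_coord_weight,
            )
        elif domains.spot_ids != spatial.spot_ids:
            raise ValueError("domain labels do not match spatial spot ids")
        log["n_domains"] = domains.n_domains
    except Exception as exc:
        raise RuntimeError(f"domains: {exc}") from exc

    try:
        coef, selection = select_cell_types(spatial, signature, domains, config)
        log["lambda_summary"] = {
            "min": float(coef.lambda_chosen.min()),
            "median": float(np.median(coef.lambda_chosen)),
            "max": float(coef.lambda_chosen.max()),
        }
        log["domain_sets"] = {
            str(d): sorted(s) for d, s in selection.domain_sets.items()
        }
    except Exception as exc:
        raise RuntimeError(f"selection: {exc}") from exc

    try:
        proportions = deconvolve_dataset(
            spatial, signature, selection, domains, config
        )
        log["objective"] = {
            "mean": float(proportions.objective_value.mean()),
            "max": float(proportions.objective_value.max()),
        }
    except Exception as exc:
        raise RuntimeError(f"deconvolution: {exc}") from exc

    if run_log_path is not None:
        with open(run_log_path, "w") as fh:
            json.dump(log, fh, indent=2)
    return proportions, log
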