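"""Spatial-domain labels: CSV ingestion plus a simple fallback clusterer.

Domain detection proper (graph-convolutional methods integrating histology)
is an upstream step; this module ingests such tools' exported labels. The
fallback clusterer exists so the pipeline runs standalone: expression PCA
plus spatially-weighted k-means with one round of neighbor smoothing.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .model import DomainAssignment, SpatialDataset

logger = logging.getLogger("spade")

__all__ = ["load_domain_labels", "assign_domains_fallback"]


def load_domain_labels(
    path: str | os.PathLike, spatial: SpatialDataset
) -> DomainAssignment:
    """Read a ``spot_id,domain`` CSV and re-code labels to 0..D-1.

    Labels are re-coded categorically in first-appearance order (following
    the spot order of ``spatial``); every spot must be labeled.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"domain label file not found: {p}")
    df = pd.read_csv(p)
    mapping = {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}
    for s in spatial.spot_ids:
        if s not in mapping:
            raise ValueError(f"spot {s!r} has no domain label")
    codes: dict[str, int] = {}
    domain = np.empty(spatial.n_spots, dtype=int)
    for i, s in enumerate(spatial.spot_ids):
        lab = mapping[s]
        if lab not in codes:
            codes[lab] = len(codes)
        domain[i] = codes[lab]
    return DomainAssignment(
        spot_ids=spatial.spot_ids, domain=domain, n_domains=len(codes)
    )


def _smooth_labels(
    labels: np.ndarray, coords: np.ndarray, n_neighbors: int
) -> np.ndarray:
    """One round of majority smoothing over spatial nearest neighbors.

    Each spot takes the majority label among its ``n_neighbors`` nearest
    spots (self excluded); ties keep the spot's own label.
    """
    n = len(labels)
    k = min(n_neighbors, n - 1)
    if k < 1:
        return labels.copy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    out = labels.copy()
    for i in range(n):
        neigh = labels[idx[i, 1:]]
        counts = np.bincount(neigh)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if len(winners) == 1:
            out[i] = winners[0]
        # ties keep the original label
    return out


def assign_domains_fallback(
    spatial: SpatialDataset,
    n_domains: int,
    seed: int,
    n_pcs: int = 50,
    n_neighbors: int = 6,
    coord_weight: float = 1.0,
) -> DomainAssignment:
    """Cluster spots into spatial domains from expression plus coordinates.

    Pipeline: scale each spot to a common total and log1p-transform, reduce
    to the top ``n_pcs`` principal components, append z-scaled coordinates
    (and mean RGB when present) weighted by ``coord_weight``, run k-means
    with ``n_domains`` clusters at a fixed seed, then apply one round of
    majority smoothing over the 6 nearest spatial neighbors. Labels are
    re-coded to contiguous 0..D-1 in first-appearance order.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    if n_domains > spatial.n_spots:
        raise ValueError(
            f"n_domains={n_domains} exceeds number of spots {spatial.n_spots}"
        )
    if n_domains == 1:
        return DomainAssignment(
            spot_ids=spatial.spot_ids,
            domain=np.zeros(spatial.n_spots, dtype=int),
            n_domains=1,
        )
    counts = np.asarray(spatial.counts, dtype=float)
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    expr = np.log1p(1e4 * counts / totals).T  # spots x genes
    n_comp = min(n_pcs, min(expr.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(expr)

    def zscale(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0)
        sd[sd == 0] = 1.0
        return (a - a.mean(axis=0)) / sd

    feats = [zscale(pcs), coord_weight * zscale(spatial.coords.copy())]
    if spatial.histology_rgb is not None:
        feats.append(coord_weight * zscale(spatial.histology_rgb.copy()))
    Z = np.hstack(feats)
    km = KMeans(n_clusters=n_domains, random_state=seed, n_init=10).fit(Z)
    labels = _smooth_labels(km.labels_.astype(int), spatial.coords, n_neighbors)
    # recode to contiguous first-appearance order (smoothing can drop labels)
    codes: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in codes:
            codes[lab] = len(codes)
        out[i] = codes[lab]
    return DomainAssignment(
        spot_ids=spatial.spot_ids, domain=out, n_domains=len(codes)
    )
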