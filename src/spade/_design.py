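"""Shared construction of the fitting matrices (feature genes x spots/types)."""

from __future__ import annotations

import logging

import numpy as np

from .model import SpatialDataset
from .reference import SignatureMatrix

logger = logging.getLogger("spade")


def design_matrices(
    spatial: SpatialDataset, signature: SignatureMatrix, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (Y, X): spot expression and signature over the feature genes.

    Y is genes x spots, X is genes x cell types, both restricted to the
    signature's feature genes in signature order. Under mode "sum1" each
    spot vector and each signature column is scaled to unit sum so a convex
    combination of columns can reproduce a mixture exactly; "none" leaves
    both on their raw scale.
    """
    missing = [g for g in signature.gene_ids if g not in set(spatial.gene_ids)]
    if missing:
        raise ValueError(
            f"{len(missing)} feature gene(s) absent from spatial data, "
            f"first: {missing[0]!r}"
        )
    sp = spatial.subset_genes(signature.gene_ids)
    Y = np.asarray(sp.counts, dtype=float).copy()
    X = np.asarray(signature.values, dtype=float).copy()
    if mode == "sum1":
        ysums = Y.sum(axis=0)
        zero = ysums == 0
        if zero.any():
            logger.warning(
                "%d spot(s) have zero feature-gene expression", int(zero.sum())
            )
            ysums[zero] = 1.0
        Y /= ysums[np.newaxis, :]
        xsums = X.sum(axis=0)
        if (xsums == 0).any():
            raise ValueError("a signature column is all zero over feature genes")
        X /= xsums[np.newaxis, :]
    elif mode != "none":
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Y, X
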