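"""Evaluation of estimated proportions and cell-type selections.

Accuracy of a proportion matrix against ground truth is summarized by the
mean absolute deviation (mAD), root-mean-square error (RMSE) and Pearson
correlation R over all (spot, cell type) entries; selection quality per
domain by true/false positive rates over the cell-type sets; and spatial
co-occurrence of cell types by the pairwise Pearson correlation of their
proportion profiles across spots (colocalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("spade")

__all__ = [
    "EvaluationReport",
    "compute_mad_rmse_r",
    "compute_selection_tpr_fpr",
    "colocalization_matrix",
    "evaluate",
]


@dataclass
class EvaluationReport:
    mad_overall: float
    rmse_overall: float
    r_overall: float
    per_cell_type: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    per_domain_selection: dict[int, tuple[float, float]] = field(default_factory=dict)
    colocalization: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "mad_overall": self.mad_overall,
            "rmse_overall": self.rmse_overall,
            "r_overall": self.r_overall,
            "per_cell_type": {
                t: {"mad": v[0], "rmse": v[1], "r": v[2]}
                for t, v in self.per_cell_type.items()
            },
            "per_domain_selection": {
                str(d): {"tpr": v[0], "fpr": v[1]}
                for d, v in self.per_domain_selection.items()
            },
        }
        if self.colocalization is not None:
            out["colocalization"] = self.colocalization.tolist()
        return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance input; correlation undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compute_mad_rmse_r(
    P_est: np.ndarray, P_true: np.ndarray
) -> tuple[float, float, float]:
    """mAD, RMSE and Pearson R pooled over all (spot, cell-type) entries."""
    P_est = np.asarray(P_est, dtype=float)
    P_true = np.asarray(P_true, dtype=float)
    if P_est.shape != P_true.shape:
        raise ValueError(f"shape mismatch: {P_est.shape} vs {P_true.shape}")
    diff = P_est - P_true
    mad = float(np.abs(diff).mean())
    rmse = float(np.sqrt((diff**2).mean()))
    r = _pearson(P_est.ravel(), P_true.ravel())
    return mad, rmse, r


def compute_selection_tpr_fpr(
    S_est: dict[int, set[str]],
    S_true: dict[int, set[str]],
    all_types: set[str],
) -> dict[int, tuple[float, float]]:
    """Per-domain true/false positive rates for cell-type detection.

    tpr_d = |S_est ∩ S_true| / |S_true|; fpr_d = |S_est \\ S_true| over the
    absent types |all_types \\ S_true| (0 when no type is absent).
    """
    out: dict[int, tuple[float, float]] = {}
    for d, truth in S_true.items():
        if not truth or not truth <= all_types:
            raise ValueError(f"invalid true set for domain {d}")
        est = S_est.get(d, set())
        unknown = est - all_types
        if unknown:
            raise ValueError(f"unknown type(s) in estimate: {sorted(unknown)}")
        tpr = len(est & truth) / len(truth)
        absent = all_types - truth
        fpr = len(est - truth) / len(absent) if absent else 0.0
        out[d] = (tpr, fpr)
    return out


def colocalization_matrix(
    P: np.ndarray, spots_subset: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise Pearson correlation of cell-type proportion profiles.

    Entry (j, k) correlates types j and k across the (optionally subset)
    spots; zero-variance types yield NaN rows/columns with a warning.
    """
    P = np.asarray(P, dtype=float)
    if spots_subset is not None:
        P = P[np.asarray(spots_subset)]
    if P.shape[0] < 3:
        raise ValueError("colocalization needs at least 3 spots")
    K = P.shape[1]
    out = np.empty((K, K))
    for j in range(K):
        for k in range(j, K):
            if j == k:
                out[j, j] = 1.0 if P[:, j].std() > 0 else float("nan")
            else:
                out[j, k] = out[k, j] = _pearson(P[:, j], P[:, k])
    return out


def evaluate(
    P_est: np.ndarray,
    P_true: np.ndarray,
    cell_types: list[str],
    S_est: dict[int, set[str]] | None = None,
    S_true: dict[int, set[str]] | None = None,
) -> EvaluationReport:
    """Full evaluation report: overall + per-type accuracy, selection rates,
    and the colocalization matrix of the estimates."""
    mad, rmse, r = compute_mad_rmse_r(P_est, P_true)
    per_type = {}
    for j, t in enumerate(cell_types):
        per_type[t] = compute_mad_rmse_r(P_est[:, j], P_true[:, j])
    report = EvaluationReport(
        mad_overall=mad,
        rmse_overall=rmse,
        r_overall=r,
        per_cell_type=per_type,
    )
    if S_est is not None and S_true is not None:
        report.per_domain_selection = compute_selection_tpr_fpr(
            S_est, S_true, set(cell_types)
        )
    if P_est.shape[0] >= 3:
        report.colocalization = colocalization_matrix(P_est)
    return report
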