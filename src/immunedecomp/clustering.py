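"""Immune-infiltration feature panel and three-class cohort clustering.

The 28-feature panel stacks the ssGSEA scores of the 24 immune-cell-type
signatures, the 40-gene angiogenesis signature, and the three single-gene
checkpoint-target signatures (PD-1, PD-L1, CTLA-4), all scored jointly so
they share one normalization.  Samples are then grouped by agglomerative
hierarchical clustering with Ward linkage on Euclidean distances over the
panel columns (the Ward.D2 contract: the Lance-Williams update applied to
squared Euclidean distances), and the tree is cut into k clusters.

For k = 3 the clusters receive semantic labels by their mean T-cell subset
score: highest -> "T_cell_enriched", lowest -> "non_infiltrated", middle ->
"heterogeneously_infiltrated".  Ties are broken by the mean checkpoint-
target score and finally by cluster id, so labeling is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .aggregates import TIS_CONSTITUENTS
from .signatures import SignatureCollection, builtin_signatures
from .ssgsea import SsgseaParams, score_matrix

__all__ = [
    "CLASS_LABELS",
    "panel_collection",
    "assemble_features",
    "cluster_cohort",
    "label_clusters",
    "predict_nearest_centroid",
]

CLASS_LABELS = ("T_cell_enriched", "heterogeneously_infiltrated", "non_infiltrated")

_CHECKPOINT_FEATURES = ("PD-1", "PD-L1", "CTLA-4")


def panel_collection() -> SignatureCollection:
    """The 28-signature panel: bindea24 + angiogenesis + checkpoint targets."""
    return (
        builtin_signatures("bindea24")
        .merge(builtin_signatures("angiogenesis"))
        .merge(builtin_signatures("checkpoint_targets"), source="builtin:panel28")
    )


def assemble_features(
    expr: pd.DataFrame, params: SsgseaParams | None = None
) -> pd.DataFrame:
    """Jointly scored 28 x samples feature panel, columns in input order."""
    return score_matrix(expr, panel_collection(), params)


def cluster_cohort(
    panel: pd.DataFrame, k: int = 3, standardize_features: bool = False
) -> np.ndarray:
    """Ward/Euclidean hierarchical clustering of the panel columns.

    Features enter as raw ssGSEA scores by default; ``standardize_features``
    optionally z-scores each feature row first.  Returns integer cluster
    ids 1..k, deterministic for fixed input.
    """
    n = panel.shape[1]
    if n < k:
        raise ValueError(f"cannot cut {n} samples into {k} clusters")
    x = panel.to_numpy(dtype=float).T
    if standardize_features:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    if k == 1:
        return np.ones(n, dtype=int)
    tree = linkage(x, method="ward", metric="euclidean")
    return fcluster(tree, t=k, criterion="maxclust")


def label_clusters(labels: np.ndarray, panel: pd.DataFrame) -> pd.DataFrame:
    """Attach semantic infiltration labels to a three-way clustering.

    Clusters are ordered by mean T-cell subset score (ties: mean checkpoint
    score, then cluster id).  With k != 3 the ids are returned unnamed.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != panel.shape[1]:
        raise ValueError("one cluster id per panel column required")
    out = pd.DataFrame(
        {"cluster_id": labels}, index=pd.Index(panel.columns, name="sample")
    )
    if np.ptp(panel.to_numpy()) == 0:
        warnings.warn("feature panel is constant; labeling is arbitrary",
                      stacklevel=2)
    ids = np.unique(labels)
    if len(ids) != 3:
        out["label"] = ""
        return out

    t_rows = [r for r in TIS_CONSTITUENTS if r in panel.index]
    cp_rows = [r for r in _CHECKPOINT_FEATURES if r in panel.index]
    if not t_rows:
        raise ValueError("panel has no T-cell subset feature rows")
    t_mean = panel.loc[t_rows].mean(axis=0)
    cp_mean = (
        panel.loc[cp_rows].mean(axis=0)
        if cp_rows
        else pd.Series(0.0, index=panel.columns)
    )

    keys = sorted(
        (
            (float(t_mean[labels == cid].mean()),
             float(cp_mean[labels == cid].mean()),
             int(cid))
            for cid in ids
        ),
    )
    ranked = [cid for *_unused, cid in keys]  # ascending T-cell mean
    name_of = {
        ranked[0]: "non_infiltrated",
        ranked[1]: "heterogeneously_infiltrated",
        ranked[2]: "T_cell_enriched",
    }
    out["label"] = [name_of[c] for c in labels]
    return out


def predict_nearest_centroid(
    panel_new: pd.DataFrame,
    panel_ref: pd.DataFrame,
    labels_ref: np.ndarray,
) -> np.ndarray:
    """Assign new samples to the nearest reference-cluster centroid.

    A convenience for transferring cluster ids to a new cohort; this is a
    plain Euclidean nearest-centroid rule, not a trained classifier.
    """
    if list(panel_new.index) != list(panel_ref.index):
        raise ValueError("feature rows of the two panels must match")
    labels_ref = np.asarray(labels_ref)
    ids = np.unique(labels_ref)
    centroids = np.stack(
        [panel_ref.loc[:, labels_ref == cid].mean(axis=1).to_numpy() for cid in ids]
    )
    x = panel_new.to_numpy(dtype=float).T
    d = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return ids[np.argmin(d, axis=1)]
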