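"""Aggregation and structure of results: per-channel significant-feature
counts and correlation-distance hierarchical clustering of features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = ["count_significant", "cluster_features", "heatmap"]


def count_significant(results: pd.DataFrame,
                      require_datasets: set[str] | list[str],
                      metric: str = "accuracy") -> pd.DataFrame:
    """Per-channel counts of features significant across datasets.

    For each channel: ``all_required`` counts features FDR-significant in
    *every* dataset of ``require_datasets`` (intersection of per-dataset
    masks), and ``in_exactly_k`` counts features significant in exactly k of
    them, k = 1..K.  A feature counts as significant in a dataset when any
    of its condition pairs is significant there.
    """
    require = sorted(set(require_datasets))
    sub = results[(results["metric"] == metric)
                  & results["dataset_id"].isin(require)]
    sig = (sub[sub["fdr_significant"]]
           .groupby(["channel", "feature_name"])["dataset_id"]
           .nunique())
    rows = []
    for ch in np.sort(results["channel"].unique()):
        per_feature = sig.loc[ch] if ch in sig.index.get_level_values(0) else \
            pd.Series(dtype=int)
        row = {"channel": ch,
               "all_required": int((per_feature == len(require)).sum())}
        for k in range(1, len(require) + 1):
            row[f"in_exactly_{k}"] = int((per_feature == k).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("channel")


def cluster_features(values: pd.DataFrame, threshold: float = 0.7,
                     method: str = "average", min_complete_pairs: int = 10
                     ) -> dict:
    """Agglomerative clustering of features by absolute Spearman distance.

    Pairwise distance d = 1 - |Spearman rho| across all epochs (rows),
    missing values pairwise-deleted; agglomeration with the given linkage
    (default average); flat groups cut at the distance ``threshold``.
    Features with fewer than ``min_complete_pairs`` complete pairs against
    any other feature are excluded.

    Returns a dict with ``features`` (retained names), ``linkage`` (scipy
    linkage matrix), ``groups`` (name -> flat cluster id), ``leaf_order``
    (dendrogram-leaf ordering of names for heatmaps), and ``distance``
    (the condensed distance matrix as a DataFrame).
    """
    finite = values.replace([np.inf, -np.inf], np.nan)
    keep = [c for c in finite.columns
            if finite[c].notna().sum() >= min_complete_pairs]
    if len(keep) < 2:
        raise ValueError("need at least 2 features with enough complete pairs")
    sub = finite[keep]
    rho = sub.corr(method="spearman", min_periods=min_complete_pairs)
    # pairs with too few complete observations are treated as unrelated
    dist = (1.0 - rho.abs()).clip(lower=0.0).fillna(1.0)
    np.fill_diagonal(dist.values, 0.0)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=method)
    flat = fcluster(z, t=threshold, criterion="distance")
    order = leaves_list(z)
    return {
        "features": keep,
        "linkage": z,
        "groups": dict(zip(keep, (int(g) for g in flat))),
        "leaf_order": [keep[i] for i in order],
        "distance": dist,
    }


def heatmap(scaled_values: pd.DataFrame, meta: pd.DataFrame,
            feature_order: list[str] | None = None, ax=None):
    """Epochs x features image plot of sigmoid-scaled values.

    ``scaled_values`` must already be on [0, 1] (robust sigmoid scaling);
    rows are grouped by fly and condition, columns optionally follow a
    dendrogram-leaf ordering.
    """
    import matplotlib.pyplot as plt

    cols = feature_order or list(scaled_values.columns)
    order = meta.sort_values(["condition", "fly_id"]).index
    img = scaled_values.loc[order, cols].to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(img, aspect="auto", vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xlabel("feature")
    ax.set_ylabel("epoch (grouped by condition, fly)")
    plt.colorbar(im, ax=ax, label="scaled value")
    return ax
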