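"""Within-fly effect-direction consistency and its permutation null.

Classification accuracy requires feature value *ranges* to transfer across
flies and datasets; consistency asks only whether the *direction* of the
anesthesia/sleep effect is conserved within each fly.  For each wake epoch
of a fly, the statistic takes the proportion of that same fly's unconscious
epochs lying below it (after multiplying values by the +1/-1 direction label
learned from discovery data), and averages over all wake epochs and flies.
A value of 1 means the direction is conserved for every within-fly pairing,
0.5 is chance, and 0 means the effect is perfectly reversed relative to the
discovery-derived direction.  Being rank-based, the statistic is invariant
to any strictly increasing per-fly transform of the feature values — which
is exactly why it survives fly-level baseline offsets that destroy
across-fly classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import median_direction, permutation_pvalue, fdr_correct, \
    DEFAULT_N_REPS
from .features import FeatureMatrix

__all__ = [
    "effect_direction_labels",
    "within_fly_consistency",
    "consistency_table",
    "permutation_null_consistency",
]


def effect_direction_labels(matrix: FeatureMatrix,
                            wake_conditions: list[str] = ("wake",),
                            unconscious_conditions: list[str] = ("anesthesia",),
                            ) -> dict[tuple[str, int], int]:
    """Per-(feature, channel) direction labels from discovery medians.

    +1 when the median wakeful value exceeds the median unconscious value,
    -1 otherwise (the tie also maps to -1); identical to the classifier
    direction component.
    """
    labels: dict[tuple[str, int], int] = {}
    for ch in matrix.validity.index:
        vals, meta = matrix.channel(ch)
        w_mask = meta["condition"].isin(list(wake_conditions)).to_numpy()
        u_mask = meta["condition"].isin(list(unconscious_conditions)).to_numpy()
        for name in matrix.valid_features(ch):
            col = vals[name].to_numpy()
            labels[(name, ch)] = median_direction(col[w_mask], col[u_mask])
    return labels


def within_fly_consistency(wake_by_fly: dict[str, np.ndarray],
                           unconscious_by_fly: dict[str, np.ndarray],
                           label: int,
                           weight_flies_equally: bool = False) -> float:
    """Consistency of the effect direction across within-fly epoch pairs.

    After multiplying all values by ``label``, each wake epoch contributes
    the proportion of the same fly's unconscious epochs strictly below it
    (ties count as not-below).  By default the proportions are averaged over
    all wake epochs pooled across flies (flies weighted by their wake-epoch
    counts); ``weight_flies_equally`` averages per-fly means instead.
    Flies missing either class are excluded.
    """
    if label not in (-1, 1):
        raise ValueError("label must be +1 or -1")
    per_fly_props: list[np.ndarray] = []
    for fly, w in wake_by_fly.items():
        u = unconscious_by_fly.get(fly)
        if u is None:
            continue
        w = label * np.asarray(w, dtype=float)
        u = label * np.asarray(u, dtype=float)
        if w.size == 0 or u.size == 0:
            continue
        props = (u[None, :] < w[:, None]).mean(axis=1)
        per_fly_props.append(props)
    if not per_fly_props:
        raise ValueError("no fly contributes both conditions")
    if weight_flies_equally:
        return float(np.mean([p.mean() for p in per_fly_props]))
    return float(np.concatenate(per_fly_props).mean())


def consistency_table(matrix: FeatureMatrix,
                      labels: dict[tuple[str, int], int],
                      pairing: dict[str, tuple[list[str], list[str]]],
                      ) -> pd.DataFrame:
    """Consistency for every (feature, channel, dataset, condition pair).

    ``labels`` are the discovery-derived direction labels; rows follow the
    same schema as the classification result table with metric
    'consistency'.
    """
    rows = []
    for ds, (wake_like, unc_like) in pairing.items():
        ds_mask = (matrix.meta["dataset_id"] == ds).to_numpy()
        for wc in wake_like:
            for uc in unc_like:
                for (name, ch), label in labels.items():
                    ch_mask = ds_mask & (matrix.meta["channel"] == ch).to_numpy()
                    meta = matrix.meta.loc[ch_mask]
                    col = matrix.values[name].to_numpy()[ch_mask]
                    wake_by_fly, unc_by_fly = {}, {}
                    for fly in meta["fly_id"].unique():
                        f_mask = (meta["fly_id"] == fly).to_numpy()
                        wake_by_fly[fly] = col[
                            f_mask & (meta["condition"] == wc).to_numpy()]
                        unc_by_fly[fly] = col[
                            f_mask & (meta["condition"] == uc).to_numpy()]
                    try:
                        value = within_fly_consistency(
                            wake_by_fly, unc_by_fly, label)
                    except ValueError:
                        continue
                    n = sum(v.size for v in wake_by_fly.values())
                    rows.append({
                        "feature_name": name, "channel": ch,
                        "dataset_id": ds, "condition_pair": f"{wc}|{uc}",
                        "metric": "consistency", "value": value,
                        "n_epochs": n, "normalized": False,
                    })
    return pd.DataFrame(rows)


def permutation_null_consistency(epoch_counts: dict[str, tuple[int, int]],
                                 n_reps: int = DEFAULT_N_REPS,
                                 rng: np.random.Generator | None = None,
                                 weight_flies_equally: bool = False
                                 ) -> np.ndarray:
    """Null distribution of the consistency statistic.

    ``epoch_counts`` maps fly -> (n_wake, n_unconscious).  Each repetition
    draws, for every wake epoch of every fly, a proportion uniformly from
    that fly's achievable set {0, 1/n_u, ..., 1}, and averages across wake
    epochs and flies (pooled by default, matching the statistic).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    per_fly: list[np.ndarray] = []
    for fly, (n_w, n_u) in epoch_counts.items():
        if n_w < 1 or n_u < 1:
            raise ValueError(f"fly {fly!r} needs >= 1 epoch per condition")
        draws = rng.integers(0, n_u + 1, size=(n_reps, n_w)) / n_u
        per_fly.append(draws)
    if not per_fly:
        raise ValueError("no flies given")
    if weight_flies_equally:
        return np.mean([d.mean(axis=1) for d in per_fly], axis=0)
    return np.concatenate(per_fly, axis=1).mean(axis=1)
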