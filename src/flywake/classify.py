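"""Per-(feature, channel) nearest-median classification of conscious level.

A classifier for one feature at one channel is a threshold (the midpoint
between the wake and unconscious class medians of the training epochs) and a
direction (whether values above the threshold are called wake).  Medians are
order statistics, so +/-infinity feature values are handled without special
casing.  The module provides leave-one-fly-out cross-validation on the
discovery flies, evaluation of discovery-trained classifiers over
wake-like x unconscious-like condition pairs in independent datasets,
dataset-level batch normalization (z-score to discovery moments), a
random-classification permutation null, and per-channel Benjamini-Hochberg
FDR correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix

__all__ = [
    "MedianClassifier",
    "fit_classifier",
    "predict_accuracy",
    "lofo_cross_validate",
    "train_full",
    "evaluate_condition_pairs",
    "batch_normalize",
    "batch_normalize_matrix",
    "permutation_null_accuracy",
    "permutation_pvalue",
    "fdr_correct",
    "attach_significance",
    "DEFAULT_N_REPS",
]

#: permutation repetitions matching the size of the full feature library
DEFAULT_N_REPS = 7702


def _median_with_inf(values: np.ndarray) -> float:
    """Median by order statistics over non-NaN values (+-inf allowed)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan
    v = np.sort(v)
    mid = v.size // 2
    if v.size % 2:
        return float(v[mid])
    lo, hi = v[mid - 1], v[mid]
    if np.isinf(lo) and np.isinf(hi):
        return float(lo) if lo == hi else math.nan
    return float((lo + hi) / 2.0)


def median_direction(wake_values: np.ndarray, unconscious_values: np.ndarray
                     ) -> int:
    """+1 if the wake median exceeds the unconscious median, else -1.

    Ties get -1 (the literal 'otherwise' branch); callers flag such
    classifiers as degenerate.
    """
    mw = _median_with_inf(wake_values)
    mu = _median_with_inf(unconscious_values)
    return 1 if mw > mu else -1


@dataclass(frozen=True)
class MedianClassifier:
    """Threshold + direction pair for one feature at one channel."""

    feature_name: str
    channel: int
    threshold: float
    direction: int
    train_fly_ids: tuple[str, ...] = ()
    degenerate: bool = False


def fit_classifier(wake_values: np.ndarray, unconscious_values: np.ndarray,
                   feature_name: str = "", channel: int = 0,
                   train_fly_ids: tuple[str, ...] = ()) -> MedianClassifier:
    """Train on raw class values: threshold = midpoint of class medians.

    Requires at least one non-NaN value per class; raises ValueError for an
    untrainable (all-missing) class so callers can skip and log the feature.
    """
    mw = _median_with_inf(np.asarray(wake_values, dtype=float))
    mu = _median_with_inf(np.asarray(unconscious_values, dtype=float))
    if math.isnan(mw) or math.isnan(mu):
        raise ValueError("a class has no usable values; feature untrainable")
    if np.isinf(mw) and np.isinf(mu) and mw == mu:
        threshold = mw
    else:
        threshold = (mw + mu) / 2.0
    degenerate = mw == mu
    direction = 1 if mw > mu else -1
    return MedianClassifier(feature_name, channel, float(threshold),
                            direction, tuple(train_fly_ids), degenerate)


def predict_accuracy(clf: MedianClassifier, wake_values: np.ndarray,
                     unconscious_values: np.ndarray) -> float:
    """Fraction of correctly labeled epochs pooled over both conditions.

    A value v is classified wake iff direction * (v - threshold) > 0;
    values exactly on the threshold are classified unconscious.  NaN values
    cannot be classified and count as incorrect.
    """
    w = np.asarray(wake_values, dtype=float)
    u = np.asarray(unconscious_values, dtype=float)
    with np.errstate(invalid="ignore"):
        correct = (np.count_nonzero(clf.direction * (w - clf.threshold) > 0)
                   + np.count_nonzero(~(clf.direction * (u - clf.threshold) > 0)
                                      & ~np.isnan(u)))
    return correct / (w.size + u.size)


def _class_values(values: pd.Series, meta: pd.DataFrame,
                  conditions: tuple[str, ...] | list[str]) -> np.ndarray:
    mask = meta["condition"].isin(list(conditions)).to_numpy()
    return values.to_numpy()[mask]


def lofo_cross_validate(matrix: FeatureMatrix,
                        wake_conditions: list[str] = ("wake",),
                        unconscious_conditions: list[str] = ("anesthesia",),
                        ) -> pd.DataFrame:
    """Leave-one-fly-out cross-validation on (discovery) data.

    One fold per fly: train the nearest-median classifier on all remaining
    flies' epochs and test on the held-out fly's epochs.  Returns one row
    per (feature, channel) with the mean and SD of fold accuracies and the
    fold count.  Features invalid at a channel, or untrainable in any fold,
    are skipped.
    """
    rows = []
    for ch in matrix.validity.index:
        vals, meta = matrix.channel(ch)
        flies = list(dict.fromkeys(meta["fly_id"]))
        for name in matrix.valid_features(ch):
            col = vals[name]
            fold_acc = []
            try:
                for fly in flies:
                    test = (meta["fly_id"] == fly).to_numpy()
                    train_v, train_m = col[~test], meta[~test]
                    test_v, test_m = col[test], meta[test]
                    clf = fit_classifier(
                        _class_values(train_v, train_m, wake_conditions),
                        _class_values(train_v, train_m, unconscious_conditions),
                        name, ch)
                    fold_acc.append(predict_accuracy(
                        clf,
                        _class_values(test_v, test_m, wake_conditions),
                        _class_values(test_v, test_m, unconscious_conditions)))
            except ValueError:
                continue
            acc = np.asarray(fold_acc)
            rows.append({"feature_name": name, "channel": ch,
                         "mean_accuracy": acc.mean(),
                         "sd_accuracy": acc.std(ddof=1) if acc.size > 1 else 0.0,
                         "n_folds": acc.size})
    return pd.DataFrame(rows)


def train_full(matrix: FeatureMatrix,
               wake_conditions: list[str] = ("wake",),
               unconscious_conditions: list[str] = ("anesthesia",),
               ) -> dict[tuple[str, int], MedianClassifier]:
    """Final classifiers trained on all flies of the (discovery) matrix."""
    clfs: dict[tuple[str, int], MedianClassifier] = {}
    for ch in matrix.validity.index:
        vals, meta = matrix.channel(ch)
        flies = tuple(dict.fromkeys(meta["fly_id"]))
        for name in matrix.valid_features(ch):
            try:
                clfs[(name, ch)] = fit_classifier(
                    _class_values(vals[name], meta, wake_conditions),
                    _class_values(vals[name], meta, unconscious_conditions),
                    name, ch, flies)
            except ValueError:
                continue
    return clfs


def evaluate_condition_pairs(
    clfs: dict[tuple[str, int], MedianClassifier],
    eval_matrix: FeatureMatrix,
    pairing: dict[str, tuple[list[str], list[str]]],
    normalized: bool = False,
) -> pd.DataFrame:
    """Accuracy of discovery-trained classifiers on evaluation datasets.

    ``pairing`` maps each dataset id to (wake-like conditions,
    unconscious-like conditions); each wake-like condition is paired with
    each unconscious-like condition, giving one accuracy per (feature,
    channel, dataset, pair).  Balanced epoch counts make chance exactly 0.5.
    """
    rows = []
    for ds, (wake_like, unc_like) in pairing.items():
        ds_mask = (eval_matrix.meta["dataset_id"] == ds).to_numpy()
        for wc in wake_like:
            for uc in unc_like:
                for (name, ch), clf in clfs.items():
                    ch_mask = ds_mask & (eval_matrix.meta["channel"] == ch
                                         ).to_numpy()
                    meta = eval_matrix.meta.loc[ch_mask]
                    col = eval_matrix.values[name].to_numpy()[ch_mask]
                    w = col[(meta["condition"] == wc).to_numpy()]
                    u = col[(meta["condition"] == uc).to_numpy()]
                    if w.size == 0 or u.size == 0:
                        continue
                    rows.append({
                        "feature_name": name, "channel": ch,
                        "dataset_id": ds, "condition_pair": f"{wc}|{uc}",
                        "metric": "accuracy",
                        "value": predict_accuracy(clf, w, u),
                        "n_epochs": w.size + u.size,
                        "normalized": normalized,
                    })
    return pd.DataFrame(rows)


def batch_normalize(eval_values: np.ndarray,
                    eval_mean: float, eval_sd: float,
                    discovery_mean: float, discovery_sd: float) -> np.ndarray:
    """Map evaluation values onto the discovery distribution:

    v' = (v - m_eval)/s_eval * s_disc + m_disc.

    Infinities pass through unchanged; requires s_eval > 0.
    """
    if not eval_sd > 0:
        raise ValueError("evaluation reference SD must be > 0")
    v = np.asarray(eval_values, dtype=float)
    out = (v - eval_mean) / eval_sd * discovery_sd + discovery_mean
    inf = np.isinf(v)
    out[inf] = v[inf]
    return out


def _finite_moments(v: np.ndarray) -> tuple[float, float]:
    f = v[np.isfinite(v)]
    if f.size < 2:
        return math.nan, math.nan
    return float(f.mean()), float(f.std(ddof=1))


def batch_normalize_matrix(eval_matrix: FeatureMatrix,
                           discovery_matrix: FeatureMatrix) -> FeatureMatrix:
    """Batch-normalize every (feature, channel) of an evaluation matrix.

    Moments are computed over all epochs of each evaluation dataset
    (separately per dataset, per channel) ignoring non-finite values, and
    mapped onto the discovery moments for the same feature and channel.
    Features whose evaluation SD is zero are left unnormalized.
    """
    values = eval_matrix.values.copy()
    for ds in eval_matrix.meta["dataset_id"].unique():
        ds_mask = (eval_matrix.meta["dataset_id"] == ds).to_numpy()
        for ch in eval_matrix.validity.index:
            ch_mask = ds_mask & (eval_matrix.meta["channel"] == ch).to_numpy()
            d_mask = (discovery_matrix.meta["channel"] == ch).to_numpy()
            for name in eval_matrix.feature_names:
                if name not in discovery_matrix.values.columns:
                    continue
                ev = eval_matrix.values[name].to_numpy()[ch_mask]
                dv = discovery_matrix.values[name].to_numpy()[d_mask]
                me, se = _finite_moments(ev)
                md, sd = _finite_moments(dv)
                if not (se > 0) or math.isnan(md):
                    continue
                values.loc[ch_mask, name] = batch_normalize(ev, me, se, md, sd)
    return FeatureMatrix(values, eval_matrix.meta, eval_matrix.validity)


def permutation_null_accuracy(n_wake: int, n_unconscious: int,
                              n_reps: int = DEFAULT_N_REPS,
                              rng: np.random.Generator | None = None
                              ) -> np.ndarray:
    """Null distribution of accuracies under random classification.

    Each repetition labels each of the n_wake + n_unconscious epochs wake or
    unconscious independently with probability 1/2; the recorded statistic
    is the fraction of epochs whose random label matches the true one.
    """
    if n_wake < 1 or n_unconscious < 1 or n_reps < 1:
        raise ValueError("epoch counts and n_reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n = n_wake + n_unconscious
    correct = rng.random((n_reps, n)) < 0.5
    return correct.mean(axis=1)


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """p = (1 + #{null >= observed}) / (n_reps + 1)."""
    null = np.asarray(null)
    return (1.0 + np.count_nonzero(null >= observed)) / (null.size + 1.0)


def fdr_correct(p_values: np.ndarray, q: float = 0.05
                ) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up at level q (valid under positive
    dependency).  Returns the boolean significance mask and the adaptive
    p-value threshold (0.0 when nothing passes)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    mask = multipletests(p, alpha=q, method="fdr_bh")[0]
    threshold = float(p[mask].max()) if mask.any() else 0.0
    return mask, threshold


def attach_significance(results: pd.DataFrame,
                        null_by_key: dict, q: float = 0.05) -> pd.DataFrame:
    """Add permutation p-values and per-channel FDR flags to a result table.

    ``null_by_key`` maps (dataset_id, condition_pair) -> null distribution
    (accuracy or consistency, matching the table's metric).  FDR is applied
    within each (channel, dataset, condition_pair) group across features.
    """
    out = results.copy()
    out["p_value"] = [
        permutation_pvalue(row.value,
                           null_by_key[(row.dataset_id, row.condition_pair)])
        for row in out.itertuples()
    ]
    out["fdr_significant"] = False
    for _, idx in out.groupby(["channel", "dataset_id", "condition_pair"]
                              ).groups.items():
        mask, _ = fdr_correct(out.loc[idx, "p_value"].to_numpy(), q)
        out.loc[idx, "fdr_significant"] = mask
    return out
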