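"""High-level pipeline: synthetic study -> preprocessing -> features ->
classification + consistency with permutation significance.

Chains the stage modules with the study's default contracts (discovery
training, leave-one-fly-out cross-validation, evaluation over condition
pairs with optional batch normalization, permutation nulls and per-channel
FDR).  Each stage remains usable on its own; this module only wires them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, consistency
from .features import FeatureDef, FeatureMatrix, extract_matrix, fast_registry
from .preprocess import PreprocessParams, preprocess_epochset
from .synth import EpochSet, SynthConfig, generate_study

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    """Everything a downstream report needs from one pipeline run."""

    epochs: EpochSet
    discovery_matrix: FeatureMatrix
    eval_matrix: FeatureMatrix | None
    eval_matrix_normalized: FeatureMatrix | None
    classifiers: dict
    direction_labels: dict
    cv: pd.DataFrame
    results: pd.DataFrame = field(default_factory=pd.DataFrame)


def _split(matrix: FeatureMatrix, datasets: list[str]) -> FeatureMatrix:
    mask = matrix.meta["dataset_id"].isin(datasets).to_numpy()
    return FeatureMatrix(matrix.values.loc[mask].reset_index(drop=True),
                         matrix.meta.loc[mask].reset_index(drop=True),
                         matrix.validity)


def run_study(config: SynthConfig,
              registry: list[FeatureDef] | None = None,
              discovery_dataset: str = "discovery",
              pairing: dict | None = None,
              n_reps: int = classify.DEFAULT_N_REPS,
              q: float = 0.05,
              normalize: bool = True,
              null_seed: int = 0) -> StudyResult:
    """Run the full analysis on a freshly generated synthetic study.

    The discovery dataset trains classifiers and direction labels; every
    other dataset in the config is evaluated (raw and, when ``normalize``,
    batch-normalized) over the given condition pairing (default: all
    wake-like x unconscious-like pairs of the config).  The returned result
    table carries accuracies, consistencies, permutation p-values and
    per-channel FDR flags.
    """
    registry = fast_registry() if registry is None else registry
    raw = generate_study(config)
    epochs = preprocess_epochset(
        raw, PreprocessParams(epoch_seconds=config.epoch_seconds,
                              line_freq=config.line_noise_hz,
                              sample_rate=config.sample_rate))
    matrix = extract_matrix(epochs, registry,
                            reference_datasets=[discovery_dataset])
    disc = _split(matrix, [discovery_dataset])
    eval_datasets = [d for d in config.n_flies_per_dataset
                     if d != discovery_dataset]

    wake_like = list(config.wake_conditions)
    unc_like = list(config.unconscious_conditions)
    if pairing is None:
        pairing = {ds: (wake_like, unc_like) for ds in eval_datasets}

    cv = classify.lofo_cross_validate(disc, wake_like, unc_like)
    clfs = classify.train_full(disc, wake_like, unc_like)
    labels = consistency.effect_direction_labels(disc, wake_like, unc_like)

    rng = np.random.default_rng(null_seed)
    tables: list[pd.DataFrame] = []
    null_by_key: dict = {}

    # discovery-level results (cross-validated accuracy + consistency)
    disc_pairing = {discovery_dataset: (wake_like, unc_like)}
    n_per = config.n_epochs_per_condition
    n_disc_flies = config.n_flies_per_dataset[discovery_dataset]
    disc_key = (discovery_dataset, f"{wake_like[0]}|{unc_like[0]}")
    null_by_key[disc_key] = classify.permutation_null_accuracy(
        n_per * n_disc_flies, n_per * n_disc_flies, n_reps, rng)
    disc_rows = cv.assign(dataset_id=discovery_dataset,
                          condition_pair=f"{wake_like[0]}|{unc_like[0]}",
                          metric="accuracy", value=cv["mean_accuracy"],
                          n_epochs=2 * n_per * n_disc_flies, normalized=False)
    tables.append(disc_rows[["feature_name", "channel", "dataset_id",
                             "condition_pair", "metric", "value", "n_epochs",
                             "normalized"]])
    disc_cons = consistency.consistency_table(disc, labels, disc_pairing)
    tables.append(disc_cons)

    eval_norm = None
    if eval_datasets:
        ev = _split(matrix, eval_datasets)
        tables.append(classify.evaluate_condition_pairs(
            clfs, ev, pairing, normalized=False))
        if normalize:
            eval_norm = classify.batch_normalize_matrix(ev, disc)
            norm_rows = classify.evaluate_condition_pairs(
                clfs, eval_norm, pairing, normalized=True)
            tables.append(norm_rows)
        tables.append(consistency.consistency_table(ev, labels, pairing))
    else:
        ev = None

    results = pd.concat(tables, ignore_index=True)

    # permutation nulls per (dataset, pair); balanced counts per condition
    for ds, (wl, ul) in pairing.items():
        n_flies = config.n_flies_per_dataset[ds]
        for wc in wl:
            for uc in ul:
                key = (ds, f"{wc}|{uc}")
                if key not in null_by_key:
                    null_by_key[key] = classify.permutation_null_accuracy(
                        n_per * n_flies, n_per * n_flies, n_reps, rng)

    acc = results[results["metric"] == "accuracy"]
    acc = classify.attach_significance(acc, null_by_key, q)

    cons_null_by_key = {}
    all_keys = set(zip(results.loc[results["metric"] == "consistency",
                                   "dataset_id"],
                       results.loc[results["metric"] == "consistency",
                                   "condition_pair"]))
    for ds, pair in all_keys:
        n_flies = config.n_flies_per_dataset[ds]
        counts = {f"fly{i}": (n_per, n_per) for i in range(n_flies)}
        cons_null_by_key[(ds, pair)] = \
            consistency.permutation_null_consistency(counts, n_reps, rng)
    cons = results[results["metric"] == "consistency"]
    cons = classify.attach_significance(cons, cons_null_by_key, q)

    results = pd.concat([acc, cons], ignore_index=True)
    return StudyResult(epochs, disc, ev, eval_norm, clfs, labels, cv, results)
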