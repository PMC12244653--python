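"""Nearest-median classification with cross-dataset generalization.

Trains per-(feature, channel) nearest-median classifiers on the discovery
flies, cross-validates them leave-one-fly-out, then evaluates them on a
second synthetic dataset recorded with a 3x amplitude batch shift — the
kind of dataset-level drift that ruins variance-based features until their
values are re-normalized to the discovery distribution, while
autocorrelation features generalize untouched.
"""

import numpy as np

from flywake import SynthConfig
from flywake.features import registry_subset
from flywake.workflow import run_study

cfg = SynthConfig(n_flies_per_dataset={"discovery": 6, "evaluation": 5},
                  n_electrodes=5,
                  channel_effect_profile=np.array([1.0, 0.7, 0.3, 0.0]),
                  seed=11)
registry = registry_subset(["AC_30", "standard_deviation", "StatAvl250",
                            "EN_PermEn"])
res = run_study(cfg, registry=registry, n_reps=2000, null_seed=11)

print("leave-one-fly-out CV on discovery (channel 1):")
cv1 = res.cv[res.cv["channel"] == 1]
for row in cv1.itertuples():
    print(f"  {row.feature_name:22s} mean acc {row.mean_accuracy:.2f} "
          f"(SD {row.sd_accuracy:.2f} over {row.n_folds} folds)")

r = res.results
ev = r[(r.dataset_id == "evaluation") & (r.metric == "accuracy")
       & (r.channel == 1)]
print("\nevaluation dataset, channel 1 (batch gain 3x):")
for name in registry_subset([d.name for d in registry]):
    sub = ev[ev["feature_name"] == name.name]
    raw = sub[~sub["normalized"]].iloc[0]
    norm = sub[sub["normalized"]].iloc[0]
    print(f"  {name.name:22s} raw acc {raw.value:.2f} "
          f"(sig={bool(raw.fdr_significant)})   "
          f"normalized acc {norm.value:.2f} "
          f"(sig={bool(norm.fdr_significant)})")
print("\nAccuracies near 0.5 are chance; the batch shift leaves "
      "autocorrelation untouched but breaks raw variance features, "
      "which batch normalization repairs.")
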