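"""Within-fly effect-direction consistency and feature clustering.

Even when per-fly baseline differences spoil across-fly classification, a
feature whose wake-to-unconscious change keeps its sign within every fly is
still useful when a baseline recording exists.  This example computes the
consistency statistic (1 = direction conserved for every within-fly epoch
pair, 0.5 = chance, 0 = reversed) and then groups features by absolute
Spearman correlation distance, the structure used to recognize families of
features that carry the same signal.
"""

import numpy as np

from flywake import SynthConfig
from flywake.features import registry_subset
from flywake.report import cluster_features
from flywake.workflow import run_study

cfg = SynthConfig(n_flies_per_dataset={"discovery": 6, "evaluation": 5},
                  n_electrodes=5, fly_offset_sd=1.5,
                  channel_effect_profile=np.array([1.0, 0.7, 0.3, 0.0]),
                  seed=13)
registry = registry_subset(["AC_29", "AC_30", "AC_31", "standard_deviation",
                            "rms", "EN_PermEn"])
res = run_study(cfg, registry=registry, n_reps=2000, null_seed=13)

r = res.results
cons = r[(r.metric == "consistency") & (r.channel == 1)
         & (r.dataset_id == "evaluation")]
print("within-fly consistency, evaluation flies, channel 1:")
for row in cons.itertuples():
    print(f"  {row.feature_name:20s} consistency {row.value:.2f} "
          f"(p = {row.p_value:.4f}, sig={bool(row.fdr_significant)})")

vals, _ = res.discovery_matrix.channel(1)
for thr in (0.7, 0.1):
    clusters = cluster_features(vals, threshold=thr)
    print(f"\nfeature groups at |Spearman| distance {thr} "
          "(discovery, channel 1):")
    groups: dict[int, list[str]] = {}
    for name, g in clusters["groups"].items():
        groups.setdefault(g, []).append(name)
    for g, names in sorted(groups.items()):
        print(f"  group {g}: {', '.join(names)}")
print("\nAt the loose cut every feature tracks the same condition effect; "
      "the tight cut separates the near-duplicate autocorrelation lags "
      "and the two variance measures from the rest.")
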