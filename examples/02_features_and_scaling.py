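"""Extract the feature matrix and scale it for visualization.

Runs the feature registry over a small preprocessed study, shows the
validity filtering rule (features missing or constant across all discovery
epochs at a channel are dropped), and maps one feature's values to [0, 1]
with the outlier-robust sigmoid, using discovery epochs as the scaling
reference — exactly how evaluation flies are displayed against discovery
scaling in practice.
"""

import numpy as np

from flywake import SynthConfig, generate_study
from flywake.features import extract_matrix, registry_subset, \
    robust_sigmoid_scale
from flywake.preprocess import preprocess_epochset

cfg = SynthConfig(n_flies_per_dataset={"discovery": 3, "evaluation": 2},
                  n_electrodes=5,
                  channel_effect_profile=np.array([1.0, 0.7, 0.3, 0.0]),
                  seed=7)
epochs = preprocess_epochset(generate_study(cfg))

registry = registry_subset(["AC_30", "standard_deviation", "StatAvl250",
                            "MD_rawHRVmeas_SD2", "EN_PermEn"])
fm = extract_matrix(epochs, registry, reference_datasets=["discovery"])
print(f"feature matrix: {fm.values.shape[0]} channel-epochs x "
      f"{len(fm.feature_names)} features")
print("valid features at channel 1:", fm.valid_features(1))

# sigmoid-scale AC_30 at channel 1: discovery epochs are the reference
vals, meta = fm.channel(1)
disc = (meta["dataset_id"] == "discovery").to_numpy()
scaled = robust_sigmoid_scale(vals["AC_30"].to_numpy(),
                              vals["AC_30"].to_numpy()[disc])
for cond in ("wake", "anesthesia"):
    sel = (meta["condition"] == cond).to_numpy()
    print(f"scaled AC_30, {cond:10s}: mean {scaled[sel].mean():.2f} "
          f"(discovery reference spans [0, 1])")
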