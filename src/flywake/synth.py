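"""Synthetic multi-fly, multi-dataset LFP-like epoch generator.

The generator emulates the statistical structure of tethered-fly local field
potential studies of conscious level: linear 16-electrode probes sampled at
1,000 Hz, fixed-length 2.25 s epochs, 8 epochs per fly and condition, a
condition-dependent autocorrelation timescale (wakeful signals stay
correlated with their past for ~30 ms, unconscious ones for far less) and a
condition-dependent signal variance (wake > anesthesia), per-fly baseline
offsets, dataset-level batch gain / low-pass filtering, and mains line-noise
contamination.

The signal model is a stationary first-order autoregressive (AR(1)) process
-- the discrete Ornstein-Uhlenbeck process -- which is the simplest process
with a tunable autocorrelation time constant.  Channel-level ground truth is
exact by construction: electrode ``e`` is built as a shared base process plus
the cumulative sum of per-channel AR(1) processes, so that adjacent-electrode
(bipolar) differences recover exactly the per-channel processes whose
parameters encode the condition effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt, lfilter

__all__ = ["SynthConfig", "EpochSet", "generate_epoch", "generate_study"]


def _default_flies() -> dict[str, int]:
    return {"discovery": 13, "evaluation": 12}


def _default_gain() -> dict[str, float]:
    return {"discovery": 1.0, "evaluation": 3.0}


@dataclass
class SynthConfig:
    """Generative parameters for a synthetic multi-dataset LFP study.

    Parameters
    ----------
    n_flies_per_dataset
        Mapping dataset label -> number of flies.
    n_epochs_per_condition
        Epochs per fly per condition (equal across conditions, so chance
        classification performance is exactly 50%).
    epoch_seconds, sample_rate
        Epoch length (s) and sampling rate (Hz); their product must be an
        integer sample count.
    n_electrodes
        Electrodes per probe; bipolar re-referencing yields one fewer channel.
    tau_wake, tau_unconscious
        AR(1) autocorrelation time constants in ms for the two conditions.
    sigma_wake, sigma_unconscious
        Stationary signal SD (arbitrary voltage units) for the two conditions.
    fly_offset_sd
        SD of the per-(fly, electrode) additive DC baseline.
    batch_gain
        Per-dataset multiplicative gain (dataset-level batch shift).
    batch_lowpass_hz
        Optional per-dataset low-pass cutoff (Hz), mimicking a recording
        batch inadvertently filtered in hardware.
    line_noise_hz, line_noise_amp
        Mains contamination frequency and amplitude (0 disables).
    channel_effect_profile
        Per-channel multiplier in [0, 1] on the condition effect; channel 1
        is the deepest.  ``None`` -> linear taper from 1 (channel 1) to 0
        (shallowest channel), so the shallowest channel carries no effect.
    seed
        Master seed; each fly gets an independent child stream, so adding
        flies or datasets never perturbs existing ones.
    """

    n_flies_per_dataset: dict[str, int] = field(default_factory=_default_flies)
    n_epochs_per_condition: int = 8
    epoch_seconds: float = 2.25
    sample_rate: float = 1000.0
    n_electrodes: int = 16
    wake_conditions: tuple[str, ...] = ("wake",)
    unconscious_conditions: tuple[str, ...] = ("anesthesia",)
    tau_wake: float = 30.0
    tau_unconscious: float = 8.0
    sigma_wake: float = 1.5
    sigma_unconscious: float = 1.0
    fly_offset_sd: float = 0.5
    batch_gain: dict[str, float] = field(default_factory=_default_gain)
    batch_lowpass_hz: dict[str, float] = field(default_factory=dict)
    line_noise_hz: float = 50.0
    line_noise_amp: float = 0.5
    channel_effect_profile: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for name in ("tau_wake", "tau_unconscious", "sigma_wake",
                     "sigma_unconscious", "epoch_seconds", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fly_offset_sd < 0 or self.line_noise_amp < 0:
            raise ValueError("fly_offset_sd and line_noise_amp must be >= 0")
        if self.n_electrodes < 2:
            raise ValueError("need at least 2 electrodes for bipolar channels")
        if self.n_epochs_per_condition < 1:
            raise ValueError("n_epochs_per_condition must be >= 1")
        for label, n in self.n_flies_per_dataset.items():
            if n < 1:
                raise ValueError(f"dataset {label!r} must have >= 1 fly")
        n = self.epoch_seconds * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_seconds * sample_rate must be an integer")
        prof = self.effect_profile()
        if prof.shape != (self.n_channels,):
            raise ValueError(
                f"channel_effect_profile must have length {self.n_channels}")

    # -- derived quantities ---------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sample_rate))

    @property
    def n_channels(self) -> int:
        return self.n_electrodes - 1

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.wake_conditions + self.unconscious_conditions

    def effect_profile(self) -> np.ndarray:
        if self.channel_effect_profile is None:
            return np.linspace(1.0, 0.0, self.n_channels)
        return np.asarray(self.channel_effect_profile, dtype=float)

    def condition_params(self, condition: str, channel_weight: float
                         ) -> tuple[float, float]:
        """(tau_ms, sigma) for a condition at a channel with effect weight w.

        Unconscious-like conditions always use the unconscious parameters;
        wake-like conditions interpolate between unconscious (w = 0) and wake
        (w = 1) parameters, so a zero-weight channel carries no condition
        effect at all.
        """
        if condition in self.unconscious_conditions:
            return self.tau_unconscious, self.sigma_unconscious
        if condition in self.wake_conditions:
            w = float(channel_weight)
            tau = self.tau_unconscious + w * (self.tau_wake - self.tau_unconscious)
            sigma = (self.sigma_unconscious
                     + w * (self.sigma_wake - self.sigma_unconscious))
            return tau, sigma
        raise ValueError(f"unknown condition {condition!r}")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        prof = self.channel_effect_profile
        return {
            "n_flies_per_dataset": dict(self.n_flies_per_dataset),
            "n_epochs_per_condition": self.n_epochs_per_condition,
            "epoch_seconds": self.epoch_seconds,
            "sample_rate": self.sample_rate,
            "n_electrodes": self.n_electrodes,
            "wake_conditions": list(self.wake_conditions),
            "unconscious_conditions": list(self.unconscious_conditions),
            "tau_wake": self.tau_wake,
            "tau_unconscious": self.tau_unconscious,
            "sigma_wake": self.sigma_wake,
            "sigma_unconscious": self.sigma_unconscious,
            "fly_offset_sd": self.fly_offset_sd,
            "batch_gain": dict(self.batch_gain),
            "batch_lowpass_hz": dict(self.batch_lowpass_hz),
            "line_noise_hz": self.line_noise_hz,
            "line_noise_amp": self.line_noise_amp,
            "channel_effect_profile": None if prof is None else list(map(float, prof)),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        prof = d.get("channel_effect_profile")
        if prof is not None:
            d["channel_effect_profile"] = np.asarray(prof, dtype=float)
        for key in ("wake_conditions", "unconscious_conditions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Labeled collection of fixed-length, fixed-rate signal epochs.

    ``data`` is an (n_records, n_samples) array; ``meta`` aligns row-for-row
    with columns ``dataset_id, fly_id, condition, channel, epoch``.  Before
    preprocessing, ``channel`` indexes raw electrodes (1 = deepest); after
    bipolar re-referencing it indexes the 15 bipolar channels (1 = deepest
    pair).
    """

    data: np.ndarray
    meta: pd.DataFrame
    sample_rate: float
    provenance: dict | None = None

    REQUIRED = ("dataset_id", "fly_id", "condition", "channel", "epoch")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (records x samples)")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta rows must match data rows")
        missing = [c for c in self.REQUIRED if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        counts = self.meta.groupby(
            ["dataset_id", "fly_id", "condition", "channel"], sort=False
        ).size()
        if counts.nunique() > 1:
            raise ValueError("unbalanced epoch counts across cells")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def channels(self) -> np.ndarray:
        return np.sort(self.meta["channel"].unique())

    def select(self, **conditions) -> "EpochSet":
        """Subset by equality on meta columns, e.g. ``select(channel=1)``.

        List/tuple/set values select membership.
        """
        mask = np.ones(len(self.meta), dtype=bool)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, np.ndarray)):
                mask &= self.meta[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.meta[col] == val).to_numpy()
        return EpochSet(self.data[mask],
                        self.meta.loc[mask].reset_index(drop=True),
                        self.sample_rate, self.provenance)

    # -- container IO ----------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write to an HDF5 container plus a plain-text JSON sidecar."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["sample_rate"] = self.sample_rate
            for (ds, fly, cond), idx in self.meta.groupby(
                    ["dataset_id", "fly_id", "condition"], sort=False).groups.items():
                grp = fh.require_group(f"{ds}/fly{fly}/{cond}")
                sub = self.meta.loc[idx]
                for ch, ch_idx in sub.groupby("channel").groups.items():
                    block = self.data[np.asarray(ch_idx)]
                    grp.create_dataset(f"channel{int(ch):02d}", data=block)
        sidecar = {
            "sample_rate": self.sample_rate,
            "n_records": int(self.data.shape[0]),
            "n_samples": int(self.data.shape[1]),
            "provenance": _jsonable(self.provenance),
        }
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        import h5py

        rows, blocks = [], []
        with h5py.File(path, "r") as fh:
            sample_rate = float(fh.attrs["sample_rate"])
            for ds in fh:
                for fly in fh[ds]:
                    for cond in fh[ds][fly]:
                        for ch_name, dset in fh[ds][fly][cond].items():
                            block = dset[()]
                            ch = int(ch_name.removeprefix("channel"))
                            for ep in range(block.shape[0]):
                                rows.append((ds, fly.removeprefix("fly"),
                                             cond, ch, ep))
                            blocks.append(block)
        meta = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        prov = None
        try:
            with open(str(path) + ".meta.json") as fh:
                prov = json.load(fh).get("provenance")
        except FileNotFoundError:
            pass
        return cls(np.vstack(blocks), meta, sample_rate, prov)


def _jsonable(obj):
    if obj is None:
        return None
    if isinstance(obj, SynthConfig):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def generate_epoch(tau_ms: float, sigma: float, n_samples: int,
                   sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """One stationary AR(1) epoch with autocorrelation time constant tau.

    The AR coefficient is ``phi = exp(-dt/tau)`` with ``dt = 1000/sample_rate``
    ms, and innovations are scaled so the stationary SD equals ``sigma``.
    The lag-k autocorrelation is ``phi**k``, so at 1,000 Hz a 30 ms time
    constant gives an autocorrelation of ``1/e`` at lag 30.
    """
    if tau_ms <= 0 or sigma <= 0:
        raise ValueError("tau_ms and sigma must be strictly positive")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    dt_ms = 1000.0 / sample_rate
    phi = float(np.exp(-dt_ms / tau_ms))
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    x0 = rng.normal(0.0, sigma)
    e = rng.normal(0.0, innov_sd, size=n_samples)
    # x_t = phi * x_{t-1} + e_t, seeded from the stationary distribution
    x, _ = lfilter([1.0], [1.0, -phi], e, zi=np.array([phi * x0]))
    return x


def _fly_rng(seed: int, dataset_index: int, fly_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(dataset_index), int(fly_index)]))


def generate_study(config: SynthConfig) -> EpochSet:
    """Generate the full raw-electrode study described by ``config``.

    Returns an :class:`EpochSet` of raw electrode signals (before
    preprocessing): for every dataset, fly, condition and epoch, all
    ``n_electrodes`` electrode traces.  Deterministic given the seed.
    """
    config.validate()
    T = config.n_samples
    C = config.n_channels
    fs = config.sample_rate
    profile = config.effect_profile()
    t = np.arange(T) / fs
    omega = 2.0 * np.pi * config.line_noise_hz

    blocks: list[np.ndarray] = []
    rows: list[tuple] = []
    for d_idx, (ds_label, n_flies) in enumerate(config.n_flies_per_dataset.items()):
        gain = config.batch_gain.get(ds_label, 1.0)
        lowpass = config.batch_lowpass_hz.get(ds_label)
        if lowpass is not None:
            b, a = butter(4, lowpass / (fs / 2.0), btype="low")
        for f_idx in range(n_flies):
            rng = _fly_rng(config.seed, d_idx, f_idx)
            fly_id = f"{ds_label}_fly{f_idx + 1:02d}"
            offsets = rng.normal(0.0, config.fly_offset_sd,
                                 size=config.n_electrodes)
            for condition in config.conditions:
                for epoch in range(config.n_epochs_per_condition):
                    chans = np.empty((C, T))
                    for c in range(C):
                        tau, sigma = config.condition_params(
                            condition, profile[c])
                        chans[c] = generate_epoch(tau, sigma, T, fs, rng)
                    base = generate_epoch(config.tau_unconscious,
                                          config.sigma_unconscious, T, fs, rng)
                    # electrode e = base + sum of channel processes e..C,
                    # so adjacent differences recover the channels exactly
                    electrodes = np.empty((config.n_electrodes, T))
                    electrodes[-1] = base
                    electrodes[:-1] = base + np.cumsum(chans[::-1], axis=0)[::-1]
                    if config.line_noise_amp > 0:
                        amp = config.line_noise_amp * rng.uniform(
                            0.5, 1.5, size=config.n_electrodes)
                        phase = rng.uniform(0.0, 2.0 * np.pi,
                                            size=config.n_electrodes)
                        electrodes += amp[:, None] * np.sin(
                            omega * t[None, :] + phase[:, None])
                    electrodes += offsets[:, None]
                    electrodes *= gain
                    if lowpass is not None:
                        electrodes = filtfilt(b, a, electrodes, axis=1)
                    blocks.append(electrodes)
                    rows.extend(
                        (ds_label, fly_id, condition, e + 1, epoch)
                        for e in range(config.n_electrodes))

    meta = pd.DataFrame(rows, columns=list(EpochSet.REQUIRED))
    provenance = {
        "config": config,
        "expected_direction": {
            "autocorrelation": 1 if config.tau_wake > config.tau_unconscious else -1,
            "variance": 1 if config.sigma_wake > config.sigma_unconscious else -1,
        },
        "channel_effect_profile": profile,
    }
    return EpochSet(np.vstack(blocks), meta, fs, provenance)
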