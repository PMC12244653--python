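"""LFP preprocessing: bipolar re-referencing, epoching, mean subtraction,
and multitaper line-noise removal.

The stages mirror standard fly-LFP practice: adjacent electrodes are
subtracted to yield localized bipolar channels (16 electrodes -> 15
channels, channel 1 = deepest pair), continuous signals are cut into
consecutive non-overlapping fixed-length epochs (2.25 s), each epoch has its
mean voltage subtracted, and mains line noise is removed per epoch with a
Thomson multitaper harmonic regression (DPSS tapers; defaults: 9 tapers,
time-bandwidth product 5) that estimates and subtracts the complex sinusoid
amplitude at the line frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import welch
from scipy.signal.windows import dpss

from .synth import EpochSet

__all__ = [
    "PreprocessParams",
    "bipolar_rereference",
    "segment_epochs",
    "subtract_epoch_mean",
    "remove_line_noise",
    "preprocess_epochset",
    "line_power_db",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Epoching and line-removal parameters.

    ``n_tapers``/``time_bandwidth``/``pad_factor`` parameterize the
    multitaper harmonic regression used for line-noise removal.
    """

    epoch_seconds: float = 2.25
    n_tapers: int = 9
    time_bandwidth: float = 5.0
    pad_factor: int = 2
    line_freq: float = 50.0
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be > 0")
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")
        if self.time_bandwidth <= 0:
            raise ValueError("time_bandwidth must be > 0")


def bipolar_rereference(electrode_signals: np.ndarray) -> np.ndarray:
    """Subtract adjacent electrodes: row i of the output is electrode i
    minus electrode i+1 (deeper minus shallower; rows ordered by depth).

    An (E, T) array yields an (E-1, T) array; output channel 1 is the
    deepest pair.
    """
    x = np.asarray(electrode_signals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 electrode rows")
    return x[:-1] - x[1:]


def segment_epochs(signal: np.ndarray, sample_rate: float,
                   epoch_seconds: float, discard_tail: bool = True
                   ) -> list[np.ndarray]:
    """Cut a 1-D signal into consecutive non-overlapping epochs.

    Epochs start at sample 0; any remainder shorter than one epoch is
    discarded (18 s at 1,000 Hz with 2.25 s epochs -> 8 epochs; 20 s -> 8
    epochs with the final 2 s dropped).
    """
    x = np.asarray(signal, dtype=float)
    n_epoch = int(round(epoch_seconds * sample_rate))
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < n_epoch:
        raise ValueError("signal shorter than one epoch")
    n_full = x.size // n_epoch
    if not discard_tail and x.size % n_epoch:
        raise ValueError("signal length is not a whole number of epochs")
    return [x[i * n_epoch:(i + 1) * n_epoch].copy() for i in range(n_full)]


def subtract_epoch_mean(epoch: np.ndarray) -> np.ndarray:
    """Remove the sample mean (output mean is 0 to machine precision)."""
    x = np.asarray(epoch, dtype=float)
    return x - x.mean(axis=-1, keepdims=True)


@lru_cache(maxsize=8)
def _line_projector(n_samples: int, sample_rate: float, line_freq: float,
                    n_tapers: int, time_bandwidth: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the multitaper regression vector for a line frequency.

    For x(t) = Re(c * exp(i*w*t)) the tapered eigencoefficient
    J_k = sum_t h_k(t) x(t) exp(-i*w*t) has expectation (c/2) * U_k(0) with
    U_k(0) = sum_t h_k(t) (only even-order tapers contribute).  The
    least-squares amplitude estimate over tapers is
    c_hat = 2 * sum_k U_k J_k / sum_k U_k^2, which is linear in x; the
    returned vector m gives c_hat = x @ m.
    """
    k = min(n_tapers, max(1, int(2 * time_bandwidth) - 1))
    tapers = np.atleast_2d(dpss(n_samples, time_bandwidth, Kmax=k))
    t = np.arange(n_samples)
    carrier = np.exp(-2j * np.pi * line_freq * t / sample_rate)
    u0 = tapers.sum(axis=1)                       # U_k(0)
    m = 2.0 * (u0[:, None] * (tapers * carrier[None, :])).sum(axis=0)
    m /= (u0 ** 2).sum()
    return m, np.conj(carrier)                    # exp(+i*w*t)


def remove_line_noise(epoch: np.ndarray, params: PreprocessParams
                      ) -> np.ndarray:
    """Subtract the estimated line-frequency sinusoid from an epoch.

    The epoch mean is subtracted first (idempotent on zero-mean input).
    Accepts a 1-D epoch or a 2-D (records x samples) stack.  Raises if the
    line frequency is at or above Nyquist.
    """
    if params.line_freq >= params.sample_rate / 2.0:
        raise ValueError("line_freq must be below Nyquist")
    x = subtract_epoch_mean(np.asarray(epoch, dtype=float))
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    m, carrier = _line_projector(x.shape[1], params.sample_rate,
                                 params.line_freq, params.n_tapers,
                                 params.time_bandwidth)
    c_hat = x @ m
    cleaned = x - np.real(c_hat[:, None] * carrier[None, :])
    return cleaned[0] if squeeze else cleaned


def line_power_db(epoch: np.ndarray, params: PreprocessParams,
                  half_bandwidth_hz: float = 2.0) -> float:
    """Welch PSD power (dB) in a narrow band around the line frequency.

    Used as the quantitative stand-in for a visual power-spectrum check:
    the difference before vs after cleaning gives the attenuation.
    """
    x = np.asarray(epoch, dtype=float)
    f, p = welch(x, fs=params.sample_rate, window="hann",
                 nperseg=min(x.size, 1024))
    band = np.abs(f - params.line_freq) <= half_bandwidth_hz
    return 10.0 * np.log10(p[band].mean())


def line_qc_ok(epoch: np.ndarray, params: PreprocessParams,
               tolerance_db: float = 6.0) -> bool:
    """Post-cleaning quality check on one epoch.

    The PSD at the line frequency must sit within ``tolerance_db`` of the
    median PSD of the neighboring frequencies (5-15 Hz away).
    """
    x = np.asarray(epoch, dtype=float)
    f, p = welch(x, fs=params.sample_rate, window="hann",
                 nperseg=min(x.size, 1024))
    at_line = p[np.abs(f - params.line_freq) <= 2.0].mean()
    dist = np.abs(f - params.line_freq)
    neighbors = p[(dist > 5.0) & (dist <= 15.0)]
    return 10.0 * np.log10(at_line / np.median(neighbors)) <= tolerance_db


def preprocess_epochset(raw: EpochSet, params: PreprocessParams | None = None
                        ) -> EpochSet:
    """Full pipeline on a raw-electrode EpochSet.

    For each (dataset, fly, condition, epoch): bipolar re-reference the
    electrode stack, subtract each channel-epoch's mean, and remove line
    noise.  Epoch count and length are preserved; all outputs are zero-mean.
    """
    params = params or PreprocessParams(sample_rate=raw.sample_rate)
    groups = raw.meta.groupby(["dataset_id", "fly_id", "condition", "epoch"],
                              sort=False)
    blocks, rows = [], []
    for (ds, fly, cond, ep), idx in groups.indices.items():
        sub = raw.meta.iloc[idx]
        order = np.argsort(sub["channel"].to_numpy(), kind="stable")
        electrodes = raw.data[idx[order]]
        channels = bipolar_rereference(electrodes)
        blocks.append(channels)
        rows.extend((ds, fly, cond, c + 1, ep)
                    for c in range(channels.shape[0]))
    data = np.vstack(blocks)
    # mean subtraction happens inside remove_line_noise; the removed
    # sinusoid spans a non-integer cycle count, so re-center afterwards to
    # keep the zero-mean output contract exact
    data = subtract_epoch_mean(remove_line_noise(data, params))
    meta = pd.DataFrame(rows, columns=list(EpochSet.REQUIRED))
    return EpochSet(data, meta, raw.sample_rate, raw.provenance)
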