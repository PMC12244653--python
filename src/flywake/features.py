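"""Registry of named univariate time-series features, matrix extraction,
validity filtering, and outlier-robust sigmoidal scaling.

The registry covers the feature families that matter for discriminating
wakefulness from anesthesia/sleep in fly LFP epochs: autocorrelation at
fixed lags (AC_k, k samples = k ms at 1,000 Hz), mean-stationarity
(StatAvl250), distribution statistics (rms, standard deviation, higher
standardized moments), Poincare-plot variabilities (SD1/SD2), Welch/FFT
spectral band powers and spectral edge frequencies, entropy and complexity
measures (sample, approximate and permutation entropy, LZ76 complexity),
local-extrema statistics in short windows, and a box-counting correlation
dimension on a delay embedding.

Feature names keep the identifiers common in the highly-comparative
time-series literature (e.g. ``AC_30``, ``StatAvl250``,
``MD_rawHRVmeas_SD2``) for traceability; each is defined by the explicit
formula implemented here, with no attempt at bit-equivalence with any
external toolbox.  Conventions used throughout: sample SD uses the N-1
denominator; the autocorrelation estimator uses the biased normalization
(denominator N); a feature that is undefined on its input returns NaN
rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import periodogram, welch
from scipy.spatial.distance import pdist

from .synth import EpochSet

__all__ = [
    "FeatureDef",
    "FeatureMatrix",
    "ac_lag",
    "statav_local",
    "distribution_stats",
    "poincare_sd",
    "spectral_summaries",
    "sample_entropy",
    "approx_entropy",
    "perm_entropy",
    "lz_complexity",
    "local_extrema_stats",
    "box_corr_dim",
    "default_registry",
    "fast_registry",
    "registry_subset",
    "extract_matrix",
    "compute_validity",
    "robust_sigmoid_scale",
]


# ---------------------------------------------------------------------------
# elementary features
# ---------------------------------------------------------------------------

def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def ac_lag(x: np.ndarray, k: int) -> float:
    """Autocorrelation at lag ``k`` samples, biased normalization:

    r_k = sum_{t=1}^{N-k} (x_t - xbar)(x_{t+k} - xbar) / sum (x_t - xbar)^2.

    Constant input (zero denominator) returns NaN.  k = 0 returns 1.
    """
    x = np.asarray(x, dtype=float)
    if k < 0 or k >= x.size:
        raise ValueError("require 0 <= k < len(x)")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        return math.nan
    if k == 0:
        return 1.0
    return float(d[:-k] @ d[k:]) / denom


def statav_local(x: np.ndarray, window_len: int = 250) -> float:
    """StatAv mean-stationarity index.

    SD of the means of the floor(N/window_len) non-overlapping windows,
    divided by the SD of the whole series.  Low values indicate a
    stationary mean; NaN on constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * window_len:
        raise ValueError("need at least two full windows")
    sd_all = _sd(x)
    if sd_all == 0.0:
        return math.nan
    n_win = x.size // window_len
    means = x[: n_win * window_len].reshape(n_win, window_len).mean(axis=1)
    return _sd(means) / sd_all


def distribution_stats(x: np.ndarray) -> dict[str, float]:
    """rms, sample SD, and standardized central moments of order 3..5.

    ``moment_4`` is plain (un-excess) kurtosis, so Gaussian input gives 3.
    """
    x = np.asarray(x, dtype=float)
    out = {"rms": float(np.sqrt(np.mean(x * x))), "standard_deviation": _sd(x)}
    sd = out["standard_deviation"]
    d = x - x.mean()
    for k in (3, 4, 5):
        out[f"moment_{k}"] = (float(np.mean(d ** k)) / sd ** k
                              if sd > 0 else math.nan)
    return out


def poincare_sd(x: np.ndarray) -> dict[str, float]:
    """Poincare-plot variabilities from consecutive sample pairs.

    sd1 = SD((x_{t+1} - x_t)/sqrt(2)) measures variability between
    consecutive samples (across the identity line); sd2 uses the sum and
    measures variability along it.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    diff = (x[1:] - x[:-1]) / math.sqrt(2.0)
    summ = (x[1:] + x[:-1]) / math.sqrt(2.0)
    return {"sd1": _sd(diff), "sd2": _sd(summ)}


def _psd(x: np.ndarray, sample_rate: float, window: str
         ) -> tuple[np.ndarray, np.ndarray]:
    if window == "welch-rect":
        nperseg = min(x.size, 1024)
        return welch(x, fs=sample_rate, window="boxcar", nperseg=nperseg,
                     noverlap=nperseg // 2)
    if window == "rect":
        return periodogram(x, fs=sample_rate, window="boxcar")
    raise ValueError(f"unknown spectral window {window!r}")


def spectral_summaries(x: np.ndarray, sample_rate: float,
                       window: str = "welch-rect", n_bands: int = 2,
                       edge_percents: tuple[float, ...] = (5, 10, 25, 95),
                       ) -> dict[str, float]:
    """Band powers and spectral edge frequencies from the PSD.

    ``band_area_i_of_n`` integrates the PSD over the i-th of ``n_bands``
    equal divisions of [0, Nyquist]; ``log_band_area`` is its natural log;
    ``edge_freq_P`` is the lowest frequency at which the cumulative PSD
    reaches P% of the total.  A zero-power signal yields NaN for log and
    edge outputs.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 samples")
    f, p = _psd(x, sample_rate, window)
    df = f[1] - f[0]
    total = float(p.sum() * df)
    out: dict[str, float] = {}
    nyq = sample_rate / 2.0
    edges = np.linspace(0.0, nyq, n_bands + 1)
    for i in range(n_bands):
        sel = (f >= edges[i]) & (f < edges[i + 1] if i < n_bands - 1
                                 else f <= edges[i + 1])
        area = float(p[sel].sum() * df)
        out[f"band_area_{i + 1}_of_{n_bands}"] = area
        out[f"log_band_area_{i + 1}_of_{n_bands}"] = (
            math.log(area) if area > 0 else math.nan)
    cum = np.cumsum(p) * df
    for pc in edge_percents:
        if total > 0:
            idx = int(np.searchsorted(cum, pc / 100.0 * total))
            out[f"edge_freq_{pc:g}"] = float(f[min(idx, f.size - 1)])
        else:
            out[f"edge_freq_{pc:g}"] = math.nan
    return out


# -- entropy / complexity ---------------------------------------------------

def _phi_counts(x: np.ndarray, m: int, r: float, exclude_self: bool
                ) -> np.ndarray:
    """Per-template counts of m-length templates within Chebyshev radius r."""
    n = x.size - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    # pairwise Chebyshev distances, vectorized over one axis
    counts = np.empty(n)
    for i in range(n):
        d = np.max(np.abs(emb - emb[i]), axis=1)
        c = np.count_nonzero(d <= r)
        counts[i] = c - 1 if exclude_self else c
    return counts


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with A (B) the number of matching template
    pairs of length m+1 (m) within Chebyshev tolerance r, self-matches
    excluded.  Default r = 0.2 * SD(x).  NaN on constant input or when no
    templates match.
    """
    x = np.asarray(x, dtype=float)
    sd = _sd(x)
    if sd == 0.0:
        return math.nan
    r = 0.2 * sd if r is None else r
    b = _phi_counts(x[: x.size - 1], m, r, exclude_self=True).sum()
    a = _phi_counts(x, m + 1, r, exclude_self=True).sum()
    if a == 0 or b == 0:
        return math.nan
    return float(-math.log(a / b))


def approx_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy: phi_m - phi_{m+1} with
    phi_m = mean_i ln(C_i^m(r)), self-matches included."""
    x = np.asarray(x, dtype=float)
    sd = _sd(x)
    if sd == 0.0:
        return math.nan
    r = 0.2 * sd if r is None else r

    def phi(m_: int) -> float:
        c = _phi_counts(x, m_, r, exclude_self=False)
        n = x.size - m_ + 1
        return float(np.mean(np.log(c / n)))

    return phi(m) - phi(m + 1)


def perm_entropy(x: np.ndarray, order: int = 3, delay: int = 1,
                 normalized: bool = True) -> float:
    """Permutation entropy over ordinal patterns of the given order.

    Shannon entropy (bits) of the distribution of argsort patterns of
    overlapping windows; normalized by log2(order!) when requested.
    Constant input yields 0 by convention (a single ordinal pattern).
    """
    x = np.asarray(x, dtype=float)
    n = x.size - (order - 1) * delay
    if n < 1:
        raise ValueError("series too short for this order/delay")
    idx = np.arange(n)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    radix = order ** np.arange(order)
    codes = patterns @ radix
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    if normalized:
        h /= math.log2(math.factorial(order))
    return h


def lz_complexity(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv (LZ76) complexity of the median-binarized series.

    The series is binarized above/below its median, the number of LZ76
    phrases c is counted, and c * log2(N) / N is returned, which tends to 1
    for an i.i.d. fair-coin sequence and to 0 for periodic sequences.
    Constant input yields 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    n = len(s)
    if n < 2:
        raise ValueError("series too short")
    # Kaspar-Schuster phrase counting via substring search
    c, i, k = 1, 0, 1
    while i + k < n:
        if s.find(s[i:i + k + 1], 0, i + k) == -1:
            c += 1
            i += k + 1
            k = 1
        else:
            k += 1
    return c * math.log2(n) / n


def local_extrema_stats(x: np.ndarray, window_len: int = 50
                        ) -> dict[str, float]:
    """SD and mean of per-window maxima/minima in non-overlapping windows."""
    x = np.asarray(x, dtype=float)
    n_win = x.size // window_len
    if n_win < 2:
        raise ValueError("need at least two full windows")
    w = x[: n_win * window_len].reshape(n_win, window_len)
    maxima, minima = w.max(axis=1), w.min(axis=1)
    return {
        "stdmax": _sd(maxima), "stdmin": _sd(minima),
        "meanmax": float(maxima.mean()), "meanmin": float(minima.mean()),
        "meanrange": float((maxima - minima).mean()),
    }


def first_zero_ac(x: np.ndarray, max_lag: int | None = None) -> int | None:
    """Smallest lag k >= 1 with autocorrelation <= 0, or None within N/2."""
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        return None
    max_lag = x.size // 2 if max_lag is None else max_lag
    # full ACF via FFT, then scan
    nfft = int(2 ** np.ceil(np.log2(2 * x.size)))
    acf = np.fft.irfft(np.abs(np.fft.rfft(d, nfft)) ** 2)[: max_lag + 1] / denom
    hits = np.nonzero(acf[1:] <= 0.0)[0]
    return int(hits[0]) + 1 if hits.size else None


def box_corr_dim(x: np.ndarray, n_scales: int = 50, embed_dim: int = 5,
                 delay: int | None = None, report_scale_index: int = 13,
                 max_points: int = 1000) -> float:
    """Correlation-dimension estimate from a time-delay embedding.

    The delay defaults to the first zero-crossing of the autocorrelation
    function.  The series is embedded in ``embed_dim`` dimensions, the
    correlation sum C(r) is evaluated at ``n_scales`` logarithmically spaced
    radii spanning the pairwise-distance range, local slopes of
    log C vs log r are taken as scale-dependent dimension estimates, and the
    estimate at the (1-based) ``report_scale_index`` is returned.  At most
    ``max_points`` embedded points are used (strided subsampling) to bound
    the pairwise-distance cost.  NaN when the ACF never reaches zero within
    N/2 lags or the embedding is degenerate.
    """
    x = np.asarray(x, dtype=float)
    auto_delay = delay is None
    if auto_delay:
        delay = first_zero_ac(x)
        if delay is None:
            return math.nan
    n_pts = x.size - (embed_dim - 1) * delay
    if n_pts < 100:
        if auto_delay:       # ACF decays so slowly the embedding degenerates
            return math.nan
        raise ValueError("series too short for this embedding")
    idx = np.arange(n_pts)[:, None] + np.arange(embed_dim)[None, :] * delay
    emb = x[idx]
    if n_pts > max_points:
        emb = emb[:: int(np.ceil(n_pts / max_points))]
    d = pdist(emb)
    d = d[d > 0]
    if d.size == 0:
        return math.nan
    radii = np.logspace(np.log10(d.min()), np.log10(d.max()), n_scales)
    log_c = np.log(np.searchsorted(np.sort(d), radii, side="right")
                   .clip(min=1) / d.size)
    log_r = np.log(radii)
    # local slope by least squares over a +-2 scale window; two-point
    # gradients are too jumpy at small radii where C(r) is a step function
    slopes = np.empty(n_scales)
    for i in range(n_scales):
        lo, hi = max(0, i - 2), min(n_scales, i + 3)
        slopes[i] = np.polyfit(log_r[lo:hi], log_c[lo:hi], 1)[0]
    return float(slopes[report_scale_index - 1])


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    """A named scalar feature of a real-valued series.

    ``compute`` maps (values, sample_rate) -> float and may return NaN or
    +/-inf; it must be deterministic.
    """

    name: str
    family: str
    compute: Callable[[np.ndarray, float], float]
    params: dict = field(default_factory=dict)


def _spectral_feature(key: str, window: str, n_bands: int):
    def f(x: np.ndarray, fs: float) -> float:
        return spectral_summaries(x, fs, window=window, n_bands=n_bands)[key]
    return f


def default_registry() -> list[FeatureDef]:
    """The full built-in registry (one entry per named feature)."""
    defs: list[FeatureDef] = []
    for k in range(29, 35):
        defs.append(FeatureDef(
            f"AC_{k}", "correlation",
            (lambda x, fs, k=k: ac_lag(x, k)), {"lag": k}))
    defs.append(FeatureDef("StatAvl250", "stationarity",
                           lambda x, fs: statav_local(x, 250),
                           {"window_len": 250}))
    defs.append(FeatureDef("rms", "distribution",
                           lambda x, fs: distribution_stats(x)["rms"]))
    defs.append(FeatureDef(
        "standard_deviation", "distribution",
        lambda x, fs: distribution_stats(x)["standard_deviation"]))
    for k in (3, 4, 5):
        defs.append(FeatureDef(
            f"DN_Moments_raw_{k}", "distribution",
            (lambda x, fs, k=k: distribution_stats(x)[f"moment_{k}"]),
            {"order": k}))
    defs.append(FeatureDef("MD_rawHRVmeas_SD1", "distribution",
                           lambda x, fs: poincare_sd(x)["sd1"]))
    defs.append(FeatureDef("MD_rawHRVmeas_SD2", "distribution",
                           lambda x, fs: poincare_sd(x)["sd2"]))
    defs.append(FeatureDef(
        "SP_Summaries_welch_rect_logarea_2_1", "spectral",
        _spectral_feature("log_band_area_1_of_2", "welch-rect", 2),
        {"n_bands": 2, "band": 1}))
    defs.append(FeatureDef(
        "SP_Summaries_fft_area_5_1", "spectral",
        _spectral_feature("band_area_1_of_5", "rect", 5),
        {"n_bands": 5, "band": 1}))
    for pc in (5, 10, 25, 95):
        defs.append(FeatureDef(
            f"SP_Summaries_welch_wmax_{pc}", "spectral",
            (lambda x, fs, pc=pc:
             spectral_summaries(x, fs, window="welch-rect")[f"edge_freq_{pc}"]),
            {"percent": pc}))
    defs.append(FeatureDef("EN_SampEn", "entropy",
                           lambda x, fs: sample_entropy(x),
                           {"m": 2, "r": "0.2*SD"}))
    defs.append(FeatureDef("ApEn", "entropy",
                           lambda x, fs: approx_entropy(x),
                           {"m": 2, "r": "0.2*SD"}))
    defs.append(FeatureDef("EN_PermEn", "entropy",
                           lambda x, fs: perm_entropy(x),
                           {"order": 3, "delay": 1}))
    defs.append(FeatureDef("EN_MS_LZcomplexity", "entropy",
                           lambda x, fs: lz_complexity(x)))
    defs.append(FeatureDef("ST_LocalExtrema_n50_stdmax", "extrema",
                           lambda x, fs: local_extrema_stats(x, 50)["stdmax"],
                           {"window_len": 50}))
    defs.append(FeatureDef("ST_LocalExtrema_n50_stdmin", "extrema",
                           lambda x, fs: local_extrema_stats(x, 50)["stdmin"],
                           {"window_len": 50}))
    defs.append(FeatureDef(
        "NL_BoxCorrDim_50_ac_5_minr13", "nonlinear",
        lambda x, fs: box_corr_dim(x),
        {"n_scales": 50, "embed_dim": 5, "scale_index": 13}))
    names = [d.name for d in defs]
    assert len(names) == len(set(names)), "duplicate feature names"
    return defs


FAST_FAMILIES = ("correlation", "stationarity", "distribution", "spectral",
                 "extrema")


def fast_registry() -> list[FeatureDef]:
    """Registry subset cheap enough for study-scale extraction, plus the
    (vectorized, fast) permutation entropy."""
    return [d for d in default_registry()
            if d.family in FAST_FAMILIES or d.name == "EN_PermEn"]


def registry_subset(names: list[str]) -> list[FeatureDef]:
    by_name = {d.name: d for d in default_registry()}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise KeyError(f"unknown features: {missing}")
    return [by_name[n] for n in names]


# ---------------------------------------------------------------------------
# matrix extraction, validity, scaling
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Epochs x features table with per-row metadata and a per-(feature,
    channel) validity mask.

    ``values``: DataFrame, one row per channel-epoch, one column per
    feature (NaN/+-inf allowed, never silently replaced).
    ``meta``: aligned DataFrame with dataset_id / fly_id / condition /
    channel / epoch columns.
    ``validity``: DataFrame indexed by channel with one boolean column per
    feature; a feature is invalid at a channel when it is NaN for all
    reference (discovery) epochs or constant across all of them.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    validity: pd.DataFrame

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def channel(self, ch: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        mask = (self.meta["channel"] == ch).to_numpy()
        return self.values.loc[mask], self.meta.loc[mask]

    def valid_features(self, ch: int) -> list[str]:
        row = self.validity.loc[ch]
        return [name for name in self.values.columns if row[name]]

    def to_csv(self, path) -> None:
        pd.concat([self.meta.reset_index(drop=True),
                   self.values.reset_index(drop=True)], axis=1).to_csv(
            path, index=False)


def compute_validity(values: pd.DataFrame, meta: pd.DataFrame,
                     reference_mask: np.ndarray | None = None
                     ) -> pd.DataFrame:
    """Per-(feature, channel) validity from the reference (discovery) rows.

    Invalid when the feature is NaN for every reference epoch at that
    channel, or constant across all of them.
    """
    if reference_mask is None:
        reference_mask = np.ones(len(meta), dtype=bool)
    rows = {}
    channels = np.sort(meta["channel"].unique())
    for ch in channels:
        sel = reference_mask & (meta["channel"] == ch).to_numpy()
        block = values.loc[sel]
        ok = {}
        for name in values.columns:
            col = block[name].to_numpy()
            finite_or_inf = col[~np.isnan(col)]
            if finite_or_inf.size == 0:
                ok[name] = False
            elif np.all(finite_or_inf == finite_or_inf[0]) and \
                    np.isnan(col).sum() == 0 and np.unique(col).size == 1:
                ok[name] = False
            else:
                ok[name] = True
        rows[ch] = ok
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "channel"
    return out


def extract_matrix(epochs: EpochSet, registry: list[FeatureDef],
                   reference_datasets: list[str] | None = None
                   ) -> FeatureMatrix:
    """Compute every registry feature for every channel-epoch.

    NaN and +-inf outputs are propagated as-is.  The validity mask is
    computed from the ``reference_datasets`` rows only (default: all rows),
    matching the rule that feature filtering is decided on discovery data.
    """
    names = [d.name for d in registry]
    if len(names) != len(set(names)):
        raise ValueError("registry feature names must be unique")
    out = np.empty((epochs.data.shape[0], len(registry)))
    for j, fdef in enumerate(registry):
        for i in range(epochs.data.shape[0]):
            try:
                out[i, j] = fdef.compute(epochs.data[i], epochs.sample_rate)
            except (ValueError, FloatingPointError, ZeroDivisionError):
                out[i, j] = math.nan
    values = pd.DataFrame(out, columns=names)
    meta = epochs.meta.reset_index(drop=True)
    if reference_datasets is None:
        ref_mask = np.ones(len(meta), dtype=bool)
    else:
        ref_mask = meta["dataset_id"].isin(reference_datasets).to_numpy()
    validity = compute_validity(values, meta, ref_mask)
    return FeatureMatrix(values, meta, validity)


def robust_sigmoid_scale(values: np.ndarray, reference: np.ndarray
                         ) -> np.ndarray:
    """Outlier-robust sigmoidal transform of ``values`` to [0, 1].

    Using the median m and interquartile range q of the *reference* vector:
    s(v) = 1 / (1 + exp(-(v - m) / (1.35 q))), then min-max rescaled by the
    reference's transformed range so the reference spans [0, 1] exactly.
    Evaluation data is scaled with discovery reference parameters.  q = 0
    yields all-NaN output (flagged by the caller via validity).
    """
    v = np.asarray(values, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ref_finite = ref[np.isfinite(ref)]
    if ref_finite.size == 0:
        return np.full_like(v, math.nan)
    m = float(np.median(ref_finite))
    q = float(np.subtract(*np.percentile(ref_finite, [75, 25])))
    if q == 0.0:
        return np.full_like(v, math.nan)

    def sig(a: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(a - m) / (1.35 * q)))

    s = sig(v)
    s_ref = sig(ref_finite)
    lo, hi = float(s_ref.min()), float(s_ref.max())
    if hi == lo:
        return np.full_like(v, math.nan)
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)
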