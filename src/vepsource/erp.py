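"""ERP averaging, first-peak latency statistics, VEP time-frequency and power
topography, and the accuracy-vs-power spatial correlation.

Latency is defined on the squared amplitude of a waveform: the first local
maximum inside the search window whose height reaches 3x the baseline-window
standard deviation of the squared amplitude.  Quartiles use linear
interpolation between order statistics.  Spectral power is 0-30 Hz band
power of the color-averaged ERP in the 0-400 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import CorrelationUndefinedError, PeakNotFoundError
from .preprocess import EpochSet


@dataclass(frozen=True)
class LatencySample:
    subject: int
    color: str
    channel_code: int
    latency_ms: float


@dataclass(frozen=True)
class LatencyStats:
    """Quartile summary of one color's latency samples.

    ``upper_quartile_ms`` is the 75th percentile and ``lower_quartile_ms``
    the 25th (some reports label these Q1 and Q3 respectively).
    """

    color: str
    latencies: tuple[float, ...]
    upper_quartile_ms: float
    median_ms: float
    lower_quartile_ms: float
    mean_ms: float
    iqr_whisker: float = 1.5


@dataclass
class PowerMap:
    """Per-channel mean 0-30 Hz VEP power (uV^2) of the averaged ERP."""

    power: np.ndarray             # (59,)
    subject: int = 0
    pair: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if np.any(p < -1e-12):
            raise ValueError("power entries must be non-negative")
        self.power = np.clip(p, 0.0, None)


def average_erp(epochs: EpochSet, color: str, channel_code: int
                ) -> np.ndarray:
    """Pointwise mean over one color's epochs for one channel."""
    mask = epochs.labels == color
    if not mask.any():
        raise ValueError(f"no epochs with color {color!r}")
    return epochs.data[mask, channel_code - 1, :].mean(axis=0)


def first_peak_latency(waveform: np.ndarray, fs: float,
                       search_ms: tuple[float, float] = (0.0, 500.0),
                       t_start_ms: float = -200.0,
                       threshold_factor: float = 3.0,
                       rel_threshold: float = 0.2) -> float:
    """Latency (ms after onset) of the first qualifying power peak.

    Works on the squared amplitude.  A peak qualifies if it is a local
    maximum within the search window, at least ``threshold_factor`` times the
    baseline-window standard deviation of the squared amplitude, and at least
    ``rel_threshold`` of the in-window maximum (so minor pre-component lobes
    and residual noise ripples are not mistaken for the first component).
    """
    w = np.asarray(waveform, dtype=float)
    sq = w ** 2
    onset = int(round(-t_start_ms / 1000.0 * fs))
    i0 = onset + int(round(search_ms[0] / 1000.0 * fs))
    i1 = onset + int(round(search_ms[1] / 1000.0 * fs))
    if i0 < 0 or i1 > sq.size or i1 <= i0:
        raise ValueError("search window outside the waveform")
    baseline_sd = float(sq[:onset].std()) if onset > 0 else 0.0
    seg = sq[i0:i1]
    threshold = max(threshold_factor * baseline_sd,
                    rel_threshold * float(seg.max()), 0.0)
    peaks, _ = sps.find_peaks(seg)
    # an interior global maximum with no left neighbor dip still counts
    for idx in peaks:
        if seg[idx] >= threshold and seg[idx] > 0.0:
            return (i0 + idx - onset) / fs * 1000.0
    raise PeakNotFoundError("no qualifying peak in the search window")


def latency_statistics(color: str, latencies_ms: list[float] | np.ndarray
                       ) -> LatencyStats:
    """Quartiles (linear interpolation), mean, and box bounds for one color."""
    lat = np.asarray(latencies_ms, dtype=float)
    if lat.size == 0:
        raise ValueError("need at least one latency sample")
    q25, q50, q75 = np.percentile(lat, [25, 50, 75])
    return LatencyStats(color=color, latencies=tuple(float(v) for v in lat),
                        upper_quartile_ms=float(q75), median_ms=float(q50),
                        lower_quartile_ms=float(q25),
                        mean_ms=float(lat.mean()))


def collect_latencies(epochs: EpochSet, channel_codes: list[int],
                      colors: tuple[str, ...] | None = None,
                      search_ms: tuple[float, float] = (0.0, 500.0)
                      ) -> list[LatencySample]:
    """First-peak latencies of the color-averaged ERP on each channel.

    Channels whose average shows no qualifying peak are skipped.
    """
    out: list[LatencySample] = []
    colors = colors if colors is not None else tuple(
        np.unique(epochs.labels))
    for color in colors:
        for code in channel_codes:
            wave = average_erp(epochs, color, code)
            try:
                lat = first_peak_latency(wave, epochs.fs, search_ms,
                                         epochs.t_start_ms)
            except PeakNotFoundError:
                continue
            out.append(LatencySample(subject=epochs.subject, color=color,
                                     channel_code=code, latency_ms=lat))
    return out


def time_frequency(epochs: EpochSet, channel_code: int,
                   window_ms: float = 250.0, overlap: float = 0.8,
                   fmax: float = 30.0
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time FFT power of the epoch-averaged signal on one channel.

    Hann window of ``window_ms`` with ``overlap`` fractional overlap, zero
    padded 4x for a fine frequency grid; bins above ``fmax`` are discarded.
    Returns (frequencies Hz, times ms relative to onset, power t x f).
    """
    wave = epochs.data[:, channel_code - 1, :].mean(axis=0)
    nperseg = int(round(window_ms / 1000.0 * epochs.fs))
    noverlap = int(round(overlap * nperseg))
    f, t, Z = sps.stft(wave, fs=epochs.fs, window="hann", nperseg=nperseg,
                       noverlap=noverlap, nfft=4 * nperseg, boundary=None,
                       padded=False)
    power = (np.abs(Z) ** 2).T          # time x frequency
    keep = f <= fmax
    times_ms = epochs.t_start_ms + t * 1000.0
    return f[keep], times_ms, power[:, keep]


def band_power(wave: np.ndarray, fs: float, fmax: float = 30.0) -> float:
    """Mean spectral power of a short segment in the [0, fmax] band."""
    f, p = sps.periodogram(wave, fs=fs, detrend=False)
    keep = f <= fmax
    return float(p[keep].mean())


def vep_power_map(epochs: EpochSet,
                  window_ms: tuple[float, float] = (0.0, 400.0),
                  fmax: float = 30.0) -> PowerMap:
    """Per channel: mean 0-``fmax`` Hz power of the color-averaged ERP in the
    analysis window, averaged over the pair's colors."""
    fs = epochs.fs
    i0 = epochs.onset_index + int(round(window_ms[0] / 1000.0 * fs))
    i1 = epochs.onset_index + int(round(window_ms[1] / 1000.0 * fs))
    if i0 < 0 or i1 > epochs.data.shape[2] or i1 <= i0:
        raise ValueError("analysis window outside the epoch")
    colors = np.unique(epochs.labels)
    power = np.zeros(epochs.n_channels)
    for color in colors:
        mean = epochs.data[epochs.labels == color].mean(axis=0)  # ch x t
        for ch in range(epochs.n_channels):
            power[ch] += band_power(mean[ch, i0:i1], fs, fmax)
    power /= colors.size
    return PowerMap(power=power, subject=epochs.subject, pair=epochs.team)


def spatial_correlation(accuracy_row: np.ndarray, power_map: PowerMap,
                        method: str = "pearson") -> tuple[float, float]:
    """Correlation across the 59 channels between decoding accuracy and VEP
    power.  ``method`` is "pearson" (product-moment) or "spearman"."""
    acc = np.asarray(accuracy_row, dtype=float).ravel()
    pw = power_map.power
    if acc.shape != pw.shape:
        raise ValueError("accuracy row and power map must share channels")
    keep = np.isfinite(acc) & np.isfinite(pw)
    acc, pw = acc[keep], pw[keep]
    if np.ptp(acc) == 0 or np.ptp(pw) == 0:
        raise CorrelationUndefinedError(
            "zero variance in accuracy or power values")
    if method == "pearson":
        r, p = stats.pearsonr(acc, pw)
    elif method == "spearman":
        r, p = stats.spearmanr(acc, pw)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)
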