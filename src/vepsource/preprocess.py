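"""Signal chain: notch, low-pass FIR, resample to 200 Hz, epoching, artifact
rejection, and the repeated stratified train/test split bookkeeping.

All filters are applied forward-backward (zero phase), so latency analyses
downstream see no group delay.  Epochs span [-200, +1000) ms around stimulus
onset with the baseline mean removed per epoch and channel: 240 samples at
the 200 Hz working rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal

from .errors import DataQualityError, EpochError
from .simulate import ContinuousRecording, Event


@dataclass
class EpochSet:
    """Epochs x channels x samples (uV) with color labels.

    ``t_start_ms`` is the time of the first sample relative to stimulus
    onset (-200 by default); the onset sample index is ``-t_start_ms/1000*fs``.
    """

    fs: float
    data: np.ndarray
    labels: np.ndarray            # per-epoch color name
    t_start_ms: float = -200.0
    subject: int = 0
    team: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3 or self.data.shape[0] != self.labels.size:
            raise ValueError("data must be epochs x channels x samples "
                             "matching labels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def onset_index(self) -> int:
        return int(round(-self.t_start_ms / 1000.0 * self.fs))

    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.data.shape[2]) / self.fs * 1e3


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified holdout plan (80/20 by default, 30 repeats)."""

    n_epochs: int
    train_fraction: float
    n_repeats: int
    seed: int
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]

    @property
    def train_size(self) -> int:
        return self.splits[0][0].size

    @property
    def test_size(self) -> int:
        return self.splits[0][1].size


def notch_filter(recording: ContinuousRecording, f0: float = 50.0,
                 quality: float = 30.0) -> ContinuousRecording:
    """Remove line interference with a zero-phase IIR notch at ``f0`` Hz."""
    if f0 >= recording.fs / 2:
        raise ValueError("notch frequency must be below Nyquist")
    b, a = signal.iirnotch(f0, quality, fs=recording.fs)
    out = signal.filtfilt(b, a, recording.data, axis=1)
    return _dc_replace(recording, data=out)


def lowpass_fir(recording: ContinuousRecording, cutoff: float = 30.0,
                transition_hz: float = 10.0) -> ContinuousRecording:
    """Zero-phase windowed-sinc FIR low-pass.

    The -6 dB point sits at ``cutoff + transition_hz/2`` so the passband edge
    (``cutoff``) is flat and the stopband starts at ``cutoff + transition_hz``.
    """
    nyq = recording.fs / 2
    if cutoff >= nyq:
        raise ValueError("cutoff must be below Nyquist")
    # Hamming-window order rule: ~3.3 cycles over the normalized transition
    numtaps = int(np.ceil(3.3 * recording.fs / transition_hz)) | 1
    band_edge = min(cutoff + transition_hz / 2.0, 0.99 * nyq)
    taps = signal.firwin(numtaps, band_edge, window="hamming",
                         fs=recording.fs)
    out = signal.filtfilt(taps, [1.0], recording.data, axis=1)
    return _dc_replace(recording, data=out)


def resample_200(recording: ContinuousRecording) -> ContinuousRecording:
    """Decimate 1000 Hz data to the 200 Hz working rate (anti-aliased).

    Event onsets are remapped by ``round(onset * 200 / 1000)``.
    """
    if recording.fs != 1000.0:
        raise ValueError("resample_200 expects a 1000 Hz recording")
    out = signal.resample_poly(recording.data, up=1, down=5, axis=1)
    events = [Event(onset=int(round(e.onset * 200.0 / 1000.0)),
                    label=e.label, trial=e.trial, team=e.team)
              for e in recording.events]
    return ContinuousRecording(fs=200.0, data=out, events=events,
                               montage=recording.montage,
                               subject=recording.subject, team=recording.team)


def extract_epochs(recording: ContinuousRecording,
                   window_ms: tuple[float, float] = (-200.0, 1000.0)
                   ) -> EpochSet:
    """Cut one epoch per labeled event; remove the per-channel baseline mean.

    The window is half-open in samples: ``[t0, t1)`` relative to onset, so
    (-200, 1000) at 200 Hz yields 240 samples with onset at index 40.  The
    baseline is the part of the window before onset.
    """
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    fs = recording.fs
    pre = int(round(-t0 / 1000.0 * fs))
    post = int(round(t1 / 1000.0 * fs))
    n = recording.n_samples
    bad = [e for e in recording.events
           if e.onset - pre < 0 or e.onset + post > n]
    if bad:
        raise EpochError(
            f"{len(bad)} events have truncated windows: "
            f"onsets {[e.onset for e in bad[:5]]}...")
    epochs = np.stack([
        recording.data[:, e.onset - pre:e.onset + post]
        for e in recording.events])
    if pre > 0:
        baseline = epochs[:, :, :pre].mean(axis=2, keepdims=True)
        epochs = epochs - baseline
    labels = np.array([e.label for e in recording.events])
    return EpochSet(fs=fs, data=epochs, labels=labels, t_start_ms=t0,
                    subject=recording.subject, team=recording.team)


@dataclass(frozen=True)
class RejectionReport:
    removed: tuple[int, ...]            # epoch indices removed
    peak_channels: tuple[int, ...]      # 1-based code of the offending channel
    threshold_uv: float


def reject_artifacts(epochs: EpochSet, amp_thresh: float = 100.0
                     ) -> tuple[EpochSet, RejectionReport]:
    """Drop epochs whose absolute amplitude exceeds ``amp_thresh`` uV on any
    channel.  Raises :class:`DataQualityError` if nothing survives."""
    if amp_thresh <= 0:
        raise ValueError("amp_thresh must be positive")
    peak = np.abs(epochs.data).max(axis=2)          # epochs x channels
    over = peak.max(axis=1) > amp_thresh
    removed = np.flatnonzero(over)
    if removed.size == epochs.n_epochs:
        raise DataQualityError("all epochs exceeded the amplitude threshold")
    peak_ch = peak[removed].argmax(axis=1) + 1
    kept = EpochSet(fs=epochs.fs, data=epochs.data[~over],
                    labels=epochs.labels[~over], t_start_ms=epochs.t_start_ms,
                    subject=epochs.subject, team=epochs.team)
    report = RejectionReport(removed=tuple(int(i) for i in removed),
                             peak_channels=tuple(int(c) for c in peak_ch),
                             threshold_uv=amp_thresh)
    return kept, report


def make_split_plan(n_epochs: int, labels: np.ndarray,
                    train_fraction: float = 0.8, n_repeats: int = 30,
                    seed: int = 0) -> SplitPlan:
    """Repeated stratified holdout: test size ``round((1-f) * n)``, class
    proportions preserved within one epoch, deterministic under ``seed``."""
    labels = np.asarray(labels)
    if n_epochs < 5 or labels.size != n_epochs:
        raise ValueError("need at least 5 epochs and matching labels")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two label classes")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_test = int(round((1.0 - train_fraction) * n_epochs))
    n_test = max(n_test, classes.size)
    # stratified allocation of the test set: proportional with largest
    # remainders, at least one test epoch per class
    quota = counts * n_test / n_epochs
    base = np.floor(quota).astype(int)
    rem = quota - base
    short = n_test - base.sum()
    for idx in np.argsort(-rem)[:short]:
        base[idx] += 1
    base = np.maximum(base, 1)
    while base.sum() > n_test:
        base[int(np.argmax(base))] -= 1

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        test_idx: list[int] = []
        for cls, k in zip(classes, base):
            members = np.flatnonzero(labels == cls)
            test_idx.extend(rng.permutation(members)[:k])
        test = np.sort(np.array(test_idx))
        mask = np.ones(n_epochs, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), test))
    return SplitPlan(n_epochs=n_epochs, train_fraction=train_fraction,
                     n_repeats=n_repeats, seed=seed, splits=tuple(splits))
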