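"""Channel-wise binary color decoding, accuracy topographies, the V1-vs-other
comparison, and the ROC/AUC analysis over subject x channel accuracy points.

Features for one channel are the raw post-baseline samples in the first
500 ms after stimulus onset (100 columns at 200 Hz).  Two classifiers are
supported: a linear max-margin SVM (C=1, per-column z-scoring fit on the
training fold) and a small conv1d feedforward net.  A channel's accuracy is
the mean over the repeated stratified 80/20 splits of one epoch set; the
topography over all subjects and channels is what guides source localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from ._fnn import ConvFnn, FnnParams
from .montage import Montage, region_codes
from .preprocess import EpochSet, SplitPlan, make_split_plan

POSITIVE_CODES_DEFAULT = tuple(range(50, 60))   # POz..O2


@dataclass
class AccuracyMap:
    """subject x channel mean classification accuracy for one pair/classifier."""

    accuracy: np.ndarray          # (n_subjects, 59), NaN = missing
    classifier: str               # "svm" | "fnn"
    pair: str                     # "RG" | "RB" | "GB"
    n_repeats: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy, dtype=float)
        finite = acc[np.isfinite(acc)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        self.accuracy = acc


@dataclass(frozen=True)
class ROCResult:
    auc: float
    std_error: float
    asymptotic_p: float
    ci95: tuple[float, float]
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class RegionComparison:
    statistic: float
    p_value: float
    median_posterior: float
    median_other: float
    n_posterior: int
    n_other: int


def extract_features(epochs: EpochSet, channel_code: int,
                     window_ms: tuple[float, float] = (0.0, 500.0)
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Raw samples of one channel in the decoding window, rows = epochs.

    Returns ``(X, labels)``; the window is half-open ``[t0, t1)``.
    """
    if not 1 <= channel_code <= epochs.n_channels:
        raise ValueError(f"channel code {channel_code} out of range")
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("decoding window must have positive duration")
    fs = epochs.fs
    i0 = epochs.onset_index + int(round(t0 / 1000.0 * fs))
    i1 = epochs.onset_index + int(round(t1 / 1000.0 * fs))
    if i0 < 0 or i1 > epochs.data.shape[2]:
        raise ValueError("decoding window outside the epoch")
    X = epochs.data[:, channel_code - 1, i0:i1]
    return np.ascontiguousarray(X), epochs.labels


def _standardize(train: np.ndarray, test: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _encode(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary decoding needs exactly two classes")
    return (labels == classes[1]).astype(int)


def train_eval_linear(X: np.ndarray, labels: np.ndarray,
                      split: tuple[np.ndarray, np.ndarray],
                      C: float = 1.0) -> float:
    """Accuracy of a linear max-margin classifier on one train/test split."""
    train_idx, test_idx = split
    y = _encode(labels)
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training fold contains a single class")
    Xtr, Xte = _standardize(X[train_idx], X[test_idx])
    clf = LinearSVC(C=C, dual="auto")
    clf.fit(Xtr, y[train_idx])
    return float((clf.predict(Xte) == y[test_idx]).mean())


def train_eval_fnn(X: np.ndarray, labels: np.ndarray,
                   split: tuple[np.ndarray, np.ndarray], seed: int = 0,
                   params: FnnParams = FnnParams()) -> float:
    """Accuracy of the conv1d feedforward net on one split (seed-determined)."""
    train_idx, test_idx = split
    y = _encode(labels)
    if np.unique(y[train_idx]).size < 2:
        raise ValueError("training fold contains a single class")
    Xtr, Xte = _standardize(X[train_idx], X[test_idx])
    net = ConvFnn(n_time=X.shape[1], params=params, seed=seed)
    net.fit(Xtr, y[train_idx])
    return float((net.predict(Xte) == y[test_idx]).mean())


def channel_accuracy(epochs: EpochSet, channel_code: int, classifier: str,
                     plan: SplitPlan, seed: int = 0,
                     window_ms: tuple[float, float] = (0.0, 500.0)) -> float:
    """Mean accuracy of one channel over all repeats of the split plan."""
    X, labels = extract_features(epochs, channel_code, window_ms)
    accs = []
    for rep, split in enumerate(plan.splits):
        if classifier == "svm":
            accs.append(train_eval_linear(X, labels, split))
        elif classifier == "fnn":
            accs.append(train_eval_fnn(X, labels, split,
                                       seed=seed * 1000 + rep))
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
    return float(np.mean(accs))


def build_accuracy_map(epoch_sets: list[EpochSet], classifier: str = "svm",
                       n_repeats: int = 30, train_fraction: float = 0.8,
                       seed: int = 0, pair: str = "") -> AccuracyMap:
    """One mean accuracy per (subject, channel) over every epoch set.

    ``epoch_sets`` holds one preprocessed set per subject (same pair/team).
    Each subject gets its own deterministic split plan derived from ``seed``.
    """
    if not epoch_sets:
        raise ValueError("need at least one subject epoch set")
    n_ch = epoch_sets[0].n_channels
    acc = np.full((len(epoch_sets), n_ch), np.nan)
    for s, epochs in enumerate(epoch_sets):
        plan = make_split_plan(epochs.n_epochs, epochs.labels,
                               train_fraction=train_fraction,
                               n_repeats=n_repeats, seed=seed + 7919 * s)
        for code in range(1, n_ch + 1):
            acc[s, code - 1] = channel_accuracy(
                epochs, code, classifier, plan, seed=seed + 7919 * s + code)
    return AccuracyMap(accuracy=acc, classifier=classifier,
                       pair=pair or (epoch_sets[0].team or ""),
                       n_repeats=n_repeats)


def compare_regions(acc_map: AccuracyMap, montage: Montage
                    ) -> RegionComparison:
    """Two-sided rank-sum test: posterior-V1 vs other channel accuracies."""
    post = np.array(region_codes(montage, "posterior_v1")) - 1
    other = np.array(region_codes(montage, "other")) - 1
    a = acc_map.accuracy[:, post].ravel()
    b = acc_map.accuracy[:, other].ravel()
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    stat, p = stats.ranksums(a, b)
    return RegionComparison(statistic=float(stat), p_value=float(p),
                            median_posterior=float(np.median(a)),
                            median_other=float(np.median(b)),
                            n_posterior=a.size, n_other=b.size)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the rank statistic (midranks for ties)."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = pos.size, neg.size
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def roc_over_channels(acc_map: AccuracyMap,
                      positive_codes: tuple[int, ...] = POSITIVE_CODES_DEFAULT
                      ) -> ROCResult:
    """ROC over all subject x channel accuracy points.

    Points with codes in ``positive_codes`` (default POz..O2) are the positive
    state.  AUC by the rank statistic; standard error by the Hanley-McNeil
    formula; p from the normal approximation against AUC = 0.5; Wald 95% CI.
    Missing (NaN) entries are excluded.
    """
    if not positive_codes:
        raise ValueError("positive code set must be non-empty")
    acc = acc_map.accuracy
    codes = np.arange(1, acc.shape[1] + 1)
    pos_mask = np.isin(codes, positive_codes)
    pos = acc[:, pos_mask].ravel()
    neg = acc[:, ~pos_mask].ravel()
    pos, neg = pos[np.isfinite(pos)], neg[np.isfinite(neg)]
    n_pos, n_neg = pos.size, neg.size
    auc = _rank_auc(pos, neg)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 0.0 if auc != 0.5 else 1.0
    lo = max(0.0, auc - 1.959963984540054 * se)
    hi = min(1.0, auc + 1.959963984540054 * se)
    return ROCResult(auc=auc, std_error=se, asymptotic_p=p, ci95=(lo, hi),
                     n_positive=n_pos, n_negative=n_neg)
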