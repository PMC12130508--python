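"""Dynamic time warping, relative average DTW profiling, and domain descriptors.

The DTW accumulated-cost matrix is (n+1) x (m+1): the origin D[0,0] is zero
and the rest of the first row and column are +inf, so D[1,1] becomes the
starting local cost.  Each interior cell adds the local cost |a_i - b_j| to
the minimum of its three predecessors (diagonal, left, down), each multiplied
by a tuning coefficient (all 1 by default).  The distance is the last cell;
the warping path is recovered by traceback with a deterministic tie-break
(diagonal, then vertical, then horizontal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numba import njit

from airsig.errors import ConfigError, DataError
from airsig.schema import SignatureDataset, SignatureRecord


@dataclass
class DTWResult:
    distance: float
    cost_matrix: np.ndarray          # (n+1) x (m+1) accumulated cost
    path: list[tuple[int, int]]      # 1-based index pairs from (1,1) to (n,m)


@dataclass
class RelativeDTWReport:
    """Per-subject mean DTW distance to all other subjects' signatures."""

    per_subject: dict[str, float]
    global_mean: float
    above_mean_flags: dict[str, bool]


@njit(cache=True)
def _accumulate(a, b, w_diag, w_left, w_down, squared):
    n, m = a.size, b.size
    cost = np.empty((n + 1, m + 1))
    cost[:] = np.inf
    cost[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = a[i - 1] - b[j - 1]
            local = d * d if squared else abs(d)
            best = w_diag * cost[i - 1, j - 1]
            cand = w_left * cost[i, j - 1]
            if cand < best:
                best = cand
            cand = w_down * cost[i - 1, j]
            if cand < best:
                best = cand
            cost[i, j] = local + best
    return cost


def dtw(
    a: np.ndarray,
    b: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    squared: bool = False,
) -> DTWResult:
    """DTW between two 1-D sequences.

    `weights` are the (diagonal, left, down) tuning coefficients applied to
    the predecessor cells; `squared` switches the local cost from absolute to
    squared difference.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise DataError("DTW requires non-empty sequences")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise DataError("DTW sequences must be finite")
    w_diag, w_left, w_down = (float(w) for w in weights)
    if min(w_diag, w_left, w_down) <= 0:
        raise ConfigError("step weights must be positive")

    cost = _accumulate(a, b, w_diag, w_left, w_down, squared)
    path = _traceback(cost, (w_diag, w_left, w_down))
    return DTWResult(distance=float(cost[a.size, b.size]), cost_matrix=cost, path=path)


def _traceback(cost: np.ndarray, weights) -> list[tuple[int, int]]:
    w_diag, w_left, w_down = weights
    i, j = cost.shape[0] - 1, cost.shape[1] - 1
    path = [(i, j)]
    while (i, j) != (1, 1):
        # candidate order encodes the tie-break: diagonal, vertical, horizontal
        candidates = []
        if i > 1 and j > 1:
            candidates.append((w_diag * cost[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            candidates.append((w_down * cost[i - 1, j], (i - 1, j)))
        if j > 1:
            candidates.append((w_left * cost[i, j - 1], (i, j - 1)))
        best = min(candidates, key=lambda c: c[0])[0]
        for value, cell in candidates:
            if value == best:
                i, j = cell
                break
        path.append((i, j))
    path.reverse()
    return path


def channel_mean_reducer(record: SignatureRecord) -> np.ndarray:
    """Default multivariate-to-univariate reduction: mean over channels."""
    return record.values.mean(axis=1)


def relative_average_dtw(
    dataset: SignatureDataset,
    reducer: Callable[[SignatureRecord], np.ndarray] = channel_mean_reducer,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RelativeDTWReport:
    """For each subject, the mean DTW distance from its signatures to all
    signatures of *other* subjects, with the corpus-wide mean and
    above/below-mean flags."""
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise DataError("relative average DTW needs at least 2 subjects")
    recs = sorted(dataset.records, key=lambda r: r.key)
    series = [np.asarray(reducer(r), dtype=np.float64) for r in recs]
    labels = [r.subject_id for r in recs]

    n = len(recs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw(series[i], series[j], weights=weights).distance
            dist[i, j] = dist[j, i] = d

    per_subject: dict[str, float] = {}
    for subject in subjects:
        own = [i for i, s in enumerate(labels) if s == subject]
        other = [i for i, s in enumerate(labels) if s != subject]
        per_subject[subject] = float(dist[np.ix_(own, other)].mean())
    global_mean = float(np.mean(list(per_subject.values())))
    flags = {s: v > global_mean for s, v in per_subject.items()}
    return RelativeDTWReport(per_subject=per_subject, global_mean=global_mean, above_mean_flags=flags)


def descriptors(sequence: np.ndarray, sampling_interval_ms: float) -> dict[str, float]:
    """Time, frequency and complexity descriptors of a 1-D sequence.

    Time domain: mean, standard deviation, RMS.  Frequency domain: dominant
    frequency and spectral centroid (Hz) of the de-meaned magnitude spectrum.
    Complexity: permutation entropy of order 3, normalized to [0, 1].
    """
    x = np.asarray(sequence, dtype=np.float64).ravel()
    if x.size < 8:
        raise DataError(f"descriptors need at least 8 samples, got {x.size}")
    if sampling_interval_ms <= 0:
        raise ConfigError("sampling_interval_ms must be positive")
    fs = 1000.0 / sampling_interval_ms

    centered = x - x.mean()
    spectrum = np.abs(np.fft.rfft(centered))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    # exclude DC (zero after de-meaning up to rounding) from the dominant bin
    dominant = float(freqs[1:][np.argmax(spectrum[1:])])
    total = spectrum[1:].sum()
    centroid = float((freqs[1:] * spectrum[1:]).sum() / total) if total > 0 else 0.0

    return {
        "mean": float(x.mean()),
        "sd": float(x.std()),
        "rms": float(np.sqrt(np.mean(x**2))),
        "dominant_freq_hz": dominant,
        "spectral_centroid_hz": centroid,
        "permutation_entropy": permutation_entropy(x, order=3),
    }


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1].

    Embeds the sequence into overlapping windows of `order` samples, maps each
    window to its ordinal pattern, and returns the Shannon entropy of the
    pattern distribution divided by log(order!).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    n_windows = x.size - (order - 1) * delay
    if n_windows < 1:
        raise DataError("sequence too short for the requested embedding")
    windows = np.lib.stride_tricks.sliding_window_view(x, order * delay - delay + 1)[:, ::delay]
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each ordinal pattern as an integer
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / math.log(math.factorial(order)))
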