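"""Signed-r^2 discriminability maps and interval-mean features.

The classifier does not see raw epochs: per channel, the epoch is
summarised by its mean amplitude over a small number of discriminative
time intervals.  The intervals are chosen on training data from the
signed-r^2 map — the signed squared point-biserial correlation between
single-sample amplitude and the binary target label — by a greedy
peak-growing heuristic, and are then frozen into the model so test data
is scored with training-derived intervals only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EpochSet


@dataclass
class DiscriminabilityMap:
    """sgn r^2 per (channel, time); values in [-1, 1]."""

    values: np.ndarray            # (n_channels, n_times)
    times_ms: np.ndarray
    channels: tuple[str, ...]


@dataclass(frozen=True)
class DiscriminativeIntervals:
    """Disjoint half-open (start, end] ms intervals, sorted by start."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        iv = self.intervals
        if any(a >= b for a, b in iv):
            raise ValueError("intervals must have positive width")
        for (a1, b1), (a2, b2) in zip(iv, iv[1:]):
            if a2 < b1:
                raise ValueError("intervals must be disjoint and sorted")

    def __len__(self) -> int:
        return len(self.intervals)

    def sample_masks(self, times_ms: np.ndarray) -> list[np.ndarray]:
        """Boolean sample mask per interval ((start, end] membership)."""
        return [(times_ms > a) & (times_ms <= b) for a, b in self.intervals]

    def to_list(self) -> list[dict[str, float]]:
        return [{"start_ms": a, "end_ms": b} for a, b in self.intervals]

    @classmethod
    def from_list(cls, items) -> "DiscriminativeIntervals":
        return cls(tuple((d["start_ms"], d["end_ms"]) for d in items))


def signed_r_squared_map(epochs: EpochSet) -> DiscriminabilityMap:
    """Signed squared biserial correlation per (channel, time) point.

    r = sqrt(N1 N2) / (N1 + N2) * (mu1 - mu2) / sigma with class means
    mu1 (target), mu2 (non-target) and sigma the population standard
    deviation over all epochs; sgn r^2 = sign(mu1 - mu2) * r^2.  This
    equals the signed squared Pearson correlation between amplitude and
    the 0/1 label.  Points with sigma = 0 get value 0.
    """
    y = epochs.labels.astype(bool)
    n1, n2 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both target and non-target epochs are required")
    mu1 = epochs.data[y].mean(axis=0)
    mu2 = epochs.data[~y].mean(axis=0)
    sigma = epochs.data.std(axis=0)          # population (divide-by-N)
    diff = mu1 - mu2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(n1 * n2) / (n1 + n2) * diff / sigma
    r = np.where(sigma > 0, r, 0.0)
    return DiscriminabilityMap(values=np.sign(diff) * r**2,
                               times_ms=epochs.times_ms,
                               channels=epochs.channels)


def _tile_window(window_ms: tuple[float, float], n: int,
                 ) -> list[tuple[float, float]]:
    lo, hi = window_ms
    edges = np.linspace(lo, hi, n + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def select_discriminative_intervals(
        dmap: DiscriminabilityMap, n: int = 8,
        window_ms: tuple[float, float] = (100.0, 600.0),
        ) -> DiscriminativeIntervals:
    """Greedy peak-growing selection of ``n`` discriminative intervals.

    The per-sample score is s(t) = sum over channels of r^2(c, t).
    Repeatedly: take the unmasked sample with maximal score, grow a
    contiguous interval around it while s stays >= half the peak score,
    then mask those samples.  If the remaining scores are all zero
    before ``n`` intervals are found, the unoccupied parts of the search
    window are tiled left-to-right to fill up the count.  Deterministic
    given the map.
    """
    lo, hi = window_ms
    t = dmap.times_ms
    if t.min() > lo or t.max() < hi - 1e-9:
        raise ValueError("map does not cover the search window")
    # candidate samples: (lo, hi] membership on the sample grid
    cand = np.flatnonzero((t > lo) & (t <= hi))
    if cand.size == 0:
        raise ValueError("search window contains no samples")
    if cand.size < n:
        raise ValueError(f"window has {cand.size} samples, need >= {n}")
    step = float(np.median(np.diff(t)))
    score = (dmap.values[:, cand] ** 2).sum(axis=0)

    taken = np.zeros(cand.size, dtype=bool)
    ranges: list[tuple[int, int]] = []     # inclusive index ranges into cand
    for _ in range(n):
        masked = np.where(taken, -np.inf, score)
        peak = int(np.argmax(masked))
        if not np.isfinite(masked[peak]) or score[peak] <= 0:
            break
        thr = 0.5 * score[peak]
        a = b = peak
        while a - 1 >= 0 and not taken[a - 1] and score[a - 1] >= thr:
            a -= 1
        while b + 1 < cand.size and not taken[b + 1] and score[b + 1] >= thr:
            b += 1
        taken[a:b + 1] = True
        ranges.append((a, b))

    if not ranges:                         # all-zero map: tile the window
        return DiscriminativeIntervals(tuple(_tile_window(window_ms, n)))

    # fill up with unoccupied stretches (left to right), then, if still
    # short, split the widest intervals on sample boundaries
    free: list[tuple[int, int]] = []
    i = 0
    while i < cand.size:
        if taken[i]:
            i += 1
            continue
        j = i
        while j + 1 < cand.size and not taken[j + 1]:
            j += 1
        free.append((i, j))
        i = j + 1
    while len(ranges) < n and free:
        ranges.append(free.pop(0))
    while len(ranges) < n:
        widths = [b - a for a, b in ranges]
        w = int(np.argmax(widths))
        a, b = ranges[w]
        if b == a:
            raise RuntimeError("not enough samples to split further")
        mid = (a + b) // 2
        ranges[w] = (a, mid)
        ranges.append((mid + 1, b))

    intervals = sorted((max(lo, float(t[cand[a]] - step / 2)),
                        min(hi, float(t[cand[b]] + step / 2)))
                       for a, b in ranges)
    return DiscriminativeIntervals(tuple(intervals))


def interval_mean_features(epochs: EpochSet,
                           intervals: DiscriminativeIntervals,
                           ) -> np.ndarray:
    """Mean amplitude per (channel, interval); channel-major columns.

    Returns an (n_epochs, n_channels * n_intervals) matrix whose column
    (c * n_intervals + i) is the mean of channel c over interval i.
    """
    masks = intervals.sample_masks(epochs.times_ms)
    empty = [i for i, m in enumerate(masks) if not m.any()]
    if empty:
        raise ValueError(f"intervals with no samples: "
                         f"{[intervals.intervals[i] for i in empty]}")
    cols = [epochs.data[:, :, m].mean(axis=2) for m in masks]
    # cols[i] is (n_epochs, n_channels); interleave to channel-major order
    stacked = np.stack(cols, axis=2)    # (n_epochs, n_channels, n_intervals)
    n = len(epochs)
    return stacked.reshape(n, -1)
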