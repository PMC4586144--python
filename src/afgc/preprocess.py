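"""Turn oscillatory traces into the stationary differenced panel.

Granger-causal inference assumes stationary series, which raw circadian
traces are not.  On the rising phase of each cycle the mRNA count grows
approximately linearly, so its one-step difference is stationary there.
This module detects the rising intervals shared by all cells, differences
the counts within each interval, concatenates the differenced segments
across cycles, and provides ACF/CCF diagnostics for stationarity and
model-order choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network_sim import Trajectory

__all__ = [
    "RisingIntervals",
    "DifferencedPanel",
    "detect_rising_intervals",
    "difference_and_concatenate",
    "acf",
    "ccf",
    "significance_band",
    "suggest_model_order",
]


@dataclass(frozen=True)
class RisingIntervals:
    """Closed sample-index intervals [start, stop] (inclusive) during which
    every cell's smoothed series is rising, one per qualifying cycle."""

    intervals: tuple               # ((start_idx, stop_idx), ...)
    sample_interval: float         # minutes
    smoothing_window_min: float
    margin_min: float
    min_length_h: float

    def __post_init__(self) -> None:
        prev_stop = -1
        for a, b in self.intervals:
            if a > b:
                raise ValueError(f"empty interval ({a}, {b})")
            if a <= prev_stop:
                raise ValueError("intervals must be disjoint and sorted")
            prev_stop = b

    @property
    def hours(self) -> tuple:
        """Intervals as (start_h, end_h) pairs."""
        dt = self.sample_interval / 60.0
        return tuple((a * dt, b * dt) for a, b in self.intervals)

    def total_hours(self) -> float:
        dt = self.sample_interval / 60.0
        return sum((b - a) * dt for a, b in self.intervals)


@dataclass
class DifferencedPanel:
    """Concatenated one-step differences of the rising segments.

    ``values[t, i]`` is D_i[t] = M_i[t] - M_i[t-1] within a segment; no
    difference spans a gap between segments.  ``segment_boundaries`` are the
    indices in ``values`` where a new segment starts (the first segment's
    start, 0, is implicit).
    """

    values: np.ndarray
    segment_boundaries: np.ndarray
    sample_interval: float          # minutes
    segment_starts: np.ndarray = field(default_factory=lambda: np.array([]))
    # raw count at the first sample of each segment, per cell; lets the
    # panel be undifferenced exactly

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def observation_hours(self) -> float:
        """Hours of retained observations: n_points * interval / 60."""
        return self.n_points * self.sample_interval / 60.0

    def truncated(self, n_points: int) -> "DifferencedPanel":
        """First ``n_points`` rows with boundary bookkeeping preserved."""
        if n_points > self.n_points:
            raise ValueError(
                f"requested {n_points} points, panel has {self.n_points}")
        keep = self.segment_boundaries < n_points
        n_segs = int(keep.sum()) + 1
        return DifferencedPanel(
            values=self.values[:n_points],
            segment_boundaries=self.segment_boundaries[keep],
            sample_interval=self.sample_interval,
            segment_starts=self.segment_starts[:n_segs]
            if len(self.segment_starts) else self.segment_starts,
        )

    def segments(self) -> list:
        """The differenced values split back into per-segment blocks."""
        return np.split(self.values, self.segment_boundaries)

    def undifference(self) -> list:
        """Reconstruct the original count segments by cumulative summation
        from the stored segment start values (exact for integer input)."""
        if not len(self.segment_starts):
            raise ValueError("segment start values were not recorded")
        out = []
        for start, block in zip(self.segment_starts, self.segments()):
            out.append(np.vstack([start, start + np.cumsum(block, axis=0)]))
        return out

    # -- serialization ------------------------------------------------------

    def write_csv(self, path, sidecar_path=None) -> None:
        header = ",".join(f"cell{c}" for c in range(self.n_cells))
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump({
                    "segment_boundaries": self.segment_boundaries.tolist(),
                    "sample_interval_min": self.sample_interval,
                    "segment_starts": self.segment_starts.tolist(),
                }, fh)

    @classmethod
    def read_csv(cls, path, sidecar_path=None,
                 sample_interval: float = 1.0) -> "DifferencedPanel":
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        boundaries = np.array([], dtype=int)
        starts = np.array([])
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = json.load(fh)
            boundaries = np.asarray(meta["segment_boundaries"], dtype=int)
            sample_interval = meta.get("sample_interval_min", sample_interval)
            starts = np.asarray(meta.get("segment_starts", []))
        return cls(values=values, segment_boundaries=boundaries,
                   sample_interval=sample_interval, segment_starts=starts)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window odd-ized)."""
    if window <= 1:
        return x.astype(float)
    if window % 2 == 0:
        window += 1
    kern = np.ones(window) / window
    sm = np.convolve(x, kern, mode="same")
    # correct the edges where the kernel hangs off the series
    norm = np.convolve(np.ones_like(x, dtype=float), kern, mode="same")
    return sm / norm


def _rising_mask(sm: np.ndarray, prominence_frac: float = 0.15) -> np.ndarray:
    """True between each trough of the smoothed trace and the next peak.

    Extrema are taken with a prominence threshold relative to the trace's
    range, so small residual wiggles (counting noise, measurement noise that
    survives smoothing) do not fragment a rising phase.
    """
    from scipy.signal import find_peaks

    n = len(sm)
    rng = sm.max() - sm.min()
    if rng <= 0:
        return np.zeros(n - 1, dtype=bool)
    prom = prominence_frac * rng
    peaks, _ = find_peaks(sm, prominence=prom)
    troughs, _ = find_peaks(-sm, prominence=prom)
    ext = sorted([(int(i), +1) for i in peaks] + [(int(i), -1) for i in troughs])
    if not ext:
        # monotone-ish trace: rising iff it ends higher than it starts
        return np.full(n - 1, sm[-1] > sm[0])
    # endpoints act as the opposite extremum of their nearest neighbour
    if ext[0][1] == +1:
        ext.insert(0, (0, -1))
    if ext[-1][1] == -1:
        ext.append((n - 1, +1))
    mask = np.zeros(n - 1, dtype=bool)
    for (a, ta), (b, tb) in zip(ext, ext[1:]):
        if ta == -1 and tb == +1:
            mask[a:b] = True
    return mask


def detect_rising_intervals(
    traj: Trajectory,
    species: str = "M",
    smoothing_window_min: float = 60.0,
    margin_min: float = 30.0,
    min_length_h: float = 3.0,
    require: bool = True,
) -> RisingIntervals:
    """Find the per-cycle intervals common to all cells during which each
    cell's smoothed series runs from a trough to the following peak, trimmed
    by ``margin_min`` at both ends and at least ``min_length_h`` long.
    Deterministic.

    Raises ``ValueError`` when ``require`` is set and no interval qualifies
    (desynchronized cells or too short a recording).
    """
    mat = traj.species_matrix(species)
    n_samp, n_cells = mat.shape
    dt_min = traj.sample_interval
    window = max(1, int(round(smoothing_window_min / dt_min)))
    margin = int(round(margin_min / dt_min))
    min_len = int(round(min_length_h * 60.0 / dt_min))

    rising = np.ones(n_samp - 1, dtype=bool)
    for c in range(n_cells):
        sm = _moving_average(mat[:, c], window)
        rising &= _rising_mask(sm)

    intervals = []
    i = 0
    n = len(rising)
    while i < n:
        if rising[i]:
            j = i
            while j < n and rising[j]:
                j += 1
            a, b = i + margin, j - margin   # closed sample-index interval
            if b - a >= min_len:
                intervals.append((a, b))
            i = j
        else:
            i += 1
    if require and not intervals:
        raise ValueError(
            "no qualifying rising interval found: cells may be "
            "desynchronized or the recording too short")
    return RisingIntervals(
        intervals=tuple(intervals), sample_interval=dt_min,
        smoothing_window_min=smoothing_window_min, margin_min=margin_min,
        min_length_h=min_length_h)


def difference_and_concatenate(
    traj: Trajectory,
    intervals: RisingIntervals,
    species: str = "M",
) -> DifferencedPanel:
    """One-step difference within each rising interval and concatenate the
    segments in time order, recording the join indices."""
    mat = traj.species_matrix(species)
    n_samp = mat.shape[0]
    segs = []
    starts = []
    for a, b in intervals.intervals:
        if a < 0 or b >= n_samp:
            raise ValueError(f"interval ({a}, {b}) outside trajectory of {n_samp} samples")
        segs.append(np.diff(mat[a:b + 1], axis=0))
        starts.append(mat[a])
    if not segs:
        raise ValueError("no intervals to difference")
    values = np.vstack(segs)
    boundaries = np.cumsum([s.shape[0] for s in segs])[:-1]
    return DifferencedPanel(
        values=values, segment_boundaries=np.asarray(boundaries, dtype=int),
        sample_interval=intervals.sample_interval,
        segment_starts=np.asarray(starts))


# ---------------------------------------------------------------------------
# correlation diagnostics
# ---------------------------------------------------------------------------

def significance_band(n: int) -> float:
    """Approximate 95% white-noise band for sample (cross-)correlations."""
    return 1.96 / np.sqrt(n)


def acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation at lags 0..max_lag, normalized by the lag-0
    variance."""
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("series shorter than max_lag")
    x = x - x.mean()
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("zero-variance input")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        out[lag] = np.dot(x[:-lag], x[lag:]) / denom
    return out


def ccf(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample cross-correlation of ``a`` leading ``b`` at lags
    -max_lag..max_lag (index ``max_lag + k`` holds corr(a[t], b[t+k]))."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) <= max_lag:
        raise ValueError("series shorter than max_lag")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0:
        raise ValueError("zero-variance input")
    out = np.empty(2 * max_lag + 1)
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            v = np.dot(x[: len(x) - k] if k else x, y[k:]) / denom
        else:
            v = np.dot(x[-k:], y[: len(y) + k]) / denom
        out[max_lag + k] = v
    return out


def suggest_model_order(panel: DifferencedPanel, max_lag: int = 15) -> int:
    """Largest lag (in samples) at which any pairwise cross-correlation of
    the panel exceeds the white-noise significance band, capped at
    ``max_lag``.  Advisory; returns 1 when nothing is significant."""
    D = panel.values
    n, K = D.shape
    if K < 2:
        raise ValueError("need at least 2 cells")
    band = significance_band(n)
    best = 0
    for a_i in range(K):
        for b_i in range(K):
            if a_i == b_i:
                continue
            cc = ccf(D[:, a_i], D[:, b_i], max_lag)
            for lag in range(1, max_lag + 1):
                if abs(cc[max_lag + lag]) > band:
                    best = max(best, lag)
    return max(best, 1)
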