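"""Event–Up cross-correlation synchrony with a time-shuffled null.

The synchrogram is the histogram of (Up onset − event onset) lags in 50 ms
bins spanning −1000…+1000 ms, normalised per trigger event, so each bin is
the probability of an Up onset at that lag per event. "Total synchrony" is
the histogram mass in a 250 ms window centred on the peak bin (peak searched
over the positive-lag half). The null shuffles event times by non-zero
multiples of 100 ms within ±1 s (100 iterations), wrapping circularly over
the block duration so event count and local rate are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["Synchrogram", "event_up_synchrony", "shuffle_null",
           "compare_synchrony", "analyze_synchrony"]


@dataclass
class Synchrogram:
    """Lagged event–Up histogram plus optional shuffle-null statistics."""

    lag_bin_edges_ms: np.ndarray
    rate: np.ndarray                  # coincidences per trigger event, per bin
    peak_lag_ms: float                # centre of the max bin (positive lags)
    total_synchrony: float            # mass in the 250 ms window on the peak
    n_events: int
    n_ups: int
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    empty: bool = False               # set when there were no Up onsets

    @property
    def lag_bin_centers_ms(self) -> np.ndarray:
        e = self.lag_bin_edges_ms
        return (e[:-1] + e[1:]) / 2.0

    @property
    def peak_rate(self) -> float:
        return float(self.rate.max()) if len(self.rate) else 0.0

    def null_z(self) -> float:
        """z of the observed peak-bin rate against the shuffle null."""
        if self.null_mean is None or self.null_sd is None:
            raise ValueError("no null attached; run shuffle_null first")
        i = int(np.argmax(np.where(self.lag_bin_edges_ms[:-1] >= 0, self.rate, -np.inf)))
        sd = self.null_sd[i]
        return float((self.rate[i] - self.null_mean[i]) / sd) if sd > 0 else np.inf


def _histogram(up_onsets: np.ndarray, event_onsets: np.ndarray,
               edges_ms: np.ndarray) -> np.ndarray:
    lags_ms = (up_onsets[None, :] - event_onsets[:, None]).ravel() * 1000.0
    # round to 1 ns so exact-latency lags cannot straddle a bin edge through
    # floating-point representation error; drop the top edge itself so every
    # bin is half-open [lo, hi) (np.histogram would close the last bin)
    lags_ms = np.round(lags_ms, 6)
    counts, _ = np.histogram(lags_ms[lags_ms < edges_ms[-1]], bins=edges_ms)
    return counts


def event_up_synchrony(up_onsets, event_onsets, bin_ms: float = 50.0,
                       lag_range_ms: tuple[float, float] = (-1000.0, 1000.0),
                       total_window_ms: float = 250.0) -> Synchrogram:
    """Cross-correlation synchrogram of Up onsets relative to events."""
    event_onsets = np.asarray(event_onsets, dtype=float)
    up_onsets = np.asarray(up_onsets, dtype=float)
    if len(event_onsets) == 0:
        raise ValueError("event list is empty")
    lo, hi = lag_range_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    if len(up_onsets) == 0:
        z = np.zeros(len(edges) - 1)
        return Synchrogram(edges, z, np.nan, 0.0, len(event_onsets), 0, empty=True)
    counts = _histogram(up_onsets, event_onsets, edges)
    rate = counts / len(event_onsets)
    centers = (edges[:-1] + edges[1:]) / 2.0
    pos = edges[:-1] >= 0
    i_peak = int(np.argmax(np.where(pos, rate, -np.inf)))
    half = int(round(total_window_ms / bin_ms)) // 2
    window = slice(max(0, i_peak - half), min(len(rate), i_peak + half + 1))
    return Synchrogram(edges, rate, float(centers[i_peak]),
                       float(rate[window].sum()), len(event_onsets), len(up_onsets))


def shuffle_null(up_onsets, event_onsets, iterations: int = 100,
                 offset_range_ms: tuple[float, float] = (-1000.0, 1000.0),
                 step_ms: float = 100.0, seed: int | np.random.Generator = 0,
                 bin_ms: float = 50.0,
                 lag_range_ms: tuple[float, float] = (-1000.0, 1000.0),
                 block_duration_s: float | None = None,
                 common_offset: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean/SD of the synchrogram under event-time shuffling.

    Each iteration displaces events by offsets drawn uniformly from the
    non-zero multiples of ``step_ms`` within ``offset_range_ms`` (every event
    independently by default; one common offset per iteration with
    ``common_offset=True``). Events shifted past the block edge wrap
    circularly so the event count is conserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    event_onsets = np.asarray(event_onsets, dtype=float)
    up_onsets = np.asarray(up_onsets, dtype=float)
    lo, hi = offset_range_ms
    if step_ms > hi - lo:
        raise ValueError("step_ms larger than the offset range")
    ks = np.arange(np.ceil(lo / step_ms), np.floor(hi / step_ms) + 1)
    ks = ks[ks != 0]
    if len(ks) == 0:
        raise ValueError("no non-zero offsets available")
    offsets_s = ks * step_ms / 1000.0
    if block_duration_s is None:
        upper = max(event_onsets.max(), up_onsets.max() if len(up_onsets) else 0.0)
        block_duration_s = upper + abs(hi) / 1000.0
    edges = np.arange(lag_range_ms[0], lag_range_ms[1] + bin_ms / 2, bin_ms)
    rates = np.empty((iterations, len(edges) - 1))
    for it in range(iterations):
        if common_offset:
            off = rng.choice(offsets_s)
        else:
            off = rng.choice(offsets_s, size=len(event_onsets))
        shifted = np.mod(event_onsets + off, block_duration_s)
        counts = _histogram(up_onsets, shifted, edges) if len(up_onsets) else 0
        rates[it] = counts / len(event_onsets)
    return rates.mean(axis=0), rates.std(axis=0, ddof=0)


def analyze_synchrony(up_onsets, event_onsets, bin_ms: float = 50.0,
                      lag_range_ms: tuple[float, float] = (-1000.0, 1000.0),
                      total_window_ms: float = 250.0, iterations: int = 100,
                      offset_range_ms: tuple[float, float] = (-1000.0, 1000.0),
                      step_ms: float = 100.0, seed: int | np.random.Generator = 0,
                      block_duration_s: float | None = None) -> Synchrogram:
    """Synchrogram with the shuffle null attached."""
    sg = event_up_synchrony(up_onsets, event_onsets, bin_ms, lag_range_ms,
                            total_window_ms)
    if not sg.empty:
        sg.null_mean, sg.null_sd = shuffle_null(
            up_onsets, event_onsets, iterations, offset_range_ms, step_ms, seed,
            bin_ms, lag_range_ms, block_duration_s)
    return sg


def compare_synchrony(group_a_totals, group_b_totals) -> tuple[float, float]:
    """Two-sample (unpaired, equal-variance) t-test on per-animal totals."""
    a = np.asarray(group_a_totals, dtype=float)
    b = np.asarray(group_b_totals, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two totals per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
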