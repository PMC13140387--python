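"""Up-state onset detection and evoked/spontaneous classification.

Up-state initiations are the first negative peaks of the detection-band
(default 0.1–10 Hz) LFP trace. Detection mirrors a peak finder run on the
negated trace with a topographic-prominence floor of 3 trace standard
deviations and a minimum spacing of 382 samples (≈ 0.5 s at 763 Hz); any
candidate with another candidate in its preceding 2 s is then removed as a
later wave of the same Up state (the removal chains, so only the first wave
of a multi-wave Up survives). A fixed-threshold detector (0.1 mV crossings)
is provided for anaesthetic-depth comparisons where the trace SD itself
changes with depth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .types import AnalysisConfig, EventTable, UpStateTable

__all__ = [
    "detect_up_onsets",
    "classify_onsets",
    "detect_up_threshold",
    "evoked_fraction",
    "detect_and_classify",
]

_EPS = 1e-9


def _distance_select(indices: np.ndarray, heights: np.ndarray,
                     min_distance: int) -> np.ndarray:
    """Greedy minimum-distance selection, highest peak first (stable ties)."""
    order = np.argsort(-heights, kind="stable")
    keep = np.ones(len(indices), dtype=bool)
    for k in order:
        if not keep[k]:
            continue
        close = np.abs(indices - indices[k]) < min_distance
        close[k] = False
        keep[close] = False
    return keep


def _dedup_preceding(times_s: np.ndarray, dedup_s: float) -> np.ndarray:
    """Keep a candidate only if no candidate lies in its preceding `dedup_s`.

    The reference set is the full candidate list (removed or not), so removal
    chains across the successive waves of one Up state.
    """
    keep = np.ones(len(times_s), dtype=bool)
    if len(times_s) > 1:
        keep[1:] = np.diff(times_s) > dedup_s + _EPS
    return keep


def detect_up_onsets(trace: np.ndarray, fs: float,
                     min_distance_samples: int = 382,
                     prominence_sd: float = 3.0,
                     dedup_s: float = 2.0) -> list[tuple[float, float]]:
    """Detect Up-state onsets on a detection-band trace.

    Parameters
    ----------
    trace : ndarray
        Single-channel trace in µV, already band-passed to the detection band.
    fs : float
        Sampling rate of ``trace``. ``min_distance_samples`` is interpreted at
        this rate (callers converting from the 763 Hz reference should use
        :meth:`AnalysisConfig.min_peak_distance_for`).

    Returns
    -------
    list of (onset_s, peak_amplitude_uv)
        Sorted onsets; amplitudes keep the negative sign of the trough.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < min_distance_samples:
        warnings.warn("trace shorter than the minimum peak distance; no onsets")
        return []
    sd = trace.std()
    if sd == 0:
        return []
    neg = -trace
    peaks, props = signal.find_peaks(neg, prominence=prominence_sd * sd)
    if len(peaks) == 0:
        return []
    keep = _distance_select(peaks, neg[peaks], min_distance_samples)
    peaks = peaks[keep]
    times = peaks / fs
    keep2 = _dedup_preceding(times, dedup_s)
    peaks = peaks[keep2]
    return [(i / fs, float(trace[i])) for i in peaks]


def detect_up_threshold(trace: np.ndarray, fs: float, threshold_uv: float = 100.0,
                        refractory_s: float = 2.0,
                        report: str = "peak") -> list[tuple[float, float]]:
    """Fixed-threshold detector: downward crossings of −threshold.

    Crossings within ``refractory_s`` of a retained crossing are suppressed.
    With ``report="peak"`` (default) the returned time is the trace minimum
    within the refractory window after each crossing, so both detectors
    report the same landmark (the negative onset peak) and their onset sets
    are directly comparable; ``report="crossing"`` returns the raw crossing
    time. The amplitude is the trough minimum either way.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    if report not in ("peak", "crossing"):
        raise ValueError("report must be 'peak' or 'crossing'")
    trace = np.asarray(trace, dtype=float)
    below = trace <= -threshold_uv
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below[0]:
        crossings = np.insert(crossings, 0, 0)
    out: list[tuple[float, float]] = []
    last = -np.inf
    ref_n = max(1, int(round(refractory_s * fs)))
    for i in crossings:
        t = i / fs
        if t - last < refractory_s:
            continue
        j = i + int(np.argmin(trace[i:i + ref_n]))
        amp = float(trace[j])
        out.append((j / fs if report == "peak" else t, amp))
        last = t
    return out


def classify_onsets(onsets: list[tuple[float, float]], events: EventTable,
                    window_ms: tuple[float, float] = (100.0, 500.0),
                    trigger_kinds: frozenset[str] | set[str] = frozenset({"DEV"}),
                    detection_channel: str = "mPFC-L",
                    dedup_s: float | None = 2.0) -> UpStateTable:
    """Label detected onsets as deviant-evoked or spontaneous.

    An onset is evoked iff some trigger event ``e`` satisfies
    ``window_ms[0] <= (onset - e) * 1000 <= window_ms[1]`` (closed window,
    default 100–500 ms); the most recent qualifying event wins when two
    qualify. ``trigger_kinds`` may be ``{"OMIS"}`` or ``{"POST"}`` for the
    omission analyses.
    """
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    trig_idx = np.flatnonzero(events.df["kind"].isin(set(trigger_kinds)).to_numpy())
    trig_t = events.df["onset_s"].to_numpy()[trig_idx]
    rows = []
    for onset, amp in onsets:
        dt = onset - trig_t
        q = np.flatnonzero((dt >= lo - _EPS) & (dt <= hi + _EPS))
        if len(q):
            j = q[np.argmax(trig_t[q])]  # most recent qualifying event
            rows.append((onset, amp, "evoked", int(trig_idx[j])))
        else:
            rows.append((onset, amp, "spontaneous", -1))
    df = pd.DataFrame(rows, columns=["onset_s", "peak_amplitude_uv", "cls",
                                     "trigger_index"])
    df["detection_channel"] = detection_channel
    return UpStateTable(df, min_spacing_s=dedup_s)


def evoked_fraction(up_table: UpStateTable, events: EventTable,
                    trigger_kinds: frozenset[str] | set[str] = frozenset({"DEV"})) -> float:
    """Percentage of trigger events followed by a linked evoked Up state."""
    trig_idx = np.flatnonzero(events.df["kind"].isin(set(trigger_kinds)).to_numpy())
    if len(trig_idx) == 0:
        raise ValueError("no trigger events; evoked fraction undefined")
    linked = set(up_table.df.loc[up_table.df["cls"] == "evoked", "trigger_index"])
    n_hit = sum(1 for i in trig_idx if int(i) in linked)
    return 100.0 * n_hit / len(trig_idx)


def detect_and_classify(trace: np.ndarray, fs: float, events: EventTable,
                        config: AnalysisConfig | None = None,
                        trigger_kinds: frozenset[str] | set[str] = frozenset({"DEV"}),
                        ) -> UpStateTable:
    """Convenience wrapper: detect on a detection-band trace, then classify."""
    cfg = config or AnalysisConfig()
    onsets = detect_up_onsets(
        trace, fs,
        min_distance_samples=cfg.min_peak_distance_for(fs),
        prominence_sd=cfg.prominence_sd,
        dedup_s=cfg.dedup_s,
    )
    return classify_onsets(onsets, events, cfg.evoked_window_ms, trigger_kinds,
                           cfg.detection_channel, cfg.dedup_s)
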