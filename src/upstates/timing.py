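"""Refractory-period analyses and hazard modelling of Up-state initiation.

A deviant is less likely to evoke an Up state the more recently a previous
Up state occurred. Two complementary analyses quantify this: (1) a two-sided
Wilcoxon rank-sum test comparing time-since-previous-Up between deviants
that did and did not evoke an Up state (mid-ranks, tie-corrected normal
approximation with continuity correction), and (2) a Cox proportional-hazards
regression on the clock "time since the last Up onset" with a time-varying
covariate marking exposure to a deviant's 100–500 ms triggering window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import EventTable, UpStateTable

__all__ = [
    "IntervalRecord",
    "build_intervals",
    "records_to_frame",
    "refractory_test",
    "RefractoryResult",
    "build_hazard_data",
    "cox_up_hazard",
    "CoxResult",
]


@dataclass
class IntervalRecord:
    """Timing context of one deviant trial or one Up onset."""

    event_index: int
    t_since_prev_up_s: float
    t_since_prev_dev_s: float
    outcome: str | None        # 'evoked'/'failed' for deviant trials, else None
    origin: str                # 'dev_trial' or 'spontaneous_up'
    cls: str | None = None     # Up class for origin='spontaneous_up' rows


def build_intervals(up_table: UpStateTable, events: EventTable,
                    trigger_kinds: frozenset[str] | set[str] = frozenset({"DEV"}),
                    evoked_window_ms: tuple[float, float] = (100.0, 500.0),
                    ) -> list[IntervalRecord]:
    """Per-deviant and per-Up timing records.

    For each deviant: the time since the previous Up onset — excluding any Up
    inside that deviant's own triggering window, so the outcome cannot leak
    into its own predictor — the time since the previous deviant, and whether
    it evoked an Up. For each Up onset: the time since the previous Up and
    its class. Events with no predecessor are dropped (and simply absent).
    """
    lo, hi = evoked_window_ms[0] / 1000.0, evoked_window_ms[1] / 1000.0
    up_t = up_table.onset_s
    up_cls = up_table.df["cls"].to_numpy()
    trig_idx = np.flatnonzero(events.df["kind"].isin(set(trigger_kinds)).to_numpy())
    trig_t = events.df["onset_s"].to_numpy()[trig_idx]
    linked = up_table.df.loc[up_table.df["cls"] == "evoked", "trigger_index"]
    linked = set(int(i) for i in linked)

    records: list[IntervalRecord] = []
    for j, (ei, t_dev) in enumerate(zip(trig_idx, trig_t)):
        dt = t_dev - up_t
        own = (up_t - t_dev >= lo - 1e-9) & (up_t - t_dev <= hi + 1e-9)
        prev = np.flatnonzero((dt > 0) & ~own)
        if len(prev) == 0:
            continue  # no previous Up: dropped
        records.append(IntervalRecord(
            event_index=int(ei),
            t_since_prev_up_s=float(dt[prev[-1]]),
            t_since_prev_dev_s=float(t_dev - trig_t[j - 1]) if j > 0 else np.nan,
            outcome="evoked" if int(ei) in linked else "failed",
            origin="dev_trial",
        ))
    for k in range(1, len(up_t)):
        dt_dev = up_t[k] - trig_t[trig_t < up_t[k]]
        records.append(IntervalRecord(
            event_index=-1,
            t_since_prev_up_s=float(up_t[k] - up_t[k - 1]),
            t_since_prev_dev_s=float(dt_dev[-1]) if len(dt_dev) else np.nan,
            outcome=None,
            origin="spontaneous_up",
            cls=str(up_cls[k]),
        ))
    return records


def records_to_frame(records: list[IntervalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum Z with mid-ranks, tie correction and continuity."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # mid-ranks
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n1 * n2 * (n + 1) / 12.0 - n1 * n2 * tie / (12.0 * n * (n - 1))
    if var <= 0:
        return 0.0, 1.0
    d = w - mu
    d -= np.sign(d) * 0.5                   # continuity correction
    z = d / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass
class RefractoryResult:
    z: float
    p: float
    n: dict[str, int]
    cdf: dict[str, tuple[np.ndarray, np.ndarray]]   # label -> (sorted x, F(x))


def refractory_test(records: list[IntervalRecord],
                    groups: tuple[str, str] = ("evoked", "failed")) -> RefractoryResult:
    """Rank-sum test of time-since-previous-Up between two outcome groups.

    ``groups`` may be ``("evoked", "failed")`` (deviant trials) or
    ``("evoked", "spontaneous")`` (Up onsets by class, for the entrainment
    control). Empirical CDFs of both groups are returned for plotting.
    """
    by_outcome = "failed" in groups   # deviant trials; else Up onsets by class

    def _pick(name: str) -> np.ndarray:
        if by_outcome:
            sel = [r for r in records if r.origin == "dev_trial" and r.outcome == name]
        else:
            sel = [r for r in records if r.origin == "spontaneous_up" and r.cls == name]
        return np.array([r.t_since_prev_up_s for r in sel])

    a, b = _pick(groups[0]), _pick(groups[1])
    if len(a) < 5 or len(b) < 5:
        raise ValueError(f"need >= 5 records per group, have {len(a)} and {len(b)}")
    z, p = _ranksum_z(a, b)
    cdf = {}
    for name, v in zip(groups, (a, b)):
        xs = np.sort(v)
        cdf[name] = (xs, np.arange(1, len(xs) + 1) / len(xs))
    return RefractoryResult(z, p, {groups[0]: len(a), groups[1]: len(b)}, cdf)


def build_hazard_data(up_table: UpStateTable, events: EventTable,
                      trigger_kinds: frozenset[str] | set[str] = frozenset({"DEV"}),
                      bin_s: float = 0.05,
                      exposure_window_s: tuple[float, float] = (0.1, 0.5),
                      session_duration_s: float | None = None) -> pd.DataFrame:
    """Risk intervals on the clock "time since last Up onset".

    Each inter-Up gap is one episode starting at clock 0 at an Up onset and
    ending (event=1) at the next Up onset. Time is discretised in 50 ms bins;
    a bin is exposed (``dev=1``) when it falls inside some deviant's 100–500 ms
    triggering window. Runs of bins with constant exposure are merged into
    single (start, stop] intervals, which leaves the Cox partial likelihood
    unchanged.
    """
    up_t = up_table.onset_s
    if len(up_t) < 2:
        raise ValueError("need at least two Up onsets to form risk intervals")
    trig_t = events.onsets(trigger_kinds)
    rows = []
    for ep, (t0, t1) in enumerate(zip(up_t[:-1], up_t[1:])):
        n_bins = int(np.ceil((t1 - t0) / bin_s))
        if n_bins == 0:
            continue
        starts = t0 + np.arange(n_bins) * bin_s
        stops = np.minimum(starts + bin_s, t1)
        mids = (starts + stops) / 2.0
        exposed = np.zeros(n_bins, dtype=bool)
        for td in trig_t:
            exposed |= (mids >= td + exposure_window_s[0]) & (mids < td + exposure_window_s[1])
        # merge constant-exposure runs
        change = np.flatnonzero(np.diff(exposed.astype(int))) + 1
        seg_bounds = np.concatenate([[0], change, [n_bins]])
        for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
            rows.append({
                "id": ep,
                "start": starts[a] - t0,
                "stop": stops[b - 1] - t0,
                "dev": int(exposed[a]),
                "event": int(b == n_bins),
            })
    df = pd.DataFrame(rows)
    if df.empty or df["dev"].sum() == 0:
        raise ValueError("degenerate design: no deviant exposure in any risk interval")
    return df


@dataclass
class CoxResult:
    beta: float
    se: float
    p: float
    n_events: int


def cox_up_hazard(hazard_data: pd.DataFrame, penalizer: float = 0.01) -> CoxResult:
    """Cox PH estimate of the deviant-exposure effect on Up-initiation hazard.

    Fits the time-varying model on the (start, stop] risk intervals from
    :func:`build_hazard_data`; a positive ``beta`` means deviants increase the
    probability of initiating an Up state beyond what inter-Up timing alone
    predicts. The small ridge ``penalizer`` keeps the fit defined when the
    evocation effect is strong enough to quasi-separate exposed bins.
    """
    n_events = int(hazard_data["event"].sum())
    if n_events < 10:
        raise ValueError(f"need >= 10 Up-initiation events, have {n_events}")
    if hazard_data["dev"].nunique() < 2:
        raise ValueError("degenerate design: deviant exposure is constant")
    from lifelines import CoxTimeVaryingFitter
    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    ctv.fit(hazard_data, id_col="id", start_col="start", stop_col="stop",
            event_col="event", formula="dev")
    s = ctv.summary.loc["dev"]
    return CoxResult(float(s["coef"]), float(s["se(coef)"]), float(s["p"]), n_events)
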