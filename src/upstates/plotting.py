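"""Quick-look figures: session trace with detected onsets, synchrogram, ERPs."""

from __future__ import annotations

import numpy as np

from .evoked import PartitionResult
from .synchrony import Synchrogram
from .types import Recording, UpStateTable

__all__ = ["plot_session", "plot_synchrogram", "plot_partition"]


def plot_session(rec: Recording, ups: UpStateTable | None = None,
                 t_range_s: tuple[float, float] | None = None, ax=None):
    """Stacked channel traces with Up-state onsets marked."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.2 * rec.n_channels))
    t = rec.times
    sel = slice(None) if t_range_s is None else slice(
        int(t_range_s[0] * rec.fs), int(t_range_s[1] * rec.fs))
    spread = 3 * rec.samples.std() or 1.0
    for c, lab in enumerate(rec.channel_labels):
        ax.plot(t[sel], rec.samples[c, sel] - c * spread, lw=0.5, label=lab)
    if ups is not None and len(ups):
        colors = {"spontaneous": "k", "evoked": "g"}
        for cls, sub in ups.df.groupby("cls"):
            on = sub.onset_s.to_numpy()
            if t_range_s is not None:
                on = on[(on >= t_range_s[0]) & (on <= t_range_s[1])]
            ax.plot(on, np.zeros_like(on) + spread / 2, "v",
                    color=colors.get(cls, "r"), label=f"{cls} Up")
    ax.set_xlabel("time (s)")
    ax.set_yticks([])
    ax.legend(loc="upper right", fontsize="x-small", ncol=2)
    return ax


def plot_synchrogram(sg: Synchrogram, ax=None):
    """Lag histogram with the shuffle-null band (mean ± 3 SD) when present."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    c = sg.lag_bin_centers_ms
    ax.bar(c, sg.rate, width=np.diff(sg.lag_bin_edges_ms), color="C0",
           label="observed")
    if sg.null_mean is not None:
        ax.plot(c, sg.null_mean, "k-", lw=1, label="null mean")
        ax.fill_between(c, sg.null_mean - 3 * sg.null_sd,
                        sg.null_mean + 3 * sg.null_sd, color="k", alpha=0.15,
                        label="null ± 3 SD")
    if np.isfinite(sg.peak_lag_ms):
        ax.axvline(sg.peak_lag_ms, color="r", ls="--", lw=1)
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("Up onsets per event")
    ax.legend(fontsize="x-small")
    return ax


def plot_partition(part: PartitionResult, ax=None):
    """Mean ± 95 % CI per condition with the pointwise significance bar."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for lab in part.labels:
        m, ci = part.mean[lab], part.ci_halfwidth[lab]
        line, = ax.plot(part.times_ms, m, label=f"{lab} (n={part.n[lab]})")
        ax.fill_between(part.times_ms, m - ci, m + ci, alpha=0.25,
                        color=line.get_color())
    y = ax.get_ylim()[0]
    ax.plot(part.times_ms[part.sig_mask], np.full(part.sig_mask.sum(), y), "k.",
            ms=2, label="p < 0.05")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus (ms)")
    ax.set_ylabel("LFP (µV)")
    ax.legend(fontsize="x-small")
    return ax
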