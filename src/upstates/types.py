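"""Core domain types: recordings, event tables, Up-state tables, analysis config.

Conventions used throughout the package:

* time base is seconds, session-relative, ``t0 = 0``; sample index 0-based
* potentials are microvolts (µV) everywhere in memory; the fixed depth-mode
  threshold of 0.1 mV is converted to 100 µV at config load
* windows are half-open ``[lo, hi)`` in ms except the evoked-classification
  window, which is closed ``[100, 500]`` ms (the inclusive phrasing
  "100–500 ms after a DEV")
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "UP_CLASSES",
    "DEFAULT_CHANNELS",
    "Recording",
    "EventTable",
    "UpStateTable",
    "AnalysisConfig",
    "BandSet",
    "DataError",
    "FormatError",
]

#: Stimulus kinds: standard, deviant, many-standards tone, omission, and the
#: first standard following an omission.
EVENT_KINDS = ("STD", "DEV", "MS", "OMIS", "POST")
UP_CLASSES = ("spontaneous", "evoked")

#: Electrode montage of the six-channel ECoG array (labels only; positions are
#: deliberately not modelled — cross-channel analyses are label-based).
DEFAULT_CHANNELS = (
    "mPFC-L",
    "mPFC-R",
    "AC-L-rostral",
    "AC-L-caudal",
    "AC-R-rostral",
    "AC-R-caudal",
)


class DataError(ValueError):
    """Raised when data content violates a type invariant."""


class FormatError(ValueError):
    """Raised when a file is structurally missing required fields."""


@dataclass
class Recording:
    """Multichannel continuous ECoG/LFP potential.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Potential in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique, ordered channel names.
    channel_delay_truth_ms : ndarray or None
        Per-channel traveling-wave propagation delay in ms (synthetic ground
        truth only; absent for real data).
    t0 : float
        Session start time in seconds (0 by convention).
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    channel_delay_truth_ms: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D [n_channels x n_samples] array")
        if not self.fs > 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise DataError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        if self.channel_delay_truth_ms is not None:
            self.channel_delay_truth_ms = np.asarray(self.channel_delay_truth_ms, float)
            if self.channel_delay_truth_ms.shape != (self.n_channels,):
                raise DataError("channel_delay_truth_ms must have one entry per channel")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (session-relative)."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's trace by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}; have {self.channel_labels}") from None
        return self.samples[idx]


EVENT_COLUMNS = ["onset_s", "kind", "freq_hz", "duration_ms", "level_db", "block"]


class EventTable:
    """Stimulus/omission event table.

    Thin validating wrapper around a :class:`pandas.DataFrame` with columns
    ``onset_s, kind, freq_hz, duration_ms, level_db, block``. Onsets must be
    strictly increasing within each block; ``OMIS`` rows carry no frequency.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"event table missing columns: {missing}")
        df = df.loc[:, EVENT_COLUMNS].reset_index(drop=True)
        df["onset_s"] = df["onset_s"].astype(float)
        df["kind"] = df["kind"].astype(str)
        bad = sorted(set(df["kind"]) - set(EVENT_KINDS))
        if bad:
            raise DataError(f"unknown event kind(s) {bad}; expected one of {EVENT_KINDS}")
        for block, sub in df.groupby("block", sort=False):
            d = np.diff(sub["onset_s"].to_numpy())
            if len(d) and not np.all(d > 0):
                raise DataError(f"onsets not strictly increasing within block {block!r}")
        omis = df["kind"] == "OMIS"
        if omis.any() and df.loc[omis, "freq_hz"].notna().any():
            raise DataError("OMIS events must not carry a tone frequency")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def onsets(self, kinds: Iterable[str] | None = None) -> np.ndarray:
        """Onset times (s) of events, optionally restricted to the given kinds."""
        if kinds is None:
            return self.df["onset_s"].to_numpy()
        kinds = set(kinds)
        return self.df.loc[self.df["kind"].isin(kinds), "onset_s"].to_numpy()

    def subset(self, kinds: Iterable[str]) -> "EventTable":
        return EventTable(self.df[self.df["kind"].isin(set(kinds))].reset_index(drop=True))


UPSTATE_COLUMNS = ["onset_s", "peak_amplitude_uv", "cls", "trigger_index", "detection_channel"]


class UpStateTable:
    """Detected Up-state onsets with evoked/spontaneous class and trigger links.

    ``trigger_index`` indexes into the session's :class:`EventTable` for
    evoked entries and is ``-1`` (NA) for spontaneous ones. Onsets are strictly
    increasing; consecutive onsets are at least ``dedup_s`` apart after the
    detector's deduplication (checked with the default 2 s unless relaxed).
    """

    def __init__(self, df: pd.DataFrame, min_spacing_s: float | None = 2.0):
        missing = [c for c in UPSTATE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"up-state table missing columns: {missing}")
        df = df.loc[:, UPSTATE_COLUMNS].reset_index(drop=True)
        df["onset_s"] = df["onset_s"].astype(float)
        df["peak_amplitude_uv"] = df["peak_amplitude_uv"].astype(float)
        df["cls"] = df["cls"].astype(str)
        df["trigger_index"] = df["trigger_index"].fillna(-1).astype(int)
        bad = sorted(set(df["cls"]) - set(UP_CLASSES))
        if bad:
            raise DataError(f"unknown up-state class(es) {bad}")
        d = np.diff(df["onset_s"].to_numpy())
        if len(d) and not np.all(d > 0):
            raise DataError("up-state onsets must be strictly increasing")
        if min_spacing_s is not None and len(d) and d.min() < min_spacing_s - 1e-9:
            raise DataError(
                f"consecutive onsets {d.min():.3f} s apart; expected >= {min_spacing_s} s"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, UpStateTable) and self.df.equals(other.df)

    @property
    def onset_s(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy()

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.df[self.df["cls"] == cls]


@dataclass
class BandSet:
    """Named oscillatory analysis bands (Hz): delta through high gamma."""

    bands: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (2.0, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 14.0),
            "beta": (14.0, 30.0),
            "low_gamma": (30.0, 70.0),
            "high_gamma": (70.0, 150.0),
        }
    )

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi) in edges:
            if not 0 < lo < hi:
                raise DataError(f"invalid band ({lo}, {hi})")
        for (a, b), (c, d) in zip(edges, edges[1:]):
            if c < b:  # shared edges allowed, overlap not
                raise DataError(f"bands ({a},{b}) and ({c},{d}) overlap")

    def validate_against_fs(self, fs: float) -> None:
        for name, (lo, hi) in self.bands.items():
            if hi >= fs / 2:
                raise DataError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist for fs={fs}")

    def items(self):
        return self.bands.items()


@dataclass
class AnalysisConfig:
    """Analysis parameters; defaults are the published values.

    Notes
    -----
    ``min_peak_distance_samples = 382`` is specified in samples at the 763 Hz
    working rate (≈ 0.5007 s) and is rescaled when a trace at a different rate
    is analysed. The fixed depth-mode threshold is 0.1 mV = 100 µV.
    """

    detection_band_hz: tuple[float, float] = (0.1, 10.0)
    lfp_band_hz: tuple[float, float] = (0.1, 1.0)
    oscillation_band_hz: tuple[float, float] = (0.1, 150.0)
    filter_order: int = 8
    working_fs_hz: float = 763.0
    min_peak_distance_samples: int = 382
    prominence_sd: float = 3.0
    dedup_s: float = 2.0
    evoked_window_ms: tuple[float, float] = (100.0, 500.0)
    synchrony_bin_ms: float = 50.0
    synchrony_lag_range_ms: tuple[float, float] = (-1000.0, 1000.0)
    synchrony_total_window_ms: float = 250.0
    shuffle_iterations: int = 100
    shuffle_offset_range_ms: tuple[float, float] = (-1000.0, 1000.0)
    shuffle_step_ms: float = 100.0
    rms_window_ms: tuple[float, float] = (0.0, 500.0)
    fixed_threshold_uv: float = 100.0
    detection_channel: str = "mPFC-L"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_band_hz", "lfp_band_hz", "oscillation_band_hz",
                     "evoked_window_ms", "synchrony_lag_range_ms",
                     "shuffle_offset_range_ms", "rms_window_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise DataError(f"{name} must be well-ordered, got ({lo}, {hi})")
        if self.fixed_threshold_uv <= 0:
            raise DataError("fixed_threshold_uv must be positive")

    def min_peak_distance_for(self, fs: float) -> int:
        """Minimum peak distance in samples at rate ``fs``."""
        return max(1, int(round(self.min_peak_distance_samples * fs / self.working_fs_hz)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "fixed_threshold_mv" in d:  # external configs may state mV
            d["fixed_threshold_uv"] = float(d.pop("fixed_threshold_mv")) * 1000.0
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown analysis-config keys: {sorted(unknown)}")
        for name in known:
            if name in d and isinstance(cls.__dataclass_fields__[name].default, tuple):
                d[name] = tuple(d[name])
        return cls(**d)
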