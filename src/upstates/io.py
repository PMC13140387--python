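"""Readers/writers for recordings (HDF5), event and Up-state tables (CSV), config (YAML).

Container layout for signals::

    /samples                 float32 [n_channels x n_samples], µV
    /channel_delay_truth_ms  optional float array (synthetic ground truth)
    attrs: fs (Hz), channel_labels (string array), t0 (s)
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    AnalysisConfig,
    DataError,
    EventTable,
    FormatError,
    Recording,
    UpStateTable,
    EVENT_COLUMNS,
    UPSTATE_COLUMNS,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_upstates",
    "write_upstates",
    "read_config",
    "write_config",
]


def write_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples.astype(np.float32))
        f.attrs["fs"] = float(rec.fs)
        f.attrs["t0"] = float(rec.t0)
        f.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        if rec.channel_delay_truth_ms is not None:
            f.create_dataset("channel_delay_truth_ms", data=rec.channel_delay_truth_ms)


def read_recording(path: str | Path) -> Recording:
    """Read a Recording from the HDF5 container; µV units, fs from file."""
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise FormatError(f"{path}: missing dataset 'samples'")
        for attr in ("fs", "channel_labels"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr!r}")
        samples = np.asarray(f["samples"], dtype=float)
        if not np.all(np.isfinite(samples)):
            raise DataError(f"{path}: samples contain non-finite values")
        labels = [c.decode() if isinstance(c, bytes) else str(c) for c in f.attrs["channel_labels"]]
        delays = None
        if "channel_delay_truth_ms" in f:
            delays = np.asarray(f["channel_delay_truth_ms"], dtype=float)
        return Recording(
            samples=samples,
            fs=float(f.attrs["fs"]),
            channel_labels=labels,
            channel_delay_truth_ms=delays,
            t0=float(f.attrs.get("t0", 0.0)),
        )


def write_events(table: EventTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: event CSV missing columns {missing}")
    return EventTable(df)


def write_upstates(table: UpStateTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_upstates(path: str | Path, min_spacing_s: float | None = 2.0) -> UpStateTable:
    df = pd.read_csv(path)
    missing = [c for c in UPSTATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: up-state CSV missing columns {missing}")
    return UpStateTable(df, min_spacing_s=min_spacing_s)


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    d = config.to_dict()
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: str | Path) -> AnalysisConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise FormatError(f"{path}: config YAML must be a mapping")
    return AnalysisConfig.from_dict(d)
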