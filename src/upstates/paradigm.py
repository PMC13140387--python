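"""Stimulus sequence generation: oddball, flip-flop, many-standards, omission paradigms.

All onsets lie on the SOA grid. Deviant (or omission) placement is
pseudo-random subject to inter-deviant interval bounds, mirroring the
constrained randomisation used for auditory oddball presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import EventTable

__all__ = ["ParadigmSpec", "GenerationError", "generate_sequence"]

PARADIGMS = ("oddball", "classic_oddball", "flipflop", "many_standards", "omission")


class GenerationError(RuntimeError):
    """Raised when a sequence satisfying the interval constraints cannot be found."""


@dataclass
class ParadigmSpec:
    """Parameters of one stimulation block family.

    Defaults are the fast oddball used for the primary analyses: 250 ms SOA,
    6.45 % deviant probability, 620 stimuli (40 deviants over 155 s),
    inter-deviant interval 3–4.75 s, 10 kHz standard vs 14.142 kHz deviant,
    75 ms tones at 60 dB SPL.
    """

    paradigm: str = "oddball"
    soa_ms: float = 250.0
    tone_duration_ms: float = 75.0
    dev_probability: float = 0.0645
    inter_dev_interval_s: tuple[float, float] | None = (3.0, 4.75)
    freq_std_hz: float = 10000.0
    freq_dev_hz: float = 14142.0
    n_stimuli: int = 620
    level_db: float = 60.0

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}; expected one of {PARADIGMS}")
        if not 0 <= self.dev_probability < 1:
            raise ValueError("dev_probability must be in [0, 1)")
        if self.n_stimuli < 0:
            raise ValueError("n_stimuli must be non-negative")
        if self.inter_dev_interval_s is not None:
            lo, hi = self.inter_dev_interval_s
            soa = self.soa_ms / 1000.0
            if math.ceil(lo / soa) > math.floor(hi / soa):
                raise ValueError(
                    f"no SOA multiple lies in the inter-deviant interval ({lo}, {hi}) s"
                )

    @classmethod
    def classic_oddball(cls, **kw) -> "ParadigmSpec":
        """Classical oddball: 500 ms SOA, 10 % deviants, mean inter-deviant 5 s."""
        defaults = dict(
            paradigm="classic_oddball", soa_ms=500.0, dev_probability=0.10,
            inter_dev_interval_s=(3.0, 7.0), n_stimuli=620,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def omission(cls, soa_ms: float = 250.0, **kw) -> "ParadigmSpec":
        """Omission paradigm; interval bounds follow the SOA variant."""
        interval = (3.0, 4.75) if soa_ms >= 200 else (1.5, 2.375)
        defaults = dict(
            paradigm="omission", soa_ms=soa_ms, dev_probability=0.0645,
            inter_dev_interval_s=interval, n_stimuli=620,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def many_standards(cls, **kw) -> "ParadigmSpec":
        defaults = dict(paradigm="many_standards", dev_probability=0.0,
                        inter_dev_interval_s=None)
        defaults.update(kw)
        return cls(**defaults)


def _place_deviants(spec: ParadigmSpec, rng: np.random.Generator,
                    max_tries: int = 5000) -> np.ndarray:
    """Grid indices of deviant slots, gaps constrained to the interval bounds."""
    n = spec.n_stimuli
    n_dev = int(round(spec.dev_probability * n))
    if n_dev == 0:
        return np.empty(0, dtype=int)
    soa = spec.soa_ms / 1000.0
    if spec.inter_dev_interval_s is None:
        # unconstrained: any slots, no two adjacent
        for _ in range(max_tries):
            idx = np.sort(rng.choice(np.arange(1, n), size=n_dev, replace=False))
            if n_dev == 1 or np.diff(idx).min() >= 2:
                return idx
        raise GenerationError("could not place deviants without adjacency")
    lo, hi = spec.inter_dev_interval_s
    k_lo = math.ceil(lo / soa - 1e-9)
    k_hi = math.floor(hi / soa + 1e-9)
    if n_dev * k_lo > n - 1:
        raise GenerationError(
            f"{n_dev} deviants with minimum gap {k_lo} slots do not fit in {n} stimuli"
        )
    for _ in range(max_tries):
        gaps = rng.integers(k_lo, k_hi + 1, size=n_dev)
        idx = np.cumsum(gaps)
        if idx[-1] <= n - 1:
            return idx
    raise GenerationError(
        f"no deviant placement found in {max_tries} tries "
        f"(n={n}, n_dev={n_dev}, gap range [{k_lo}, {k_hi}] slots)"
    )


def _tone_set(spec: ParadigmSpec, size: int = 10) -> np.ndarray:
    """Half-octave ladder of `size` tones starting at the standard frequency.

    Includes both oddball frequencies when the deviant is half an octave above
    the standard (10 vs 14.142 kHz).
    """
    return spec.freq_std_hz * 2.0 ** (np.arange(size) / 2.0)


def generate_sequence(spec: ParadigmSpec, seed: int | np.random.Generator = 0) -> EventTable:
    """Generate one stimulation block (or flip/flop pair) as an EventTable."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    soa = spec.soa_ms / 1000.0

    if spec.paradigm == "flipflop":
        half = ParadigmSpec(**{**spec.__dict__, "paradigm": "oddball",
                               "n_stimuli": spec.n_stimuli // 2})
        flip = generate_sequence(half, rng).df.assign(block="flip")
        flop = generate_sequence(half, rng).df
        flop["onset_s"] += half.n_stimuli * soa
        # swap standard and deviant frequencies in the second half
        flop["freq_hz"] = flop["freq_hz"].map(
            {spec.freq_std_hz: spec.freq_dev_hz, spec.freq_dev_hz: spec.freq_std_hz})
        flop = flop.assign(block="flop")
        return EventTable(pd.concat([flip, flop], ignore_index=True))

    onsets = np.arange(spec.n_stimuli) * soa
    kinds = np.full(spec.n_stimuli, "STD", dtype=object)
    freqs = np.full(spec.n_stimuli, spec.freq_std_hz, dtype=float)

    if spec.paradigm == "many_standards":
        tones = _tone_set(spec)
        kinds[:] = "MS"
        freqs = rng.choice(tones, size=spec.n_stimuli)
    else:
        dev_idx = _place_deviants(spec, rng)
        if spec.paradigm == "omission":
            kinds[dev_idx] = "OMIS"
            freqs[dev_idx] = np.nan
            post = dev_idx + 1
            post = post[post < spec.n_stimuli]
            post = post[kinds[post] == "STD"]  # the first standard after each omission
            kinds[post] = "POST"
        else:
            kinds[dev_idx] = "DEV"
            freqs[dev_idx] = spec.freq_dev_hz

    df = pd.DataFrame({
        "onset_s": onsets,
        "kind": kinds,
        "freq_hz": freqs,
        "duration_ms": spec.tone_duration_ms,
        "level_db": spec.level_db,
        "block": spec.paradigm,
    })
    return EventTable(df)
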