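"""Epoching, RMS bimodality, evoked/fail partition statistics, latency, contrasts.

The all-or-nothing character of deviant-evoked Up states shows up as a
bimodal distribution of per-trial RMS amplitudes in the 0–500 ms window
after each deviant. Bimodality is quantified with the bimodality
coefficient

    BC = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))

using the adjusted Fisher–Pearson skewness ``g1`` and the bias-corrected
excess kurtosis ``g2``; BC above 5/9 ≈ 0.555 indicates bimodality
(Gaussian → 1/3, uniform → 5/9, symmetric two-point mixture → 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import EventTable, Recording

__all__ = [
    "EpochSet",
    "BimodalityResult",
    "PartitionResult",
    "epoch",
    "epoch_rms",
    "bimodality_stats",
    "partition_mean_ci",
    "response_latency",
    "condition_contrast",
]

BIMODALITY_THRESHOLD = 5.0 / 9.0


@dataclass
class EpochSet:
    """Per-channel stacks of peri-event snippets.

    ``data[label]`` is an ``[n_trials x n_samples]`` array in µV; all epochs
    are full length (trials truncated by the session edges are dropped and
    counted in ``n_dropped``).
    """

    data: dict[str, np.ndarray]
    fs: float
    window_ms: tuple[float, float]
    event_indices: np.ndarray
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = next(iter(self.data.values())).shape[1]
        return self.window_ms[0] + np.arange(n) / self.fs * 1000.0

    def channel(self, label: str | None = None) -> np.ndarray:
        if label is None:
            label = next(iter(self.data))
        return self.data[label]


def epoch(rec: Recording, events: EventTable | np.ndarray,
          window_ms: tuple[float, float] = (-100.0, 1000.0),
          baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
          kinds: set[str] | None = None) -> EpochSet:
    """Cut peri-event epochs from every channel.

    ``events`` may be an EventTable (optionally filtered by ``kinds``) or a
    plain array of onset times in seconds. Baseline correction subtracts each
    trial's mean over ``baseline_ms`` (pass ``None`` to disable).
    """
    if isinstance(events, EventTable):
        if kinds is not None:
            idx = np.flatnonzero(events.df["kind"].isin(kinds).to_numpy())
        else:
            idx = np.arange(len(events))
        onsets = events.df["onset_s"].to_numpy()[idx]
    else:
        onsets = np.asarray(events, dtype=float)
        idx = np.arange(len(onsets))
    lo_n = int(round(window_ms[0] / 1000.0 * rec.fs))
    hi_n = int(round(window_ms[1] / 1000.0 * rec.fs))
    n_samp = hi_n - lo_n
    starts = np.round(onsets * rec.fs).astype(int) + lo_n
    ok = (starts >= 0) & (starts + n_samp <= rec.n_samples)
    n_dropped = int((~ok).sum())
    starts, idx = starts[ok], idx[ok]
    if len(starts) == 0:
        raise ValueError("no events with a full epoch inside the session")
    gather = starts[:, None] + np.arange(n_samp)[None, :]
    data = {lab: rec.samples[c][gather] for c, lab in enumerate(rec.channel_labels)}
    if baseline_ms is not None:
        t_ms = window_ms[0] + np.arange(n_samp) / rec.fs * 1000.0
        bmask = (t_ms >= baseline_ms[0]) & (t_ms < baseline_ms[1])
        if not bmask.any():
            raise ValueError("baseline window outside the epoch window")
        for lab in data:
            data[lab] = data[lab] - data[lab][:, bmask].mean(axis=1, keepdims=True)
    return EpochSet(data, rec.fs, tuple(window_ms), idx, n_dropped)


def _window_mask(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    m = (times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9)
    if not m.any():
        raise ValueError(f"window {window_ms} ms outside the epoch")
    return m


def epoch_rms(epochs: EpochSet, window_ms: tuple[float, float] = (0.0, 500.0),
              channel: str | None = None) -> np.ndarray:
    """Per-trial RMS amplitude (µV) over ``window_ms``."""
    x = epochs.channel(channel)
    m = _window_mask(epochs.times_ms, window_ms)
    return np.sqrt(np.mean(x[:, m] ** 2, axis=1))


@dataclass
class BimodalityResult:
    n: int
    skewness: float            # adjusted Fisher–Pearson g1
    excess_kurtosis: float     # bias-corrected g2
    bimodality_coefficient: float
    threshold: float
    ks_stat: float             # one-sample KS of z-scored values vs N(0,1)
    ks_p: float

    @property
    def is_bimodal(self) -> bool:
        return self.bimodality_coefficient > self.threshold


def bimodality_stats(values, groups=None) -> BimodalityResult:
    """Bimodality coefficient and KS normality check of (pooled) values.

    With ``groups`` supplied (e.g. animal identity), values are z-scored
    within each group before pooling, the cross-animal normalisation used for
    group-level RMS histograms.
    """
    values = np.asarray(values, dtype=float)
    if groups is not None:
        groups = np.asarray(groups)
        out = np.empty_like(values)
        for g in np.unique(groups):
            m = groups == g
            sd = values[m].std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero variance within group {g!r}")
            out[m] = (values[m] - values[m].mean()) / sd
        values = out
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 values for the bias-corrected kurtosis")
    if values.std() == 0:
        raise ValueError("zero variance")
    g1 = float(stats.skew(values, bias=False))
    g2 = float(stats.kurtosis(values, fisher=True, bias=False))
    corr = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    bc = (g1 ** 2 + 1.0) / (g2 + corr)
    z = (values - values.mean()) / values.std(ddof=1)
    ks_stat, ks_p = stats.kstest(z, "norm")
    return BimodalityResult(n, g1, g2, float(bc), BIMODALITY_THRESHOLD,
                            float(ks_stat), float(ks_p))


@dataclass
class PartitionResult:
    """Per-label mean traces ± CI with a pointwise significance mask."""

    times_ms: np.ndarray
    labels: tuple[str, str]
    mean: dict[str, np.ndarray]
    ci_halfwidth: dict[str, np.ndarray]
    n: dict[str, int]
    sig_mask: np.ndarray               # pointwise two-sample t, uncorrected
    window_rms: pd.DataFrame = field(repr=False)   # trial, label, rms


def _align_to_negative_peak(x: np.ndarray) -> np.ndarray:
    """Shift each trial so its negative peak sits at the median peak index."""
    peaks = np.argmin(x, axis=1)
    target = int(np.median(peaks))
    out = np.empty_like(x)
    for i, (row, p) in enumerate(zip(x, peaks)):
        out[i] = np.roll(row, target - p)
    return out


def partition_mean_ci(trials: np.ndarray, labels, fs: float, t0_ms: float = 0.0,
                      alpha: float = 0.05,
                      rms_window_ms: tuple[float, float] = (100.0, 400.0),
                      align_to_peak: bool = False,
                      cluster_correction: bool = False,
                      n_permutations: int = 500,
                      seed: int = 0) -> PartitionResult:
    """Mean ± t-based CI per label and a pointwise two-sample t-test mask.

    ``labels`` assigns each trial to one of two conditions (e.g. evoked vs
    fail, or spontaneous vs evoked). By default the mask is uncorrected at
    ``alpha``, matching how pointwise significance bars are conventionally
    drawn; ``cluster_correction`` instead keeps only clusters of contiguous
    supra-threshold samples whose t-mass exceeds the permutation null of the
    maximum cluster mass. ``align_to_peak`` aligns trials to their negative
    peaks before averaging (shape comparison of spontaneous vs evoked Up
    states).
    """
    trials = np.asarray(trials, dtype=float)
    labels = np.asarray(labels)
    names = [str(u) for u in pd.unique(labels)]
    kept = []
    for u in names:
        if (labels == u).sum() >= 2:
            kept.append(u)
        else:
            warnings.warn(f"label {u!r} has fewer than 2 trials; excluded")
    if len(kept) != 2:
        raise ValueError(f"need exactly two labels with >= 2 trials, have {kept}")
    times_ms = t0_ms + np.arange(trials.shape[1]) / fs * 1000.0
    mean, ci, n, parts = {}, {}, {}, {}
    for u in kept:
        x = trials[labels == u]
        if align_to_peak:
            x = _align_to_negative_peak(x)
        parts[u] = x
        m = x.mean(axis=0)
        sem = x.std(axis=0, ddof=1) / np.sqrt(x.shape[0])
        tcrit = stats.t.ppf(1 - alpha / 2, x.shape[0] - 1)
        mean[u], ci[u], n[u] = m, tcrit * sem, x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(parts[kept[0]], parts[kept[1]], axis=0, equal_var=True)
    sig = np.nan_to_num(p, nan=1.0) < alpha
    if cluster_correction:
        sig = _cluster_correct(parts[kept[0]], parts[kept[1]], alpha,
                               n_permutations, seed)
    wmask = _window_mask(times_ms, rms_window_ms)
    rows = []
    for u in kept:
        r = np.sqrt(np.mean(parts[u][:, wmask] ** 2, axis=1))
        rows.append(pd.DataFrame({"trial": np.arange(len(r)), "label": u, "rms": r}))
    return PartitionResult(times_ms, (kept[0], kept[1]), mean, ci, n, sig,
                           pd.concat(rows, ignore_index=True))


def _cluster_masses(t: np.ndarray, thresh: float) -> list[tuple[slice, float]]:
    above = np.abs(t) > thresh
    out = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            out.append((slice(i, j), float(np.abs(t[i:j]).sum())))
            i = j
        else:
            i += 1
    return out


def _cluster_correct(xa: np.ndarray, xb: np.ndarray, alpha: float,
                     n_permutations: int, seed: int) -> np.ndarray:
    """Cluster-mass permutation correction of the pointwise t-test mask."""
    rng = np.random.default_rng(seed)
    na = xa.shape[0]
    pooled = np.vstack([xa, xb])
    thresh = stats.t.ppf(1 - alpha / 2, na + xb.shape[0] - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs, _ = stats.ttest_ind(xa, xb, axis=0, equal_var=True)
    t_obs = np.nan_to_num(t_obs)
    null_max = np.empty(n_permutations)
    for k in range(n_permutations):
        idx = rng.permutation(pooled.shape[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm, _ = stats.ttest_ind(pooled[idx[:na]], pooled[idx[na:]],
                                        axis=0, equal_var=True)
        masses = [m for _, m in _cluster_masses(np.nan_to_num(t_perm), thresh)]
        null_max[k] = max(masses, default=0.0)
    crit = np.quantile(null_max, 1 - alpha)
    sig = np.zeros(xa.shape[1], dtype=bool)
    for sl, mass in _cluster_masses(t_obs, thresh):
        if mass > crit:
            sig[sl] = True
    return sig


def response_latency(trials: np.ndarray, fs: float, t0_ms: float = 0.0,
                     alpha: float = 0.05, sustain_ms: float = 13.0) -> float | None:
    """Onset latency: first time >= 0 with a sustained departure from zero.

    A pointwise one-sample t-test is run per sample; the latency is the start
    of the first run of ``p < alpha`` lasting at least ``sustain_ms``
    (10 samples at 763 Hz). Returns ``None`` when no such run exists —
    absence of a response is a valid outcome.
    """
    trials = np.asarray(trials, dtype=float)
    times_ms = t0_ms + np.arange(trials.shape[1]) / fs * 1000.0
    post = times_ms >= 0
    x = trials[:, post]
    t_ms = times_ms[post]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_1samp(x, 0.0, axis=0)
    sig = np.nan_to_num(p, nan=1.0) < alpha
    need = max(1, int(np.ceil(sustain_ms / 1000.0 * fs)))
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= need:
            return float(t_ms[i - need + 1])
    return None


def condition_contrast(trials_a: np.ndarray, trials_b: np.ndarray, fs: float,
                       window_ms: tuple[float, float], t0_ms: float = 0.0,
                       model: str = "two_sample_t",
                       animal_a=None, animal_b=None,
                       freq_a=None, freq_b=None) -> tuple[float, float]:
    """Compare per-trial window RMS between two conditions.

    ``two_sample_t`` is an unpaired pooled-variance t-test on the per-trial
    RMS over ``window_ms``. ``mixed_model`` fits a linear mixed-effects model
    (REML) with condition as the fixed effect, random intercepts per animal,
    and a tone-frequency variance component when frequencies are supplied;
    trial-level variation is the residual. Returns the fixed-effect Wald F
    (z²) and its p-value for the mixed model, (t, p) for the t-test.
    """
    def _summ(x):
        x = np.asarray(x, dtype=float)
        times_ms = t0_ms + np.arange(x.shape[1]) / fs * 1000.0
        m = _window_mask(times_ms, window_ms)
        return np.sqrt(np.mean(x[:, m] ** 2, axis=1))

    va, vb = _summ(trials_a), _summ(trials_b)
    if model == "two_sample_t":
        t, p = stats.ttest_ind(va, vb, equal_var=True)
        return float(t), float(p)
    if model != "mixed_model":
        raise ValueError(f"unknown model {model!r}")
    import statsmodels.formula.api as smf
    df = pd.DataFrame({
        "value": np.concatenate([va, vb]),
        "cond": ["A"] * len(va) + ["B"] * len(vb),
        "animal": np.concatenate([
            np.asarray(animal_a if animal_a is not None else np.zeros(len(va))),
            np.asarray(animal_b if animal_b is not None else np.zeros(len(vb)))]).astype(str),
    })
    vc = None
    if freq_a is not None and freq_b is not None:
        df["freq"] = np.concatenate([np.asarray(freq_a), np.asarray(freq_b)]).astype(str)
        vc = {"freq": "0 + C(freq)"}
    for attempt_vc in ([vc, None] if vc is not None else [None]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("value ~ cond", df, groups=df["animal"],
                                 vc_formula=attempt_vc)
                fit = md.fit(reml=True)
            z = fit.params["cond[T.B]"] / fit.bse["cond[T.B]"]
            if np.isfinite(z):
                return float(z ** 2), float(2 * stats.norm.sf(abs(z)))
        except Exception:
            continue
    warnings.warn("mixed model failed to converge; falling back to the t-test")
    t, p = stats.ttest_ind(va, vb, equal_var=True)
    return float(t), float(p)
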