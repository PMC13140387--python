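"""Shared fixtures: synthetic sessions and the brute-force detection oracle."""

from __future__ import annotations

import numpy as np
import pytest

import upstates as u


def brute_force_up_onsets(trace, fs, min_distance_samples=382, prominence_sd=3.0,
                          dedup_s=2.0):
    """Literal O(n²) reference for Up-onset detection.

    Enumerates strict local maxima of the negated trace by scanning, computes
    topographic prominence directly from the definition, then applies the
    prominence floor, the greedy minimum-distance rule (highest peak first),
    and the preceding-2-s removal rule, each literally.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < min_distance_samples:
        return []
    sd = trace.std()
    if sd == 0:
        return []
    neg = -trace
    peaks = [i for i in range(1, n - 1) if neg[i - 1] < neg[i] > neg[i + 1]]

    def prominence(i):
        h = neg[i]
        left = 0
        for j in range(i - 1, -1, -1):
            if neg[j] > h:
                left = j + 1
                break
        left_min = neg[left:i].min() if i > left else h
        right = n
        for j in range(i + 1, n):
            if neg[j] > h:
                right = j
                break
        right_min = neg[i + 1:right].min() if right > i + 1 else h
        return h - max(left_min, right_min)

    cand = [i for i in peaks if prominence(i) >= prominence_sd * sd]
    # minimum-distance rule: highest peak wins, stable for equal heights
    order = sorted(range(len(cand)), key=lambda k: (-neg[cand[k]], k))
    alive = [True] * len(cand)
    for k in order:
        if not alive[k]:
            continue
        for m in range(len(cand)):
            if m != k and abs(cand[m] - cand[k]) < min_distance_samples:
                alive[m] = False
    kept = [cand[k] for k in range(len(cand)) if alive[k]]
    # preceding-2-s rule against the full candidate list (removal chains)
    final = [i for i in kept
             if not any(0 < (i - j) / fs <= dedup_s + 1e-9 for j in kept)]
    return [(i / fs, float(trace[i])) for i in sorted(final)]


@pytest.fixture(scope="session")
def default_session():
    """One mid-length default-parameter oddball session with ground truth."""
    events = u.generate_sequence(u.ParadigmSpec(n_stimuli=1200), seed=11)
    rec, truth = u.simulate_session(u.SimConfig(duration_s=302.0, seed=11), events)
    return rec, events, truth


@pytest.fixture(scope="session")
def detected_session(default_session):
    """Detection-band trace and classified Up-state table for the default session."""
    rec, events, truth = default_session
    det = u.bandpass(rec, 0.1, 10.0)
    trace = det.channel("mPFC-L")
    ups = u.detect_and_classify(trace, det.fs, events)
    return trace, det.fs, events, truth, ups


def match_fraction(onsets_s, truth_s, tol_s=0.1):
    """Fraction of truth onsets with a detected onset within ±tol."""
    onsets_s = np.asarray(onsets_s, dtype=float)
    truth_s = np.asarray(truth_s, dtype=float)
    if len(truth_s) == 0:
        return 1.0
    if len(onsets_s) == 0:
        return 0.0
    d = np.abs(onsets_s[:, None] - truth_s[None, :])
    return float((d.min(axis=0) <= tol_s).mean())
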