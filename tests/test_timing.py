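"""Interval construction, rank-sum refractory test, and Cox hazard model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import upstates as u
from upstates.timing import (_ranksum_z, build_hazard_data, build_intervals,
                             cox_up_hazard, records_to_frame, refractory_test)


def _ups(rows, spacing=None):
    df = pd.DataFrame(rows, columns=["onset_s", "cls", "trigger_index"])
    df["peak_amplitude_uv"] = -250.0
    df["detection_channel"] = "mPFC-L"
    return u.UpStateTable(df[["onset_s", "peak_amplitude_uv", "cls",
                              "trigger_index", "detection_channel"]],
                         min_spacing_s=spacing)


def _events(onsets, kinds):
    return u.EventTable(pd.DataFrame({
        "onset_s": onsets, "kind": kinds,
        "freq_hz": [np.nan if k == "OMIS" else 1e4 for k in kinds],
        "duration_ms": 75.0, "level_db": 60.0, "block": "b"}))


class TestBuildIntervals:
    def test_single_deviant_after_one_up(self):
        ups = _ups([(7.0, "spontaneous", -1)])
        ev = _events([10.0], ["DEV"])
        rec = [r for r in build_intervals(ups, ev) if r.origin == "dev_trial"]
        assert len(rec) == 1
        assert rec[0].t_since_prev_up_s == pytest.approx(3.0)
        assert rec[0].outcome == "failed"
        assert np.isnan(rec[0].t_since_prev_dev_s)

    def test_own_evoked_up_excluded_from_previous_up(self):
        # the Up this deviant evokes must not count as its own "previous Up"
        ups = _ups([(5.0, "spontaneous", -1), (10.2, "evoked", 1)])
        ev = _events([2.0, 10.0], ["DEV", "DEV"])
        recs = [r for r in build_intervals(ups, ev) if r.origin == "dev_trial"]
        r10 = [r for r in recs if r.event_index == 1][0]
        assert r10.t_since_prev_up_s == pytest.approx(5.0)  # the 5 s Up, not 10.2
        assert r10.outcome == "evoked"
        assert r10.t_since_prev_dev_s == pytest.approx(8.0)

    def test_deviant_with_no_previous_up_dropped(self):
        ups = _ups([(20.0, "spontaneous", -1)])
        ev = _events([10.0], ["DEV"])
        assert [r for r in build_intervals(ups, ev) if r.origin == "dev_trial"] == []

    def test_matches_brute_force_scan(self, detected_session):
        """Interval records equal an independent double-loop over sorted streams."""
        trace, fs, events, truth, ups = detected_session
        got = records_to_frame(
            [r for r in build_intervals(ups, events) if r.origin == "dev_trial"])
        up_t = ups.onset_s
        dev_rows = events.df[events.df.kind == "DEV"]
        linked = set(ups.df.loc[ups.df.cls == "evoked", "trigger_index"].astype(int))
        expect = []
        prev_dev = None
        for i, t in zip(dev_rows.index, dev_rows.onset_s):
            prior = [tu for tu in up_t
                     if tu < t or not (0.1 - 1e-9 <= tu - t <= 0.5 + 1e-9)]
            prior = [tu for tu in prior if tu < t]
            if prior:
                expect.append((int(i), t - max(prior),
                               np.nan if prev_dev is None else t - prev_dev,
                               "evoked" if int(i) in linked else "failed"))
            prev_dev = t
        assert len(got) == len(expect)
        for row, (ei, dup, ddev, out) in zip(got.itertuples(), expect):
            assert row.event_index == ei
            assert row.t_since_prev_up_s == pytest.approx(dup)
            assert row.outcome == out
            assert (np.isnan(ddev) and np.isnan(row.t_since_prev_dev_s)) or \
                row.t_since_prev_dev_s == pytest.approx(ddev)

    def test_generator_refractory_separates_outcomes(self, detected_session):
        trace, fs, events, truth, ups = detected_session
        df = records_to_frame(
            [r for r in build_intervals(ups, events) if r.origin == "dev_trial"])
        m_ev = df.loc[df.outcome == "evoked", "t_since_prev_up_s"].mean()
        m_fail = df.loc[df.outcome == "failed", "t_since_prev_up_s"].mean()
        assert m_ev > m_fail


class TestRefractoryTest:
    def test_matches_mannwhitney_normal_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(3, 1, 40), rng.normal(2.4, 1, 35)
        z, p = _ranksum_z(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        false_pos = 0
        for _ in range(200):
            x, y = rng.normal(3, 1, 30), rng.normal(3, 1, 30)
            z, p = _ranksum_z(x, y)
            false_pos += p < 0.05
        assert false_pos <= 0.1 * 200

    def test_disjoint_supports_give_maximal_z(self):
        x = np.arange(10) + 100.0
        y = np.arange(10) * 1.0
        z, p = _ranksum_z(x, y)
        n1 = n2 = 10
        var = n1 * n2 * (n1 + n2 + 1) / 12.0
        z_max = (n1 * n2 / 2.0 - 0.5) / np.sqrt(var)
        assert z == pytest.approx(z_max)
        assert p < 0.001

    def test_evoked_vs_failed_from_records(self, detected_session):
        trace, fs, events, truth, ups = detected_session
        recs = build_intervals(ups, events)
        res = refractory_test(recs)
        assert res.z > 0 and res.p < 0.05
        for name, (xs, F) in res.cdf.items():
            assert np.all(np.diff(F) >= 0) and F[-1] == 1.0

    def test_evoked_vs_spontaneous_grouping(self, detected_session):
        trace, fs, events, truth, ups = detected_session
        recs = build_intervals(ups, events)
        res = refractory_test(recs, groups=("evoked", "spontaneous"))
        assert set(res.n) == {"evoked", "spontaneous"}

    def test_empty_group_rejected(self):
        recs = build_intervals(
            _ups([(1.0, "spontaneous", -1), (8.0, "spontaneous", -1)]),
            _events([4.0], ["DEV"]))
        with pytest.raises(ValueError):
            refractory_test(recs)


class TestCoxHazard:
    def test_hand_traced_risk_intervals(self):
        ups = _ups([(0.0, "spontaneous", -1), (3.0, "spontaneous", -1)], spacing=None)
        ev = _events([1.0], ["DEV"])
        hz = build_hazard_data(ups, ev)
        assert set(hz.id) == {0}
        assert hz.stop.max() == pytest.approx(3.0)
        assert hz.event.sum() == 1
        # exposure covers 1.1–1.5 s after the Up at 0 → one exposed segment
        exp = hz[hz.dev == 1]
        assert len(exp) == 1
        assert exp.start.iloc[0] == pytest.approx(1.1, abs=0.051)
        assert exp.stop.iloc[0] == pytest.approx(1.5, abs=0.051)

    def test_degenerate_designs_rejected(self):
        ups = _ups([(0.0, "spontaneous", -1)])
        ev = _events([1.0], ["DEV"])
        with pytest.raises(ValueError):
            build_hazard_data(ups, ev)  # single Up: no interval
        ups2 = _ups([(0.0, "spontaneous", -1), (3.0, "spontaneous", -1)], spacing=None)
        ev2 = _events([100.0], ["DEV"])
        with pytest.raises(ValueError):
            build_hazard_data(ups2, ev2)  # no exposure in any interval

    def test_minimum_event_count_enforced(self):
        ups = _ups([(0.0, "spontaneous", -1), (3.0, "spontaneous", -1)], spacing=None)
        ev = _events([1.0], ["DEV"])
        with pytest.raises(ValueError, match=">= 10"):
            cox_up_hazard(build_hazard_data(ups, ev))

    def test_positive_beta_on_generator_session(self, detected_session):
        trace, fs, events, truth, ups = detected_session
        res = cox_up_hazard(build_hazard_data(ups, events))
        assert res.beta > 0
        assert res.p < 0.05

    def test_null_beta_when_ups_independent_of_deviants(self):
        """Deviants never followed by Ups beyond chance → β ≈ 0 mostly."""
        rng = np.random.default_rng(2)
        n_sig = 0
        n_rep = 30
        for _ in range(n_rep):
            t, ts = 0.0, []
            while t < 600.0:
                t += rng.exponential(4.0) + 1.0
                ts.append(t)
            ups = _ups([(round(t, 3), "spontaneous", -1) for t in ts], spacing=None)
            dev = np.arange(5.0, 595.0, 3.9)
            ev = _events(dev, ["DEV"] * len(dev))
            res = cox_up_hazard(build_hazard_data(ups, ev))
            n_sig += abs(res.beta / res.se) >= 2
        assert n_sig <= 0.1 * n_rep + 2
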