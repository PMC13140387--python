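"""Epoching, bimodality coefficient, partition statistics, latency, contrasts."""

import numpy as np
import pytest
from scipy import stats

import upstates as u
from upstates.evoked import (BIMODALITY_THRESHOLD, EpochSet, _align_to_negative_peak,
                             partition_mean_ci, response_latency, condition_contrast)

FS = 763.0


def _rec_from(x):
    return u.Recording(x[None, :], FS, ["mPFC-L"])


class TestEpoch:
    def test_shape_and_count(self):
        rec = _rec_from(np.zeros(int(30 * FS)))
        onsets = np.arange(10) * 2.0 + 2.0
        eps = u.epoch(rec, onsets, window_ms=(0.0, 500.0), baseline_ms=None)
        assert eps.channel().shape == (10, round(0.5 * FS))

    def test_constant_signal_with_baseline_is_zero(self):
        rec = _rec_from(np.full(int(30 * FS), 123.0))
        eps = u.epoch(rec, np.arange(5) * 3.0 + 2.0, window_ms=(-100.0, 500.0))
        assert np.allclose(eps.channel(), 0.0)

    def test_injected_deflection_recovered_at_50ms_20uv(self):
        x = np.zeros(int(30 * FS))
        onsets = np.arange(8) * 3.0 + 2.0
        w = int(0.02 * FS)
        for t in onsets:
            i = int((t + 0.05) * FS)
            x[i:i + w] += 20.0
        eps = u.epoch(_rec_from(x), onsets, window_ms=(-100.0, 500.0))
        m = eps.channel().mean(axis=0)
        assert m.max() == pytest.approx(20.0, abs=0.5)
        assert eps.times_ms[np.argmax(m)] == pytest.approx(50.0, abs=15.0)

    def test_edge_trials_dropped_and_counted(self):
        rec = _rec_from(np.zeros(int(5 * FS)))
        eps = u.epoch(rec, [0.01, 2.0, 4.9], window_ms=(-100.0, 500.0),
                      baseline_ms=None)
        assert eps.n_trials == 1
        assert eps.n_dropped == 2

    def test_all_trials_dropped_rejected(self):
        rec = _rec_from(np.zeros(int(1 * FS)))
        with pytest.raises(ValueError):
            u.epoch(rec, [0.0], window_ms=(-2000.0, 2000.0))


class TestEpochRMS:
    def _eps(self, trials):
        return EpochSet({"mPFC-L": trials}, FS, (0.0, trials.shape[1] / FS * 1000.0),
                        np.arange(trials.shape[0]))

    def test_constant_trial_rms_is_magnitude(self):
        r = u.epoch_rms(self._eps(np.full((3, 100), -7.0)), window_ms=(0.0, 100.0))
        assert np.allclose(r, 7.0)

    def test_unit_sinusoid_rms(self):
        n = int(FS)  # whole seconds → whole periods of an integer-Hz sine
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 4 * t)[None, :]
        r = u.epoch_rms(self._eps(x), window_ms=(0.0, 1000.0))
        assert r[0] == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_evoked_and_fail_trials_form_separated_clusters(self, default_session):
        rec, events, truth = default_session
        eps = u.epoch(rec, events, window_ms=(-100.0, 1000.0), kinds={"DEV"})
        rms = u.epoch_rms(eps, window_ms=(0.0, 500.0))
        # a trial "has an Up" when any ground-truth onset (evoked or
        # spontaneous) falls in its RMS window
        dev_t = events.df.onset_s.to_numpy()[eps.event_indices]
        up_t = truth.onset_s
        lab = np.array([np.any((up_t >= t) & (up_t <= t + 0.5)) for t in dev_t])
        assert lab.sum() >= 5 and (~lab).sum() >= 5
        gap = rms[lab].mean() - rms[~lab].mean()
        within = max(rms[lab].std(), rms[~lab].std())
        assert gap > 3 * within

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            u.epoch_rms(self._eps(np.zeros((2, 100))), window_ms=(900.0, 1000.0))


class TestBimodalityStats:
    def test_gaussian_bc_one_third(self):
        rng = np.random.default_rng(0)
        r = u.bimodality_stats(rng.standard_normal(10**6))
        assert r.bimodality_coefficient == pytest.approx(1 / 3, abs=0.01)
        assert not r.is_bimodal

    def test_two_point_mixture_bc_one(self):
        rng = np.random.default_rng(1)
        vals = rng.choice([-1.0, 1.0], size=10**6)
        r = u.bimodality_stats(vals)
        assert r.bimodality_coefficient == pytest.approx(1.0, abs=0.01)
        assert r.is_bimodal

    def test_uniform_bc_at_5_9_threshold(self):
        rng = np.random.default_rng(2)
        r = u.bimodality_stats(rng.uniform(size=10**6))
        assert r.bimodality_coefficient == pytest.approx(5 / 9, abs=0.01)
        assert BIMODALITY_THRESHOLD == pytest.approx(0.555, abs=1e-3)

    def test_ks_detects_non_normal_mixture(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(-3, 0.5, 500), rng.normal(3, 0.5, 500)])
        r = u.bimodality_stats(vals)
        assert r.ks_p < 1e-4
        assert r.is_bimodal

    def test_within_group_normalisation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(100, 5, 400)     # animal with large offset
        b = rng.normal(0, 1, 400)
        pooled = u.bimodality_stats(np.r_[a, b])
        grouped = u.bimodality_stats(np.r_[a, b], groups=np.r_[np.zeros(400), np.ones(400)])
        assert pooled.is_bimodal            # offset masquerades as bimodality
        assert not grouped.is_bimodal       # removed by per-animal z-scoring

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            u.bimodality_stats([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            u.bimodality_stats(np.full(10, 2.0))


class TestPartitionMeanCI:
    def test_false_positive_mask_rate_near_alpha(self):
        """Identical label distributions → mask flags ≈5 % of samples."""
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(200):
            x = rng.standard_normal((30, 150))
            lab = np.array(["a"] * 15 + ["b"] * 15)
            part = partition_mean_ci(x, lab, FS)
            rates.append(part.sig_mask.mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)

    def test_injected_offset_yields_contiguous_mask(self):
        rng = np.random.default_rng(6)
        n = int(0.6 * FS)
        x = rng.standard_normal((40, n))
        t_ms = np.arange(n) / FS * 1000.0
        lab = np.array(["a"] * 20 + ["b"] * 20)
        x[20:, t_ms >= 200.0] += 100.0
        part = partition_mean_ci(x, lab, FS, rms_window_ms=(100.0, 400.0))
        sig_after = part.sig_mask[t_ms >= 210.0].mean()
        sig_before = part.sig_mask[t_ms < 190.0].mean()
        assert sig_after > 0.95 and sig_before < 0.2

    def test_generator_evoked_peak_and_sustained_component(self, default_session):
        """Evoked mean: negative peak near 200 ms with sustained deflection;
        fail trials flat after the early response."""
        rec, events, truth = default_session
        eps = u.epoch(rec, events, window_ms=(-100.0, 1000.0), kinds={"DEV"})
        linked = set(truth.df.loc[truth.df.cls == "evoked", "trigger_index"])
        lab = np.array(["evoked" if i in linked else "fail" for i in eps.event_indices])
        part = partition_mean_ci(eps.channel("mPFC-L"), lab, eps.fs, t0_ms=-100.0)
        t_ms = part.times_ms
        m_ev = part.mean["evoked"]
        peak_t = t_ms[np.argmin(m_ev)]
        assert 150.0 <= peak_t <= 280.0
        late = (t_ms >= 400.0) & (t_ms <= 850.0)
        assert m_ev[late].mean() < -20.0            # sustained negativity
        m_fail = part.mean["fail"]
        assert np.abs(m_fail[late]).mean() < 15.0   # fail trials flat
        rms = part.window_rms
        assert rms[rms.label == "evoked"].rms.mean() > 2 * rms[rms.label == "fail"].rms.mean()

    def test_cluster_correction_controls_familywise_rate_but_keeps_real_effect(self):
        rng = np.random.default_rng(12)
        n = 150
        # real effect: strong offset over a contiguous block
        x = rng.standard_normal((30, n))
        x[15:, 60:100] += 3.0
        lab = np.array(["a"] * 15 + ["b"] * 15)
        part = partition_mean_ci(x, lab, FS, cluster_correction=True,
                                 n_permutations=200)
        assert part.sig_mask[60:100].mean() > 0.8
        # null: corrected masks are empty in most replicates
        empties = 0
        for k in range(30):
            xn = rng.standard_normal((30, n))
            pn = partition_mean_ci(xn, lab, FS, cluster_correction=True,
                                   n_permutations=200, seed=k)
            empties += not pn.sig_mask.any()
        assert empties >= 25

    def test_peak_alignment_reduces_smearing(self):
        rng = np.random.default_rng(7)
        n = 300
        base = -100.0 * np.exp(-0.5 * ((np.arange(n) - 150) / 12.0) ** 2)
        trials = np.stack([np.roll(base, k) for k in rng.integers(-40, 40, 24)])
        trials += rng.standard_normal(trials.shape)
        aligned = _align_to_negative_peak(trials)
        assert aligned.mean(axis=0).min() < trials.mean(axis=0).min()
        assert aligned.mean(axis=0).min() == pytest.approx(-100.0, abs=10.0)

    def test_single_trial_label_excluded(self):
        x = np.zeros((3, 50))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                partition_mean_ci(x, np.array(["a", "a", "b"]), FS)


class TestResponseLatency:
    def test_all_zero_trials_have_no_latency(self):
        rng = np.random.default_rng(8)
        assert response_latency(rng.standard_normal((20, 400)), FS, t0_ms=-100.0) is None

    def test_constructed_onset_recovered(self):
        rng = np.random.default_rng(9)
        n = int(0.5 * FS)
        x = rng.standard_normal((40, n)) * 0.5
        t_ms = np.arange(n) / FS * 1000.0
        x[:, t_ms >= 120.0] -= 10.0
        lat = response_latency(x, FS, t0_ms=0.0)
        assert lat == pytest.approx(120.0, abs=10.0)

    def test_latency_estimator_is_monotone_in_delay(self):
        rng = np.random.default_rng(10)
        n = int(0.6 * FS)
        t_ms = np.arange(n) / FS * 1000.0
        lats = []
        for start in (100.0, 180.0, 260.0):
            x = rng.standard_normal((40, n)) * 0.5
            x[:, t_ms >= start] -= 10.0
            lats.append(response_latency(x, FS))
        deltas = np.diff(lats)
        assert np.all(np.abs(deltas - 80.0) <= 10.0)


class TestConditionContrast:
    def test_null_calibration_p_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            a = rng.standard_normal((12, 80)) + 5.0
            b = rng.standard_normal((12, 80)) + 5.0
            _, p = condition_contrast(a, b, FS, window_ms=(0.0, 100.0))
            ps.append(p)
        _, ks_p = stats.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_deviant_vs_many_standards_mixed_model(self):
        """DEV trials carry evoked Ups, MS trials only early responses →
        strongly larger DEV window amplitude across 5 synthetic animals."""
        dev_trials, ms_trials, dev_an, ms_an, dev_fq, ms_fq = [], [], [], [], [], []
        for animal in range(5):
            ev_d = u.generate_sequence(u.ParadigmSpec(n_stimuli=640), seed=20 + animal)
            rec_d, truth_d = u.simulate_session(
                u.SimConfig(duration_s=162.0, seed=20 + animal,
                            channel_labels=("AC-L-rostral",)), ev_d)
            eps_d = u.epoch(rec_d, ev_d, window_ms=(-100.0, 600.0), kinds={"DEV"})
            dev_trials.append(eps_d.channel())
            dev_an += [animal] * eps_d.n_trials
            dev_fq += list(ev_d.df.freq_hz.to_numpy()[eps_d.event_indices])
            ev_m = u.generate_sequence(
                u.ParadigmSpec.many_standards(n_stimuli=160), seed=50 + animal)
            rec_m, _ = u.simulate_session(
                u.SimConfig(duration_s=42.0, seed=50 + animal,
                            channel_labels=("AC-L-rostral",)), ev_m)
            eps_m = u.epoch(rec_m, ev_m, window_ms=(-100.0, 600.0), kinds={"MS"})
            keep = slice(0, 40)
            ms_trials.append(eps_m.channel()[keep])
            ms_an += [animal] * min(40, eps_m.n_trials)
            ms_fq += list(ev_m.df.freq_hz.to_numpy()[eps_m.event_indices][keep])
        a = np.vstack(dev_trials)
        b = np.vstack(ms_trials)
        f, p = condition_contrast(a, b, FS, window_ms=(100.0, 300.0), t0_ms=-100.0,
                                  model="mixed_model", animal_a=dev_an, animal_b=ms_an,
                                  freq_a=dev_fq, freq_b=ms_fq)
        assert p < 0.01
        t, p_t = condition_contrast(a, b, FS, window_ms=(100.0, 300.0), t0_ms=-100.0)
        assert t > 0 and p_t < 0.01

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            condition_contrast(np.zeros((3, 10)), np.zeros((3, 10)), FS,
                               window_ms=(0.0, 10.0), model="anova")
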