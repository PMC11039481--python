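import numpy as np
import pandas as pd
import pytest
from scipy import stats

from illusionephys import stimgen as sg
from illusionephys import synthetic as syn
from illusionephys import unitclass as uc


def make_unit(**overrides):
    params = dict(
        unit_id=0,
        preferred_direction=90.0,
        tuning_width=40.0,
        baseline_rate=5.0,
        evoked_rate_ldg=30.0,
        evoked_rate_ncs=30.0,
        latency_ldg=65.0,
        latency_ncs=100.0,
        latency_rect=40.0,
        f1_ratio=0.0,
        response_phase_ldg=0.0,
        phase_offset_ncs=180.0,
        cell_class="E",
        tpl_ms=0.65,
        rf_center=(0.0, 0.0),
        rf_sigma=(3.0, 3.0),
        surround_index_true=0.2,
        depth_um=400.0,
        channel=16,
    )
    params.update(overrides)
    return syn.GroundTruthUnit(**params)


@pytest.fixture(scope="module")
def short_trials():
    return sg.condition_table(trials_per_condition=20, order_seed=0)


class TestUnitSpikes:
    def test_determinism(self, short_trials):
        u = make_unit()
        a = syn.simulate_unit_spikes(u, short_trials, seed=42)
        b = syn.simulate_unit_spikes(u, short_trials, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_evoked_ncs_matches_baseline(self, short_trials):
        u = make_unit(evoked_rate_ncs=0.0)
        sp = syn.simulate_unit_spikes(u, short_trials, seed=1)
        merged = sp.merge(short_trials, on="trial_id")
        rel = merged["t_s"] - merged["onset_s"]
        stim = merged[(rel >= 0) & (rel < 1.0)]
        ncs = stim[stim["stimulus_type"] == "NCS"]
        dbc = stim[stim["stimulus_type"] == "DBC"]
        n_ncs = (short_trials["stimulus_type"] == "NCS").sum()
        n_dbc = (short_trials["stimulus_type"] == "DBC").sum()
        # two-sample Poisson rate test (normal approximation)
        r1, r2 = len(ncs) / n_ncs, len(dbc) / n_dbc
        se = np.sqrt(r1 / n_ncs + r2 / n_dbc)
        assert abs(r1 - r2) < 4 * se

    def test_dbc_is_baseline_only(self, short_trials):
        u = make_unit()
        sp = syn.simulate_unit_spikes(u, short_trials, seed=2)
        merged = sp.merge(short_trials, on="trial_id")
        rel = merged["t_s"] - merged["onset_s"]
        dbc = merged[(merged["stimulus_type"] == "DBC") & (rel >= 0) & (rel < 1)]
        n_dbc = (short_trials["stimulus_type"] == "DBC").sum()
        expected = u.baseline_rate * n_dbc  # 1 s windows
        assert stats.poisson.cdf(len(dbc), expected) > 0.001
        assert stats.poisson.sf(len(dbc), expected) > 0.001

    def test_psth_spectrum_peaks_at_tf(self):
        # f1_ratio=1, TF=2 Hz: PSTH power spectrum peak at 2 Hz, matching
        # an FFT oracle on the analytic rate
        trials = pd.DataFrame(
            {
                "trial_id": np.arange(70),
                "stimulus_type": "LDG",
                "direction": 90.0,
                "light": False,
                "onset_s": np.arange(70) * 1.6,
            }
        )
        u = make_unit(f1_ratio=1.0, latency_ldg=0.0)
        sp = syn.simulate_unit_spikes(u, trials, seed=3, onset_boost=0.0)
        rel = sp.merge(trials, on="trial_id")
        t = (rel["t_s"] - rel["onset_s"]).to_numpy()
        counts, _ = np.histogram(t, bins=np.arange(0, 1.001, 0.001))
        spec = np.abs(np.fft.rfft(counts - counts.mean())) ** 2
        freqs = np.fft.rfftfreq(len(counts), 0.001)
        assert freqs[np.argmax(spec)] == pytest.approx(2.0)
        # oracle: analytic rate has the same dominant frequency
        tt = np.arange(0, 1, 0.001)
        rate = 1 + np.cos(2 * np.pi * 2.0 * tt)
        spec_o = np.abs(np.fft.rfft(rate - rate.mean())) ** 2
        assert freqs[np.argmax(spec_o)] == pytest.approx(2.0)

    def test_spike_count_matches_analytic_expectation(self, short_trials):
        # chi-square goodness of fit of per-condition totals vs analytic rates
        u = make_unit(f1_ratio=0.0, tuning_width=40.0)
        sp = syn.simulate_unit_spikes(u, short_trials, seed=4, onset_boost=0.0)
        merged = sp.merge(short_trials, on="trial_id")
        rel = merged["t_s"] - merged["onset_s"]
        stim = merged[(rel >= 0) & (rel < 1)]
        observed, expected = [], []
        for (stype, d), grp in short_trials.groupby(["stimulus_type", "direction"]):
            n = len(grp)
            sel = stim[(stim["stimulus_type"] == stype) & (stim["direction"] == d)]
            tun = float(syn.von_mises_tuning(d, 90.0, 40.0))
            if stype == "LDG":
                lam = u.baseline_rate + u.evoked_rate_ldg * tun * (1 - 0.065)
            elif stype == "NCS":
                lam = u.baseline_rate + u.evoked_rate_ncs * tun * (1 - 0.100)
            else:
                lam = u.baseline_rate
            observed.append(len(sel))
            expected.append(lam * n)
        chi2 = np.sum((np.array(observed) - expected) ** 2 / np.array(expected))
        assert stats.chi2.sf(chi2, len(observed)) > 1e-4

    def test_light_scales_ncs_only(self, short_trials):
        trials = short_trials.copy()
        trials["light"] = trials["trial_id"] % 2 == 0
        u = make_unit(light_gain_ncs=0.3, light_gain_ldg=1.0, tuning_width=1000.0)
        sp = syn.simulate_unit_spikes(u, trials, seed=5)
        merged = sp.merge(trials, on="trial_id")
        rel = merged["t_s"] - merged["onset_s"]
        stim = merged[(rel >= 0) & (rel < 1)]

        def rate(stype, light):
            sel = stim[(stim["stimulus_type"] == stype) & (stim["light"] == light)]
            n = ((trials["stimulus_type"] == stype) & (trials["light"] == light)).sum()
            return len(sel) / n

        assert rate("NCS", True) < 0.6 * rate("NCS", False)
        assert rate("LDG", True) == pytest.approx(rate("LDG", False), rel=0.12)


class TestWaveforms:
    def test_tpl_matches_construction(self):
        units = [make_unit(unit_id=i, tpl_ms=t) for i, t in enumerate((0.2, 0.5, 0.9))]
        wfs = syn.simulate_waveforms(units, seed=0, noise_sd=0.0)
        for u in units:
            measured = uc.tpl(wfs[u.unit_id], syn.WAVEFORM_FS)
            assert measured == pytest.approx(u.tpl_ms, abs=1000.0 / syn.WAVEFORM_FS)

    def test_bimodality_of_cohort(self):
        units = syn.make_cohort(400, seed=1)
        tpls = np.array([u.tpl_ms for u in units])
        # density at the midpoint between modes dips below both mode densities
        kde = stats.gaussian_kde(tpls)
        lo, mid, hi = kde(0.25)[0], kde(0.45)[0], kde(0.65)[0]
        assert mid < lo and mid < hi

    def test_threshold_classification_accuracy(self):
        # Bayes-oracle check: threshold at the density intersection recovers
        # ground-truth labels for well separated components
        units = syn.make_cohort(500, seed=2)
        tpls = np.array([u.tpl_ms for u in units])
        labels = np.array([u.cell_class for u in units])
        res = uc.ei_threshold(tpls)
        assert (res["labels"] == labels).mean() >= 0.95


class TestLfp:
    def test_sink_at_requested_channel(self):
        lfp = syn.simulate_lfp_csd(32, 12, seed=0, noise_sd=0.0)
        csd = uc.csd(lfp)
        ch = np.unravel_index(np.argmin(csd), csd.shape)[0]
        assert ch == 12

    def test_linear_profile_gives_zero_csd(self):
        lfp = syn.simulate_lfp_csd(16, 8, seed=0, noise_sd=0.0, amplitude=0.0,
                                   linear_gradient=3.0)
        csd = uc.csd(lfp)
        assert np.allclose(csd[1:-1], 0.0, atol=1e-9)

    def test_sink_recovery_under_noise(self):
        # SNR sweep: sink recovered within +/-1 channel down to noise 10%
        # of the amplitude
        for noise in (1.0, 5.0, 10.0):
            hits = 0
            for seed in range(10):
                lfp = syn.simulate_lfp_csd(32, 20, seed=seed, noise_sd=noise)
                sink = uc.find_sink(uc.csd(lfp))
                hits += abs(sink["channel"] - 20) <= 1
            assert hits >= 9

    def test_invalid_sink_channel(self):
        with pytest.raises(ValueError):
            syn.simulate_lfp_csd(8, 99)


class TestBehaviorSim:
    def test_run_fraction_zero(self):
        trials = sg.condition_table(trials_per_condition=5, order_seed=0)
        from illusionephys import behavior as beh

        enc, _, flags = syn.simulate_behavior(trials, run_fraction=0.0, seed=0)
        assert not flags.any()
        t, speed = beh.disk_speed(enc["t_s"].to_numpy(), enc["voltage"].to_numpy())
        labels = beh.classify_run_still(t, speed, trials)
        assert (labels == "still").all()

    def test_wrap_produces_no_speed_spike(self):
        from illusionephys import behavior as beh

        # constant rotation crossing many 5V->0V wraps
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        angle = 720.0 * t  # 2 rev/s
        v = np.mod(angle, 360.0) / 360.0 * 5.0
        t_out, speed = beh.disk_speed(t, v, disk_diameter_cm=20.0)
        inner = speed[5:-5]
        assert np.ptp(inner) < 1e-6 * np.mean(inner) + 1e-9

    def test_pupil_sign_pattern(self):
        trials = sg.condition_table(trials_per_condition=10, order_seed=1)
        from illusionephys import behavior as beh

        _, pupil, _ = syn.simulate_behavior(
            trials, run_fraction=0.0, pupil_effects={"NCS": 0.06, "LDG": -0.08, "DBC": 0.0},
            seed=2,
        )
        di = beh.dilation_index(pupil["t_s"].to_numpy(), pupil["diameter"].to_numpy(), trials)
        per = trials.set_index("trial_id").assign(di=di)
        means = per.groupby("stimulus_type")["di"].mean()
        assert means["NCS"] > 0.01
        assert means["LDG"] < -0.01
        assert abs(means["DBC"]) < 0.005


class TestBundle:
    def test_session_determinism(self):
        trials = sg.condition_table(trials_per_condition=3, order_seed=2)
        units = syn.make_cohort(3, seed=3)
        a = syn.simulate_session(units, trials, seed=4)
        b = syn.simulate_session(units, trials, seed=4)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        np.testing.assert_array_equal(a.lfp, b.lfp)

    def test_spikes_within_session(self):
        trials = sg.condition_table(trials_per_condition=3, order_seed=2)
        units = syn.make_cohort(3, seed=3)
        bundle = syn.simulate_session(units, trials, seed=4)
        assert bundle.spikes["t_s"].min() >= -0.5
        assert bundle.spikes["t_s"].max() <= trials["offset_s"].max() + 0.5

    def test_save_load_roundtrip(self, tmp_path):
        trials = sg.condition_table(trials_per_condition=2, order_seed=2)
        units = syn.make_cohort(2, seed=3)
        bundle = syn.simulate_session(units, trials, seed=4)
        bundle.save(tmp_path / "bundle")
        loaded = syn.RecordingBundle.load(tmp_path / "bundle")
        pd.testing.assert_frame_equal(bundle.spikes, loaded.spikes)
        assert loaded.ground_truth[0].preferred_direction == pytest.approx(
            units[0].preferred_direction
        )
        np.testing.assert_allclose(loaded.waveforms[0], bundle.waveforms[0])
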