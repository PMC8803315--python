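"""Generator contracts: determinism, limiting cases, and ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from impulsekit import synthetic as syn
from impulsekit.behavior import compute_session_metrics
from impulsekit.validation import event_grid_session


class TestCohort:
    def test_bimodal_cohort_records_ground_truth_labels(self):
        cohort = syn.simulate_cohort(
            10, {"kind": "bimodal", "low": 0.2, "high": 0.8}, seed=1)
        assert len(cohort) == 10
        groups = [a.latent_group for a in cohort]
        assert groups.count("HI") == 5 and groups.count("LI") == 5
        for a in cohort:
            near = 0.8 if a.latent_group == "HI" else 0.2
            assert abs(a.trait_theta - near) < 0.25

    def test_same_seed_gives_identical_cohort(self):
        a = syn.simulate_cohort(10, seed=1)
        b = syn.simulate_cohort(10, seed=1)
        assert [x.trait_theta for x in a] == [x.trait_theta for x in b]
        assert [x.latent_group for x in a] == [x.latent_group for x in b]

    def test_point_mass_cohort_has_equal_traits(self):
        cohort = syn.simulate_cohort(10, {"kind": "point", "value": 0.5},
                                     seed=3)
        assert all(a.trait_theta == 0.5 for a in cohort)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(syn.InvalidCohortError):
            syn.simulate_cohort(1, seed=0)


class TestSession:
    def test_quiet_agent_never_pokes_and_always_hits(self, quiet_session):
        tr = quiet_session.trials
        assert tr["n_precue_pokes"].sum() == 0
        assert (tr.loc[tr["trial_type"] == "Go", "outcome"] == "CorrectGo").all()
        m = compute_session_metrics(quiet_session)
        assert m.precue_response_rate == 0.0
        assert m.pct_correct_go == 100.0

    def test_certain_fa_agent_fails_every_ng_trial(self):
        agent = syn.AgentSpec("fa", 0.5, precue_poke_rate_fn=lambda t: 0.0,
                              fa_prob_fn=lambda t: 1.0)
        session = syn.simulate_session(agent, seed=5)
        ng = session.trials[session.trials["trial_type"] == "NG"]
        assert (ng["outcome"] == "FalseAlarm").all()

    def test_default_config_runs_thirty_go_and_thirty_nogo(self, quiet_session):
        tr = quiet_session.trials
        completed = tr[tr["outcome"] != "Aborted"]
        assert len(completed) == 60
        assert (completed["trial_type"] == "Go").sum() == 30
        assert (completed["trial_type"] == "NG").sum() == 30

    def test_outcome_conservation_per_trial_type(self):
        # moderate poke rate so aborts occur and are replaced
        agent = syn.AgentSpec("c", 0.5, precue_poke_rate_fn=lambda t: 0.05,
                              fa_prob_fn=lambda t: 0.3)
        task = syn.TaskConfig(session_cap_min=120.0)
        session = syn.simulate_session(agent, task, seed=6)
        tr = session.trials
        go = tr[tr["trial_type"] == "Go"]["outcome"].value_counts()
        ng = tr[tr["trial_type"] == "NG"]["outcome"].value_counts()
        assert go.get("CorrectGo", 0) + go.get("Omission", 0) == 30
        assert ng.get("CorrectNoGo", 0) + ng.get("FalseAlarm", 0) == 30

    def test_aborted_trials_are_replaced_or_kept_per_config(self):
        agent = syn.AgentSpec("a", 0.9)  # pokes a lot
        keep = syn.simulate_session(
            agent, syn.TaskConfig(replace_aborted=False), seed=7)
        tr = keep.trials
        assert len(tr) == 60  # no replacements appended
        assert (tr["outcome"] == "Aborted").sum() > 0

    def test_precue_durations_within_stated_range(self, quiet_session):
        d = quiet_session.trials["precue_duration_s"]
        assert d.between(9.0, 24.0).all()

    def test_mean_precue_rate_nondecreasing_in_trait(self):
        # trait grid, >= 100 sessions in total
        thetas = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for j, th in enumerate(thetas):
            agent = syn.AgentSpec(f"t{j}", th)
            rates = [compute_session_metrics(
                syn.simulate_session(agent, seed=j * 100 + k)
            ).precue_response_rate for k in range(21)]
            means.append(np.mean(rates))
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_determinism(self, quiet_agent):
        a = syn.simulate_session(quiet_agent, seed=9)
        b = syn.simulate_session(quiet_agent, seed=9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.events, b.events)


class TestSpikeTrains:
    def test_homogeneous_poisson_count_matches_oracle(self, grid_session):
        # Poisson(rate * T): count within 5 sigma of the mean
        trains = syn.simulate_spike_trains(
            grid_session, [syn.UnitSpec("u", 10.0)], seed=1)
        mean = 10.0 * grid_session.duration_s
        assert abs(trains[0].n_spikes - mean) < 5 * np.sqrt(mean)

    def test_gain_zero_silences_the_window(self, grid_session):
        unit = syn.UnitSpec("u", 20.0, (("precue_poke", 0.0, 0.0, 1.0),))
        train = syn.simulate_spike_trains(grid_session, [unit], seed=2)[0]
        for te in grid_session.event_times("precue_poke"):
            in_win = ((train.spike_times_s >= te)
                      & (train.spike_times_s < te + 1.0))
            assert not in_win.any()

    def test_same_seed_identical_spikes(self, grid_session):
        u = [syn.UnitSpec("u", 10.0)]
        a = syn.simulate_spike_trains(grid_session, u, seed=3)[0]
        b = syn.simulate_spike_trains(grid_session, u, seed=3)[0]
        np.testing.assert_array_equal(a.spike_times_s, b.spike_times_s)

    def test_unknown_event_label_rejected(self, grid_session):
        unit = syn.UnitSpec("u", 10.0, (("no_such_event", 2.0, 0.0, 1.0),))
        with pytest.raises(syn.ConfigurationError, match="no_such_event"):
            syn.simulate_spike_trains(grid_session, [unit], seed=0)

    def test_refractory_period_enforced(self, grid_session):
        unit = syn.UnitSpec("u", 50.0, refractory_s=0.005)
        train = syn.simulate_spike_trains(grid_session, [unit], seed=4)[0]
        assert np.diff(train.spike_times_s).min() >= 0.005


class TestLFP:
    def test_single_band_without_modulation_is_narrowband(self):
        session = event_grid_session(n_events=10, seed=2)
        spec = syn.LFPSpec(fs_hz=500.0,
                           bands=(syn.BandComponent("x", 18.0, 22.0, 1.0),),
                           noise_amplitude=0.0)
        rec = syn.simulate_lfp(session, spec, 1, seed=1)[0]
        f, p = signal.welch(rec.samples, fs=500.0, nperseg=2048)
        inside = p[(f >= 18) & (f <= 22)].sum()
        assert inside / p.sum() > 0.95

    def test_beta_suppression_lowers_band_power_in_windows(self):
        # oracle: band-filtered RMS inside pre-event windows vs overall
        session = event_grid_session(n_events=30, spacing=(17.0, 21.0),
                                     margin_s=10.0, seed=3)
        spec = syn.LFPSpec(
            fs_hz=500.0, bands=(syn.BandComponent("beta", 15.0, 30.0, 1.0),),
            noise_amplitude=0.1,
            event_modulations=(syn.EventModulation("precue_poke", "beta",
                                                   -0.5, 2.0),))
        rec = syn.simulate_lfp(session, spec, 1, seed=5)[0]
        sos = signal.butter(4, (15, 30), "bandpass", fs=500.0, output="sos")
        x = signal.sosfiltfilt(sos, rec.samples)
        mask = np.zeros(len(x), dtype=bool)
        for te in session.event_times("precue_poke"):
            mask[int((te - 2) * 500):int(te * 500)] = True
        assert np.sqrt(np.mean(x[mask] ** 2)) < np.sqrt(np.mean(x[~mask] ** 2))

    def test_zero_band_amplitudes_leave_pure_noise(self):
        session = event_grid_session(n_events=5, seed=4)
        spec = syn.LFPSpec(fs_hz=500.0,
                           bands=(syn.BandComponent("x", 10.0, 20.0, 0.0),))
        rec = syn.simulate_lfp(session, spec, 1, seed=1)[0]
        assert np.isfinite(rec.samples).all()
        assert abs(np.sqrt(np.mean(rec.samples ** 2))
                   - syn.LFPSpec().noise_amplitude) < 0.05

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(syn.ConfigurationError, match="Nyquist"):
            syn.LFPSpec(fs_hz=100.0,
                        bands=(syn.BandComponent("hi", 40.0, 80.0, 1.0),))

    def test_realized_band_power_ratio_matches_spec(self):
        # 600 s record: band power ratio within 10% of the amplitude ratio
        session = event_grid_session(n_events=55, seed=6)
        spec = syn.LFPSpec(fs_hz=500.0, noise_amplitude=0.0,
                           bands=(syn.BandComponent("a", 5.0, 10.0, 1.0),
                                  syn.BandComponent("b", 20.0, 40.0, 0.5)))
        rec = syn.simulate_lfp(session, spec, 1, seed=7)[0]
        f, p = signal.welch(rec.samples, fs=500.0, nperseg=4096)
        pa = np.trapezoid(p[(f >= 5) & (f <= 10)], f[(f >= 5) & (f <= 10)])
        pb = np.trapezoid(p[(f >= 20) & (f <= 40)], f[(f >= 20) & (f <= 40)])
        assert abs(pa / pb - 4.0) / 4.0 < 0.10


class TestNodeTimeseries:
    def test_no_effects_means_identical_cell_covariances(self):
        spec = syn.NetworkSpec(n_nodes=8)
        np.testing.assert_array_equal(spec.covariance_for("HI", "vehicle"),
                                      spec.covariance_for("LI", "vehicle"))

    def test_injected_strength_deficit_matches_analytic_value(self):
        # closed form: delta on 50 couplings changes node strength by delta
        spec = syn.NetworkSpec(n_nodes=20, group_effect=(0, -0.2),
                               n_timepoints=400)
        cohort = syn.simulate_cohort(12, seed=1)
        data = syn.simulate_node_timeseries(cohort, spec, ("vehicle",), seed=2)
        hi, li = [], []
        for (animal, _t), arr in data.series.items():
            r = np.corrcoef(arr)
            s0 = (r[0].sum() - 1.0) / (spec.n_nodes - 1)
            (hi if data.groups[animal] == "HI" else li).append(s0)
        observed = np.mean(hi) - np.mean(li)
        # expected strength difference: cov delta -0.2 on unit-variance nodes
        assert observed < 0
        assert abs(observed - (-0.2)) < 0.05

    def test_white_noise_when_ar_coefficient_zero(self):
        spec = syn.NetworkSpec(n_nodes=4, ar_coefficient=0.0,
                               n_timepoints=500)
        cohort = syn.simulate_cohort(2, seed=3)
        data = syn.simulate_node_timeseries(cohort, spec, ("vehicle",), seed=4)
        x = next(iter(data.series.values()))[0]
        # Ljung-Box portmanteau at 10 lags
        n = len(x)
        xc = x - x.mean()
        acf = np.array([np.dot(xc[:-k], xc[k:]) / np.dot(xc, xc)
                        for k in range(1, 11)])
        q = n * (n + 2) * np.sum(acf ** 2 / (n - np.arange(1, 11)))
        from scipy import stats as st
        assert st.chi2.sf(q, 10) > 0.01

    def test_ar_process_has_requested_autocorrelation(self):
        spec = syn.NetworkSpec(n_nodes=3, ar_coefficient=0.5,
                               n_timepoints=2000)
        cohort = syn.simulate_cohort(2, seed=5)
        data = syn.simulate_node_timeseries(cohort, spec, ("vehicle",), seed=6)
        x = next(iter(data.series.values()))[0]
        xc = x - x.mean()
        r1 = np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc)
        assert abs(r1 - 0.5) < 0.07

    def test_non_psd_modification_raises_generation_error(self):
        spec = syn.NetworkSpec(n_nodes=5, group_effect=(0, -1.2))
        cohort = syn.simulate_cohort(4, seed=7)
        with pytest.raises(syn.GenerationError, match="positive semidefinite"):
            syn.simulate_node_timeseries(cohort, spec, ("vehicle",), seed=8)

    def test_series_shape_after_burn_in(self):
        spec = syn.NetworkSpec(n_nodes=6, n_timepoints=230)
        cohort = syn.simulate_cohort(2, seed=9)
        data = syn.simulate_node_timeseries(cohort, spec, ("vehicle",),
                                            seed=10)
        for arr in data.series.values():
            assert arr.shape == (6, 230)
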