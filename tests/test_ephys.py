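"""Peri-event unit statistics: Z-scoring, cluster permutation, population tests."""

import numpy as np
import pandas as pd
import pytest

from impulsekit import behavior, ephys, synthetic as syn
from impulsekit.validation import event_grid_session


def _poisson_train(rng, rate, duration, uid="u"):
    n = rng.poisson(rate * duration)
    return ephys.SpikeTrain(uid, np.sort(rng.uniform(0, duration, n)),
                            (0.0, duration))


class TestBinAndZscore:
    def test_one_spike_per_bin_gives_zero_z_with_warning(self):
        times = np.arange(100) * 0.25 + 0.1
        train = ephys.SpikeTrain("u", times, (0.0, 25.0))
        with pytest.warns(UserWarning, match="constant"):
            z = ephys.bin_and_zscore(train)
        assert np.all(z.z_raw == 0.0)
        assert np.all(z.z == 0.0)

    def test_poisson_unit_z_has_unit_moments_before_smoothing(self):
        rng = np.random.default_rng(0)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 600.0))
        assert z.z_raw.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.z_raw.std() == pytest.approx(1.0, abs=1e-12)
        # smoothing shrinks variance but preserves the mean
        assert z.z.std() < 1.0

    def test_sparse_unit_rejected_by_spike_count_filter(self):
        train = ephys.SpikeTrain("u", np.linspace(1, 599, 19), (0.0, 600.0))
        with pytest.raises(ValueError, match="19 spikes"):
            ephys.bin_and_zscore(train)

    def test_kernel_interpreted_as_six_sigma_window(self):
        rng = np.random.default_rng(1)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 100.0))
        assert z.smoothing_sd_s == pytest.approx(0.25)


class TestPeriEventMatrix:
    def test_constant_series_gives_identical_rows(self):
        rng = np.random.default_rng(2)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 300.0))
        zc = ephys.ZRateSeries(z.unit_id, z.bin_width_s, z.t0,
                               np.full_like(z.z, 0.7), np.full_like(z.z, 0.7),
                               z.mean_rate_hz, z.sd_rate_hz, z.smoothing_sd_s)
        mat = ephys.build_peri_event_matrix(zc, [50.0, 100.0, 150.0])
        assert np.all(mat.matrix == 0.7)

    def test_edge_events_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 300.0))
        mat = ephys.build_peri_event_matrix(z, [2.0, 100.0, 150.0, 299.0])
        assert mat.matrix.shape[0] == 2
        assert mat.n_dropped_events == 2

    def test_too_few_retained_events_is_an_error(self):
        rng = np.random.default_rng(4)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 300.0))
        with pytest.raises(ValueError, match="fewer than 2"):
            ephys.build_peri_event_matrix(z, [2.0, 150.0])

    def test_injected_gain_elevates_exactly_its_bins(self, grid_session):
        unit = syn.UnitSpec("u", 10.0, (("precue_poke", 3.0, 0.0, 0.5),))
        train = syn.simulate_spike_trains(grid_session, [unit], seed=5)[0]
        z = ephys.bin_and_zscore(train)
        ev = grid_session.event_times("precue_poke")
        mat = ephys.build_peri_event_matrix(z, ev, use_smoothed=False)
        means = mat.matrix.mean(axis=0)
        c = mat.bin_centers
        inside = means[(c > 0) & (c < 0.5)]
        outside = means[(c < -0.5) | (c > 1.0)]
        assert inside.min() > outside.max()

    def test_window_bins_are_half_open(self):
        rng = np.random.default_rng(6)
        z = ephys.bin_and_zscore(_poisson_train(rng, 10.0, 300.0))
        mat = ephys.build_peri_event_matrix(z, [100.0, 150.0, 200.0])
        assert len(mat.baseline_bins) == 4   # [-2, -1) at 0.25 s bins
        assert len(mat.post_bins) == 4       # [0, +1)
        assert mat.bin_centers[mat.post_bins][0] == pytest.approx(0.125)


class TestClusterPermutation:
    def _matrix(self, data):
        return ephys.PeriEventMatrix("u", "e", (-5.0, 5.0), data, 0.25)

    def test_all_zero_matrix_yields_no_clusters(self):
        assert ephys.cluster_permutation_test(self._matrix(np.zeros((10, 40))),
                                              n_iter=200, seed=0) == []

    def test_no_bin_crossing_threshold_yields_empty_cluster_list(self):
        # post bins alternate +1/-1 across trials: per-bin t is exactly 0
        data = np.zeros((30, 40))
        data[::2, 20:24] = 1.0
        data[1::2, 20:24] = -1.0
        clusters = ephys.cluster_permutation_test(self._matrix(data),
                                                  n_iter=200, seed=1)
        assert clusters == []

    def test_unstable_iteration_count_refused(self):
        with pytest.raises(ValueError, match="n_iter"):
            ephys.cluster_permutation_test(self._matrix(np.zeros((5, 40))),
                                           n_iter=50, seed=0)

    def test_strong_injected_response_is_one_significant_cluster(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 1, (60, 40))
        data[:, 20:24] += 2.0    # delta-z 2 over the 4 post bins
        clusters = ephys.cluster_permutation_test(self._matrix(data),
                                                  n_iter=500, seed=2)
        sig = [c for c in clusters if c.p_corrected < 0.05]
        assert len(sig) == 1
        assert sig[0].sign == 1
        assert (sig[0].start_bin, sig[0].end_bin) == (0, 4)

    def test_corrected_p_has_permutation_floor(self):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 1, (60, 40))
        data[:, 20:24] += 3.0
        clusters = ephys.cluster_permutation_test(self._matrix(data),
                                                  n_iter=500, seed=3)
        assert min(c.p_corrected for c in clusters) >= 1.0 / 501.0


class TestClassifyUnitResponse:
    def test_injected_excitation_labelled_up(self, grid_session):
        gain = syn.gain_for_z_shift(2.0, 10.0)
        unit = syn.UnitSpec("u", 10.0, (("precue_poke", gain, 0.0, 1.0),))
        train = syn.simulate_spike_trains(grid_session, [unit], seed=10)[0]
        mat = ephys.build_peri_event_matrix(
            ephys.bin_and_zscore(train),
            grid_session.event_times("precue_poke"))
        assert ephys.classify_unit_response(mat, n_iter=500, seed=0).label == "Up"

    def test_injected_suppression_labelled_down(self, grid_session):
        unit = syn.UnitSpec("u", 10.0, (("precue_poke", 0.05, 0.0, 1.0),))
        train = syn.simulate_spike_trains(grid_session, [unit], seed=11)[0]
        mat = ephys.build_peri_event_matrix(
            ephys.bin_and_zscore(train),
            grid_session.event_times("precue_poke"))
        assert ephys.classify_unit_response(mat, n_iter=500,
                                            seed=0).label == "Down"

    def test_null_units_mostly_nonresponders(self, grid_session):
        units = [syn.UnitSpec(f"u{i}", 10.0) for i in range(20)]
        trains = syn.simulate_spike_trains(grid_session, units, seed=12)
        ev = grid_session.event_times("precue_poke")
        labels = [ephys.classify_unit_response(
            ephys.build_peri_event_matrix(ephys.bin_and_zscore(t), ev),
            n_iter=300, seed=i).label for i, t in enumerate(trains)]
        assert labels.count("NonResponder") >= 17
        assert set(labels) <= {"Up", "Down", "NonResponder"}

    def test_shift_invariance_of_classification(self, grid_session):
        # moving spikes and events by the same whole-bin offset changes nothing
        unit = syn.UnitSpec("u", 10.0, (("precue_poke", 2.0, 0.0, 1.0),))
        train = syn.simulate_spike_trains(grid_session, [unit], seed=13)[0]
        ev = grid_session.event_times("precue_poke")
        off = 5.0
        dur = grid_session.duration_s + 2 * off
        shifted = ephys.SpikeTrain("u", train.spike_times_s + off, (0.0, dur))
        m1 = ephys.build_peri_event_matrix(ephys.bin_and_zscore(train), ev)
        z2 = ephys.ZRateSeries(**{**ephys.bin_and_zscore(shifted).__dict__})
        m2 = ephys.build_peri_event_matrix(z2, ev + off)
        r1 = ephys.classify_unit_response(m1, n_iter=300, seed=7)
        r2 = ephys.classify_unit_response(m2, n_iter=300, seed=7)
        assert r1.label == r2.label


class TestPopulationCountTest:
    def test_zero_responsive_units_never_pass(self, grid_session):
        units = [syn.UnitSpec(f"u{i}", 10.0) for i in range(5)]
        trains = syn.simulate_spike_trains(grid_session, units, seed=14)
        res = ephys.population_count_test(
            trains, grid_session.event_times("precue_poke"),
            (0.0, grid_session.duration_s), n_iter=150, cluster_n_iter=150,
            seed=3)
        if res.observed_count == 0:
            assert not res.passed

    def test_requires_units_and_events(self, grid_session):
        ev = grid_session.event_times("precue_poke")
        with pytest.raises(ValueError, match="unit"):
            ephys.population_count_test([], ev, (0.0, 600.0), n_iter=150)
        train = ephys.SpikeTrain("u", np.linspace(1, 599, 50), (0.0, 600.0))
        with pytest.raises(ValueError, match="events"):
            ephys.population_count_test([train], [10.0], (0.0, 600.0),
                                        n_iter=150)

    def test_short_session_warns(self):
        train = ephys.SpikeTrain("u", np.sort(
            np.random.default_rng(0).uniform(0, 60, 600)), (0.0, 60.0))
        with pytest.warns(UserWarning, match="short"):
            ephys.population_count_test(train and [train], [20.0, 40.0],
                                        (0.0, 60.0), n_iter=150,
                                        cluster_n_iter=150, seed=0)


class TestPopulationPCA:
    def _mats(self, responses, n_trials=5, n_bins=40):
        out = []
        for r in responses:
            data = np.tile(r, (n_trials, 1))
            out.append(ephys.PeriEventMatrix("u", "e", (-5.0, 5.0), data, 0.25))
        return out

    def test_identical_event_responses_give_coincident_trajectories(self):
        rng = np.random.default_rng(15)
        pattern = [rng.normal(size=40) for _ in range(4)]
        mats = {lab: self._mats(pattern) for lab in ("a", "b")}
        res = ephys.population_pca_trajectories(mats, n_components=2)
        d = np.abs(res.trajectories["a"] - res.trajectories["b"]).max()
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_patterns_separate_in_component_space(self):
        n_bins = 40
        mats_a, mats_b = [], []
        for u in range(6):
            pa = np.zeros(n_bins)
            pa[10:20] = 1.0 if u % 2 else -1.0
            pb = np.zeros(n_bins)
            pb[25:35] = 1.0 if u < 3 else -1.0
            mats_a.append(self._mats([pa])[0])
            mats_b.append(self._mats([pb])[0])
        res = ephys.population_pca_trajectories({"a": mats_a, "b": mats_b})
        dist = np.linalg.norm(res.trajectories["a"] - res.trajectories["b"],
                              axis=1)
        assert dist.max() > 1.0

    def test_explained_variance_ratios_valid(self):
        rng = np.random.default_rng(16)
        mats = {"a": self._mats([rng.normal(size=40) for _ in range(5)])}
        res = ephys.population_pca_trajectories(mats, n_components=3)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_rank_truncation_warns(self):
        mats = {"a": self._mats([np.ones(40), 2 * np.ones(40)])}
        with pytest.warns(UserWarning, match="rank"):
            ephys.population_pca_trajectories(mats, n_components=10)


class TestRateByPrecueCategory:
    @pytest.mark.parametrize("rate,n,cat", [
        (0.14, 2, "low"), (0.15, 2, "mid"), (0.299, 2, "mid"),
        (0.3, 2, "high"), (0.31, 2, "high"), (0.0, 0, "none"),
    ])
    def test_category_boundaries(self, rate, n, cat):
        assert behavior.precue_rate_category(rate, n) == cat

    def _session_with_precue_rates(self, seed=17):
        agent = syn.AgentSpec("a", 0.7)
        task = syn.TaskConfig(session_cap_min=120.0)
        return syn.simulate_session(agent, task, seed=seed)

    def test_negative_coupling_gives_decreasing_category_means(self):
        session = self._session_with_precue_rates()
        unit = syn.UnitSpec("u", 10.0, (("precue_poke", 0.2, -0.5, 1.0),))
        train = syn.simulate_spike_trains(session, [unit], seed=18)[0]
        z = ephys.bin_and_zscore(train)
        table = behavior.per_trial_precue_rates(session)
        agg = ephys.rate_by_precue_category([(z, "Down")], table)
        sub = agg[agg["response_class"] == "Down"].set_index("category")
        present = [c for c in ("none", "low", "mid", "high")
                   if c in sub.index]
        vals = [sub.loc[c, "mean_dz"] for c in present]
        assert vals[0] > vals[-1]  # activity falls as precue load rises

    def test_uncoupled_unit_category_means_indistinguishable(self):
        from scipy import stats as st
        session = self._session_with_precue_rates(seed=19)
        unit = syn.UnitSpec("u", 10.0)
        train = syn.simulate_spike_trains(session, [unit], seed=20)[0]
        z = ephys.bin_and_zscore(train)
        table = behavior.per_trial_precue_rates(session)
        cats = [behavior.precue_rate_category(r, int(n)) for r, n in
                zip(table["precue_rate"], table["n_precue_pokes"])]
        table = table.assign(category=cats)
        groups = []
        c = z.bin_centers
        for _, sub in table.groupby("category"):
            vals = []
            for _, trial in sub.iterrows():
                sel = (c >= trial["precue_onset_s"]) & (c < trial["cue_onset_s"])
                if sel.any():
                    vals.append(z.z[sel].mean())
            if len(vals) >= 3:
                groups.append(vals)
        _, p = st.f_oneway(*groups)
        assert p > 0.05
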