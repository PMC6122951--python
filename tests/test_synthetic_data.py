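import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photospike.behavior_cpp import occupancy, preference_score
from photospike.core import DARK, GREEN, VIOLET, Epoch, LightSchedule, ValidationError
from photospike.pharmacology import photoinhibition_index
from photospike.photoswitch_analysis import analyze_neuron
from photospike.spiketrain_metrics import detect_bursts
from photospike.synthetic_data import (
    DEFAULT_COHORT,
    DEFAULT_SPECS,
    NeuronSpec,
    NicotineKernel,
    photoswitch_state,
    simulate_cohort,
    simulate_cpp_cohort,
    simulate_current_pairs,
    simulate_train,
)


class TestPhotoswitchState:
    def test_darkness_half_life(self):
        sched = LightSchedule((Epoch(0, 5, VIOLET),))
        state = photoswitch_state(sched)
        assert state.cis_fraction(5 + 74 * 60) == pytest.approx(0.5, abs=1e-9)

    def test_darkness_ten_minutes(self):
        sched = LightSchedule((Epoch(0, 5, VIOLET),))
        state = photoswitch_state(sched)
        expected = 0.5 ** (10 / 74)
        assert state.cis_fraction(5 + 600) == pytest.approx(expected, abs=1e-9)

    def test_green_epoch_relieves_fully(self):
        sched = LightSchedule((Epoch(0, 5, VIOLET), Epoch(5, 10, GREEN)))
        state = photoswitch_state(sched)
        assert state.cis_fraction(10.0) < 1e-6

    def test_violet_onset_is_instantaneous(self):
        sched = LightSchedule((Epoch(10, 15, VIOLET),))
        state = photoswitch_state(sched)
        assert state.cis_fraction(9.999) == 0.0
        assert state.cis_fraction(10.0) == 1.0

    def test_explicit_dark_epoch_decays(self):
        sched = LightSchedule(
            (Epoch(0, 5, VIOLET), Epoch(5, 5 + 74 * 60, DARK), Epoch(5 + 74 * 60, 5 + 74 * 60 + 1, GREEN))
        )
        state = photoswitch_state(sched)
        assert state.cis_fraction(5 + 74 * 60 - 1e-6) == pytest.approx(0.5, rel=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([VIOLET, GREEN, DARK]), min_size=1, max_size=12), st.integers(0, 1000))
    def test_cis_confined_to_unit_interval(self, wavelengths, offset):
        epochs, t = [], 0.0
        for wl in wavelengths:
            epochs.append(Epoch(t, t + 5.0, wl))
            t += 5.0 + (1.0 if wl == DARK else 0.0)
        state = photoswitch_state(LightSchedule(tuple(epochs)))
        ts = np.linspace(0, t + offset, 500)
        cis = state.cis_fraction(ts)
        assert np.all((cis >= 0) & (cis <= 1))

    def test_monotone_nonincreasing_in_darkness(self):
        sched = LightSchedule((Epoch(0, 5, VIOLET),))
        state = photoswitch_state(sched)
        ts = np.linspace(5, 5 + 3600, 200)
        cis = np.asarray(state.cis_fraction(ts))
        assert np.all(np.diff(cis) <= 0)


class TestSimulateTrain:
    def test_deterministic_under_seed(self, alt_schedule):
        spec = DEFAULT_SPECS["type1"]
        t1 = simulate_train(spec, alt_schedule, alt_schedule.t_stop, seed=3)
        t2 = simulate_train(spec, alt_schedule, alt_schedule.t_stop, seed=3)
        np.testing.assert_array_equal(t1.times, t2.times)

    def test_control_spec_index_near_zero(self, alt_schedule):
        spec = DEFAULT_SPECS["control"]
        idxs = [
            analyze_neuron(
                simulate_train(spec, alt_schedule, alt_schedule.t_stop, seed=s),
                alt_schedule,
            ).index
            for s in range(15)
        ]
        assert abs(np.mean(idxs)) < 5.0

    def test_burst_free_spec_yields_no_bursts(self, alt_schedule):
        spec = NeuronSpec(
            "control", tonic_rate_hz=2.0, isi_shape=8.0, burst_rate_per_min=0.0
        )
        train = simulate_train(spec, alt_schedule, alt_schedule.t_stop, seed=0)
        # high-shape renewal at 2 Hz essentially never makes an ISI < 80 ms
        assert len(detect_bursts(train)) == 0

    def test_long_run_rate_matches_spec(self):
        spec = NeuronSpec("control", tonic_rate_hz=3.0, burst_rate_per_min=0.0)
        duration = 1000.0
        train = simulate_train(spec, None, duration, seed=1)
        se = np.sqrt(3.0 / (spec.isi_shape * duration))
        assert abs(train.mean_rate - 3.0) < 3 * se

    def test_intra_burst_isis_below_80ms(self):
        spec = NeuronSpec("control", tonic_rate_hz=1.0, burst_rate_per_min=20.0)
        train = simulate_train(spec, None, 300.0, seed=2)
        bursts = detect_bursts(train)
        assert len(bursts) > 0

    def test_type1_spec_validation(self):
        with pytest.raises(ValidationError):
            NeuronSpec("type1", m_390=1.2)
        with pytest.raises(ValidationError):
            NeuronSpec("control", m_390=0.5)
        with pytest.raises(ValidationError):
            NeuronSpec("control", tonic_rate_hz=0.2)


class TestSimulateCohort:
    def test_composition_matches_truth_table(self):
        trains, metas, truth = simulate_cohort(seed=0)
        assert len(trains) == sum(DEFAULT_COHORT.values())
        counts = truth.groupby("true_class").size().to_dict()
        assert counts["type1"] == 24 and counts["type2"] == 9
        assert counts["nonresponder"] == 60 and counts["control"] == 28
        assert (truth[truth.true_class == "control"].cohort == "control").all()

    def test_same_seed_identical_recordings(self):
        small = {"control": 2, "type1": 2}
        t1, _, _ = simulate_cohort(small, seed=5)
        t2, _, _ = simulate_cohort(small, seed=5)
        for nid in t1:
            np.testing.assert_array_equal(t1[nid].times, t2[nid].times)

    def test_different_seed_differs(self):
        small = {"type1": 1}
        t1, _, _ = simulate_cohort(small, seed=1)
        t2, _, _ = simulate_cohort(small, seed=2)
        assert not np.array_equal(t1["type1_000"].times, t2["type1_000"].times)


class TestNicotineKernel:
    def test_peak_within_200s(self):
        kernel = NicotineKernel()
        assert kernel.peak_time() < 200.0
        dts = np.linspace(0, 400, 2000)
        h = kernel.shape(dts)
        assert h.max() == pytest.approx(1.0, abs=1e-3)
        assert h[0] == 0.0

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValidationError):
            NicotineKernel(rise_s=100.0, decay_s=50.0)


class TestCurrentPairs:
    def test_zero_noise_reproduces_fraction_exactly(self):
        cells = simulate_current_pairs(10, 0.67, noise_cv=0.0, seed=0)
        for c in cells:
            idx = photoinhibition_index(c.amplitude_380, c.amplitude_525)
            assert idx == pytest.approx(67.0)

    def test_zero_fraction_centers_on_zero(self):
        cells = simulate_current_pairs(200, 0.0, noise_cv=0.1, seed=1)
        idxs = [
            photoinhibition_index(c.amplitude_380, c.amplitude_525) for c in cells
        ]
        assert abs(np.mean(idxs)) < 3 * np.std(idxs) / np.sqrt(len(idxs))

    def test_noisy_mean_within_three_se(self):
        cells = simulate_current_pairs(100, 0.67, noise_cv=0.1, seed=2)
        idxs = np.array(
            [photoinhibition_index(c.amplitude_380, c.amplitude_525) for c in cells]
        )
        se = idxs.std(ddof=1) / np.sqrt(idxs.size)
        assert abs(idxs.mean() - 67.0) < 3 * se

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValidationError):
            simulate_current_pairs(5, 1.5)


class TestCPPCohort:
    def test_null_group_mean_near_zero(self):
        cohort = simulate_cpp_cohort(
            {"saline": 8}, conditioning_shift_s=0.0, seed=0
        )
        scores = [
            preference_score(a["sessions"]["test"], a["sessions"]["pretest"])
            for a in cohort["animals"]
        ]
        sem = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores)) < 3 * max(sem, 1.0)

    def test_conditioned_group_recovers_shift(self):
        cohort = simulate_cpp_cohort({"nicotine": 8}, seed=1)
        scores = np.array(
            [
                preference_score(a["sessions"]["test"], a["sessions"]["pretest"])
                for a in cohort["animals"]
            ]
        )
        sem = scores.std(ddof=1) / np.sqrt(scores.size)
        assert abs(scores.mean() - 166.0) < 3 * sem

    def test_occupancy_exact_to_frame_period(self):
        """Generated trajectories reproduce their per-zone frame counts."""
        cohort = simulate_cpp_cohort({"g": 1}, seed=2)
        animal = cohort["animals"][0]
        traj = animal["trajectories"]["pretest"]
        occ = occupancy(traj, cohort["zone_map"])
        stored = animal["sessions"]["pretest"].occupancy
        for zone, secs in stored.items():
            assert occ[zone] == pytest.approx(secs, abs=1e-9)
            assert (secs / 0.05) == pytest.approx(round(secs / 0.05))

    def test_same_seed_identical_sessions(self):
        c1 = simulate_cpp_cohort({"g": 2}, seed=3)
        c2 = simulate_cpp_cohort({"g": 2}, seed=3)
        for a1, a2 in zip(c1["animals"], c2["animals"]):
            np.testing.assert_array_equal(
                a1["trajectories"]["test"].x, a2["trajectories"]["test"].x
            )

    def test_excessive_shift_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cpp_cohort({"g": 2}, conditioning_shift_s=1000.0)
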