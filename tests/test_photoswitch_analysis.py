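import numpy as np
import pytest

from photospike.core import Epoch, LightSchedule, SpikeTrain, ValidationError
from photospike.photoswitch_analysis import (
    FIXED_15PCT,
    PhotoswitchResult,
    ThresholdSpec,
    analyze_neuron,
    classify_neuron,
    cohort_compare,
    control_threshold,
    epoch_frequencies,
    photoswitching_index,
    swb_frequency_by_epoch,
)
from photospike.spiketrain_metrics import detect_bursts
from photospike.synthetic_data import (
    DEFAULT_SPECS,
    alternating_schedule,
    simulate_train,
)


def _result(index: float) -> PhotoswitchResult:
    return PhotoswitchResult("n", f_390=1.0, f_520=1.0, index=index)


@pytest.fixture
def four_epoch_schedule():
    return LightSchedule(
        (Epoch(0, 5, 390), Epoch(5, 10, 520), Epoch(10, 15, 390), Epoch(15, 20, 520))
    )


class TestEpochFrequencies:
    def test_pooled_counts(self, four_epoch_schedule):
        # 5 spikes in each 390 epoch, 15 in each 520 epoch
        t390 = np.concatenate([np.linspace(0.5, 4.5, 5), np.linspace(10.5, 14.5, 5)])
        t520 = np.concatenate([np.linspace(5.2, 9.8, 15), np.linspace(15.2, 19.8, 15)])
        train = SpikeTrain("n", np.sort(np.concatenate([t390, t520])), 0, 20)
        f_390, f_520 = epoch_frequencies(train, four_epoch_schedule)
        assert (f_390, f_520) == (pytest.approx(1.0), pytest.approx(3.0))

    def test_symmetric_spiking_gives_equal_frequencies(self, four_epoch_schedule):
        times = np.arange(0.25, 20, 0.5)
        train = SpikeTrain("n", times, 0, 20)
        f_390, f_520 = epoch_frequencies(train, four_epoch_schedule)
        assert f_390 == pytest.approx(f_520)

    def test_empty_train_gives_zero(self, four_epoch_schedule):
        train = SpikeTrain("n", [], 0, 20)
        assert epoch_frequencies(train, four_epoch_schedule) == (0.0, 0.0)

    def test_missing_wavelength_rejected(self):
        schedule = LightSchedule((Epoch(0, 5, 390),))
        train = SpikeTrain("n", [1.0], 0, 5)
        with pytest.raises(ValidationError, match="520"):
            epoch_frequencies(train, schedule)

    def test_per_epoch_average_variant(self, four_epoch_schedule):
        # 4 spikes in the first 390 epoch, none in the second: pooled gives
        # 0.4 Hz; the per-epoch mean gives (0.8 + 0) / 2
        train = SpikeTrain("n", [1.0, 2.0, 3.0, 4.0, 6.0], 0, 20)
        pooled, _ = epoch_frequencies(train, four_epoch_schedule)
        mean_of, _ = epoch_frequencies(train, four_epoch_schedule, pooled=False)
        assert pooled == pytest.approx(0.4)
        assert mean_of == pytest.approx(0.4)  # equal durations: same value


class TestPhotoswitchingIndex:
    @pytest.mark.parametrize(
        "f_520,f_390,expected",
        [
            (4.0, 2.0, 100.0),
            (2.0, 4.0, -50.0),
            # the type 1 group means: 1.85 Hz under violet, 3.41 Hz under green
            (3.41, 1.85, 84.32),
            # the type 2 group means reversed in sign
            (3.48, 5.25, -33.71),
        ],
    )
    def test_formula(self, f_520, f_390, expected):
        assert photoswitching_index(f_520, f_390) == pytest.approx(expected, abs=0.01)

    def test_identity_is_zero(self):
        assert photoswitching_index(3.3, 3.3) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="undefined"):
            photoswitching_index(2.0, 0.0)

    def test_antisymmetric_sign_under_role_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.uniform(0.5, 10, 2)
            if a == b:
                continue
            assert np.sign(photoswitching_index(a, b)) == -np.sign(
                photoswitching_index(b, a)
            )


class TestControlThreshold:
    def test_interpolated_order_statistic(self):
        spec = control_threshold(np.arange(1.0, 21.0), 0.95)
        assert spec.value == pytest.approx(19.05)
        assert spec.method == "control_quantile"

    def test_degenerate_distribution(self):
        spec = control_threshold(np.full(10, 3.0))
        assert spec.value == pytest.approx(3.0)

    def test_too_few_controls_advises_fixed_default(self):
        with pytest.raises(ValidationError, match="15%"):
            control_threshold(np.array([1.0, 2.0]))

    def test_fixed_method_is_15_percent(self):
        assert FIXED_15PCT.value == 15.0
        assert FIXED_15PCT.method == "fixed"


class TestClassification:
    @pytest.mark.parametrize(
        "index,expected",
        [
            (84.0, "type1"),  # firing lower under 390 nm
            (-34.0, "type2"),  # firing higher under 390 nm
            (10.0, "nonresponder"),
            (-10.0, "nonresponder"),
            (15.0, "type1"),  # exactly at threshold counts as responder
            (-15.0, "type2"),
        ],
    )
    def test_labels(self, index, expected):
        assert classify_neuron(_result(index), FIXED_15PCT) == expected

    def test_custom_threshold(self):
        thr = ThresholdSpec(value=50.0, method="fixed")
        assert classify_neuron(_result(30.0), thr) == "nonresponder"


class TestSwbFrequencyByEpoch:
    def test_burst_inside_green_epoch(self, four_epoch_schedule):
        # one 3-spike burst inside the first 520 epoch; 10 s of 520 in total
        times = np.array([1.0, 6.0, 6.05, 6.10, 12.0, 18.0])
        train = SpikeTrain("n", times, 0, 20)
        bursts = detect_bursts(train)
        swb_390, swb_520 = swb_frequency_by_epoch(train, bursts, four_epoch_schedule)
        assert swb_390 == 0.0
        assert swb_520 == pytest.approx(0.3)

    def test_burst_free_train(self, four_epoch_schedule):
        train = SpikeTrain("n", np.arange(0.5, 20, 1.0), 0, 20)
        bursts = detect_bursts(train)
        assert swb_frequency_by_epoch(train, bursts, four_epoch_schedule) == (0.0, 0.0)


class TestCohortCompare:
    def test_identical_cohorts(self):
        res = [_result(i) for i in (1.0, 2.0, 30.0)]
        summ = cohort_compare(res, res)
        assert summ["ks_statistic"] == 0.0
        assert (
            summ["control"]["responder_fraction"]
            == summ["transduced"]["responder_fraction"]
        )

    def test_disjoint_supports(self):
        ctrl = [_result(0.0) for _ in range(5)]
        trans = [_result(50.0) for _ in range(5)]
        summ = cohort_compare(ctrl, trans)
        assert summ["ks_statistic"] == 1.0
        assert summ["transduced"]["responder_fraction"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cohort_compare([], [_result(1.0)])


class TestSimulatedRecovery:
    def test_light_independent_neurons_have_near_zero_index(self):
        """Control units show |index| near 0 and rarely cross an
        independently built control-quantile threshold."""
        schedule = alternating_schedule()
        spec = DEFAULT_SPECS["control"]

        def cohort_abs(seed0, n):
            out = []
            for s in range(n):
                tr = simulate_train(spec, schedule, schedule.t_stop, seed=seed0 + s)
                res = analyze_neuron(tr, schedule)
                out.append(res.abs_index)
            return np.array(out)

        test_cohort = cohort_abs(100, 25)
        thr_cohort = cohort_abs(200, 25)
        thr = control_threshold(thr_cohort, 0.95)
        assert test_cohort.mean() < 5.0
        exceed = np.mean(test_cohort >= thr.value)
        # expected 5% exceedance; both cohorts contribute binomial error
        band = 0.05 + 3 * np.sqrt(0.05 * 0.95 * (1 / 25 + 1 / 25))
        assert exceed <= band

    def test_type1_index_recovers_construction_value(self):
        """Recovered index approaches 100*(1-m)/m for suppressed units."""
        schedule = alternating_schedule()
        spec = DEFAULT_SPECS["type1"]
        target = 100 * (1 - spec.m_390) / spec.m_390
        idxs = [
            analyze_neuron(
                simulate_train(spec, schedule, schedule.t_stop, seed=300 + s),
                schedule,
            ).index
            for s in range(25)
        ]
        assert abs(np.mean(idxs) - target) < 10.0
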