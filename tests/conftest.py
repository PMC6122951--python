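import numpy as np
import pytest

from photospike.core import LightSchedule, SpikeTrain
from photospike.synthetic_data import alternating_schedule


@pytest.fixture
def alt_schedule() -> LightSchedule:
    """200 s dark baseline + 20 cycles of 5 s 390/520 nm flashes."""
    return alternating_schedule()


@pytest.fixture
def make_train():
    def _make(times, t_start=0.0, t_stop=None, neuron_id="n1"):
        times = np.asarray(times, dtype=float)
        if t_stop is None:
            t_stop = float(times[-1]) + 1.0 if times.size else 1.0
        return SpikeTrain(neuron_id, times, t_start=t_start, t_stop=t_stop)

    return _make


@pytest.fixture
def grid_train():
    """Perfectly regular train at a given rate over a span."""

    def _make(rate_hz, duration_s, t_start=0.0, phase=None):
        dt = 1.0 / rate_hz
        if phase is None:
            phase = dt / 2
        times = np.arange(t_start + phase, t_start + duration_s, dt)
        return SpikeTrain("grid", times, t_start=t_start, t_stop=t_start + duration_s)

    return _make


def brute_force_bursts(times, onset_ms=80.0, close_ms=160.0):
    """Independent burst scanner used as the oracle for detect_bursts.

    Tests every candidate contiguous range directly against the burst
    invariants (opening ISI < onset, internal ISIs <= close, following ISI
    > close or end of train), taking for each unconsumed start the maximal
    qualifying range.
    """
    times = np.asarray(times, dtype=float)
    onset, close = onset_ms / 1000.0, close_ms / 1000.0
    n = times.size
    bursts = []
    consumed = -1
    for s in range(n - 1):
        if s <= consumed:
            continue
        if times[s + 1] - times[s] >= onset:
            continue
        e = s + 1
        while e + 1 < n and times[e + 1] - times[e] <= close:
            e += 1
        isis = np.diff(times[s : e + 1])
        assert isis[0] < onset and np.all(isis <= close)
        if e + 1 < n:
            assert times[e + 1] - times[e] > close
        bursts.append((s, e))
        consumed = e
    return bursts


@pytest.fixture
def burst_oracle():
    return brute_force_bursts


def random_trains(n_trains, seed, max_duration=60.0):
    """Randomized mixed trains: Poisson at varied rates plus injected
    high-frequency clusters, for oracle-equivalence sweeps."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trains):
        duration = rng.uniform(5.0, max_duration)
        rate = rng.uniform(0.5, 15.0)
        n = rng.poisson(rate * duration)
        times = np.sort(rng.uniform(0, duration, size=n))
        if rng.random() < 0.7 and n > 0:
            n_clusters = rng.integers(1, 6)
            extra = []
            for _ in range(n_clusters):
                t0 = rng.uniform(0, duration)
                size = rng.integers(2, 8)
                isis = rng.uniform(0.01, 0.2, size=size - 1)
                extra.append(t0 + np.concatenate([[0], np.cumsum(isis)]))
            times = np.sort(np.concatenate([times] + extra))
        times = times[(times >= 0) & (times < duration)]
        keep = np.concatenate([[True], np.diff(times) > 1e-6])
        times = times[keep]
        yield SpikeTrain("rand", times, t_start=0.0, t_stop=duration)
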