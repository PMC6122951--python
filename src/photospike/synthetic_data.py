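"""Synthetic inputs with the statistical structure the analyses assume.

Every file format and in-memory object the pipeline consumes can be
generated here at desk scale: the bistable cis/trans state of the tethered
azobenzene photoswitch, light-modulated tonic/bursting dopamine-neuron-like
spike trains, nicotine-evoked firing transients, paired evoked-current
amplitudes, and two-chamber place-preference trajectories.

The receptor-to-rate coupling is deliberately minimal: the instantaneous
tonic and burst-entry rates are multiplied by ``1 + (m_390 - 1) * cis(t)``,
where ``cis(t)`` is the photoswitch cis fraction and ``m_390`` the rate
multiplier under full antagonism.  No biophysics is modelled — the
generator exists so every analysis stage has a ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DARK,
    GREEN,
    VIOLET,
    Epoch,
    InjectionEvent,
    LightSchedule,
    NeuronMeta,
    SpikeTrain,
    ValidationError,
)
from .pharmacology import CurrentMeasurement

#: Default cis->trans thermal relaxation half-life in darkness (minutes).
T_HALF_DARK_MIN = 74.0
#: Default relief time constant under green light (s): relief is essentially
#: complete (~95%) within 450 ms, matching full current recovery in < 500 ms.
RELIEF_TAU_S = 0.15

def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-neuron streams from one seed (counter-based spawn)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Photoswitch state kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotoswitchState:
    """Piecewise cis-fraction trajectory implied by a light schedule.

    Violet (390 nm) light drives the azobenzene to *cis* instantaneously at
    epoch onset and holds it there; green (520 nm) relieves antagonism with
    time constant ``relief_s``; darkness relaxes cis -> trans thermally with
    half-life ``t_half_min``.  The trajectory is exact (piecewise analytic),
    monotone non-increasing within any lights-off segment, and confined to
    [0, 1].
    """

    # segments: (t0, mode, c0) with mode in {"hold", "relief", "dark"};
    # each segment runs to the next t0, the last extends to +inf as darkness
    segments: tuple[tuple[float, str, float], ...]
    t_half_min: float = T_HALF_DARK_MIN
    relief_s: float = RELIEF_TAU_S

    @property
    def _tau_dark_s(self) -> float:
        return self.t_half_min * 60.0 / math.log(2.0)

    def cis_fraction(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([s[0] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t_arr, side="right") - 1, 0, None)
        out = np.empty_like(t_arr)
        for k, (t0, mode, c0) in enumerate(self.segments):
            sel = idx == k
            if not sel.any():
                continue
            dt = t_arr[sel] - t0
            if mode == "hold":
                out[sel] = c0
            elif mode == "relief":
                out[sel] = c0 * np.exp(-dt / self.relief_s)
            else:  # dark
                out[sel] = c0 * np.power(0.5, dt / (self.t_half_min * 60.0))
        out[t_arr < starts[0]] = 0.0
        return out if np.ndim(t) else float(out[0])


def photoswitch_state(
    schedule: LightSchedule,
    t_half_min: float = T_HALF_DARK_MIN,
    relief_s: float = RELIEF_TAU_S,
    initial_cis: float = 0.0,
) -> PhotoswitchState:
    """Cis-fraction trajectory for a light schedule.

    Gaps between epochs and the tail after the last epoch count as darkness.
    From full *cis*, 74 min of darkness leaves a fraction of exactly 0.5 and
    10 min leaves ``0.5 ** (10 / 74)`` (about 0.911).
    """
    if not 0.0 <= initial_cis <= 1.0:
        raise ValidationError("initial_cis must lie in [0, 1]")
    segments: list[tuple[float, str, float]] = []
    cis = float(initial_cis)
    # darkness precedes the first epoch (relevant when initial_cis > 0)
    t_prev_end: float | None = min(0.0, schedule.t_start) if len(schedule) else None

    def close_gap(t_on: float) -> None:
        nonlocal cis, t_prev_end
        if t_prev_end is not None and t_on > t_prev_end:
            segments.append((t_prev_end, "dark", cis))
            cis = cis * 0.5 ** ((t_on - t_prev_end) / (t_half_min * 60.0))

    for epoch in schedule:
        close_gap(epoch.t_on)
        if epoch.wavelength == VIOLET:
            cis = 1.0
            segments.append((epoch.t_on, "hold", cis))
        elif epoch.wavelength == GREEN:
            segments.append((epoch.t_on, "relief", cis))
            cis = cis * math.exp(-epoch.duration / relief_s)
        else:  # explicit dark epoch
            segments.append((epoch.t_on, "dark", cis))
            cis = cis * 0.5 ** (epoch.duration / (t_half_min * 60.0))
        t_prev_end = epoch.t_off
    if t_prev_end is not None:
        segments.append((t_prev_end, "dark", cis))
    if not segments:
        segments.append((0.0, "dark", initial_cis))
    return PhotoswitchState(
        tuple(segments), t_half_min=t_half_min, relief_s=relief_s
    )


# ---------------------------------------------------------------------------
# Neuron specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters of one simulated pDA-like unit.

    ``m_390`` is the firing-rate multiplier under full antagonism: 1 for
    control and non-responding neurons, < 1 for type 1 (firing suppressed
    under 390 nm) and > 1 for type 2 (firing enhanced under 390 nm).
    """

    neuron_type: str  # "control" | "nonresponder" | "type1" | "type2"
    tonic_rate_hz: float = 4.0
    isi_shape: float = 4.0  # gamma renewal shape; CV = shape**-0.5
    burst_rate_per_min: float = 4.0
    burst_size_mean: float = 3.2  # 2 + geometric tail
    intra_burst_isi_ms: tuple[float, float] = (30.0, 70.0)
    m_390: float = 1.0
    rebound_amp: float = 0.0  # optional transient rate boost after relief
    rebound_tau_s: float = 1.0

    def __post_init__(self) -> None:
        if self.neuron_type not in ("control", "nonresponder", "type1", "type2"):
            raise ValidationError(f"unknown neuron type {self.neuron_type!r}")
        if not 1.0 <= self.tonic_rate_hz <= 10.0:
            raise ValidationError("pDA tonic rate must lie in [1, 10] Hz")
        if self.m_390 <= 0:
            raise ValidationError("m_390 must be > 0 (rate cannot vanish)")
        if self.neuron_type in ("control", "nonresponder") and self.m_390 != 1.0:
            raise ValidationError(f"{self.neuron_type} spec requires m_390 = 1")
        if self.neuron_type == "type1" and self.m_390 >= 1.0:
            raise ValidationError("type1 spec requires m_390 < 1")
        if self.neuron_type == "type2" and self.m_390 <= 1.0:
            raise ValidationError("type2 spec requires m_390 > 1")
        lo, hi = self.intra_burst_isi_ms
        if not 0 < lo <= hi < 80.0:
            raise ValidationError("intra-burst ISIs must stay below 80 ms")


#: Versioned default class parameters.  Type 1 and type 2 effect sizes mirror
#: the measured group means: 3.41 Hz under green falling to 1.85 Hz under
#: violet (m = 1.85/3.41) and 3.48 Hz rising to 5.25 Hz (m = 5.25/3.48).
DEFAULT_SPECS: dict[str, NeuronSpec] = {
    "control": NeuronSpec("control", tonic_rate_hz=4.0),
    "nonresponder": NeuronSpec("nonresponder", tonic_rate_hz=4.0),
    "type1": NeuronSpec("type1", tonic_rate_hz=3.41, m_390=1.85 / 3.41),
    "type2": NeuronSpec("type2", tonic_rate_hz=3.48, m_390=5.25 / 3.48),
}

#: Default cohort composition: 93 transduced units (60 non-responding,
#: 24 type 1, 9 type 2) and an independent cohort of 28 controls.
DEFAULT_COHORT: dict[str, int] = {
    "control": 28,
    "nonresponder": 60,
    "type1": 24,
    "type2": 9,
}


def alternating_schedule(
    n_cycles: int = 20,
    epoch_s: float = 5.0,
    baseline_dark_s: float = 200.0,
    first: int = VIOLET,
) -> LightSchedule:
    """Darkness baseline followed by alternating 5 s violet/green flashes."""
    second = GREEN if first == VIOLET else VIOLET
    epochs = []
    if baseline_dark_s > 0:
        epochs.append(Epoch(0.0, baseline_dark_s, DARK))
    t = baseline_dark_s
    for _ in range(n_cycles):
        epochs.append(Epoch(t, t + epoch_s, first))
        epochs.append(Epoch(t + epoch_s, t + 2 * epoch_s, second))
        t += 2 * epoch_s
    return LightSchedule(tuple(epochs))


# ---------------------------------------------------------------------------
# Spike-train generation (time-rescaled gamma renewal + burst insertion)
# ---------------------------------------------------------------------------

_GRID_DT = 0.005  # s; rate-grid resolution for time rescaling


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _rate_multiplier(
    spec: NeuronSpec, state: PhotoswitchState, grid: np.ndarray,
    schedule: LightSchedule | None,
) -> np.ndarray:
    cis = np.asarray(state.cis_fraction(grid))
    mult = 1.0 + (spec.m_390 - 1.0) * cis
    if spec.rebound_amp > 0 and schedule is not None:
        for t_rel in schedule.transitions(from_nm=VIOLET, to_nm=GREEN):
            dt = grid - t_rel
            mult += np.where(
                dt >= 0, spec.rebound_amp * np.exp(-dt / spec.rebound_tau_s), 0.0
            )
    if np.any(mult <= 0):
        raise ValidationError("rate multiplier drove the firing rate to <= 0")
    return mult


def _renewal_times(
    grid: np.ndarray, rate: np.ndarray, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous gamma-renewal process by time rescaling.

    Unit-mean gamma ISIs are generated in operational time and mapped back
    through the inverse cumulative intensity, which is exact for a renewal
    process with intensity modulated on the operational-time axis.
    """
    dt = grid[1] - grid[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    grid_edges = np.concatenate([grid, [grid[-1] + dt]])
    total = cum[-1]
    n_draw = int(total + 6.0 * math.sqrt(max(total, 1.0)) + 20)
    isis = rng.gamma(shape, 1.0 / shape, size=n_draw)
    ops = np.cumsum(isis)
    ops = ops[ops < total]
    while ops.size and ops[-1] < total * 0.999 and isis.size:  # pragma: no cover
        extra = rng.gamma(shape, 1.0 / shape, size=n_draw)
        ops = np.concatenate([ops, ops[-1] + np.cumsum(extra)])
        ops = ops[ops < total]
    return np.interp(ops, cum, grid_edges)


def _poisson_times(
    grid: np.ndarray, rate: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson event times by the same time rescaling."""
    dt = grid[1] - grid[0]
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    grid_edges = np.concatenate([grid, [grid[-1] + dt]])
    total = cum[-1]
    n = rng.poisson(total)
    ops = np.sort(rng.uniform(0.0, total, size=n))
    return np.interp(ops, cum, grid_edges)


def _insert_bursts(
    tonic: np.ndarray,
    burst_onsets: np.ndarray,
    spec: NeuronSpec,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    spikes = [tonic]
    lo, hi = (v / 1000.0 for v in spec.intra_burst_isi_ms)
    p = 1.0 / max(spec.burst_size_mean - 2.0 + 1.0, 1.0)
    for t0 in burst_onsets:
        size = 2 + rng.geometric(p) - 1  # >= 2 spikes per burst
        isis = rng.uniform(lo, hi, size=size - 1)
        spikes.append(t0 + np.concatenate([[0.0], np.cumsum(isis)]))
    merged = np.sort(np.concatenate(spikes))
    merged = merged[(merged >= 0.0) & (merged < duration_s)]
    if merged.size:
        # enforce strict ordering with a 1 ms refractory guard
        keep = np.concatenate([[True], np.diff(merged) > 1e-3])
        merged = merged[keep]
    return merged


def simulate_train(
    spec: NeuronSpec,
    schedule: LightSchedule | None,
    duration_s: float,
    seed: int | np.random.Generator,
    neuron_id: str = "sim",
    relief_s: float = RELIEF_TAU_S,
    t_half_min: float = T_HALF_DARK_MIN,
) -> SpikeTrain:
    """Simulate one light-modulated tonic/bursting spike train.

    Tonic firing is a gamma-renewal process whose instantaneous rate is the
    base rate scaled by the photoswitch multiplier; bursts are entered as an
    inhomogeneous Poisson process at ``burst_rate_per_min`` (same
    multiplier) and emit 2+ spikes with intra-burst ISIs below 80 ms.
    Reproducible given the seed.
    """
    rng = _as_rng(seed)
    if schedule is not None and schedule.t_stop > duration_s:
        raise ValidationError("duration must cover the light schedule")
    grid = np.arange(0.0, duration_s, _GRID_DT)
    if schedule is not None:
        state = photoswitch_state(schedule, t_half_min=t_half_min, relief_s=relief_s)
        mult = _rate_multiplier(spec, state, grid, schedule)
    else:
        mult = np.ones_like(grid)
    tonic = _renewal_times(grid, spec.tonic_rate_hz * mult, spec.isi_shape, rng)
    if spec.burst_rate_per_min > 0:
        onsets = _poisson_times(grid, spec.burst_rate_per_min / 60.0 * mult, rng)
    else:
        onsets = np.empty(0)
    times = _insert_bursts(tonic, onsets, spec, duration_s, rng)
    return SpikeTrain(neuron_id, times, t_start=0.0, t_stop=duration_s)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    counts: dict[str, int] | None = None,
    seed: int = 0,
    schedule: LightSchedule | None = None,
    duration_s: float | None = None,
    specs: dict[str, NeuronSpec] | None = None,
    rate_jitter_cv: float = 0.25,
) -> tuple[dict[str, SpikeTrain], dict[str, NeuronMeta], pd.DataFrame]:
    """Simulate a labelled cohort of units plus its ground-truth table.

    Default composition mirrors the recorded population (28 controls;
    93 transduced split 60 non-responders / 24 type 1 / 9 type 2) under the
    20-cycle alternating-flash protocol.  Each neuron draws its base rate
    around the class default (lognormal jitter, truncated to [1, 10] Hz) from
    its own counter-derived stream, so the cohort is reproducible and any
    subset can be regenerated.
    """
    counts = dict(DEFAULT_COHORT if counts is None else counts)
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    if schedule is None:
        schedule = alternating_schedule()
    if duration_s is None:
        duration_s = schedule.t_stop
    n_total = sum(counts.values())
    rngs = _spawn_rngs(seed, n_total)
    trains: dict[str, SpikeTrain] = {}
    metas: dict[str, NeuronMeta] = {}
    rows = []
    i = 0
    for cls in sorted(counts):
        base_spec = specs[cls]
        for k in range(counts[cls]):
            rng = rngs[i]
            nid = f"{cls}_{k:03d}"
            sigma = math.sqrt(math.log(1.0 + rate_jitter_cv**2))
            rate = base_spec.tonic_rate_hz * rng.lognormal(-sigma**2 / 2, sigma)
            rate = float(np.clip(rate, 1.0, 10.0))
            spec = NeuronSpec(
                neuron_type=base_spec.neuron_type,
                tonic_rate_hz=rate,
                isi_shape=base_spec.isi_shape,
                burst_rate_per_min=base_spec.burst_rate_per_min,
                burst_size_mean=base_spec.burst_size_mean,
                intra_burst_isi_ms=base_spec.intra_burst_isi_ms,
                m_390=base_spec.m_390,
                rebound_amp=base_spec.rebound_amp,
                rebound_tau_s=base_spec.rebound_tau_s,
            )
            train = simulate_train(spec, schedule, duration_s, rng, neuron_id=nid)
            cohort = "control" if cls == "control" else "transduced"
            metas[nid] = NeuronMeta(
                neuron_id=nid,
                cohort=cohort,
                half_ap_width=float(rng.uniform(1.2, 1.8)),
                mean_rate=train.mean_rate,
                isi_cv=train.isi_cv(),
            )
            trains[nid] = train
            rows.append(
                {
                    "neuron_id": nid,
                    "cohort": cohort,
                    "true_class": cls if cls != "control" else "control",
                    "base_rate_hz": rate,
                    "m_390": spec.m_390,
                }
            )
            i += 1
    truth = pd.DataFrame(rows)
    return trains, metas, truth


# ---------------------------------------------------------------------------
# Nicotine sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NicotineKernel:
    """Multiplicative firing transient following an i.v. nicotine bolus.

    The rate multiplier is ``1 + (g - 1) * h(t)`` with a double-exponential
    ``h`` normalized to peak 1; default time constants put the peak around
    60 s post-injection, comfortably inside the 200 s response horizon.
    Under *cis* (antagonized) receptors the rate increment is scaled by the
    ``antagonism_factor``.
    """

    latency_s: float = 5.0
    peak_multiplier: float = 2.0  # g
    rise_s: float = 25.0
    decay_s: float = 150.0
    antagonism_factor: float = 0.4

    def __post_init__(self) -> None:
        if self.peak_multiplier <= 0:
            raise ValidationError("peak multiplier must be > 0")
        if not 0 < self.rise_s < self.decay_s:
            raise ValidationError("require 0 < rise_s < decay_s")
        if self.peak_time() > 200.0:
            raise ValidationError("kernel peak must occur within 200 s")

    def peak_time(self) -> float:
        r, d = self.rise_s, self.decay_s
        return self.latency_s + math.log(d / r) * r * d / (d - r)

    def shape(self, dt: np.ndarray) -> np.ndarray:
        """Normalized transient h(dt), peak 1, zero before the latency."""
        r, d = self.rise_s, self.decay_s
        tp = self.peak_time() - self.latency_s
        norm = math.exp(-tp / d) - math.exp(-tp / r)
        u = np.clip(dt - self.latency_s, 0.0, None)
        h = (np.exp(-u / d) - np.exp(-u / r)) / norm
        return np.where(dt >= self.latency_s, h, 0.0)


def injection_light_schedule(
    injections: list[InjectionEvent],
    flash_lead_s: float = 10.0,
    flash_total_s: float = 30.0,
) -> LightSchedule:
    """Light epochs implied by the injection protocol: the flash starts
    ``flash_lead_s`` before each injection and lasts ``flash_total_s``."""
    epochs = []
    for inj in injections:
        if inj.light_condition == "dark":
            continue
        wl = VIOLET if inj.light_condition == "390" else GREEN
        epochs.append(Epoch(inj.t - flash_lead_s, inj.t - flash_lead_s + flash_total_s, wl))
    return LightSchedule(tuple(sorted(epochs, key=lambda e: e.t_on)))


def simulate_nicotine_session(
    spec: NeuronSpec,
    kernel: NicotineKernel,
    injections: list[InjectionEvent],
    duration_s: float,
    seed: int | np.random.Generator,
    neuron_id: str = "sim_nic",
    schedule: LightSchedule | None = None,
) -> SpikeTrain:
    """Simulate a juxtacellular-style session with nicotine transients.

    Each nicotine injection multiplies the rate by its kernel; saline
    injections are inert.  When the photoswitch is *cis* at response time
    (390 nm flash before the injection, persisting by dark bistability) the
    kernel's rate increment is scaled by the antagonism factor.  A baseline
    of at least 300 s before the first injection is required.
    """
    rng = _as_rng(seed)
    if injections and min(i.t for i in injections) < 300.0:
        raise ValidationError("need >= 300 s of baseline before the first injection")
    if sorted(i.t for i in injections) != [i.t for i in injections]:
        raise ValidationError("injections must be sorted in time")
    if schedule is None:
        schedule = injection_light_schedule(injections)
    grid = np.arange(0.0, duration_s, _GRID_DT)
    if len(schedule):
        state = photoswitch_state(schedule)
        cis = np.asarray(state.cis_fraction(grid))
    else:
        cis = np.zeros_like(grid)
    mult = 1.0 + (spec.m_390 - 1.0) * cis
    g = kernel.peak_multiplier
    for inj in injections:
        if inj.substance != "nicotine":
            continue
        h = kernel.shape(grid - inj.t)
        increment_scale = 1.0 - (1.0 - kernel.antagonism_factor) * cis
        mult = mult * (1.0 + (g - 1.0) * h * increment_scale)
    if np.any(mult <= 0):
        raise ValidationError("rate multiplier drove the firing rate to <= 0")
    tonic = _renewal_times(grid, spec.tonic_rate_hz * mult, spec.isi_shape, rng)
    if spec.burst_rate_per_min > 0:
        onsets = _poisson_times(grid, spec.burst_rate_per_min / 60.0 * mult, rng)
    else:
        onsets = np.empty(0)
    times = _insert_bursts(tonic, onsets, spec, duration_s, rng)
    return SpikeTrain(neuron_id, times, t_start=0.0, t_stop=duration_s)


# ---------------------------------------------------------------------------
# Place-preference trajectories
# ---------------------------------------------------------------------------

_FRAME_S = 0.05  # 20 samples/s


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    import shapely

    while out.shape[0] < n:
        m = max(2 * (n - out.shape[0]), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, x, y)
        out = np.vstack([out, np.column_stack([x[keep], y[keep]])])
    return out[:n]


def _trajectory_from_counts(
    zone_counts: dict[str, int],
    zone_map,
    rng: np.random.Generator,
    n_bouts: int = 8,
) -> "np.ndarray":
    """Frame-accurate visit sequence realising exact per-zone frame counts.

    Side visits alternate through the center compartment; frames within a
    bout are uniform points inside the zone polygon, so measured occupancy
    equals the requested counts times the frame period exactly.
    """
    from .behavior_cpp import Trajectory

    sides = [z for z in zone_counts if z != "center"]
    bouts: list[tuple[str, int]] = []
    per_side_bouts = {}
    for s in sides:
        n = zone_counts[s]
        weights = rng.dirichlet(np.full(n_bouts, 2.0))
        counts = np.floor(weights * n).astype(int)
        counts[0] += n - counts.sum()
        per_side_bouts[s] = [int(c) for c in counts if c > 0]
    n_center_visits = max(
        1, sum(len(v) for v in per_side_bouts.values()) - 1
    )
    c_total = zone_counts.get("center", 0)
    c_each = [c_total // n_center_visits] * n_center_visits
    for j in range(c_total - sum(c_each)):
        c_each[j % n_center_visits] += 1
    order = []
    iters = {s: iter(per_side_bouts[s]) for s in sides}
    alive = {s: True for s in sides}
    turn = rng.permutation(sides).tolist()
    ti = 0
    while any(alive.values()):
        s = turn[ti % len(turn)]
        ti += 1
        if not alive[s]:
            continue
        try:
            order.append((s, next(iters[s])))
        except StopIteration:
            alive[s] = False
    bouts = []
    ci = 0
    for j, (zone, cnt) in enumerate(order):
        bouts.append((zone, cnt))
        if j < len(order) - 1 and ci < len(c_each):
            bouts.append(("center", c_each[ci]))
            ci += 1
    while ci < len(c_each):  # leftover center frames appended at the end
        bouts.append(("center", c_each[ci]))
        ci += 1
    xs, ys = [], []
    for zone, cnt in bouts:
        if cnt <= 0:
            continue
        pts = _sample_in_polygon(zone_map.zones[zone], cnt, rng)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = x.size
    return Trajectory(
        t=_FRAME_S * np.arange(n), x=x, y=y, span=n * _FRAME_S
    )


def simulate_cpp_cohort(
    n_per_group: dict[str, int] | None = None,
    bias_sd_s: float = 120.0,
    conditioning_shift_s: float = 166.0,
    seed: int = 0,
    session_s: float = 900.0,
    center_mean_s: float = 100.0,
    ps_noise_sd_s: float = 100.0,
    conditioned_groups: tuple[str, ...] = ("nicotine",),
) -> dict:
    """Simulate pretest and test trajectories for CPP groups.

    Groups listed in ``conditioned_groups`` have their test-phase
    paired-side occupancy shifted by ``conditioning_shift_s`` on average
    (plus per-animal noise); all other groups are null.  Defaults emulate
    the recorded cohorts: 900 s sessions, per-animal pretest bias of SD
    ~120 s, and a conditioning shift on the scale of the wild-type nicotine
    group mean (~166 s).
    """
    from .behavior_cpp import default_zone_map, session_from_trajectory

    if n_per_group is None:
        n_per_group = {"saline": 6, "nicotine": 7}
    if conditioning_shift_s >= session_s:
        raise ValidationError("conditioning shift exceeds the session length")
    zone_map = default_zone_map()
    total_frames = int(round(session_s / _FRAME_S))
    animals = []
    n_total = sum(n_per_group.values())
    rngs = _spawn_rngs(seed, n_total)
    i = 0
    for group in sorted(n_per_group):
        shift = conditioning_shift_s if group in conditioned_groups else 0.0
        for k in range(n_per_group[group]):
            rng = rngs[i]
            aid = f"{group}_{k:02d}"
            center_s = float(np.clip(rng.normal(center_mean_s, 15.0), 40.0, 200.0))
            rem = session_s - center_s
            bias = float(np.clip(rng.normal(0.0, bias_sd_s), -rem / 2 + 60, rem / 2 - 60))
            paired_pre = rem / 2 + bias / 2
            noise = float(rng.normal(0.0, ps_noise_sd_s))
            paired_test = float(np.clip(paired_pre + shift + noise, 30.0, rem - 30.0))
            sessions = {}
            trajs = {}
            for phase, paired_s in (("pretest", paired_pre), ("test", paired_test)):
                c_n = int(round(center_s / _FRAME_S))
                p_n = int(round(paired_s / _FRAME_S))
                u_n = total_frames - c_n - p_n
                counts = {
                    zone_map.paired_side: p_n,
                    "side_B" if zone_map.paired_side == "side_A" else "side_A": u_n,
                    "center": c_n,
                }
                traj = _trajectory_from_counts(counts, zone_map, rng)
                trajs[phase] = traj
                sessions[phase] = session_from_trajectory(
                    aid, phase, traj, zone_map
                )
            animals.append(
                {
                    "animal_id": aid,
                    "group": group,
                    "pretest_bias_s": bias,
                    "true_shift_s": shift,
                    "trajectories": trajs,
                    "sessions": sessions,
                }
            )
            i += 1
    return {"zone_map": zone_map, "animals": animals}


# ---------------------------------------------------------------------------
# Evoked-current pairs
# ---------------------------------------------------------------------------

def simulate_current_pairs(
    n_cells: int,
    true_inhibition_fraction: float,
    noise_cv: float = 0.1,
    seed: int = 0,
    mean_amplitude_pa: float = -100.0,
    agonist: str = "nicotine",
    concentration_um: float = 500.0,
) -> list[CurrentMeasurement]:
    """Paired 380/525 nm evoked-current amplitudes with multiplicative noise.

    Constructed so the expected photo-inhibition index is
    ``100 * true_inhibition_fraction``: the 380 nm amplitude is the 525 nm
    amplitude scaled by ``(1 - fraction) * (1 + noise_cv * z)`` with
    symmetric, truncated Gaussian ``z``.
    """
    if not -1.0 <= true_inhibition_fraction <= 1.0:
        raise ValidationError("inhibition fraction must lie in [-1, 1]")
    rng = _as_rng(seed)
    out = []
    for i in range(n_cells):
        i_525 = mean_amplitude_pa * rng.lognormal(0.0, 0.3)
        z = float(np.clip(rng.normal(), -3.0, 3.0))
        i_380 = i_525 * (1.0 - true_inhibition_fraction) * (1.0 + noise_cv * z)
        out.append(
            CurrentMeasurement(
                cell_id=f"cell_{i:03d}",
                amplitude_380=i_380,
                amplitude_525=i_525,
                agonist=agonist,
                concentration=concentration_um,
            )
        )
    return out
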