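"""Burst detection, spikes-within-bursts statistics, sliding-window series
and event-aligned rasters / peri-stimulus time histograms.

Bursts follow the classic two-criterion extracellular rule for dopamine
neurons: a burst opens at the first spike pair separated by less than 80 ms
and closes at the first interval exceeding 160 ms.  %SWB (percent of spikes
within bursts) and burst frequency are the derived summaries used by the
photoswitching and pharmacology stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrain, ValidationError


@dataclass(frozen=True)
class BurstSet:
    """Detected bursts as inclusive ``(start, end)`` index ranges.

    Invariants: each burst spans >= 2 spikes; ranges are disjoint and sorted;
    the opening ISI is strictly below ``onset_ms``; internal ISIs never exceed
    ``close_ms``; the ISI following a burst (when one exists) is strictly
    above ``close_ms``.
    """

    bursts: tuple[tuple[int, int], ...]
    onset_ms: float
    close_ms: float

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    @property
    def n_spikes_in_bursts(self) -> int:
        return sum(e - s + 1 for s, e in self.bursts)

    def spike_mask(self, n_spikes: int) -> np.ndarray:
        """Boolean mask over the train's spikes: True inside a burst."""
        mask = np.zeros(n_spikes, dtype=bool)
        for s, e in self.bursts:
            if e >= n_spikes:
                raise ValidationError(
                    f"burst range ({s}, {e}) exceeds train of {n_spikes} spikes"
                )
            mask[s : e + 1] = True
        return mask


@dataclass(frozen=True)
class RateSeries:
    """Sliding-window series of firing rate (Hz) or %SWB.

    Window centers are spaced ``step_s`` apart; each value is computed over a
    full half-open window ``[center - window_s/2, center + window_s/2)``.
    """

    window_centers: np.ndarray
    values: np.ndarray
    window_s: float
    step_s: float
    kind: str  # "rate" | "pct_swb"

    def __post_init__(self) -> None:
        if self.kind not in ("rate", "pct_swb"):
            raise ValidationError(f"unknown series kind {self.kind!r}")
        c = np.asarray(self.window_centers, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "window_centers", c)
        object.__setattr__(self, "values", v)
        if c.size != v.size:
            raise ValidationError("centers and values differ in length")
        if np.any(v < 0):
            raise ValidationError("series values must be >= 0")
        if self.kind == "pct_swb" and np.any(v > 100):
            raise ValidationError("%SWB values cannot exceed 100")

    @property
    def window_starts(self) -> np.ndarray:
        return self.window_centers - self.window_s / 2

    @property
    def window_ends(self) -> np.ndarray:
        return self.window_centers + self.window_s / 2


@dataclass(frozen=True)
class AlignedHistogram:
    """Event-aligned spike histogram (raster counts + PSTH rate)."""

    bin_edges: np.ndarray  # s relative to event, uniform bins
    counts: np.ndarray  # (n_events, n_bins)
    rate: np.ndarray  # Hz per bin, pooled over events
    n_events: int


def detect_bursts(
    train: SpikeTrain, onset_ms: float = 80.0, close_ms: float = 160.0
) -> BurstSet:
    """Scan a train left to right for bursts by the 80 / 160 ms ISI rule.

    A burst opens at the first spike pair with ISI strictly below
    ``onset_ms`` (both spikes belong to the burst); later spikes are appended
    while the ISI stays at or below ``close_ms``; the burst closes at the
    first ISI strictly above ``close_ms`` or at the end of the train, and
    scanning resumes after the closing spike.  Trains with fewer than two
    spikes yield an empty burst set.
    """
    if not 0 < onset_ms <= close_ms:
        raise ValidationError("require 0 < onset_ms <= close_ms")
    onset_s, close_s = onset_ms / 1000.0, close_ms / 1000.0
    times = train.times
    isis = np.diff(times)
    bursts: list[tuple[int, int]] = []
    i = 0
    n = times.size
    while i < n - 1:
        if isis[i] < onset_s:
            j = i + 1
            while j < n - 1 and isis[j] <= close_s:
                j += 1
            bursts.append((i, j))
            i = j + 1
        else:
            i += 1
    return BurstSet(tuple(bursts), onset_ms=onset_ms, close_ms=close_ms)


def swb_fraction(train: SpikeTrain, bursts: BurstSet) -> float:
    """Percent of all spikes that fall within bursts (%SWB)."""
    if train.n_spikes == 0:
        return 0.0
    n_in = bursts.spike_mask(train.n_spikes).sum()
    return 100.0 * float(n_in) / train.n_spikes


def burst_frequency(train: SpikeTrain, bursts: BurstSet) -> float:
    """Bursts per minute over the recording span."""
    return 60.0 * len(bursts) / train.duration


def sliding_series(
    train: SpikeTrain,
    bursts: BurstSet | None = None,
    window_s: float = 60.0,
    step_s: float = 15.0,
    kind: str = "rate",
) -> RateSeries:
    """Sliding-window firing rate or %SWB series.

    Default 60 s windows advancing by 15 s reproduce the 45 s overlap between
    consecutive windows.  Windows are anchored at ``t_start``; a truncated
    final window is dropped so every value covers exactly ``window_s``.  When
    the recording is shorter than one window a single window anchored at
    ``t_start`` is used.
    """
    if not 0 < step_s < window_s:
        raise ValidationError("require window_s > step_s > 0")
    if kind == "pct_swb" and bursts is None:
        raise ValidationError("kind='pct_swb' requires a BurstSet")
    n_windows = max(1, int(np.floor((train.duration - window_s) / step_s)) + 1)
    starts = train.t_start + step_s * np.arange(n_windows)
    if kind == "rate":
        left = np.searchsorted(train.times, starts, side="left")
        right = np.searchsorted(train.times, starts + window_s, side="left")
        values = (right - left) / window_s
    elif kind == "pct_swb":
        mask = bursts.spike_mask(train.n_spikes)
        values = np.empty(n_windows)
        for k, s in enumerate(starts):
            lo = np.searchsorted(train.times, s, side="left")
            hi = np.searchsorted(train.times, s + window_s, side="left")
            total = hi - lo
            values[k] = (
                100.0 * mask[lo:hi].sum() / total if total else 0.0
            )
    else:
        raise ValidationError(f"unknown series kind {kind!r}")
    return RateSeries(
        window_centers=starts + window_s / 2,
        values=values,
        window_s=window_s,
        step_s=step_s,
        kind=kind,
    )


def aligned_histogram(
    train: SpikeTrain,
    event_times: np.ndarray,
    window: tuple[float, float] = (2.5, 2.5),
    bin_s: float = 0.25,
) -> AlignedHistogram:
    """Raster counts and PSTH rate aligned to events (e.g. light onsets).

    ``window`` is ``(pre_s, post_s)`` around each event; ``bin_s`` (default
    250 ms) must divide the window span evenly.  The pooled rate per bin is
    total count / (n_events x bin_s).
    """
    events = np.atleast_1d(np.asarray(event_times, dtype=float))
    if events.size == 0:
        raise ValidationError("aligned_histogram requires >= 1 event")
    pre_s, post_s = window
    span = pre_s + post_s
    n_bins_f = span / bin_s
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValidationError(
            f"bin_s={bin_s} does not evenly divide window span {span}"
        )
    edges = -pre_s + bin_s * np.arange(n_bins + 1)
    counts = np.empty((events.size, n_bins), dtype=int)
    for k, ev in enumerate(events):
        offsets = train.times - ev
        sel = offsets[(offsets >= -pre_s) & (offsets < post_s)]
        counts[k], _ = np.histogram(sel, bins=edges)
    rate = counts.sum(axis=0) / (events.size * bin_s)
    return AlignedHistogram(
        bin_edges=edges, counts=counts, rate=rate, n_events=int(events.size)
    )
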