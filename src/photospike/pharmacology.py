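"""Photo-inhibition of evoked nicotinic currents and the magnitude of
nicotine-evoked firing responses under different light conditions.

Two quantities are central here.  The photo-inhibition index of a cell,

    100 * (1 - I_380 / I_525),

is the fractional suppression of an agonist-evoked current under
antagonizing (380-390 nm) light relative to relieving (520-525 nm) light.
The nicotine response of a neuron is the largest-magnitude percent change
of the sliding-window firing rate (or %SWB) within 200 s of an i.v.
injection, relative to the pre-injection baseline; responses recorded under
light are normalized to the response obtained in darkness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InjectionEvent, SpikeTrain, ValidationError
from .spiketrain_metrics import BurstSet, RateSeries, sliding_series


@dataclass(frozen=True)
class CurrentMeasurement:
    """Paired evoked-current amplitudes of one cell (pA, negative inward)."""

    cell_id: str
    amplitude_380: float
    amplitude_525: float
    agonist: str = "nicotine"
    concentration: float = 30.0  # µM

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude_380) and np.isfinite(self.amplitude_525)):
            raise ValidationError(f"{self.cell_id}: amplitudes must be finite")
        if self.concentration <= 0:
            raise ValidationError(f"{self.cell_id}: concentration must be > 0")


@dataclass(frozen=True)
class NicotineResponse:
    """One injection's firing response under one light condition."""

    neuron_id: str
    condition: str  # "dark" | "390" | "520"
    baseline_hz: float
    peak_variation: float  # signed percent vs baseline
    swb_variation: float | None = None  # signed percent, bursting neurons only
    normalized: float | None = None  # percent of the dark response
    partial: bool = False  # series ended before the 200 s horizon


def photoinhibition_index(i_380: float, i_525: float) -> float:
    """Percent photo-inhibition of a current: 100 * (1 - I_380 / I_525).

    Both amplitudes must share a sign (inward currents are negative by
    convention); a negative index flags apparent potentiation.  Invariant to
    rescaling both amplitudes by any positive factor.
    """
    if i_525 == 0:
        raise ValidationError("photo-inhibition undefined for I_525 = 0")
    if i_380 != 0 and np.sign(i_380) != np.sign(i_525):
        raise ValidationError(
            "amplitudes of opposite sign — artifactual trace rejected"
        )
    return 100.0 * (1.0 - i_380 / i_525)


def baseline_rate(
    series: RateSeries,
    injection: InjectionEvent,
    baseline_span_s: float = 180.0,
) -> float:
    """Mean of sliding-window values whose windows end in the
    ``baseline_span_s`` seconds before the injection."""
    ends = series.window_ends
    sel = (ends >= injection.t - baseline_span_s) & (ends < injection.t)
    if not sel.any():
        raise ValidationError(
            f"no complete window ends within {baseline_span_s} s before the "
            f"injection at t={injection.t}"
        )
    return float(series.values[sel].mean())


def response_magnitude(
    series: RateSeries,
    injection: InjectionEvent,
    horizon_s: float = 200.0,
    baseline_span_s: float = 180.0,
) -> tuple[float, bool]:
    """Largest-magnitude percent variation within the post-injection horizon.

    Scans windows starting in ``[t, t + horizon_s)``, converts each to a
    percent variation from baseline and returns the excursion of largest
    absolute magnitude with its sign preserved (nicotine produces both
    excitations and inhibitions).  Returns ``(variation, partial)`` where
    ``partial`` flags a series that ends before the horizon.
    """
    base = baseline_rate(series, injection, baseline_span_s)
    if base <= 0:
        raise ValidationError("baseline rate must be > 0 for a percent response")
    starts = series.window_starts
    sel = (starts >= injection.t) & (starts < injection.t + horizon_s)
    if not sel.any():
        raise ValidationError("series has no window starting after the injection")
    variations = 100.0 * (series.values[sel] - base) / base
    # partial: the series ends before the last window of the horizon exists
    partial = bool(starts.max() < injection.t + horizon_s - series.step_s)
    peak = variations[np.argmax(np.abs(variations))]
    return float(peak), partial


def normalize_to_dark(resp_light: float, resp_dark: float) -> float:
    """Response under light as a percent of the dark response."""
    if resp_dark == 0:
        raise ValidationError("cannot normalize to a zero dark response")
    return 100.0 * resp_light / resp_dark


def nicotine_response(
    train: SpikeTrain,
    injection: InjectionEvent,
    bursts: BurstSet | None = None,
    window_s: float = 60.0,
    step_s: float = 15.0,
    horizon_s: float = 200.0,
    baseline_span_s: float = 180.0,
) -> NicotineResponse:
    """Full per-injection analysis on the 60 s / 15 s sliding series.

    %SWB variation is reported only for neurons with at least one burst in
    the pre-injection baseline; non-bursting neurons carry ``swb_variation``
    of None (excluded from SWB group statistics).
    """
    rate_series = sliding_series(train, window_s=window_s, step_s=step_s, kind="rate")
    base = baseline_rate(rate_series, injection, baseline_span_s)
    peak, partial = response_magnitude(
        rate_series, injection, horizon_s, baseline_span_s
    )
    swb_var: float | None = None
    if bursts is not None:
        has_baseline_burst = any(
            train.times[s] < injection.t for s, _ in bursts
        )
        if has_baseline_burst:
            swb_series = sliding_series(
                train, bursts, window_s=window_s, step_s=step_s, kind="pct_swb"
            )
            try:
                swb_var, _ = response_magnitude(
                    swb_series, injection, horizon_s, baseline_span_s
                )
            except ValidationError:
                swb_var = None
    return NicotineResponse(
        neuron_id=train.neuron_id,
        condition=injection.light_condition,
        baseline_hz=base,
        peak_variation=peak,
        swb_variation=swb_var,
        partial=partial,
    )


def check_refractory(
    series: RateSeries,
    previous: InjectionEvent,
    current: InjectionEvent,
    tolerance_fraction: float = 0.2,
) -> bool:
    """True when firing has returned to within ``tolerance_fraction`` of the
    pre-previous-injection baseline before the current injection; successive
    injections (up to six per neuron) are analysed independently, but this
    check lets callers warn on carry-over."""
    base_prev = baseline_rate(series, previous)
    ends = series.window_ends
    sel = (ends < current.t) & (series.window_starts >= previous.t)
    if not sel.any():
        return False
    last = series.values[sel][-1]
    return abs(last - base_prev) <= tolerance_fraction * base_prev
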