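"""Per-neuron light-epoch firing analysis: photoswitching index,
control-derived responder threshold, type 1 / type 2 classification and
cohort summaries.

The photoswitching index of a neuron is the percent change in firing
frequency between green (520 nm, antagonist relieved) and violet (390 nm,
receptor antagonized) illumination,

    index = 100 * (f_520 - f_390) / f_390 .

A positive index means the neuron fires less when the receptor is
antagonized (type 1); a negative index means it fires more (type 2).
Neurons whose absolute index stays below a threshold derived from the
control cohort are non-responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import GREEN, VIOLET, LightSchedule, SpikeTrain, ValidationError
from .spiketrain_metrics import BurstSet

NONRESPONDER = "nonresponder"
TYPE1 = "type1"  # firing reduced under 390 nm (index > 0)
TYPE2 = "type2"  # firing increased under 390 nm (index < 0)


@dataclass(frozen=True)
class PhotoswitchResult:
    """Epoch frequencies, photoswitching index and class of one neuron."""

    neuron_id: str
    f_390: float  # Hz, pooled over all 390 nm epochs
    f_520: float  # Hz, pooled over all 520 nm epochs
    index: float  # signed percent
    swb_freq_390: float = 0.0  # Hz of spikes-within-bursts per wavelength
    swb_freq_520: float = 0.0
    label: str = NONRESPONDER

    @property
    def abs_index(self) -> float:
        return abs(self.index)


@dataclass(frozen=True)
class ThresholdSpec:
    """Responder threshold in percent absolute photoswitching.

    ``method`` records whether the value is the fixed 15% rule or an
    empirical quantile of the control cohort chosen to exclude
    ``exclusion_fraction`` of control neurons.
    """

    value: float
    method: str  # "fixed" | "control_quantile"
    exclusion_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError("threshold value must be > 0")
        if self.method not in ("fixed", "control_quantile"):
            raise ValidationError(f"unknown threshold method {self.method!r}")
        if self.exclusion_fraction is not None and not (
            0 < self.exclusion_fraction < 1
        ):
            raise ValidationError("exclusion_fraction must be in (0, 1)")


#: The fixed threshold used for all recorded neurons in every condition.
FIXED_15PCT = ThresholdSpec(value=15.0, method="fixed")


def epoch_frequencies(
    train: SpikeTrain, schedule: LightSchedule, pooled: bool = True
) -> tuple[float, float]:
    """Firing frequency under 390 and 520 nm light.

    Default is the pooled definition: total spikes in all epochs of a
    wavelength divided by their total duration — robust for low rates over
    5 s flashes.  ``pooled=False`` averages per-epoch rates instead
    (sensitivity variant).
    """
    out = []
    for wl in (VIOLET, GREEN):
        epochs = schedule.epochs_at(wl)
        if not epochs:
            raise ValidationError(f"schedule contains no {wl} nm epoch")
        counts = np.array([train.count_in(e.t_on, e.t_off) for e in epochs])
        durations = np.array([e.duration for e in epochs])
        if pooled:
            out.append(counts.sum() / durations.sum())
        else:
            out.append(float(np.mean(counts / durations)))
    return out[0], out[1]


def photoswitching_index(f_520: float, f_390: float) -> float:
    """Signed percent change of firing between 520 and 390 nm light."""
    if f_390 <= 0:
        raise ValidationError(
            "photoswitching index undefined for f_390 = 0; pool counts over "
            "a longer span first"
        )
    return 100.0 * (f_520 - f_390) / f_390


def control_threshold(
    control_abs_indices: np.ndarray, exclusion_fraction: float = 0.95
) -> ThresholdSpec:
    """Responder threshold from the control cohort.

    The value is the empirical quantile of control |index| at
    ``exclusion_fraction`` (linear interpolation between order statistics),
    so that this fraction of control neurons falls below it.
    """
    vals = np.asarray(control_abs_indices, dtype=float)
    if vals.size < 5:
        raise ValidationError(
            f"need >= 5 control neurons to derive a threshold (got "
            f"{vals.size}); consider the fixed 15% default"
        )
    value = float(np.quantile(vals, exclusion_fraction, method="linear"))
    return ThresholdSpec(
        value=value,
        method="control_quantile",
        exclusion_fraction=exclusion_fraction,
    )


def classify_neuron(result: PhotoswitchResult, threshold: ThresholdSpec) -> str:
    """Label a neuron nonresponder / type1 / type2.

    Responders reach the threshold (>=, so the fixed 15% rule gives a
    deterministic partition); the sign of the index separates type 1 (less
    firing under 390 nm) from type 2 (more firing under 390 nm).
    """
    if result.abs_index < threshold.value:
        return NONRESPONDER
    return TYPE1 if result.index > 0 else TYPE2


def analyze_neuron(
    train: SpikeTrain,
    schedule: LightSchedule,
    bursts: BurstSet | None = None,
    threshold: ThresholdSpec = FIXED_15PCT,
    pooled: bool = True,
) -> PhotoswitchResult:
    """Full per-neuron photoswitch analysis (frequencies, index, label)."""
    f_390, f_520 = epoch_frequencies(train, schedule, pooled=pooled)
    index = photoswitching_index(f_520, f_390)
    swb_390 = swb_520 = 0.0
    if bursts is not None:
        swb_390, swb_520 = swb_frequency_by_epoch(train, bursts, schedule)
    result = PhotoswitchResult(
        neuron_id=train.neuron_id,
        f_390=f_390,
        f_520=f_520,
        index=index,
        swb_freq_390=swb_390,
        swb_freq_520=swb_520,
    )
    label = classify_neuron(result, threshold)
    return PhotoswitchResult(
        neuron_id=result.neuron_id,
        f_390=result.f_390,
        f_520=result.f_520,
        index=result.index,
        swb_freq_390=result.swb_freq_390,
        swb_freq_520=result.swb_freq_520,
        label=label,
    )


def swb_frequency_by_epoch(
    train: SpikeTrain, bursts: BurstSet, schedule: LightSchedule
) -> tuple[float, float]:
    """Frequency (Hz) of spikes-within-bursts under each wavelength.

    SWB are expressed as a frequency rather than %SWB because the 5 s
    analysis window of an epoch holds too few spikes for a stable percent.
    """
    mask = bursts.spike_mask(train.n_spikes)
    swb_times = train.times[mask]
    out = []
    for wl in (VIOLET, GREEN):
        epochs = schedule.epochs_at(wl)
        if not epochs:
            raise ValidationError(f"schedule contains no {wl} nm epoch")
        count = sum(
            int(
                np.searchsorted(swb_times, e.t_off, side="left")
                - np.searchsorted(swb_times, e.t_on, side="left")
            )
            for e in epochs
        )
        out.append(count / sum(e.duration for e in epochs))
    return out[0], out[1]


def cohort_compare(
    control_results: list[PhotoswitchResult],
    transduced_results: list[PhotoswitchResult],
    threshold: ThresholdSpec = FIXED_15PCT,
) -> dict:
    """Cohort summary: mean +/- SEM of |index|, responder fractions, and the
    two-sample Kolmogorov-Smirnov comparison of the |index| distributions."""
    if not control_results or not transduced_results:
        raise ValidationError("both cohorts must be non-empty")
    ctrl = np.array([r.abs_index for r in control_results])
    trans = np.array([r.abs_index for r in transduced_results])
    ks = sps.ks_2samp(ctrl, trans, method="asymp")

    def _summ(vals: np.ndarray) -> dict:
        return {
            "n": int(vals.size),
            "mean_abs_index": float(vals.mean()),
            "sem_abs_index": float(
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            ),
            "responder_fraction": float(
                np.mean(vals >= threshold.value)
            ),
        }

    return {
        "control": _summ(ctrl),
        "transduced": _summ(trans),
        "threshold": {
            "value": threshold.value,
            "method": threshold.method,
            "exclusion_fraction": threshold.exclusion_fraction,
        },
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
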