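"""Domain types, validation and tabular I/O shared by all analysis stages.

All times are seconds internally; file columns carry explicit unit suffixes
(``time_s``, ``t_on_s``, ...).  Every interval in the package — light epochs,
sliding windows, behavioural phases — is half-open ``[on, off)`` so that a
spike falling exactly on a boundary is counted once, in the later interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Wavelength codes used throughout: darkness is encoded as 0 nm.
DARK = 0
VIOLET = 390
GREEN = 520
WAVELENGTHS = (DARK, VIOLET, GREEN)


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its contract."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one neuron over a recording span.

    Parameters
    ----------
    neuron_id : str
        Unit label from spike sorting.
    times : ndarray
        Strictly increasing spike times, seconds.
    t_start, t_stop : float
        Recording span; every spike lies in ``[t_start, t_stop]``.
    """

    neuron_id: str
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.t_stop <= self.t_start:
            raise ValidationError(
                f"{self.neuron_id}: t_stop ({self.t_stop}) must exceed "
                f"t_start ({self.t_start})"
            )
        if times.ndim != 1:
            raise ValidationError(f"{self.neuron_id}: times must be 1-D")
        if times.size and np.any(np.diff(times) <= 0):
            i = int(np.argmax(np.diff(times) <= 0))
            raise ValidationError(
                f"{self.neuron_id}: spike times not strictly increasing at "
                f"index {i + 1} (t={times[i + 1]:g})"
            )
        if times.size and (times[0] < self.t_start or times[-1] > self.t_stop):
            raise ValidationError(
                f"{self.neuron_id}: spikes outside span "
                f"[{self.t_start}, {self.t_stop}]"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def mean_rate(self) -> float:
        """Overall firing rate in Hz."""
        return self.n_spikes / self.duration

    def isis(self) -> np.ndarray:
        """Inter-spike intervals, seconds."""
        return np.diff(self.times)

    def isi_cv(self) -> float:
        """Coefficient of variation of the ISIs (nan for < 3 spikes)."""
        isis = self.isis()
        if isis.size < 2 or isis.mean() == 0:
            return float("nan")
        return float(isis.std(ddof=1) / isis.mean())

    def count_in(self, t_on: float, t_off: float) -> int:
        """Number of spikes in the half-open window ``[t_on, t_off)``."""
        return int(
            np.searchsorted(self.times, t_off, side="left")
            - np.searchsorted(self.times, t_on, side="left")
        )


@dataclass(frozen=True)
class Epoch:
    t_on: float
    t_off: float
    wavelength: int

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ValidationError(
                f"epoch [{self.t_on}, {self.t_off}) has non-positive duration"
            )
        if self.wavelength not in WAVELENGTHS:
            raise ValidationError(
                f"unknown wavelength code {self.wavelength!r}; "
                f"expected one of {WAVELENGTHS} (0 = dark)"
            )

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass(frozen=True)
class LightSchedule:
    """Ordered, non-overlapping illumination epochs (390 / 520 nm / dark)."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        epochs = tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        )
        object.__setattr__(self, "epochs", epochs)
        for prev, cur in zip(epochs, epochs[1:]):
            if cur.t_on < prev.t_off:
                raise ValidationError(
                    f"epochs overlap: [{prev.t_on}, {prev.t_off}) and "
                    f"[{cur.t_on}, {cur.t_off})"
                )

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def epochs_at(self, wavelength: int) -> list[Epoch]:
        return [e for e in self.epochs if e.wavelength == wavelength]

    def total_duration(self, wavelength: int) -> float:
        return sum(e.duration for e in self.epochs_at(wavelength))

    def transitions(self, from_nm: int | None = None, to_nm: int | None = None) -> np.ndarray:
        """Onset times of epochs, optionally restricted to transitions
        ``from_nm -> to_nm`` between temporally adjacent epochs."""
        out = []
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if prev.t_off != cur.t_on:
                continue
            if from_nm is not None and prev.wavelength != from_nm:
                continue
            if to_nm is not None and cur.wavelength != to_nm:
                continue
            out.append(cur.t_on)
        return np.asarray(out)

    @property
    def t_start(self) -> float:
        return self.epochs[0].t_on

    @property
    def t_stop(self) -> float:
        return self.epochs[-1].t_off


@dataclass(frozen=True)
class NeuronMeta:
    """Electrophysiological identity of one recorded unit.

    ``half_ap_width`` is the action-potential half-width in ms; putative
    dopaminergic neurons are broad-spiking (> 1.1 ms), slow (1-10 Hz) and
    regular.  ``th_identity`` is an optional post-hoc tyrosine-hydroxylase
    label from juxtacellular filling.
    """

    neuron_id: str
    cohort: str  # "control" | "transduced"
    half_ap_width: float  # ms
    mean_rate: float  # Hz
    isi_cv: float
    th_identity: bool | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("control", "transduced"):
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.half_ap_width <= 0:
            raise ValidationError("half_ap_width must be > 0")
        if self.mean_rate < 0 or self.isi_cv < 0:
            raise ValidationError("mean_rate and isi_cv must be >= 0")


@dataclass(frozen=True)
class InjectionEvent:
    """One intravenous injection (saline or nicotine) with its light context."""

    t: float  # s
    substance: str  # "saline" | "nicotine"
    dose: float  # µg/kg
    light_condition: str  # "dark" | "390" | "520"

    def __post_init__(self) -> None:
        if self.substance not in ("saline", "nicotine"):
            raise ValidationError(f"unknown substance {self.substance!r}")
        if self.dose < 0:
            raise ValidationError("dose must be >= 0")
        if str(self.light_condition) not in ("dark", "390", "520"):
            raise ValidationError(
                f"unknown light condition {self.light_condition!r}"
            )
        object.__setattr__(self, "light_condition", str(self.light_condition))


@dataclass
class Recording:
    """A set of spike trains with shared schedule, injections and metadata."""

    trains: dict[str, SpikeTrain]
    schedule: LightSchedule | None = None
    injections: list[InjectionEvent] = field(default_factory=list)
    meta: dict[str, NeuronMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nid in self.trains:
            if self.meta and nid not in self.meta:
                raise ValidationError(f"neuron {nid!r} has no meta entry")
        if self.trains:
            t0 = min(tr.t_start for tr in self.trains.values())
            t1 = max(tr.t_stop for tr in self.trains.values())
            if self.schedule is not None and (
                self.schedule.t_start < t0 or self.schedule.t_stop > t1
            ):
                raise ValidationError("schedule extends beyond recording span")
            for inj in self.injections:
                if not (t0 <= inj.t <= t1):
                    raise ValidationError(
                        f"injection at t={inj.t} outside recording span"
                    )


# ---------------------------------------------------------------------------
# Tabular I/O — delimited text (comma or tab autodetected), UTF-8, header row.
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; found "
            f"{list(df.columns)}"
        )
    return df


def load_spike_table(
    path: str | Path,
    t_start: float | None = None,
    t_stop: float | None = None,
) -> list[SpikeTrain]:
    """Read a spike table (columns ``neuron_id``, ``time_s``) into trains.

    The recording span defaults to ``[0, max spike time]`` across the file;
    pass ``t_start`` / ``t_stop`` (e.g. from a session manifest) to override.
    Duplicate timestamps within a neuron are rejected, naming the neuron and
    the offending row.
    """
    df = _read_table(path, ["neuron_id", "time_s"])
    if df.empty:
        return []
    span_stop = t_stop if t_stop is not None else float(df["time_s"].max())
    span_start = t_start if t_start is not None else 0.0
    trains = []
    for nid, grp in df.groupby("neuron_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        dup = np.flatnonzero(np.diff(times) == 0)
        if dup.size:
            raise ValidationError(
                f"{path}: neuron {nid!r} has duplicate spike time "
                f"{times[dup[0]]:g}"
            )
        trains.append(
            SpikeTrain(str(nid), times, t_start=span_start, t_stop=span_stop)
        )
    return trains


def write_spike_table(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"neuron_id": tr.neuron_id, "time_s": t}
        for tr in trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(
        path, index=False
    )


def load_light_schedule(path: str | Path) -> LightSchedule:
    """Read an epoch table (``t_on_s``, ``t_off_s``, ``wavelength_nm``).

    Darkness is encoded as wavelength 0.  Epochs are sorted by onset and
    validated for overlap.
    """
    df = _read_table(path, ["t_on_s", "t_off_s", "wavelength_nm"])
    df = df.sort_values("t_on_s")
    epochs = [
        Epoch(float(r.t_on_s), float(r.t_off_s), int(r.wavelength_nm))
        for r in df.itertuples()
    ]
    return LightSchedule(tuple(epochs))


def write_light_schedule(schedule: LightSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"t_on_s": e.t_on, "t_off_s": e.t_off, "wavelength_nm": e.wavelength}
            for e in schedule
        ]
    ).to_csv(path, index=False)


def load_injection_table(path: str | Path) -> list[InjectionEvent]:
    """Read injections (``t_s``, ``substance``, ``dose_ug_kg``, ``light``)."""
    df = _read_table(path, ["t_s", "substance", "dose_ug_kg", "light"])
    return [
        InjectionEvent(
            float(r.t_s), str(r.substance), float(r.dose_ug_kg), str(r.light)
        )
        for r in df.itertuples()
    ]


def load_meta_table(path: str | Path) -> dict[str, NeuronMeta]:
    df = _read_table(
        path, ["neuron_id", "cohort", "half_ap_width_ms", "mean_rate_hz", "isi_cv"]
    )
    out = {}
    for r in df.itertuples():
        out[str(r.neuron_id)] = NeuronMeta(
            str(r.neuron_id),
            str(r.cohort),
            float(r.half_ap_width_ms),
            float(r.mean_rate_hz),
            float(r.isi_cv),
            th_identity=bool(r.th_identity) if hasattr(r, "th_identity") else None,
        )
    return out


def load_manifest(path: str | Path) -> dict:
    """Read a JSON session manifest binding data files, spans and seeds."""
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    if not isinstance(manifest, dict):
        raise ValidationError(f"{path}: manifest must be a JSON object")
    return manifest


# ---------------------------------------------------------------------------
# Putative-DA identification
# ---------------------------------------------------------------------------

def is_putative_da(meta: NeuronMeta, regularity_cv_max: float = 1.0) -> bool:
    """Electrophysiological filter for putative dopaminergic neurons.

    A unit qualifies when (1) it fires regularly — operationalised as an ISI
    coefficient of variation at most ``regularity_cv_max``, a package choice
    since no number accompanies the qualitative criterion; (2) its mean rate
    lies in [1, 10] Hz; and (3) its action-potential half-width exceeds
    1.1 ms.
    """
    return (
        1.0 <= meta.mean_rate <= 10.0
        and meta.half_ap_width > 1.1
        and meta.isi_cv <= regularity_cv_max
    )
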