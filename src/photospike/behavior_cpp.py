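"""Conditioned-place-preference occupancy, preference score and
pretest-balanced group assignment.

The arena is a two-chamber box (two 11 x 25 cm rectangular pairing chambers
joined by a triangular center compartment).  The preference score of an
animal is the time it spends on the drug-paired side during the drug-free
test minus the time it spent there during the pretest, in seconds.  Groups
are formed from pretest biases so each starts with a near-zero mean score.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .core import ValidationError

OFF_ZONE = "off"


@dataclass(frozen=True)
class Trajectory:
    """Tracked positions of one animal at a nominal 20 samples/s."""

    t: np.ndarray  # s, strictly increasing
    x: np.ndarray
    y: np.ndarray
    span: float  # session length, s

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, arr in (("t", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (t.size == x.size == y.size):
            raise ValidationError("t, x, y must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must be strictly increasing")
        if self.span <= 0:
            raise ValidationError("session span must be > 0")


@dataclass(frozen=True)
class ZoneMap:
    """Named, non-overlapping zones in arena units plus the pairing side.

    ``zones`` maps names (``side_A``, ``side_B``, ``center``) to shapely
    polygons; ``paired_side`` names the nicotine-paired chamber.
    """

    zones: dict[str, Polygon]
    paired_side: str

    def __post_init__(self) -> None:
        if self.paired_side not in self.zones:
            raise ValidationError(
                f"paired side {self.paired_side!r} not among zones "
                f"{sorted(self.zones)}"
            )
        names = list(self.zones)
        for a, b in itertools.combinations(names, 2):
            inter = self.zones[a].intersection(self.zones[b])
            if inter.area > 1e-9:
                raise ValidationError(f"zones {a!r} and {b!r} overlap")

    def zone_of(self, x: float, y: float) -> str:
        p = Point(x, y)
        for name, poly in self.zones.items():
            # boundary points count as inside; non-overlap keeps this unique
            # except on shared edges, where insertion order breaks the tie
            if poly.covers(p):
                return name
        return OFF_ZONE

    def zones_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        labels = np.full(pts.shape, OFF_ZONE, dtype=object)
        # iterate in reverse so the first-declared zone wins shared edges,
        # matching zone_of
        for name in reversed(list(self.zones)):
            labels[shapely.covers(self.zones[name], pts)] = name
        return labels


def default_zone_map(paired_side: str = "side_A") -> ZoneMap:
    """The two-chamber arena: 11 x 25 cm chambers flanking an 11 cm
    triangular center, in cm with the origin at the arena's lower-left."""
    side_a = box(0.0, 0.0, 25.0, 11.0)
    center = Polygon([(25.0, 0.0), (36.0, 0.0), (30.5, 11.0)])
    side_b = box(36.0, 0.0, 61.0, 11.0)
    return ZoneMap(
        zones={"side_A": side_a, "center": center, "side_B": side_b},
        paired_side=paired_side,
    )


@dataclass(frozen=True)
class CPPSession:
    """Per-zone occupancy of one animal in one phase (pretest or test)."""

    animal_id: str
    phase: str  # "pretest" | "test"
    occupancy: dict[str, float]  # zone -> seconds
    paired_side: str
    span: float = 900.0

    def __post_init__(self) -> None:
        if self.phase not in ("pretest", "test"):
            raise ValidationError(f"unknown phase {self.phase!r}")
        if any(v < 0 for v in self.occupancy.values()):
            raise ValidationError("occupancies must be >= 0")
        total = sum(self.occupancy.values())
        if total > self.span + 1e-6:
            raise ValidationError(
                f"occupancies sum to {total:.3f} s > session span {self.span} s"
            )

    @property
    def paired_time(self) -> float:
        return self.occupancy.get(self.paired_side, 0.0)


def occupancy(trajectory: Trajectory, zone_map: ZoneMap) -> dict[str, float]:
    """Seconds spent per zone; each inter-sample interval is credited to the
    zone of its leading sample, and the final sample is credited up to the
    session span.  Samples outside every zone accumulate under ``"off"``
    with a warning."""
    labels = zone_map.zones_of(trajectory.x, trajectory.y)
    if trajectory.t.size == 0:
        return {name: 0.0 for name in zone_map.zones}
    dts = np.append(np.diff(trajectory.t), trajectory.span - trajectory.t[-1])
    dts = np.clip(dts, 0.0, None)
    out = {name: 0.0 for name in zone_map.zones}
    out[OFF_ZONE] = 0.0
    for label, dt in zip(labels, dts):
        out[label] += float(dt)
    if out[OFF_ZONE] > 0:
        warnings.warn(
            f"{out[OFF_ZONE]:.2f} s of samples fall outside every zone",
            stacklevel=2,
        )
    else:
        del out[OFF_ZONE]
    return out


def session_from_trajectory(
    animal_id: str,
    phase: str,
    trajectory: Trajectory,
    zone_map: ZoneMap,
) -> CPPSession:
    occ = occupancy(trajectory, zone_map)
    return CPPSession(
        animal_id=animal_id,
        phase=phase,
        occupancy={k: v for k, v in occ.items() if k != OFF_ZONE},
        paired_side=zone_map.paired_side,
        span=trajectory.span,
    )


def preference_score(test: CPPSession, pretest: CPPSession) -> float:
    """Preference score (s): test minus pretest time on the paired side.

    Center-compartment time never enters the score.  Antisymmetric under
    swapping the two sessions.
    """
    if test.animal_id != pretest.animal_id:
        raise ValidationError(
            f"sessions belong to different animals "
            f"({test.animal_id!r} vs {pretest.animal_id!r})"
        )
    if test.paired_side != pretest.paired_side:
        raise ValidationError("sessions disagree on the paired side")
    return test.paired_time - pretest.paired_time


def _partition_sizes(n: int, n_groups: int) -> list[int]:
    base, extra = divmod(n, n_groups)
    return [base + (1 if g < extra else 0) for g in range(n_groups)]


def _objective(biases: np.ndarray, assignment: np.ndarray, n_groups: int) -> float:
    return max(
        abs(float(biases[assignment == g].mean())) for g in range(n_groups)
    )


def balance_groups(
    pretest_biases: np.ndarray,
    n_groups: int = 2,
    seed: int = 0,
    exhaustive_max: int = 16,
    n_sweeps: int = 200,
) -> np.ndarray:
    """Assign animals to groups so each starts with near-zero mean bias.

    Minimizes the maximum absolute group-mean pretest bias over partitions
    into groups of as-equal-as-possible sizes.  Exhaustive search up to
    ``exhaustive_max`` animals; a seeded randomized swap heuristic beyond.
    Returns a group index per animal, deterministic given the seed.
    """
    biases = np.asarray(pretest_biases, dtype=float)
    n = biases.size
    if n_groups > n:
        raise ValidationError(f"cannot split {n} animals into {n_groups} groups")
    sizes = _partition_sizes(n, n_groups)
    if n <= exhaustive_max:
        best, best_obj = None, np.inf
        idx = list(range(n))

        def recurse(remaining: list[int], g: int, assignment: np.ndarray):
            nonlocal best, best_obj
            if g == n_groups - 1:
                a = assignment.copy()
                a[remaining] = g
                obj = _objective(biases, a, n_groups)
                if obj < best_obj - 1e-12:
                    best, best_obj = a, obj
                return
            anchor = remaining[0]  # fix one member to kill group-relabel symmetry
            for rest in itertools.combinations(remaining[1:], sizes[g] - 1):
                chosen = (anchor,) + rest
                a = assignment.copy()
                a[list(chosen)] = g
                recurse([i for i in remaining if i not in chosen], g + 1, a)

        recurse(idx, 0, np.full(n, -1))
        return best
    # randomized swap descent
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(n_groups), sizes)
    rng.shuffle(assignment)
    obj = _objective(biases, assignment, n_groups)
    for _ in range(n_sweeps):
        improved = False
        order = rng.permutation(n)
        for i in order:
            for j in order:
                if assignment[i] == assignment[j]:
                    continue
                assignment[i], assignment[j] = assignment[j], assignment[i]
                new_obj = _objective(biases, assignment, n_groups)
                if new_obj < obj - 1e-12:
                    obj = new_obj
                    improved = True
                else:
                    assignment[i], assignment[j] = assignment[j], assignment[i]
        if not improved:
            break
    return assignment


def cpp_summary(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean +/- SEM preference score per group plus a one-sample test of
    the score against zero (normality-gated, via the stats module)."""
    from .stats import one_sample_test

    if not groups:
        raise ValidationError("need at least one group")
    rows = []
    for name, scores in groups.items():
        scores = np.asarray(scores, dtype=float)
        res = one_sample_test(scores, mu0=0.0)
        rows.append(
            {
                "group": name,
                "n": scores.size,
                "mean_ps_s": float(scores.mean()),
                "sem_ps_s": float(
                    scores.std(ddof=1) / np.sqrt(scores.size)
                    if scores.size > 1
                    else 0.0
                ),
                "test_name": res.test_name,
                "statistic": res.statistic,
                "p_raw": res.p_raw,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File formats: trajectories as delimited text, zone maps as JSON polygons
# ---------------------------------------------------------------------------

def load_trajectory(path: str | Path, span: float | None = None) -> Trajectory:
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("t_s", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(float)
    return Trajectory(
        t=t,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        span=span if span is not None else float(t[-1]) if t.size else 0.0,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t_s": traj.t, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False
    )


def load_zone_map(path: str | Path) -> ZoneMap:
    """Zone map JSON: ``{"paired_side": ..., "zones": {name: [[x, y], ...]}}``
    where each zone is a polygon vertex list (rectangles included)."""
    with open(path, encoding="utf-8") as fh:
        spec = json.load(fh)
    zones = {
        name: Polygon(vertices) for name, vertices in spec["zones"].items()
    }
    return ZoneMap(zones=zones, paired_side=spec["paired_side"])


def write_zone_map(zone_map: ZoneMap, path: str | Path) -> None:
    spec = {
        "paired_side": zone_map.paired_side,
        "zones": {
            name: [list(c) for c in poly.exterior.coords[:-1]]
            for name, poly in zone_map.zones.items()
        },
    }
    Path(path).write_text(json.dumps(spec, indent=2), encoding="utf-8")
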