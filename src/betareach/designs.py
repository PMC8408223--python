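"""Experimental designs for the center-out reaching test and practice tasks.

Three designs are modelled as declarative schedules:

* ``mov``  — a 96-movement reaching probe: 24 targets (3 distances x 8
  directions), each presented 4 times in pseudo-random order, one every 3 s.
* ``ROT``  — 21 sets of 56 reaches to 4-cm targets (one every 1.5 s) with a
  visuomotor rotation imposed per set (steps of 10-30 deg, up to +/-60 deg),
  always ending with two 0-deg sets (112 unrotated movements).
* ``MOT``  — 20 sets of 56 reaches, never rotated; the kinematic control.

Rotation sign convention: counterclockwise positive, clockwise negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TargetSpec",
    "TaskDesign",
    "build_mov_design",
    "build_rot_design",
    "build_mot_design",
    "save_design",
    "load_design",
    "ROT_BLOCK1_ROTATIONS",
    "ROT_BLOCK3_ROTATIONS",
    "DEFAULT_EXPANSION",
]

#: mov target radii are yoked to target distance (cm -> cm).
MOV_RADIUS_BY_DISTANCE = {4.0: 0.5, 7.0: 0.88, 10.0: 1.25}

#: Task (ROT/MOT) target geometry: 8 directions, 4 cm, same radius as the
#: nearest mov target ring.
TASK_DISTANCE_CM = 4.0
TASK_RADIUS_CM = 0.5

DIRECTIONS_DEG = tuple(float(d) for d in range(0, 360, 45))

#: Printed per-entry rotation values (deg, counterclockwise positive for the
#: reference convention of Block 1; Block 3 starred entries are opposite).
ROT_BLOCK1_ROTATIONS = (0, 10, 20, 30, 40, 50, 60, 50, 40, 30, 20, 10, 0)
ROT_BLOCK3_ROTATIONS = (0, -10, 10, -20, 0, -30, -10, 20, -10, 0)

#: Default mapping of the printed rotation entries onto 21 sets: each entry
#: occupies this many consecutive sets.  Constraints honoured: totals 21, the
#: block starts with >= 2 and ends with exactly 2 zero-rotation sets (the
#: within-block contrast needs two 0-deg sets at each end), and rotations
#: change every two sets during the ramp.
DEFAULT_EXPANSION = {
    1: (2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1, 1, 2),
    3: (3, 2, 2, 2, 2, 2, 2, 2, 2, 2),
}


@dataclass(frozen=True)
class TargetSpec:
    """One target presentation."""

    direction_deg: float
    distance_cm: float
    radius_cm: float
    onset_s: float

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("target radius must be positive")
        if self.direction_deg % 45.0 != 0.0:
            raise ValueError("direction must be a multiple of 45 degrees")


@dataclass
class TaskDesign:
    """Declarative schedule of one block of a reaching test or task."""

    kind: str  # MOV | ROT | MOT
    n_sets: int
    movements_per_set: int
    inter_target_interval_s: float
    inter_set_interval_s: float
    rotation_by_set: tuple
    targets: list = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("MOV", "ROT", "MOT"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if len(self.rotation_by_set) != self.n_sets:
            raise ValueError("rotation_by_set length must equal n_sets")
        if self.kind in ("MOV", "MOT") and any(r != 0 for r in self.rotation_by_set):
            raise ValueError(f"{self.kind} sets must all have zero rotation")
        if len(self.targets) != self.n_total:
            raise ValueError("target count must equal n_sets * movements_per_set")

    @property
    def n_total(self) -> int:
        return self.n_sets * self.movements_per_set

    def set_of_trial(self, trial: int) -> int:
        return trial // self.movements_per_set

    def rotation_of_trial(self, trial: int) -> float:
        return float(self.rotation_by_set[self.set_of_trial(trial)])

    def zero_rotation_sets(self) -> list[int]:
        return [i for i, r in enumerate(self.rotation_by_set) if r == 0]

    def contrast_sets(self) -> tuple[list[int], list[int]]:
        """First-two and last-two zero-rotation sets of the block.

        These are the sets entering the within-block (last minus first)
        contrast; raises if the schedule does not provide two at each end.
        """
        zsets = self.zero_rotation_sets()
        if len(zsets) < 4 or zsets[:2] != [0, 1] or zsets[-2:] != [
            self.n_sets - 2,
            self.n_sets - 1,
        ]:
            raise ValueError(
                f"{self.kind} block lacks two zero-rotation sets at both ends"
            )
        return zsets[:2], zsets[-2:]

    def trials_in_sets(self, sets: Sequence[int]) -> np.ndarray:
        sets = set(int(s) for s in sets)
        return np.array(
            [t for t in range(self.n_total) if self.set_of_trial(t) in sets],
            dtype=int,
        )

    # ---------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_sets": self.n_sets,
            "movements_per_set": self.movements_per_set,
            "inter_target_interval_s": self.inter_target_interval_s,
            "inter_set_interval_s": self.inter_set_interval_s,
            "rotation_by_set": [float(r) for r in self.rotation_by_set],
            "targets": [asdict(t) for t in self.targets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        return cls(
            kind=d["kind"],
            n_sets=int(d["n_sets"]),
            movements_per_set=int(d["movements_per_set"]),
            inter_target_interval_s=float(d["inter_target_interval_s"]),
            inter_set_interval_s=float(d["inter_set_interval_s"]),
            rotation_by_set=tuple(float(r) for r in d["rotation_by_set"]),
            targets=[TargetSpec(**t) for t in d["targets"]],
        )

    def events_table(self) -> pd.DataFrame:
        """Event table with one row per target presentation."""
        rows = []
        for i, tgt in enumerate(self.targets):
            rows.append(
                {
                    "trial": i,
                    "set": self.set_of_trial(i),
                    "onset_s": tgt.onset_s,
                    "direction_deg": tgt.direction_deg,
                    "distance_cm": tgt.distance_cm,
                    "radius_cm": tgt.radius_cm,
                    "rotation_deg": self.rotation_of_trial(i),
                }
            )
        return pd.DataFrame(rows)


def _shuffle_no_immediate_repeat(labels: list, rng: np.random.Generator) -> list:
    """Random order of ``labels`` with no two equal consecutive entries.

    Repair-by-swap after a full shuffle; retries with a fresh shuffle if a
    repair pass stalls (cannot happen for the multiplicities used here, but
    guards degenerate inputs).
    """
    labels = list(labels)
    for _ in range(200):
        order = [labels[i] for i in rng.permutation(len(labels))]
        ok = True
        for i in range(1, len(order)):
            if order[i] == order[i - 1]:
                swapped = False
                for j in range(len(order)):
                    if abs(j - i) <= 0:
                        continue
                    left_ok = j == 0 or order[j - 1] != order[i]
                    right_ok = j == len(order) - 1 or order[j + 1] != order[i]
                    if order[j] != order[i] and order[j] != order[i - 1] and left_ok and right_ok:
                        if i + 1 < len(order) and order[j] == order[i + 1]:
                            continue
                        order[i], order[j] = order[j], order[i]
                        swapped = True
                        break
                if not swapped:
                    ok = False
                    break
        if ok and all(order[i] != order[i - 1] for i in range(1, len(order))):
            return order
    raise RuntimeError("could not produce a repetition-free order")


def _onset_times(n_sets: int, mps: int, iti: float, isi: float) -> list[float]:
    onsets = []
    t = 0.0
    for s in range(n_sets):
        for _ in range(mps):
            onsets.append(t)
            t += iti
        t += isi
    return onsets


def build_mov_design(seed: int) -> TaskDesign:
    """96-target reaching test: 24 unique (direction, distance) pairs x 4."""
    rng = np.random.default_rng(seed)
    pairs = [
        (d, dist)
        for dist in sorted(MOV_RADIUS_BY_DISTANCE)
        for d in DIRECTIONS_DEG
    ] * 4
    order = _shuffle_no_immediate_repeat(pairs, rng)
    onsets = _onset_times(1, 96, 3.0, 0.0)
    targets = [
        TargetSpec(
            direction_deg=d,
            distance_cm=dist,
            radius_cm=MOV_RADIUS_BY_DISTANCE[dist],
            onset_s=t,
        )
        for (d, dist), t in zip(order, onsets)
    ]
    return TaskDesign(
        kind="MOV",
        n_sets=1,
        movements_per_set=96,
        inter_target_interval_s=3.0,
        inter_set_interval_s=0.0,
        rotation_by_set=(0.0,),
        targets=targets,
    )


def _task_targets(n_sets: int, rng: np.random.Generator) -> list[TargetSpec]:
    onsets = _onset_times(n_sets, 56, 1.5, 30.0)
    targets = []
    k = 0
    for _ in range(n_sets):
        dirs = _shuffle_no_immediate_repeat(list(DIRECTIONS_DEG) * 7, rng)
        for d in dirs:
            targets.append(
                TargetSpec(
                    direction_deg=d,
                    distance_cm=TASK_DISTANCE_CM,
                    radius_cm=TASK_RADIUS_CM,
                    onset_s=onsets[k],
                )
            )
            k += 1
    return targets


def _expand_rotations(entries: Sequence[float], repeats: Sequence[int]) -> tuple:
    if len(repeats) != len(entries):
        raise ValueError(
            f"expansion has {len(repeats)} repeat counts for {len(entries)} entries"
        )
    per_set: list[float] = []
    for r, n in zip(entries, repeats):
        per_set.extend([float(r)] * int(n))
    if len(per_set) != 21:
        raise ValueError(f"expansion maps onto {len(per_set)} sets, expected 21")
    if per_set[-1] != 0.0 or per_set[-2] != 0.0:
        raise ValueError("ROT block must end with two zero-rotation sets")
    return tuple(per_set)


def build_rot_design(
    block: int,
    schedule_expansion: Sequence[int] | None = None,
    seed: int = 0,
    ccw_positive: bool = True,
) -> TaskDesign:
    """ROT practice block: 21 sets x 56 movements with per-set rotations.

    Parameters
    ----------
    block : {1, 3}
        Which practice block's printed rotation schedule to use.  Block 3
        entries marked as counter-rotations carry the opposite sign to
        Block 1's convention.
    schedule_expansion : sequence of int, optional
        Consecutive-set repeat count per printed rotation entry; must map
        onto exactly 21 sets ending with two 0-deg sets.  Defaults to
        ``DEFAULT_EXPANSION[block]``.
    ccw_positive : bool
        If False, flips the sign of every rotation (the rotation direction
        was counterbalanced across subjects).
    """
    if block not in (1, 3):
        raise ValueError("block must be 1 or 3")
    entries = ROT_BLOCK1_ROTATIONS if block == 1 else ROT_BLOCK3_ROTATIONS
    repeats = (
        tuple(schedule_expansion)
        if schedule_expansion is not None
        else DEFAULT_EXPANSION[block]
    )
    rotations = _expand_rotations(entries, repeats)
    if not ccw_positive:
        rotations = tuple(-r for r in rotations)
    if any(abs(r) > 60 or r % 10 != 0 for r in rotations):
        raise ValueError("ROT rotations must be multiples of 10 deg, <= 60 deg")
    rng = np.random.default_rng(seed)
    return TaskDesign(
        kind="ROT",
        n_sets=21,
        movements_per_set=56,
        inter_target_interval_s=1.5,
        inter_set_interval_s=30.0,
        rotation_by_set=rotations,
        targets=_task_targets(21, rng),
    )


def build_mot_design(seed: int = 0) -> TaskDesign:
    """MOT practice block: 20 unrotated sets x 56 movements."""
    rng = np.random.default_rng(seed)
    return TaskDesign(
        kind="MOT",
        n_sets=20,
        movements_per_set=56,
        inter_target_interval_s=1.5,
        inter_set_interval_s=30.0,
        rotation_by_set=(0.0,) * 20,
        targets=_task_targets(20, rng),
    )


def save_design(design: TaskDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def load_design(path) -> TaskDesign:
    with open(path) as fh:
        return TaskDesign.from_dict(yaml.safe_load(fh))
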