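"""Per-movement kinematic indices and behavioral summaries.

For each out-and-back reach the trajectory is zero-phase Butterworth
low-pass filtered, differentiated, and scored:

* reaction time — target appearance to movement onset (speed threshold with
  back-search from the first speed peak);
* movement time — onset to reversal (outgoing duration; the full
  out-and-back duration is kept as a secondary field);
* peak velocity — first local speed maximum between onset and reversal;
* directional error — signed angle (deg, counterclockwise positive) between
  the cursor-space direction of the center -> PV point line and the target
  direction; the sign matches the imposed-rotation sign convention, which
  the adaptation-rate formula requires;
* normalized hand-path area — shoelace area enclosed by the (closed) path
  divided by path length.

%Adaptation = [1 - mean(DirErr)/rotation] * 100 per set; a block's rate is
the mean over its nonzero-rotation sets.  Correct movements fall within
1.5 SD of the subject's baseline (mov0) on |directional error|, reaction
and movement times, and normalized hand-path area.  A 2-SD outlier rule
(any index) marks trials for joint kinematic/EEG exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, argrelmax

from .simulate import Trajectory

__all__ = [
    "KinematicRecord",
    "BaselineNorms",
    "smooth_and_differentiate",
    "compute_kinematics",
    "hand_path_area",
    "adaptation_rate",
    "block_adaptation_rate",
    "classify_correct",
    "exclude_outliers",
    "records_table",
    "CORRECTNESS_INDICES",
]

#: Indices entering the correct-movement rule and the outlier rule.
CORRECTNESS_INDICES = (
    "abs_directional_error",
    "reaction_time_ms",
    "movement_time_ms",
    "hand_path_area_norm",
)


@dataclass
class KinematicRecord:
    trial_id: int
    set_index: int
    reaction_time_ms: float
    movement_time_ms: float
    out_and_back_time_ms: float
    peak_velocity_cms: float
    pv_time_s: float
    directional_error_deg: float
    abs_directional_error: float
    hand_path_area_norm: float
    onset_s: float
    rotation_deg: float
    valid: bool


@dataclass
class BaselineNorms:
    """Per-index mean and SD from the subject's baseline mov0 block."""

    mean: dict
    sd: dict

    def __post_init__(self) -> None:
        for k, v in self.sd.items():
            if not v > 0:
                raise ValueError(f"baseline SD for {k} must be positive")

    @classmethod
    def from_records(cls, records: Sequence[KinematicRecord]) -> "BaselineNorms":
        df = records_table([r for r in records if r.valid])
        mean = {k: float(df[k].mean()) for k in CORRECTNESS_INDICES}
        sd = {k: float(df[k].std(ddof=1)) for k in CORRECTNESS_INDICES}
        return cls(mean=mean, sd=sd)


def smooth_and_differentiate(
    traj: Trajectory, cutoff_hz: float = 10.0, order: int = 4
):
    """Zero-phase low-pass filter the path and differentiate.

    Returns (x_f, y_f, velocity (2 x n), speed, acceleration, jerk); the
    derivative chain uses central differences via ``np.gradient``.
    """
    n = traj.t.size
    if n < int(0.5 * traj.fs):
        raise ValueError("trajectory shorter than 0.5 s")
    b, a = butter(order, cutoff_hz / (traj.fs / 2), btype="low")
    xf = filtfilt(b, a, traj.x)
    yf = filtfilt(b, a, traj.y)
    vx = np.gradient(xf, 1.0 / traj.fs)
    vy = np.gradient(yf, 1.0 / traj.fs)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, 1.0 / traj.fs)
    ay = np.gradient(vy, 1.0 / traj.fs)
    accel = np.hypot(ax, ay)
    jerk = np.hypot(np.gradient(ax, 1.0 / traj.fs), np.gradient(ay, 1.0 / traj.fs))
    return xf, yf, np.vstack([vx, vy]), speed, accel, jerk


def _first_local_max(
    values: np.ndarray, lo: int, hi: int, min_height: float = 0.0
) -> int:
    """First interior local maximum in [lo, hi) at least ``min_height`` tall.

    Falls back to the segment argmax when no qualifying peak exists; the
    height floor keeps sensor-noise ripples from masquerading as the
    movement's speed peak.
    """
    seg = values[lo:hi]
    peaks = argrelmax(seg)[0]
    peaks = peaks[seg[peaks] >= min_height]
    if peaks.size:
        return lo + int(peaks[0])
    return lo + int(np.argmax(seg))


def _refine_onset(
    t: np.ndarray,
    speed: np.ndarray,
    coarse_idx: int,
    peak_idx: int,
    fraction: float = 0.05,
) -> float:
    """Sub-sample onset: extrapolate sqrt(speed) to zero near a coarse onset.

    A bell-shaped (minimum-jerk) speed profile starts quadratically, so
    sqrt(speed) is locally linear in time; fitting it between the onset
    threshold and 12% of the first peak and taking the zero crossing removes
    the systematic lag of a plain threshold crossing.  ``speed`` here is the
    lightly filtered variant (see ``compute_kinematics``), which preserves
    the sharp movement start better than the 10-Hz pipeline speed.
    """
    vp = speed[peak_idx]
    lo_lim = max(0, coarse_idx - 10)
    below = np.flatnonzero(speed[lo_lim : peak_idx + 1] <= fraction * vp)
    i0 = lo_lim + (int(below[-1]) if below.size else 0)
    hi = i0
    while hi < peak_idx and speed[hi] < 0.12 * vp:
        hi += 1
    tt, vv = t[i0 : hi + 1], np.sqrt(np.maximum(speed[i0 : hi + 1], 0.0))
    if tt.size < 2:
        return float(t[i0])
    slope, intercept = np.polyfit(tt, vv, 1)
    if slope <= 0:
        return float(t[i0])
    t0 = -intercept / slope
    return float(np.clip(t0, t[i0] - 0.05, t[i0] + 0.02))


def compute_kinematics(
    traj: Trajectory,
    onset_fraction: float = 0.05,
    cutoff_hz: float = 10.0,
) -> KinematicRecord:
    """Score one reach.

    Movement onset is the last sample before the first speed peak at which
    speed falls below ``onset_fraction`` of that peak (back-search).  Trials
    with no detectable movement are flagged invalid rather than raising.
    """
    xf, yf, _, speed, _, _ = smooth_and_differentiate(traj, cutoff_hz=cutoff_hz)
    fs = traj.fs
    radial = np.hypot(xf, yf)
    invalid = KinematicRecord(
        trial_id=traj.trial_id,
        set_index=traj.set_index,
        reaction_time_ms=np.nan,
        movement_time_ms=np.nan,
        out_and_back_time_ms=np.nan,
        peak_velocity_cms=np.nan,
        pv_time_s=np.nan,
        directional_error_deg=np.nan,
        abs_directional_error=np.nan,
        hand_path_area_norm=np.nan,
        onset_s=np.nan,
        rotation_deg=traj.rotation_deg,
        valid=False,
    )
    # no reach: the hand never left the start region (targets are >= 4 cm out)
    if radial.max() < 0.5:
        return invalid
    first_peak = _first_local_max(speed, 0, speed.size, min_height=0.5 * speed.max())
    threshold = onset_fraction * speed[first_peak]
    below = np.flatnonzero(speed[: first_peak + 1] <= threshold)
    if below.size == 0:
        return invalid
    onset_idx = int(below[-1])
    # refine on a lightly smoothed speed: the 10-Hz pipeline filter smears
    # the movement start by several samples
    _, _, _, speed_lite, _, _ = smooth_and_differentiate(
        traj, cutoff_hz=max(2 * cutoff_hz, 20.0)
    )
    onset_s = _refine_onset(traj.t, speed_lite, onset_idx, first_peak)
    reversal_idx = int(np.argmax(radial))
    if reversal_idx <= onset_idx:
        return invalid
    pv_idx = _first_local_max(
        speed,
        onset_idx,
        reversal_idx + 1,
        min_height=0.2 * speed[onset_idx : reversal_idx + 1].max(),
    )
    pv_dir = np.degrees(np.arctan2(yf[pv_idx], xf[pv_idx]))
    cursor_dir = pv_dir + traj.rotation_deg
    err = (cursor_dir - traj.target.direction_deg + 180.0) % 360.0 - 180.0
    # return end: first time after reversal the hand is back near the origin
    back = np.flatnonzero(radial[reversal_idx:] < 0.1 * radial[reversal_idx])
    end_idx = reversal_idx + int(back[0]) if back.size else traj.t.size - 1
    return KinematicRecord(
        trial_id=traj.trial_id,
        set_index=traj.set_index,
        reaction_time_ms=1000.0 * onset_s,
        movement_time_ms=1000.0 * (traj.t[reversal_idx] - onset_s),
        out_and_back_time_ms=1000.0 * (traj.t[end_idx] - onset_s),
        peak_velocity_cms=float(speed[pv_idx]),
        pv_time_s=float(traj.t[pv_idx]),
        directional_error_deg=float(err),
        abs_directional_error=float(abs(err)),
        hand_path_area_norm=hand_path_area(traj, xf=xf, yf=yf),
        onset_s=float(onset_s),
        rotation_deg=traj.rotation_deg,
        valid=True,
    )


def hand_path_area(
    traj: Trajectory, xf: np.ndarray | None = None, yf: np.ndarray | None = None
) -> float:
    """Enclosed area of the (closed) hand path divided by its length (cm)."""
    x = traj.x if xf is None else xf
    y = traj.y if yf is None else yf
    length = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    if length == 0.0:
        return 0.0
    area = 0.5 * abs(
        float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    )  # shoelace on the implicitly closed polygon
    return area / length


def adaptation_rate(
    records: Sequence[KinematicRecord], rotation_deg: float
) -> float:
    """%Adaptation of one set: [1 - mean(DirErr)/rotation] * 100."""
    if rotation_deg == 0:
        raise ValueError("adaptation rate is undefined for zero rotation")
    errs = np.array(
        [r.directional_error_deg for r in records if r.valid], float
    )
    if errs.size == 0:
        raise ValueError("no valid records in set")
    return float((1.0 - errs.mean() / rotation_deg) * 100.0)


def block_adaptation_rate(
    records: Sequence[KinematicRecord],
) -> float:
    """Block-level rate: mean %Adaptation over the block's nonzero-rotation sets."""
    by_set: dict[int, list[KinematicRecord]] = {}
    for r in records:
        by_set.setdefault(r.set_index, []).append(r)
    rates = []
    for s in sorted(by_set):
        rot = by_set[s][0].rotation_deg
        if rot != 0:
            rates.append(adaptation_rate(by_set[s], rot))
    if not rates:
        raise ValueError("block has no rotated sets")
    return float(np.mean(rates))


def classify_correct(
    records: Sequence[KinematicRecord], norms: BaselineNorms, k: float = 1.5
):
    """Correct-movement rule: all four indices within k SD of baseline.

    Returns (per-trial bool flags aligned with ``records``, percent correct
    among valid trials).  Invalid trials are flagged incorrect and excluded
    from the percentage denominator.
    """
    flags = []
    n_valid = 0
    n_correct = 0
    for r in records:
        if not r.valid:
            flags.append(False)
            continue
        n_valid += 1
        ok = all(
            abs(getattr(r, name) - norms.mean[name]) <= k * norms.sd[name]
            for name in CORRECTNESS_INDICES
        )
        flags.append(ok)
        n_correct += ok
    pct = 100.0 * n_correct / n_valid if n_valid else np.nan
    return np.array(flags), pct


def exclude_outliers(
    records: Sequence[KinematicRecord], k: float = 2.0
) -> np.ndarray:
    """Keep-mask: False where any index deviates > k SD from the sample mean.

    Computed within the group of records passed in (the unit of the
    subsequent contrast); invalid trials are always excluded.  Indices with
    zero SD never trigger exclusion.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for outlier exclusion")
    df = records_table(records)
    keep = df["valid"].to_numpy(bool).copy()
    if not np.isfinite(k):
        return keep
    for name in CORRECTNESS_INDICES:
        vals = df[name].to_numpy(float)
        sub = vals[keep]
        mu, sd = np.nanmean(sub), np.nanstd(sub, ddof=1)
        if not sd > 0:
            continue
        keep &= np.where(np.isnan(vals), False, np.abs(vals - mu) <= k * sd)
    return keep


def records_table(records: Sequence[KinematicRecord]) -> pd.DataFrame:
    """Tidy per-trial table with stable column names."""
    return pd.DataFrame([r.__dict__ for r in records])
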