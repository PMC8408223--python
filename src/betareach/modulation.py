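"""ERD/ERS peak estimation, personalized ROIs, and beta modulation depth.

On a movement-onset-aligned relative beta power time course:

* peak ERD = minimum value inside the ERD window, peak ERS = maximum inside
  the ERS window (mov context: -0.1 to 0.95 s and 0.7 to 2.5 s; practice
  task context: -0.2 to 0.7 s and 0.5 to 1.2 s); ties take the earliest
  latency;
* beta modulation depth = peak ERS amplitude - peak ERD amplitude;
* for each scalp region (frontal / left / right) the personalized ROI is
  the channel with the maximum modulation depth on the reference block plus
  its six nearest layout neighbors; the selection is frozen and reused for
  every other block of that subject.

Peaks of an ROI are computed on the ROI-averaged time course (a single
trace per ROI), not as averages of per-channel peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tfr import BetaTimeCourse, ChannelLayout, ANALYSIS_REGIONS, nanmean_quiet

__all__ = [
    "PeakEstimate",
    "ROISelection",
    "ModulationResult",
    "PEAK_WINDOWS",
    "find_peaks",
    "channel_depths",
    "select_personalized_rois",
    "roi_modulation",
    "within_block_change",
    "between_block_change",
]

#: ERD / ERS search windows (s from movement onset) per analysis context.
PEAK_WINDOWS = {
    "mov": {"erd": (-0.1, 0.95), "ers": (0.7, 2.5)},
    "task": {"erd": (-0.2, 0.7), "ers": (0.5, 1.2)},
}


@dataclass(frozen=True)
class PeakEstimate:
    kind: str  # ERD | ERS
    amplitude: float  # relative power, dimensionless
    latency_s: float
    window: tuple

    def __post_init__(self) -> None:
        if not (
            self.window[0] - 1e-6 <= self.latency_s <= self.window[1] + 1e-6
        ):
            raise ValueError("peak latency outside its search window")


@dataclass(frozen=True)
class ROISelection:
    region: str
    peak_channel: int
    member_channels: tuple  # exactly 7 ids, peak included
    selection_depth: float

    def __post_init__(self) -> None:
        if len(set(self.member_channels)) != 7:
            raise ValueError("ROI must contain 7 unique channels")
        if self.peak_channel not in self.member_channels:
            raise ValueError("ROI members must include the peak channel")


@dataclass
class ModulationResult:
    region: str
    erd: PeakEstimate
    ers: PeakEstimate
    modulation_depth: float
    mean_beta_power: float

    def __post_init__(self) -> None:
        if not np.isclose(
            self.modulation_depth, self.ers.amplitude - self.erd.amplitude
        ):
            raise ValueError("depth must equal ERS amplitude - ERD amplitude")


def _window_slice(times: np.ndarray, window: tuple, values: np.ndarray):
    sel = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    sel &= np.isfinite(values)
    if not sel.any():
        raise ValueError(f"window {window} has no valid samples on the time axis")
    return times[sel], values[sel]


def find_peaks(
    times: np.ndarray, values: np.ndarray, context: str = "mov"
) -> tuple[PeakEstimate, PeakEstimate]:
    """Peak ERD (window minimum) and peak ERS (window maximum) of one trace.

    The search windows are intersected with the valid (non-NaN) part of the
    time course; ties resolve to the earliest latency.
    """
    windows = PEAK_WINDOWS[context]
    t_erd, v_erd = _window_slice(times, windows["erd"], values)
    t_ers, v_ers = _window_slice(times, windows["ers"], values)
    i = int(np.argmin(v_erd))
    j = int(np.argmax(v_ers))
    erd = PeakEstimate("ERD", float(v_erd[i]), float(t_erd[i]), windows["erd"])
    ers = PeakEstimate("ERS", float(v_ers[j]), float(t_ers[j]), windows["ers"])
    return erd, ers


def channel_depths(tc: BetaTimeCourse, context: str = "mov") -> np.ndarray:
    """Modulation depth (peak ERS - peak ERD) per channel."""
    out = np.empty(tc.values.shape[0])
    for c in range(tc.values.shape[0]):
        erd, ers = find_peaks(tc.times, tc.values[c], context)
        out[c] = ers.amplitude - erd.amplitude
    return out


def select_personalized_rois(
    depths: np.ndarray, layout: ChannelLayout
) -> dict[str, ROISelection]:
    """Per region: the maximum-depth channel plus its six nearest neighbors.

    ``depths`` is aligned with ``layout`` order and should come from the
    fixed-10-cycle beta TFR of the subject's reference block.  Depth ties
    resolve to the lowest channel id; neighbors are the six nearest by 2-D
    Euclidean distance irrespective of region boundaries.
    """
    rois = {}
    for region in ANALYSIS_REGIONS:
        members = layout.region_channels(region)
        if members.size < 7:
            raise ValueError(f"region {region!r} has fewer than 7 channels")
        idx = np.array([layout.index_of(c) for c in members])
        region_depths = depths[idx]
        best = np.lexsort((members, -region_depths))[0]
        peak = int(members[best])
        neighbors = layout.nearest_neighbors(peak, k=6)
        rois[region] = ROISelection(
            region=region,
            peak_channel=peak,
            member_channels=tuple([peak] + [int(c) for c in neighbors]),
            selection_depth=float(region_depths[best]),
        )
    return rois


def roi_modulation(
    tc: BetaTimeCourse,
    roi: ROISelection,
    layout: ChannelLayout,
    context: str = "mov",
) -> ModulationResult:
    """ERD/ERS peaks and depth of the ROI-averaged beta time course."""
    idx = [layout.index_of(c) for c in roi.member_channels]
    trace = nanmean_quiet(tc.values[idx], axis=0)
    erd, ers = find_peaks(tc.times, trace, context)
    return ModulationResult(
        region=roi.region,
        erd=erd,
        ers=ers,
        modulation_depth=ers.amplitude - erd.amplitude,
        mean_beta_power=float(nanmean_quiet(trace)),
    )


def within_block_change(
    first: dict,
    last: dict,
) -> dict:
    """Within-block change: metric(last two 0-deg sets) - metric(first two).

    ``first`` and ``last`` each map metric names to per-channel arrays or
    per-ROI scalars computed on the corresponding trial subsets (shared
    normalization reference); the result holds elementwise differences.
    """
    if first.keys() != last.keys():
        raise ValueError("first/last metric sets differ")
    out = {}
    for k in first:
        a, b = first[k], last[k]
        if isinstance(a, ModulationResult):
            out[k] = b.modulation_depth - a.modulation_depth
        else:
            out[k] = np.asarray(b) - np.asarray(a)
    return out


def between_block_change(
    mov0: dict[str, ModulationResult], mov3: dict[str, ModulationResult]
) -> dict[str, dict[str, float]]:
    """Per-ROI mov3 - mov0 deltas for ERD, ERS, depth and mean beta power.

    Both blocks must be normalized against the same (mov0) reference.
    """
    if set(mov0) != set(mov3):
        raise ValueError("ROI sets differ between blocks")
    out = {}
    for region in mov0:
        a, b = mov0[region], mov3[region]
        out[region] = {
            "erd": b.erd.amplitude - a.erd.amplitude,
            "ers": b.ers.amplitude - a.ers.amplitude,
            "depth": b.modulation_depth - a.modulation_depth,
            "mean_power": b.mean_beta_power - a.mean_beta_power,
        }
    return out
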