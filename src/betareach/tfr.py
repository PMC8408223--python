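"""Epoch handling and Morlet time-frequency analysis.

The spectral pipeline mirrors a standard movement-locked EEG workflow:
4-s epochs centered on target onset, realignment to movement onset
(-1 to +2.5 s), complex Morlet decomposition (1-55 Hz in 0.5-Hz bins with
cycles rising linearly from 3 to 10), relative power normalization
(P - mu)/mu against either the epoch-wide mean of the same trials or a
baseline-block reference, and reduction to the beta band (13.5-25 Hz).

Edge samples closer to an epoch boundary than half the wavelet support are
masked as NaN rather than zero-padded, so normalization means never include
convolution-contaminated samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

log = logging.getLogger(__name__)


def nanmean_quiet(a, axis=None):
    """nanmean tolerating all-NaN slices (edge-masked samples) silently."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)

__all__ = [
    "ChannelLayout",
    "make_standard_layout",
    "EEGEpochs",
    "TFR",
    "BetaTimeCourse",
    "segment_epochs",
    "realign_to_movement_onset",
    "morlet_tfr",
    "cycles_linear",
    "normalize_relative",
    "beta_band_power",
    "average_beta_power",
    "BETA_BAND",
    "DEFAULT_FREQS",
    "BETA_FREQS",
]

BETA_BAND = (13.5, 25.0)
DEFAULT_FREQS = np.arange(1.0, 55.0 + 1e-9, 0.5)
BETA_FREQS = np.arange(13.5, 25.0 + 1e-9, 0.5)

ANALYSIS_REGIONS = ("frontal", "left", "right")


@dataclass
class ChannelLayout:
    """2-D sensor layout on the unit disc with scalp-region labels."""

    table: pd.DataFrame  # columns: channel (int), x, y, region

    def __post_init__(self) -> None:
        required = {"channel", "x", "y", "region"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"layout table needs columns {sorted(required)}")
        if self.table["channel"].duplicated().any():
            raise ValueError("duplicate channel ids in layout")
        for region in ANALYSIS_REGIONS:
            if not (self.table["region"] == region).any():
                raise ValueError(f"analysis region {region!r} has no channels")

    @property
    def n_channels(self) -> int:
        return len(self.table)

    @property
    def channels(self) -> np.ndarray:
        return self.table["channel"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    def region_channels(self, region: str) -> np.ndarray:
        return self.table.loc[self.table["region"] == region, "channel"].to_numpy()

    def index_of(self, channel: int) -> int:
        idx = np.flatnonzero(self.channels == channel)
        if idx.size == 0:
            raise KeyError(f"channel {channel} not in layout")
        return int(idx[0])

    def nearest_neighbors(self, channel: int, k: int = 6) -> np.ndarray:
        """The ``k`` channels closest (Euclidean, 2-D) to ``channel``.

        Distance ties are broken by lower channel id.
        """
        pos = self.positions
        i = self.index_of(channel)
        d = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
        order = np.lexsort((self.channels, d))
        order = order[order != i]
        return self.channels[order[:k]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChannelLayout":
        return cls(pd.read_csv(path, sep="\t"))


def make_standard_layout(n_channels: int = 64) -> ChannelLayout:
    """Synthetic scalp layout: concentric rings on the unit disc.

    Channels are labelled frontal / left / right / other by position; the
    three analysis regions stand in for the frontal and the two
    centro-parietal sensor groups of a high-density net.
    """
    if n_channels < 24:
        raise ValueError("need at least 24 channels for three 7+ channel regions")
    ring_radii = (0.0, 0.25, 0.5, 0.75, 1.0)
    weights = np.array([1, 6, 12, 18, 24], float)
    counts = np.maximum(1, np.round(weights / weights.sum() * n_channels)).astype(int)
    counts[0] = 1
    while counts.sum() > n_channels:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_channels:
        counts[np.argmax(ring_radii)] += 1
    xs, ys = [], []
    for r, c in zip(ring_radii, counts):
        if r == 0.0:
            xs.append(0.0)
            ys.append(0.0)
            continue
        # stagger rings so columns do not align
        phases = np.pi / 2 + np.arange(c) * 2 * np.pi / c + (r * 2.1)
        xs.extend(r * np.cos(phases))
        ys.extend(r * np.sin(phases))
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    region = np.full(len(xs), "other", dtype=object)
    region[ys > 0.35] = "frontal"
    region[(xs < -0.2) & (ys <= 0.35) & (ys > -0.75)] = "left"
    region[(xs > 0.2) & (ys <= 0.35) & (ys > -0.75)] = "right"
    # every analysis region must support a 7-electrode ROI: grow undersized
    # regions from the nearest unassigned channels
    centers = {"frontal": (0.0, 0.65), "left": (-0.55, 0.05), "right": (0.55, 0.05)}
    for name in ANALYSIS_REGIONS:
        while (region == name).sum() < 7:
            free = np.flatnonzero(region == "other")
            if free.size == 0:
                raise ValueError("layout too small for three 7-channel regions")
            cx, cy = centers[name]
            d = (xs[free] - cx) ** 2 + (ys[free] - cy) ** 2
            region[free[np.argmin(d)]] = name
    table = pd.DataFrame(
        {"channel": np.arange(len(xs)), "x": xs, "y": ys, "region": region}
    )
    return ChannelLayout(table)


@dataclass
class EEGEpochs:
    """Epoched multichannel EEG: trials x channels x samples."""

    data: np.ndarray
    times: np.ndarray  # s relative to the alignment event
    fs: float
    layout: ChannelLayout
    alignment: str = "target_onset"  # or movement_onset
    metadata: pd.DataFrame | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("epoch tensor must be trials x channels x samples")
        nt, nc, ns = self.data.shape
        if nc != self.layout.n_channels or ns != self.times.size:
            raise ValueError("epoch tensor dims inconsistent with layout/times")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6):
            raise ValueError("times must be uniformly spaced at 1/fs")
        if self.metadata is not None and len(self.metadata) != nt:
            raise ValueError("metadata length must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, idx) -> "EEGEpochs":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        md = None
        if self.metadata is not None:
            md = self.metadata.iloc[idx].reset_index(drop=True)
        return EEGEpochs(
            data=self.data[idx],
            times=self.times,
            fs=self.fs,
            layout=self.layout,
            alignment=self.alignment,
            metadata=md,
            info=dict(self.info),
        )


def segment_epochs(
    signal: np.ndarray,
    fs: float,
    event_times_s: Sequence[float],
    window: tuple[float, float] = (-2.0, 2.0),
    layout: ChannelLayout | None = None,
    metadata: pd.DataFrame | None = None,
) -> EEGEpochs:
    """Cut fixed-length epochs around events from a continuous recording.

    One epoch per event within the signal extent; events whose window falls
    off an edge are dropped (count logged and recorded in ``info``).
    """
    signal = np.asarray(signal)
    if signal.ndim != 2:
        raise ValueError("continuous signal must be channels x samples")
    if layout is None:
        layout = make_standard_layout(signal.shape[0])
    lo = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    starts = np.round(np.asarray(event_times_s, float) * fs).astype(int) + lo
    keep = (starts >= 0) & (starts + n_samp <= signal.shape[1])
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("segment_epochs: dropped %d events too near an edge", n_dropped)
    epochs = np.stack(
        [signal[:, s : s + n_samp] for s in starts[keep]], axis=0
    ) if keep.any() else np.empty((0, signal.shape[0], n_samp), signal.dtype)
    md = metadata.iloc[np.flatnonzero(keep)].reset_index(drop=True) if metadata is not None else None
    times = window[0] + np.arange(n_samp) / fs
    return EEGEpochs(
        data=epochs,
        times=times,
        fs=fs,
        layout=layout,
        alignment="target_onset",
        metadata=md,
        info={"n_presented": len(starts), "n_edge_dropped": n_dropped},
    )


def realign_to_movement_onset(
    epochs: EEGEpochs,
    onsets_s: Sequence[float],
    window: tuple[float, float] = (-1.0, 2.5),
    keep_mask: Sequence[bool] | None = None,
) -> EEGEpochs:
    """Re-cut target-onset epochs so time zero is each trial's movement onset.

    ``onsets_s`` gives per-trial movement onset relative to target onset
    (NaN marks an invalid onset).  Trials with invalid onsets, trials
    excluded by ``keep_mask`` (e.g. the 2-SD kinematic rule) and trials
    whose realigned window exceeds the source epoch are dropped, with exact
    bookkeeping in ``info``.
    """
    if epochs.alignment != "target_onset":
        raise ValueError("epochs must be target-onset aligned")
    onsets = np.asarray(onsets_s, float)
    if onsets.size != epochs.n_trials:
        raise ValueError("one onset per trial required")
    fs = epochs.fs
    n_out = int(round((window[1] - window[0]) * fs))
    t0 = epochs.times[0]
    valid = np.isfinite(onsets)
    if keep_mask is not None:
        valid &= np.asarray(keep_mask, bool)
    n_kin_excluded = int(epochs.n_trials - valid.sum())
    starts = np.round(
        (np.nan_to_num(onsets, nan=-1e6) + window[0] - t0) * fs
    ).astype(np.int64)
    in_range = valid.copy()
    in_range[valid] &= (starts[valid] >= 0) & (
        starts[valid] + n_out <= epochs.times.size
    )
    n_window_dropped = int(valid.sum() - in_range.sum())
    idx = np.flatnonzero(in_range)
    if idx.size == 0:
        log.error("realign_to_movement_onset: no trials retained")
    data = np.stack(
        [epochs.data[i, :, starts[i] : starts[i] + n_out] for i in idx], axis=0
    ) if idx.size else np.empty((0, epochs.layout.n_channels, n_out), epochs.data.dtype)
    md = (
        epochs.metadata.iloc[idx].reset_index(drop=True)
        if epochs.metadata is not None
        else None
    )
    times = window[0] + np.arange(n_out) / fs
    info = dict(epochs.info)
    info.update(
        n_input=epochs.n_trials,
        n_invalid_or_excluded=n_kin_excluded,
        n_window_dropped=n_window_dropped,
        n_retained=int(idx.size),
    )
    return EEGEpochs(
        data=data,
        times=times,
        fs=fs,
        layout=epochs.layout,
        alignment="movement_onset",
        metadata=md,
        info=info,
    )


@dataclass
class TFR:
    """Time-frequency power: channels x frequencies x times.

    ``power`` is trial-averaged unless built with ``average=False`` (then a
    leading trial axis is present).  Edge samples inside half the wavelet
    support are NaN.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    normalization: str = "raw"
    n_trials: int = 0
    band: tuple | None = None

    def __post_init__(self) -> None:
        if self.normalization == "raw":
            with np.errstate(invalid="ignore"):
                if np.nanmin(self.power) < 0:
                    raise ValueError("raw power must be nonnegative")
        d = np.diff(self.freqs)
        if self.freqs.size > 1 and not np.allclose(d, d[0]):
            raise ValueError("frequencies must be evenly spaced, ascending")


@dataclass
class BetaTimeCourse:
    """Band-averaged power time course per channel."""

    values: np.ndarray  # channels x times
    times: np.ndarray
    band: tuple
    normalization: str


def cycles_linear(freqs: np.ndarray, lo: float = 3.0, hi: float = 10.0) -> np.ndarray:
    """Cycle counts rising linearly with frequency, 3 cycles at 1 Hz to 10 at 55 Hz."""
    freqs = np.asarray(freqs, float)
    return lo + (hi - lo) * (freqs - 1.0) / (55.0 - 1.0)


def _morlet_wavelet(f: float, n_cycles: float, fs: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def morlet_tfr(
    epochs: EEGEpochs,
    freqs: np.ndarray | None = None,
    n_cycles: float | np.ndarray | None = None,
    decim: int = 1,
    average: bool = True,
) -> TFR:
    """Complex Morlet wavelet power of epoched data.

    Parameters
    ----------
    freqs : array, default 1-55 Hz in 0.5-Hz bins
    n_cycles : scalar or per-frequency array; default rises linearly 3 -> 10.
        Pass ``10.0`` with beta-band freqs for the fixed-cycle variant used
        in personalized ROI selection.
    decim : keep every ``decim``-th time sample of the power envelope.
    average : average power over trials (memory-friendly default).
    """
    freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, float)
    if np.any(freqs >= epochs.fs / 2):
        raise ValueError("frequency at or above Nyquist")
    if n_cycles is None:
        n_cycles = cycles_linear(freqs)
    n_cycles = np.broadcast_to(np.asarray(n_cycles, float), freqs.shape)
    ns = epochs.times.size
    longest_half = int(np.ceil(3.5 * (n_cycles / (2 * np.pi * freqs)).max() * epochs.fs))
    if 2 * longest_half + 1 > ns:
        raise ValueError("epoch shorter than longest wavelet support")
    times = epochs.times[::decim]
    nt_out = times.size
    nt, nc = epochs.n_trials, epochs.layout.n_channels
    # single-precision fast path for float32 epochs; float64 input keeps
    # full-precision convolution
    work = np.float64 if epochs.data.dtype == np.float64 else np.float32
    flat = np.ascontiguousarray(epochs.data, dtype=work).reshape(nt * nc, ns)
    if average:
        out = np.zeros((nc, freqs.size, nt_out), np.float64)
    else:
        out = np.zeros((nt, nc, freqs.size, nt_out), np.float32)
    for k, (f, nco) in enumerate(zip(freqs, n_cycles)):
        w = _morlet_wavelet(f, nco, epochs.fs)
        if work == np.float32:
            w = w.astype(np.complex64)
        half = (w.size - 1) // 2
        conv = fftconvolve(flat, w[None, :], mode="same", axes=1)
        power = (conv.real**2 + conv.imag**2)[:, ::decim]
        # mask samples whose wavelet support crosses the epoch edge
        edge = np.zeros(ns, bool)
        edge[:half] = True
        edge[ns - half :] = True
        power[:, edge[::decim]] = np.nan
        power = power.reshape(nt, nc, nt_out)
        if average:
            out[:, k, :] = power.mean(axis=0)
        else:
            out[:, :, k, :] = power
    return TFR(
        power=out,
        freqs=freqs,
        times=times,
        normalization="raw",
        n_trials=nt,
    )


def normalize_relative(tfr: TFR, reference: TFR | np.ndarray | None = None) -> TFR:
    """Relative power (P - mu)/mu.

    ``reference=None`` uses the epoch-wide, all-trial mean of ``tfr`` itself
    per channel x frequency ("own window").  Pass another raw TFR (e.g. the
    baseline mov0 block) or a precomputed (channels x frequencies) mean for
    baseline-referenced normalization.
    """
    if tfr.normalization != "raw":
        raise ValueError("normalize_relative expects raw power")
    if reference is None:
        mu = np.nanmean(tfr.power, axis=tuple(range(tfr.power.ndim - 3)) + (-1,))
        tag = "relative_own"
    elif isinstance(reference, TFR):
        if reference.normalization != "raw":
            raise ValueError("reference TFR must be raw power")
        if not np.array_equal(reference.freqs, tfr.freqs):
            raise ValueError("reference frequencies differ")
        mu = np.nanmean(
            reference.power, axis=tuple(range(reference.power.ndim - 3)) + (-1,)
        )
        tag = "relative_mov0"
    else:
        mu = np.asarray(reference, float)
        tag = "relative_mov0"
    if mu.shape != (tfr.power.shape[-3], tfr.freqs.size):
        raise ValueError("reference mean must be channels x frequencies")
    bad = ~(mu > 0)
    if bad.any():
        c, f = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive normalization mean at channel index {c}, {tfr.freqs[f]} Hz"
        )
    out = (tfr.power - mu[..., None]) / mu[..., None]
    return replace(tfr, power=out, normalization=tag)


def beta_band_power(tfr: TFR, band: tuple[float, float] = BETA_BAND) -> BetaTimeCourse:
    """Unweighted mean over the band's frequency bins (trial-averaged input)."""
    if tfr.power.ndim != 3:
        raise ValueError("beta_band_power expects a trial-averaged TFR")
    sel = (tfr.freqs >= band[0] - 1e-9) & (tfr.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins")
    values = nanmean_quiet(tfr.power[:, sel, :], axis=1)
    return BetaTimeCourse(
        values=values, times=tfr.times, band=band, normalization=tfr.normalization
    )


def average_beta_power(
    tc: BetaTimeCourse, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Time-averaged band power per channel (valid samples only)."""
    vals = tc.values
    if window is not None:
        sel = (tc.times >= window[0]) & (tc.times <= window[1])
        vals = vals[:, sel]
    return nanmean_quiet(vals, axis=1)
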