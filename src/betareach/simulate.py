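"""Synthetic reaching kinematics and movement-locked EEG with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* **Kinematics** — out-and-back center-out reaches built from mirrored
  minimum-jerk segments.  Under an imposed visuomotor rotation the cursor
  directional error decays exponentially across consecutive same-rotation
  trials (adaptation state ``a_t = 1 - exp(-t/tau)``); unrotated trials show
  baseline directional noise only.  The hand aims at ``target - rotation *
  a_t``, so the cursor error is ``rotation * (1 - a_t) + eps`` with
  ``eps ~ N(0, dir_noise_sd)``: error equals the full rotation when naive
  and shrinks to noise when adapted, making the %Adaptation closed form
  ``100 * mean(a_t)`` exact in expectation.

* **EEG** — per channel, a beta-band stochastic carrier whose *power*
  envelope dips during movement (ERD) and rebounds after movement end (ERS),
  on top of 1/f background noise.  The ERD/ERS modulation is weighted by
  smooth frontal/left/right scalp topographies, so the measured relative
  beta modulation depth on a channel is approximately ``w_c * (d + g)``;
  the channel with the largest topography weight in each region is the
  planted "peak channel" the personalized ROI step should recover.  The ERS
  gain may grow multiplicatively across practice sets
  (``g_set = g * (1 + gamma_region * set_index)``) to emulate within-block
  practice effects.

Beta carriers are band-limited Gaussian noise, not sinusoids, so
single-trial power is chi-square distributed as in real EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .designs import TaskDesign, TargetSpec
from .tfr import ChannelLayout, EEGEpochs, make_standard_layout, ANALYSIS_REGIONS

__all__ = [
    "EEGParams",
    "SubjectParams",
    "Trajectory",
    "GroundTruth",
    "simulate_block_kinematics",
    "simulate_epochs",
    "make_group",
    "expected_adaptation_state",
    "default_eeg_params",
    "region_weight_matrix",
]

#: Region source centers on the unit-disc layout (approximate F z / C3 / C4).
REGION_CENTERS = {"frontal": (0.0, 0.65), "left": (-0.55, 0.05), "right": (0.55, 0.05)}


@dataclass
class EEGParams:
    """Generative parameters of the synthetic EEG.

    Windows are in seconds relative to movement onset.  ``snr`` is the RMS
    amplitude ratio between the beta carrier (at baseline envelope) and the
    broadband 1/f background on a unit-weight channel.
    """

    fs: float = 250.0
    beta_center: float = 19.25
    beta_bandwidth: float = 11.5
    erd_depth: float = 0.4
    ers_gain: float = 0.8
    erd_window: tuple = (-0.05, 0.85)
    ers_window: tuple = (0.8, 2.0)
    #: nominal span (s) of the movement-locked window over which the
    #: analysis averages power when normalizing; used to pre-compensate the
    #: planted envelope so erd_depth / ers_gain are exact on the
    #: relative-power scale
    norm_span_s: float = 3.2
    noise_exponent: float = 1.0
    snr: float = 1.0
    practice_growth: dict = field(default_factory=dict)  # region -> per-set gamma
    ers_region_scale: dict = field(default_factory=dict)  # region -> ERS gain multiplier
    region_strength: dict = field(default_factory=dict)  # region -> multiplier
    topography_sigma: float = 0.5
    peak_sharpness: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth < 1:
            raise ValueError("erd_depth must be in [0, 1)")
        if self.ers_gain < 0 or self.snr <= 0:
            raise ValueError("ers_gain must be >= 0 and snr > 0")
        if self.fs < 250:
            raise ValueError("sampling rate must be at least 250 Hz")
        if not 13.5 <= self.beta_center <= 25.0:
            raise ValueError("beta_center must lie in the 13.5-25 Hz band")


def default_eeg_params(context: str = "mov", **overrides) -> EEGParams:
    """EEG parameters with ERD/ERS bumps centered inside the analysis windows.

    ``context='mov'`` places the ERS bump inside 0.7-2.5 s (test epochs);
    ``context='task'`` inside 0.5-1.2 s (practice-task epochs).
    """
    if context == "mov":
        base = dict(erd_window=(-0.05, 0.85), ers_window=(0.8, 2.0))
    elif context == "task":
        base = dict(erd_window=(-0.15, 0.65), ers_window=(0.55, 1.15))
    else:
        raise ValueError("context must be 'mov' or 'task'")
    base.update(overrides)
    return EEGParams(**base)


@dataclass
class SubjectParams:
    """Per-subject generative parameters."""

    rng_seed: int = 0
    rt_mean_ms: float = 300.0
    rt_sd_ms: float = 30.0
    mt_mean_ms: float = 270.0
    mt_sd_ms: float = 20.0
    pv_mean_cms: float = 27.0  # emergent check value at 4 cm; PV ~ 1.875*D/MT
    dir_noise_sd_deg: float = 5.0
    adaptation_tau_trials: float = 30.0
    kin_fs: float = 250.0
    kin_noise_cm: float = 0.02
    eeg: EEGParams = field(default_factory=EEGParams)

    def __post_init__(self) -> None:
        for name in ("rt_mean_ms", "mt_mean_ms", "pv_mean_cms", "adaptation_tau_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """One reach: sampled hand path plus generator ground truth."""

    trial_id: int
    set_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    target: TargetSpec
    rotation_deg: float
    true_onset_s: float
    true_dir_error_deg: float
    true_mt_s: float


@dataclass
class GroundTruth:
    """What was planted in a block of synthetic epochs."""

    erd_depth: float
    ers_gain_by_set: dict  # region -> array over sets
    erd_window: tuple
    ers_window: tuple
    peak_channel: dict  # region -> channel id
    weights: dict  # region -> per-channel weight array
    onsets_s: np.ndarray


def expected_adaptation_state(design: TaskDesign, tau: float) -> np.ndarray:
    """Closed-form adaptation state a_t per trial under the generator model.

    ``a_t = 1 - exp(-t_rot / tau)`` where ``t_rot`` counts trials since the
    current rotation value began (a_t = 0 whenever rotation is zero).
    """
    a = np.zeros(design.n_total)
    t_rot = 0
    prev_rot = 0.0
    for i in range(design.n_total):
        rot = design.rotation_of_trial(i)
        if rot != prev_rot:
            t_rot = 0
            prev_rot = rot
        if rot == 0.0:
            a[i] = 0.0
        else:
            a[i] = 1.0 - np.exp(-t_rot / tau)
        t_rot += 1
    return a


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def simulate_block_kinematics(
    design: TaskDesign, subj: SubjectParams
) -> list[Trajectory]:
    """Simulate one block of out-and-back reaches for one subject."""
    rng = np.random.default_rng(subj.rng_seed)
    a_state = expected_adaptation_state(design, subj.adaptation_tau_trials)
    fs = subj.kin_fs
    trajectories = []
    for i, tgt in enumerate(design.targets):
        rot = design.rotation_of_trial(i)
        eps = rng.normal(0.0, subj.dir_noise_sd_deg)
        err = rot * (1.0 - a_state[i]) + eps  # cursor-space directional error
        hand_dir = np.deg2rad(tgt.direction_deg + err - rot)
        rt = max(0.08, rng.normal(subj.rt_mean_ms, subj.rt_sd_ms) / 1000.0)
        mt = max(
            0.12,
            rng.normal(subj.mt_mean_ms, subj.mt_sd_ms)
            / 1000.0
            * np.sqrt(tgt.distance_cm / 4.0),
        )
        duration = design.inter_target_interval_s
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        radial = np.zeros(n)
        out = (t >= rt) & (t < rt + mt)
        back = (t >= rt + mt) & (t < rt + 2 * mt)
        radial[out] = _minimum_jerk((t[out] - rt) / mt)
        radial[back] = _minimum_jerk(1.0 - (t[back] - rt - mt) / mt)
        radial *= tgt.distance_cm
        x = radial * np.cos(hand_dir) + rng.normal(0, subj.kin_noise_cm, n)
        y = radial * np.sin(hand_dir) + rng.normal(0, subj.kin_noise_cm, n)
        trajectories.append(
            Trajectory(
                trial_id=i,
                set_index=design.set_of_trial(i),
                t=t,
                x=x,
                y=y,
                fs=fs,
                target=tgt,
                rotation_deg=rot,
                true_onset_s=rt,
                true_dir_error_deg=err,
                true_mt_s=mt,
            )
        )
    return trajectories


def region_weight_matrix(
    layout: ChannelLayout, params: EEGParams
) -> dict[str, np.ndarray]:
    """Per-region modulation-weight topographies over channels.

    Each region projects a flat-topped (super-Gaussian) plateau around its
    source location — neighboring electrodes of a dense net see nearly the
    same modulation, as real scalp fields are smooth at electrode spacing —
    multiplied by a narrow bump (``peak_sharpness``) that makes one site the
    unambiguous regional maximum.
    """
    pos = layout.positions
    weights = {}
    for region in ANALYSIS_REGIONS:
        cx, cy = REGION_CENTERS[region]
        rho = params.region_strength.get(region, 1.0)
        # snap the source to the nearest electrode of the region so the
        # planted maximum sits on a recordable site
        ridx = np.array([layout.index_of(c) for c in layout.region_channels(region)])
        d2r = (pos[ridx, 0] - cx) ** 2 + (pos[ridx, 1] - cy) ** 2
        cx, cy = pos[ridx[np.argmin(d2r)]]
        d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
        plateau = np.exp(-(d2**2) / params.topography_sigma**4)
        bump = 1.0 + params.peak_sharpness * np.exp(-d2 / (2 * 0.12**2))
        weights[region] = rho * plateau * bump
    # dominant-source normalization: where plateaus overlap, scale each
    # channel's weight vector so the summed modulation equals the strongest
    # single region's weight -- overlapping sources compete rather than
    # stack, keeping every planted regional maximum at its source electrode
    total = sum(weights.values())
    strongest = np.maximum.reduce([weights[r] for r in ANALYSIS_REGIONS])
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, strongest / total, 1.0)
    for region in ANALYSIS_REGIONS:
        weights[region] = weights[region] * scale
    return weights


#: taper fraction of the envelope bumps (tapered-cosine / Tukey shape); the
#: central (1 - r) of the window is a flat plateau, so the planted extremum
#: is attained over an interval and survives wavelet smoothing unattenuated
TUKEY_R = 0.5


def _bump(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Unit tapered-cosine bump supported on ``window``."""
    lo, hi = window
    width = hi - lo
    taper = 0.5 * TUKEY_R * width
    out = np.zeros_like(t)
    inside = (t >= lo) & (t <= hi)
    u = t[inside]
    val = np.ones(u.size)
    rise = u < lo + taper
    fall = u > hi - taper
    val[rise] = 0.5 * (1 - np.cos(np.pi * (u[rise] - lo) / taper))
    val[fall] = 0.5 * (1 - np.cos(np.pi * (hi - u[fall]) / taper))
    out[inside] = val
    return out


def _bump_integral(window: tuple[float, float]) -> float:
    return (window[1] - window[0]) * (1.0 - TUKEY_R / 2.0)


def _spectral_noise(
    rng: np.random.Generator, shape: tuple, fs: float, profile: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral amplitude profile,
    normalized to unit standard deviation along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = profile(freqs)
    spec = rng.normal(size=shape[:-1] + (freqs.size,)) + 1j * rng.normal(
        size=shape[:-1] + (freqs.size,)
    )
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_epochs(
    design: TaskDesign,
    kinematics: Sequence[Trajectory],
    subj: SubjectParams,
    layout: ChannelLayout | None = None,
    window: tuple[float, float] = (-2.0, 3.5),
    trial_indices: Sequence[int] | None = None,
    chunk: int = 64,
    weights: dict[str, np.ndarray] | None = None,
) -> tuple[EEGEpochs, GroundTruth]:
    """Generate target-onset-locked EEG epochs for (a subset of) a block.

    Epochs are cut wider than the 4-s segmentation window so that
    movement-onset realignment to (-1, +2.5) s stays inside the epoch.
    Returns the epochs and the planted ground truth.
    """
    if len(kinematics) != design.n_total:
        raise ValueError("one kinematic record per target presentation required")
    p = subj.eeg
    if layout is None:
        layout = make_standard_layout()
    trials = (
        np.arange(design.n_total)
        if trial_indices is None
        else np.asarray(trial_indices, int)
    )
    fs = p.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    times = window[0] + np.arange(n_samp) / fs
    nc = layout.n_channels
    if weights is None:
        weights = region_weight_matrix(layout, p)
    w_total = sum(weights.values())
    gamma = {r: p.practice_growth.get(r, 0.0) for r in ANALYSIS_REGIONS}
    scale = {r: p.ers_region_scale.get(r, 1.0) for r in ANALYSIS_REGIONS}
    sets = np.arange(design.n_sets)
    g_by_set = {
        r: p.ers_gain * scale[r] * (1.0 + gamma[r] * sets) for r in ANALYSIS_REGIONS
    }

    rng = np.random.default_rng(np.random.SeedSequence([subj.rng_seed, 7919]))
    amp_uV = 10.0  # arbitrary microvolt scale of the background

    def beta_profile(f):
        # flat-top band-limited carrier with 1-Hz Gaussian roll-off: the
        # oscillation fills its band rather than peaking at a single bin
        lo = p.beta_center - p.beta_bandwidth / 2
        hi = p.beta_center + p.beta_bandwidth / 2
        out = np.ones_like(f)
        below, above = f < lo, f > hi
        out[below] = np.exp(-((f[below] - lo) ** 2) / 2.0)
        out[above] = np.exp(-((f[above] - hi) ** 2) / 2.0)
        return out

    def pink_profile(f):
        f = np.maximum(f, 1.0)
        return f ** (-p.noise_exponent)

    # Planted ERD/ERS are targets on the *relative* power scale
    # (P - mu)/mu with mu the epoch-wide mean, which the raw bumps
    # themselves inflate.  Solve per channel for raw bump coefficients a, b
    # in  E = 1 - a*phi_erd + b*phi_ers  such that after dividing by the
    # epoch mean  m = 1 + (b*I_ers - a*I_erd)/T  the envelope extremes are
    # exactly -D_c and +G_c (D_c, G_c the topography-weighted targets).
    i_erd = _bump_integral(p.erd_window)
    i_ers = _bump_integral(p.ers_window)
    span = p.norm_span_s

    def envelope_coeffs(set_index: int):
        G = sum(
            g_by_set[r][set_index] * weights[r] for r in ANALYSIS_REGIONS
        )
        D = p.erd_depth * w_total
        denom = 1.0 - ((1.0 + G) * i_ers + (1.0 - D) * i_erd) / span
        if np.any(denom <= 0.05):
            raise ValueError("planted modulation too large for the epoch span")
        m = (1.0 - (i_ers + i_erd) / span) / denom
        a = 1.0 - (1.0 - D) * m
        b = (1.0 + G) * m - 1.0
        return a, b

    data = np.empty((trials.size, nc, n_samp), np.float32)
    onsets = np.array([kinematics[i].true_onset_s for i in trials])
    for start in range(0, trials.size, chunk):
        block = trials[start : start + chunk]
        nb = block.size
        carrier = _spectral_noise(rng, (nb, nc, n_samp), fs, beta_profile)
        noise = _spectral_noise(rng, (nb, nc, n_samp), fs, pink_profile)
        envelope = np.empty((nb, nc, n_samp))
        for j, tr in enumerate(block):
            onset = kinematics[tr].true_onset_s
            a, b = envelope_coeffs(design.set_of_trial(tr))
            phi_erd = _bump(times - onset, p.erd_window)
            phi_ers = _bump(times - onset, p.ers_window)
            env = (
                1.0
                - a[:, None] * phi_erd[None, :]
                + b[:, None] * phi_ers[None, :]
            )
            envelope[j] = np.maximum(env, 0.02)
        data[start : start + nb] = (
            amp_uV * (p.snr * np.sqrt(envelope) * carrier + noise)
        ).astype(np.float32)

    metadata = pd.DataFrame(
        {
            "trial": trials,
            "set": [design.set_of_trial(i) for i in trials],
            "rotation_deg": [design.rotation_of_trial(i) for i in trials],
            "true_onset_s": onsets,
        }
    )
    epochs = EEGEpochs(
        data=data,
        times=times,
        fs=fs,
        layout=layout,
        alignment="target_onset",
        metadata=metadata,
        info={"n_presented": int(trials.size)},
    )
    truth = GroundTruth(
        erd_depth=p.erd_depth,
        ers_gain_by_set=g_by_set,
        erd_window=p.erd_window,
        ers_window=p.ers_window,
        peak_channel={
            r: int(layout.channels[np.argmax(weights[r] * np.isin(layout.channels, layout.region_channels(r)))])
            for r in ANALYSIS_REGIONS
        },
        weights=weights,
        onsets_s=onsets,
    )
    return epochs, truth


def make_group(
    n_subjects: int,
    master_seed: int,
    base: SubjectParams | None = None,
    param_sd: dict | None = None,
) -> list[SubjectParams]:
    """Draw independent subject parameter sets from a master seed.

    ``param_sd`` maps SubjectParams field names to between-subject SDs
    (Gaussian around the base value); omitted fields are identical across
    subjects.  Per-subject RNG seeds are derived deterministically.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base = base or SubjectParams()
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 104729]))
    out = []
    for seed in seeds:
        fields = {}
        if param_sd:
            for name, sd in param_sd.items():
                val = getattr(base, name) + rng.normal(0.0, sd)
                fields[name] = float(np.clip(val, 1e-3, None))
        out.append(replace(base, rng_seed=seed, **fields))
    return out
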