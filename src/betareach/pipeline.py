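"""End-to-end orchestration: simulate -> kinematics -> TFR -> modulation -> stats.

``run_experiment`` reproduces the study's two analysis arms on synthetic
groups with configurable planted effects:

* **Practice-task arm** — within-block change (last minus first two
  zero-rotation sets) of average beta power per channel and of ROI
  modulation depth, for blocks 1 and 3 of a ROT-like and a MOT-like group,
  with paired permutation maps per task and independent-groups maps between
  tasks.
* **Reaching-test arm** — mov0 vs mov3 per-ROI Wilcoxon contrasts per
  group, between-group Kruskal-Wallis on the mov3-mov0 deltas, paired and
  independent permutation maps of average beta power change, and a mixed
  ANOVA on the behavioral indices (reaction time, peak velocity, movement
  time, |directional error|, percent correct).

Everything is deterministic under the master seed; per-subject seeds are
derived from (master seed, group, subject index) and do not depend on
processing order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from . import designs, kinematics as kin, modulation as mod, simulate as sim
from . import stats as st
from . import tfr as tf

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "scaled_config",
    "run_experiment",
    "validate_pipeline",
    "analyze_mov_subject",
    "simulate_mov_subject",
    "task_within_block_subject",
]

GROUPS = ("ROT", "MOT")


@dataclass
class RunConfig:
    """Configuration of one full synthetic experiment."""

    master_seed: int = 0
    n_rot: int = 27
    n_mot: int = 14
    n_channels: int = 64
    mov_trials: int = 96  # per mov block (the full test has 96)
    n_perm: int = 10000
    alpha_block1: float = 0.01
    alpha_block3: float = 0.05
    alpha_mov: float = 0.05
    decim: int = 5
    include_tasks: bool = True
    # between-subject variability (SubjectParams field -> SD)
    subject_sd: dict = field(
        default_factory=lambda: {
            "rt_mean_ms": 15.0,
            "mt_mean_ms": 15.0,
            "dir_noise_sd_deg": 0.8,
        }
    )
    # planted mov3 ERS-gain scaling per group and region (practice traces)
    mov3_ers_scale: dict = field(
        default_factory=lambda: {
            "ROT": {"frontal": 1.5, "left": 1.35, "right": 1.25},
            "MOT": {"frontal": 1.0, "left": 1.35, "right": 1.0},
        }
    )
    # planted mov3 directional-noise scaling (performance deterioration)
    mov3_dir_noise_scale: dict = field(
        default_factory=lambda: {"ROT": 1.3, "MOT": 1.0}
    )
    # planted within-block ERS growth per set during practice tasks
    task_growth: dict = field(
        default_factory=lambda: {
            1: {"frontal": 0.03, "left": 0.03, "right": 0.015},
            3: {"frontal": 0.012, "left": 0.01, "right": 0.008},
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task_growth"] = {str(k): v for k, v in d["task_growth"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task_growth" in d:
            d["task_growth"] = {int(k): v for k, v in d["task_growth"].items()}
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def scaled_config(master_seed: int = 0, **overrides) -> RunConfig:
    """A desk-scale configuration for quick, fully-run experiments."""
    base = dict(
        master_seed=master_seed,
        n_rot=8,
        n_mot=6,
        n_channels=32,
        mov_trials=48,
        n_perm=2000,
    )
    base.update(overrides)
    return RunConfig(**base)


@dataclass
class RunReport:
    config_hash: str
    master_seed: int
    behavioral: pd.DataFrame
    behavioral_anova: pd.DataFrame
    roi_wilcoxon: pd.DataFrame
    roi_kruskal: pd.DataFrame
    mov_perm_maps: dict
    task_within_block: pd.DataFrame | None
    task_perm_maps: dict
    roi_selections: pd.DataFrame
    counts: pd.DataFrame
    excluded_subjects: list

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.behavioral.to_csv(out / "behavioral.tsv", sep="\t", index=False)
        self.behavioral_anova.to_csv(out / "behavioral_anova.tsv", sep="\t", index=False)
        self.roi_wilcoxon.to_csv(out / "roi_wilcoxon.tsv", sep="\t", index=False)
        self.roi_kruskal.to_csv(out / "roi_kruskal.tsv", sep="\t", index=False)
        self.roi_selections.to_csv(out / "roi_selections.tsv", sep="\t", index=False)
        self.counts.to_csv(out / "trial_counts.tsv", sep="\t", index=False)
        if self.task_within_block is not None:
            self.task_within_block.to_csv(
                out / "task_within_block.tsv", sep="\t", index=False
            )
        for name, res in {**self.mov_perm_maps, **self.task_perm_maps}.items():
            res.to_frame().to_csv(out / f"permmap_{name}.tsv", sep="\t", index=False)
        from .io import save_json

        save_json(
            {
                "config_hash": self.config_hash,
                "master_seed": self.master_seed,
                "excluded_subjects": self.excluded_subjects,
            },
            out / "manifest.json",
        )


# --------------------------------------------------------------------------
# per-subject building blocks
# --------------------------------------------------------------------------

def _subject_seed(master_seed: int, group: str, index: int) -> int:
    ss = np.random.SeedSequence([master_seed, GROUPS.index(group), index])
    return int(ss.generate_state(1)[0] % (2**31))


def _mov_design(seed: int, n_trials: int) -> designs.TaskDesign:
    d = designs.build_mov_design(seed)
    if n_trials >= 96:
        return d
    # truncated probe: keep schedule structure, first n_trials presentations
    d.targets = d.targets[:n_trials]
    d.movements_per_set = n_trials
    d.rotation_by_set = (0.0,)
    d.n_sets = 1
    return d


def simulate_mov_subject(
    subj: sim.SubjectParams,
    layout: tf.ChannelLayout,
    design_seed: int,
    n_trials: int = 96,
):
    """One mov block: design, trajectories, scored records, realigned epochs."""
    design = _mov_design(design_seed, n_trials)
    trajs = sim.simulate_block_kinematics(design, subj)
    records = [kin.compute_kinematics(t) for t in trajs]
    keep = kin.exclude_outliers(records)
    epochs, truth = sim.simulate_epochs(design, trajs, subj, layout=layout)
    onsets = np.array([r.onset_s for r in records])
    realigned = tf.realign_to_movement_onset(epochs, onsets, keep_mask=keep)
    return design, records, keep, realigned, truth


def analyze_mov_subject(
    re0: tf.EEGEpochs,
    re3: tf.EEGEpochs,
    layout: tf.ChannelLayout,
    decim: int = 5,
):
    """Personalized-ROI modulation analysis of one subject's mov0/mov3 pair.

    ROIs are selected on mov0 with the fixed-10-cycle beta TFR and frozen;
    both blocks are normalized against the mov0 epoch-wide reference.
    Returns (rois, results per block per ROI, per-channel average beta power
    per block, subject mean raw beta power).
    """
    freqs = tf.BETA_FREQS
    # ROI selection: fixed 10-cycle variant on the reference block
    sel_raw = tf.morlet_tfr(re0, freqs, 10.0, decim=decim)
    sel_btc = tf.beta_band_power(tf.normalize_relative(sel_raw))
    depths = mod.channel_depths(sel_btc, context="mov")
    rois = mod.select_personalized_rois(depths, layout)
    # analysis TFR: practice-standard rising-cycle wavelets, mov0 reference
    cycles = tf.cycles_linear(freqs)
    raw0 = tf.morlet_tfr(re0, freqs, cycles, decim=decim)
    raw3 = tf.morlet_tfr(re3, freqs, cycles, decim=decim)
    mu0 = np.nanmean(raw0.power, axis=-1)
    btc0 = tf.beta_band_power(tf.normalize_relative(raw0, reference=mu0))
    btc3 = tf.beta_band_power(tf.normalize_relative(raw3, reference=mu0))
    results = {
        "mov0": {r: mod.roi_modulation(btc0, rois[r], layout, "mov") for r in rois},
        "mov3": {r: mod.roi_modulation(btc3, rois[r], layout, "mov") for r in rois},
    }
    power_maps = {
        "mov0": tf.average_beta_power(btc0),
        "mov3": tf.average_beta_power(btc3),
    }
    return rois, results, power_maps, float(np.nanmean(mu0))


def _behavioral_row(records, keep, norms) -> dict:
    df = kin.records_table([r for r, k in zip(records, keep) if k and r.valid])
    _, pct = kin.classify_correct(records, norms)
    return {
        "reaction_time_ms": df["reaction_time_ms"].mean(),
        "peak_velocity_cms": df["peak_velocity_cms"].mean(),
        "movement_time_ms": df["movement_time_ms"].mean(),
        "directional_error_deg": df["abs_directional_error"].mean(),
        "pct_correct": pct,
    }


def task_within_block_subject(
    subj: sim.SubjectParams,
    design: designs.TaskDesign,
    layout: tf.ChannelLayout,
    decim: int = 5,
    rois: dict | None = None,
):
    """Within-block beta change of one practice block for one subject.

    Simulates EEG only for the contrast sets (first and last two 0-deg
    sets), normalizes by the average power of all their retained trials, and
    returns per-channel average-beta-power change, per-ROI depth change, and
    per-ROI first/last modulation results.
    """
    first_sets, last_sets = design.contrast_sets()
    trajs = sim.simulate_block_kinematics(design, subj)
    records = [kin.compute_kinematics(t) for t in trajs]
    trial_idx = np.concatenate(
        [design.trials_in_sets(first_sets), design.trials_in_sets(last_sets)]
    )
    contrast_records = [records[i] for i in trial_idx]
    keep = kin.exclude_outliers(contrast_records)
    epochs, truth = sim.simulate_epochs(
        design, trajs, subj, layout=layout, trial_indices=trial_idx
    )
    onsets = np.array([records[i].onset_s for i in trial_idx])
    realigned = tf.realign_to_movement_onset(epochs, onsets, keep_mask=keep)
    sets = realigned.metadata["set"].to_numpy()
    in_first = np.isin(sets, first_sets)
    freqs = tf.BETA_FREQS
    cycles = tf.cycles_linear(freqs)
    raw_all = tf.morlet_tfr(realigned, freqs, cycles, decim=decim)
    mu = np.nanmean(raw_all.power, axis=-1)  # all contrast trials
    raw_first = tf.morlet_tfr(realigned.select_trials(in_first), freqs, cycles, decim=decim)
    raw_last = tf.morlet_tfr(realigned.select_trials(~in_first), freqs, cycles, decim=decim)
    btc_first = tf.beta_band_power(tf.normalize_relative(raw_first, reference=mu))
    btc_last = tf.beta_band_power(tf.normalize_relative(raw_last, reference=mu))
    d_power = tf.average_beta_power(btc_last) - tf.average_beta_power(btc_first)
    out = {"d_power": d_power, "records": records, "truth": truth}
    if rois is None:
        sel_raw = tf.morlet_tfr(
            realigned.select_trials(in_first), freqs, 10.0, decim=decim
        )
        depths = mod.channel_depths(
            tf.beta_band_power(tf.normalize_relative(sel_raw)), context="task"
        )
        rois = mod.select_personalized_rois(depths, layout)
    out["rois"] = rois
    out["first"] = {
        r: mod.roi_modulation(btc_first, rois[r], layout, "task") for r in rois
    }
    out["last"] = {
        r: mod.roi_modulation(btc_last, rois[r], layout, "task") for r in rois
    }
    out["d_depth"] = {
        r: out["last"][r].modulation_depth - out["first"][r].modulation_depth
        for r in rois
    }
    return out


# --------------------------------------------------------------------------
# experiment
# --------------------------------------------------------------------------

def _group_subjects(cfg: RunConfig, group: str) -> list[sim.SubjectParams]:
    n = cfg.n_rot if group == "ROT" else cfg.n_mot
    base = sim.SubjectParams(eeg=sim.default_eeg_params("mov"))
    subs = sim.make_group(
        n, _subject_seed(cfg.master_seed, group, 9999), base, cfg.subject_sd
    )
    return [
        replace(s, rng_seed=_subject_seed(cfg.master_seed, group, i))
        for i, s in enumerate(subs)
    ]


def _mov3_params(subj: sim.SubjectParams, cfg: RunConfig, group: str) -> sim.SubjectParams:
    scale = cfg.mov3_ers_scale[group]
    eeg3 = replace(
        subj.eeg,
        ers_region_scale={r: scale.get(r, 1.0) for r in tf.ANALYSIS_REGIONS},
    )
    return replace(
        subj,
        rng_seed=subj.rng_seed + 1,
        dir_noise_sd_deg=subj.dir_noise_sd_deg * cfg.mov3_dir_noise_scale[group],
        eeg=eeg3,
    )


def run_experiment(config: RunConfig) -> RunReport:
    """Simulate both groups and execute every analysis stage."""
    layout = tf.make_standard_layout(config.n_channels)
    behavioral_rows = []
    roi_rows = []
    counts_rows = []
    subj_scalars = {g: [] for g in GROUPS}
    subj_results = {g: [] for g in GROUPS}

    for group in GROUPS:
        for i, subj in enumerate(_group_subjects(config, group)):
            d0_seed = _subject_seed(config.master_seed, group, 10000 + i)
            d3_seed = _subject_seed(config.master_seed, group, 20000 + i)
            subj3 = _mov3_params(subj, config, group)
            _, rec0, keep0, re0, _ = simulate_mov_subject(
                subj, layout, d0_seed, config.mov_trials
            )
            _, rec3, keep3, re3, _ = simulate_mov_subject(
                subj3, layout, d3_seed, config.mov_trials
            )
            rois, results, power_maps, mean_raw = analyze_mov_subject(
                re0, re3, layout, config.decim
            )
            norms = kin.BaselineNorms.from_records(
                [r for r, k in zip(rec0, keep0) if k]
            )
            for block, recs, keep in (("mov0", rec0, keep0), ("mov3", rec3, keep3)):
                row = _behavioral_row(recs, keep, norms)
                row.update(subject=f"{group}{i:02d}", group=group, block=block)
                behavioral_rows.append(row)
                counts_rows.append(
                    {
                        "subject": f"{group}{i:02d}",
                        "group": group,
                        "block": block,
                        "presented": len(recs),
                        "kinematic_excluded": int((~keep).sum()),
                        "retained": (re0 if block == "mov0" else re3).n_trials,
                        "edge_dropped": (re0 if block == "mov0" else re3).info[
                            "n_window_dropped"
                        ],
                    }
                )
            for r, roi in rois.items():
                roi_rows.append(
                    {
                        "subject": f"{group}{i:02d}",
                        "group": group,
                        "region": r,
                        "peak_channel": roi.peak_channel,
                        "members": ",".join(map(str, roi.member_channels)),
                        "selection_depth": roi.selection_depth,
                    }
                )
            subj_scalars[group].append(mean_raw)
            subj_results[group].append(
                {"rois": rois, "results": results, "power": power_maps, "id": i}
            )

    # subject exclusion: average raw beta power beyond 2 SD of the group
    excluded = []
    for group in GROUPS:
        vals = np.array(subj_scalars[group])
        mu, sd = vals.mean(), vals.std(ddof=1) if len(vals) > 2 else 0.0
        keep = np.abs(vals - mu) <= 2 * sd if np.all(sd > 0) else np.ones(len(vals), bool)
        for j in np.flatnonzero(~keep):
            excluded.append(f"{group}{subj_results[group][j]['id']:02d}")
        subj_results[group] = [s for s, k in zip(subj_results[group], keep) if k]

    behavioral = pd.DataFrame(behavioral_rows)
    behavioral = behavioral[~behavioral["subject"].isin(excluded)]

    # Table-1-like mixed ANOVA per behavioral index
    anova_rows = []
    for dv in (
        "reaction_time_ms",
        "peak_velocity_cms",
        "movement_time_ms",
        "directional_error_deg",
        "pct_correct",
    ):
        res = st.mixed_anova(
            behavioral, dv=dv, within="block", between="group", subject="subject"
        )
        for effect, r in res.items():
            anova_rows.append(
                {
                    "index": dv,
                    "effect": effect,
                    "F": r.statistic,
                    "p": r.p,
                    "partial_eta_sq": r.effect_size,
                }
            )
    behavioral_anova = pd.DataFrame(anova_rows)

    # Table-2-like Wilcoxon per group x ROI x measure, Table-3-like KW
    def measure(resblock, region, name):
        m = resblock[region]
        return {
            "erd": m.erd.amplitude,
            "ers": m.ers.amplitude,
            "depth": m.modulation_depth,
            "mean_power": m.mean_beta_power,
        }[name]

    wil_rows, kw_rows = [], []
    deltas = {g: {} for g in GROUPS}
    for region in tf.ANALYSIS_REGIONS:
        for name in ("erd", "ers", "depth", "mean_power"):
            for group in GROUPS:
                v0 = np.array(
                    [measure(s["results"]["mov0"], region, name) for s in subj_results[group]]
                )
                v3 = np.array(
                    [measure(s["results"]["mov3"], region, name) for s in subj_results[group]]
                )
                res = st.wilcoxon_signed_rank(v3, v0)
                wil_rows.append(
                    {
                        "region": region,
                        "measure": name,
                        "group": group,
                        "Z": res.statistic,
                        "p": res.p,
                        "median_mov0": float(np.median(v0)),
                        "median_mov3": float(np.median(v3)),
                    }
                )
                deltas[group][(region, name)] = v3 - v0
            kw = st.kruskal_wallis(
                deltas["ROT"][(region, name)], deltas["MOT"][(region, name)]
            )
            kw_rows.append(
                {
                    "region": region,
                    "measure": name,
                    "H": kw.statistic,
                    "p": kw.p,
                    "rank_mean_rot": kw.detail["rank_mean_a"],
                    "rank_mean_mot": kw.detail["rank_mean_b"],
                }
            )
    roi_wilcoxon = pd.DataFrame(wil_rows)
    roi_kruskal = pd.DataFrame(kw_rows)

    # permutation sensor maps on average beta power changes
    seed0 = _subject_seed(config.master_seed, "ROT", 777)
    maps = {}
    pw = {
        g: (
            np.stack([s["power"]["mov0"] for s in subj_results[g]]),
            np.stack([s["power"]["mov3"] for s in subj_results[g]]),
        )
        for g in GROUPS
    }
    for group in GROUPS:
        maps[f"{group.lower()}mov_mov3_vs_mov0"] = st.perm_ttest_paired(
            pw[group][1],
            pw[group][0],
            n_perm=config.n_perm,
            alpha=config.alpha_mov,
            seed=seed0 + GROUPS.index(group),
        )
    maps["rotmov_vs_motmov_change"] = st.perm_ttest_independent(
        pw["ROT"][1] - pw["ROT"][0],
        pw["MOT"][1] - pw["MOT"][0],
        n_perm=config.n_perm,
        alpha=config.alpha_mov,
        seed=seed0 + 17,
    )

    # practice-task arm
    task_rows = []
    task_maps = {}
    if config.include_tasks:
        task_deltas = {}
        for group in GROUPS:
            subs = _group_subjects(config, group)
            for block in (1, 3):
                d_powers, d_depths = [], []
                for i, subj in enumerate(subs):
                    dseed = _subject_seed(config.master_seed, group, 30000 + 100 * block + i)
                    design = (
                        designs.build_rot_design(block, seed=dseed)
                        if group == "ROT"
                        else designs.build_mot_design(seed=dseed)
                    )
                    eeg = sim.default_eeg_params(
                        "task",
                        snr=subj.eeg.snr,
                        practice_growth=dict(config.task_growth[block]),
                    )
                    tsub = replace(subj, rng_seed=subj.rng_seed + 31 * block, eeg=eeg)
                    res = task_within_block_subject(tsub, design, layout, config.decim)
                    d_powers.append(res["d_power"])
                    d_depths.append(res["d_depth"])
                task_deltas[(group, block)] = (np.stack(d_powers), d_depths)
                for region in tf.ANALYSIS_REGIONS:
                    vals = np.array([d[region] for d in d_depths])
                    task_rows.append(
                        {
                            "group": group,
                            "block": block,
                            "region": region,
                            "mean_d_depth": vals.mean(),
                            "sd_d_depth": vals.std(ddof=1),
                        }
                    )
        for group in GROUPS:
            for block in (1, 3):
                alpha = config.alpha_block1 if block == 1 else config.alpha_block3
                dp = task_deltas[(group, block)][0]
                task_maps[f"{group.lower()}{block}_last_vs_first"] = st.perm_ttest_paired(
                    dp,
                    np.zeros_like(dp),
                    n_perm=config.n_perm,
                    alpha=alpha,
                    seed=seed0 + 100 + 10 * block + GROUPS.index(group),
                )
        for block in (1, 3):
            task_maps[f"rot{block}_vs_mot{block}"] = st.perm_ttest_independent(
                task_deltas[("ROT", block)][0],
                task_deltas[("MOT", block)][0],
                n_perm=config.n_perm,
                alpha=0.05,
                seed=seed0 + 200 + block,
            )

    return RunReport(
        config_hash=config.hash(),
        master_seed=config.master_seed,
        behavioral=behavioral.reset_index(drop=True),
        behavioral_anova=behavioral_anova,
        roi_wilcoxon=roi_wilcoxon,
        roi_kruskal=roi_kruskal,
        mov_perm_maps=maps,
        task_within_block=pd.DataFrame(task_rows) if task_rows else None,
        task_perm_maps=task_maps,
        roi_selections=pd.DataFrame(roi_rows),
        counts=pd.DataFrame(counts_rows),
        excluded_subjects=excluded,
    )


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_pipeline(
    config: RunConfig | None = None, eeg_params: sim.EEGParams | None = None
) -> dict:
    """Quick named property checks of the whole pipeline.

    Returns a mapping check name -> (passed, value).  Covers design/epoch
    counts, the Morlet oracle, window configuration sanity, depth recovery
    on one seeded subject, and permutation-map behavior under the null.
    ``eeg_params`` overrides the generator parameters being validated.
    """
    config = config or scaled_config()
    checks = {}
    checks["mov_presentations"] = (designs.build_mov_design(1).n_total == 96, 96)
    checks["rot_presentations"] = (
        designs.build_rot_design(1).n_total == 1176,
        designs.build_rot_design(1).n_total,
    )
    checks["mot_presentations"] = (
        designs.build_mot_design().n_total == 1120,
        designs.build_mot_design().n_total,
    )
    p = eeg_params or sim.default_eeg_params("mov")
    checks["erd_before_ers"] = (
        p.erd_window[0] < p.ers_window[0] and p.erd_window[1] <= p.ers_window[1],
        (p.erd_window, p.ers_window),
    )
    # Morlet vs direct convolution on a tiny fixture
    rng = np.random.default_rng(config.master_seed)
    layout = tf.make_standard_layout(32)
    data = rng.normal(size=(2, 32, 500))  # float64: full-precision TFR path
    ep = tf.EEGEpochs(data, np.arange(500) / 250.0 - 1.0, 250.0, layout)
    t1 = tf.morlet_tfr(ep, np.array([10.0, 20.0]), 5.0)
    err = 0.0
    for f, nc in ((10.0, 5.0), (20.0, 5.0)):
        w = tf._morlet_wavelet(f, nc, 250.0)
        ref = np.abs(
            np.array(
                [
                    [np.convolve(data[i, j], w, mode="same") for j in range(32)]
                    for i in range(2)
                ]
            )
        ) ** 2
        got = t1.power[:, 0 if f == 10.0 else 1, :]
        mask = np.isfinite(got)
        ref_avg = ref.mean(axis=0)
        err = max(
            err,
            float(
                np.nanmax(np.abs(got[mask] - ref_avg[mask]) / np.abs(ref_avg[mask]))
            ),
        )
    checks["morlet_oracle_rel_error"] = (err < 1e-6, err)
    # depth recovery on one subject
    subj = sim.SubjectParams(rng_seed=config.master_seed + 5, eeg=p)
    _, _, _, re0, truth = simulate_mov_subject(subj, layout, config.master_seed, 48)
    freqs = tf.BETA_FREQS
    raw = tf.morlet_tfr(re0, freqs, tf.cycles_linear(freqs), decim=5)
    btc = tf.beta_band_power(tf.normalize_relative(raw))
    depths = mod.channel_depths(btc, "mov")
    rois = mod.select_personalized_rois(depths, layout)
    res = mod.roi_modulation(btc, rois["frontal"], layout, "mov")
    planted = subj.eeg.erd_depth + subj.eeg.ers_gain
    checks["frontal_depth_recovery"] = (
        abs(res.modulation_depth - planted) / planted < 0.25,
        res.modulation_depth,
    )
    # null permutation map: no systematic findings
    rng = np.random.default_rng(config.master_seed + 9)
    hits = 0
    for _ in range(20):
        a = rng.normal(size=(12, 16))
        b = rng.normal(size=(12, 16))
        r = st.perm_ttest_paired(a, b, n_perm=500, alpha=0.05, seed=int(rng.integers(2**31)))
        hits += int(r.significant.any())
    checks["null_map_fwer"] = (hits / 20 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 20), hits / 20)
    return checks
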