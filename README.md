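# betareach

Movement-related beta-band modulation analysis for center-out reaching
practice, with a ground-truth synthetic data generator.

## The problem

Reaching movements suppress sensorimotor beta power (13.5–25 Hz) during
execution (event-related desynchronization, ERD) and rebound above
baseline after movement end (event-related synchronization, ERS). The
**beta modulation depth** — peak ERS minus peak ERD on the relative-power
time course — grows with motor practice, and the topography of that growth
(frontal vs. left/right centro-parietal) differs between plain motor
repetition and continuous visuomotor adaptation. Testing such effects
requires a long chain of steps: trajectory filtering and per-movement
kinematics, epoch realignment to movement onset, Morlet time–frequency
decomposition, relative normalization, per-subject ("personalized")
selection of a peak electrode and its six neighbors per scalp region,
ERD/ERS peak extraction, and nonparametric group statistics (Monte-Carlo
permutation sensor maps, Wilcoxon/Kruskal–Wallis/Spearman, mixed ANOVA).

`betareach` implements that chain as a tested library for researchers in
movement neuroscience, together with a generator of synthetic reaching
kinematics and movement-locked EEG whose ERD depth `d`, ERS gain `g`,
scalp topography, and adaptation time constant `τ` are known — so the
pipeline is validated by *parameter recovery* instead of by
non-distributable human data.

Core quantities, in the field's notation:

* adaptation: cursor error `r(1 − a_t) + ε` with `a_t = 1 − e^{−t/τ}`,
  and `%Adaptation = [1 − mean(DirErr)/r]·100`;
* beta time course: Morlet power, normalized `(P − μ)/μ`;
* modulation depth: `ERS_peak − ERD_peak` on the 7-electrode ROI average;
* permutation maps: `p = (1 + #{|t*| ≥ |t_obs|})/(n_perm + 1)`,
  Bonferroni-corrected per channel.

See `docs/methods.md` for the full model description and design choices.

## Worked example

`examples/03_beta_modulation.py` simulates one subject performing a
50-trial reaching test at 64 channels with a planted ERD of −40% and ERS
of +80% (depth 1.2) and runs the personalized-ROI analysis:

```
retained 43/50 trials after the 2-SD kinematic rule
planted depth (ERD 0.4 + ERS 0.8): 1.20
frontal  peak ch 34 (= planted 34)  ERD -0.45 at 0.50s  ERS +0.84 at 1.46s  depth 1.28
left     peak ch  8 (= planted  8)  ERD -0.42 at 0.40s  ERS +0.90 at 1.70s  depth 1.31
right    peak ch 15 (= planted 15)  ERD -0.43 at 0.36s  ERS +0.90 at 1.64s  depth 1.33
```

Each line is one scalp region: the selected peak electrode matches the
planted topographic maximum, ERD/ERS amplitudes are in relative-power
units (−0.45 = 45% below the epoch mean) with their latencies from
movement onset, and the measured depth recovers the planted 1.2 to within
the single-subject noise at this trial count.

The other examples cover the task schedules (`01`), adaptation kinematics
and the %Adaptation closed form (`02` — a simulated rotation block scores
67.5% vs. 67.7% expected), and a complete two-group experiment with
Wilcoxon/Kruskal–Wallis tables and permutation maps (`04`, where the
frontal ROI shows the largest between-group depth difference).

A thin CLI wraps the orchestration layer:

```bash
betareach simulate --seed 1 --out runs/demo          # designs + kinematics (+EEG)
betareach analyze  --seed 1 --out runs/demo-report   # full experiment, report tables
betareach report   --out runs/demo-report
betareach validate --seed 1                          # pipeline property checks
```

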