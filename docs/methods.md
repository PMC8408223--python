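# Methods

`betareach` re-implements, as a verifiable pipeline, an analysis of
movement-related beta-band (13.5–25 Hz) modulation during center-out
reaching practice: event-related desynchronization (ERD) during movement,
the post-movement rebound (ERS), the personalized sensor ROIs on which
their peak-to-peak difference ("beta modulation depth") is measured, and
the within-/between-block group statistics. Because the human EEG that
motivates the design is not redistributable, the package pairs the
analysis with a synthetic-data generator that plants known ground truth,
so every stage can be checked by parameter recovery rather than by
reference data.

## Experimental designs

Three declarative schedules drive both the generator and the analysis:

* **mov** — a 96-movement reaching probe; 24 targets (4/7/10 cm × 8
  directions at 45°, radii 0.5/0.88/1.25 cm yoked to distance), each
  presented 4 times in pseudo-random order without immediate repetition,
  one per 3 s.
* **ROT** — 21 sets × 56 reaches to 4-cm targets (1.5 s pacing, 30 s
  between sets) with a per-set cursor rotation stepping by 10–30° up to
  ±60°; every block ends with two 0° sets, and the within-block contrast
  uses the first and last two 0° sets.
* **MOT** — the unrotated control, 20 sets × 56.

The printed rotation ladders (13 entries for block 1, 10 for block 3) do
not map uniquely onto 21 sets. The default expansion assigns each entry a
consecutive-set repeat count — block 1 `[2,2,2,2,2,2,2,1,1,1,1,1,2]`,
block 3 `[3,2,2,2,2,2,2,2,2,2]` — chosen so that rotations change every
two sets during the ramp and each block both starts and ends with two 0°
sets (both are required by the contrast definition). The mapping is a
constructor argument, not a constant. Counterclockwise rotations are
positive; the direction can be flipped per subject.

## Kinematic model and scoring

Reaches are mirrored minimum-jerk segments: outgoing displacement
`s(u) = D(10u³ − 15u⁴ + 6u⁵)` over movement time `T`, then the time-mirror
back to the origin, sampled at 250 Hz with 0.02 cm isotropic position
noise. Reaction time is drawn per trial (default 300 ± 30 ms), outgoing
movement time 270 ± 20 ms scaled by √(D/4 cm) so peak velocity
(`1.875·D/T`) grows with target distance.

Under a rotation `r`, the generator's adaptation state is
`a_t = 1 − exp(−t/τ)` with `t` the number of trials since that rotation
value began (τ = 30 trials by default, giving block-level adaptation rates
in the high-60s/low-70s percent range for the block-1 ladder). The hand
aims at `target − r·a_t`, so the cursor-space directional error is
`r(1 − a_t) + ε`, `ε ~ N(0, 5°)`. This makes
`%Adaptation = [1 − mean(DirErr)/r]·100` equal to `100·mean(a_t)` in
expectation — the closed form the recovery tests use.

Scoring: the path is zero-phase low-pass filtered (4th-order Butterworth,
10 Hz — the reach itself lives below ~12 Hz at these movement times) and
differentiated by central differences. Movement onset is found by
back-search from the first substantial speed peak to the 5%-of-peak
crossing, then refined by extrapolating √speed to zero on a lightly
filtered (20 Hz) speed trace — the square root of a minimum-jerk onset is
locally linear in time, and the refinement removes the threshold lag (on
noise-free trajectories the planted onset is recovered within one sample;
with sensor noise the residual jitter is ~5–20 ms, negligible against the
beta envelope's time scale). Movement time is onset to maximum radial
extent (outgoing duration; the full out-and-back duration is kept as a
secondary field), peak velocity the first interior speed maximum between
them, directional error the signed angle between the cursor-space
center→PV-point direction and the target. Hand-path area is the shoelace
area of the closed path divided by path length. Correct movements fall
within 1.5 SD of the subject's baseline on |directional error|, reaction
and movement times, and normalized hand-path area; a 2-SD any-index rule
marks trials for joint kinematic/EEG exclusion, scoped to the trial group
entering a given contrast. With four jointly tested Gaussian indices the
2-SD rule removes ≈ 1 − 0.954⁴ ≈ 17% of clean trials; this is a property
of the rule, not a defect.

## Synthetic EEG

Per channel `c` and trial, the signal is

```
x_c(t) = snr · sqrt(E_c(t)) · b_c(t) · A + η_c(t) · A
```

where `b_c` is band-limited Gaussian noise (flat spectral amplitude across
the 13.5–25 Hz analysis band, 1-Hz Gaussian roll-off) normalized to unit
variance, `η_c` is 1/f background noise (amplitude slope 1), `A` an
arbitrary 10 µV scale, and `snr` the broadband RMS amplitude ratio of
carrier to background (default 1). A stochastic carrier makes single-trial
power chi-square distributed, as in real EEG; using noise that fills the
analysis band (rather than a narrow peak) keeps every 0.5-Hz bin of the
band informative.

`E_c(t)` is the planted beta *power* envelope: a baseline of 1, minus an
ERD bump during movement, plus an ERS bump after movement end, both
tapered-cosine plateaus (Tukey, taper fraction 0.5) placed relative to the
trial's true movement onset and sized to sit inside the analysis search
windows. The plateau shape means the planted extremum is attained over an
interval and is not attenuated by wavelet smoothing.

Two calibrations make "planted" mean what the recovery tests assume:

* **Relative-scale calibration.** The analysis normalizes power as
  `(P − μ)/μ` with `μ` the epoch-wide mean, which the bumps themselves
  inflate. The generator therefore solves, per channel and set, for raw
  bump coefficients such that after dividing by the epoch mean the
  envelope extremes are exactly `−d` and `+g` on the relative scale
  (`d` = ERD depth, default 0.4; `g` = ERS gain, default 0.8; nominal
  normalization span 3.2 s ≈ the −1…2.5 s window minus wavelet edges).
* **Topography.** Each region (frontal, left, right — sources near Fz, C3,
  C4 on a unit-disc layout) projects a flat-topped super-Gaussian plateau
  (width 0.5) times a narrow bump (`peak_sharpness`, default 0.15) at the
  electrode nearest the source, making one site the unambiguous regional
  maximum while its neighbors see nearly the same modulation — as real
  scalp fields do at electrode spacing. Where plateaus overlap, each
  channel's weight vector is rescaled so the total modulation equals the
  strongest single region's weight (sources compete rather than stack),
  which keeps every planted regional maximum at its source electrode.
  The measured relative depth on channel `c` is then ≈ `w_c(d+g)`.

ERS gain can differ by region and grow across practice sets
(`g_set = g·scale_region·(1 + γ_region·set)`), which is how practice
traces and the frontal-specific adaptation effect are planted.

Epochs are cut −2…+3.5 s around target onset — wider than the 4-s
segmentation window — because re-alignment to movement onset (−1…+2.5 s)
cannot be cut from a ±2 s epoch once onset is a few hundred ms late.
`segment_epochs` keeps the ±2 s convention and its exact counts
(96 / 1176 / 1120 per design before rejection).

What the generator does **not** emulate: volume conduction and correlated
noise across channels (carriers and noise are channel-independent, which
makes ROI averaging slightly more effective than on real data), eye/muscle
artifacts, non-stationary background, continuous recordings, or any
coupling between kinematic errors and beta power. Passing tests therefore
demonstrate that the analysis recovers what it claims from data matching
its own statistical assumptions — not robustness to real-world artifact
structure.

## Spectral analysis

Complex Morlet wavelets, energy-normalized, cycles rising linearly from 3
at 1 Hz to 10 at 55 Hz (the beta-only computations evaluate the same
mapping on the 13.5–25 Hz bins; a fixed 10-cycle variant is used for
personalized ROI selection). Power is the squared magnitude of the
convolution; samples within 3.5 wavelet standard deviations of an epoch
edge are NaN-masked rather than zero-padded so normalization means exclude
contaminated samples. Normalization is `(P − μ)/μ` with `μ` per
channel × frequency from either the same trials' whole-window mean
("own"), or the baseline test block (mov0) for between-block contrasts;
for the practice-task within-block contrast, `μ` is taken over all
retained trials of the four contrast sets (the narrower of the two
readings of "all trials"; both are supported). Band power is the
unweighted mean over the band's bins. Float32 epochs take a
single-precision FFT path; float64 input keeps full precision (the
convolution oracle is checked at 1e-6).

## Modulation depth and ROIs

On the movement-aligned beta time course: peak ERD is the window minimum
(−0.1…0.95 s for mov, −0.2…0.7 s for tasks), peak ERS the window maximum
(0.7…2.5 s / 0.5…1.2 s), windows intersected with the valid (non-masked)
time axis; ties take the earliest latency. Depth = ERS − ERD, asserted as
an identity on every result. Per region the ROI is the maximum-depth
channel (ties → lowest id) plus its six nearest layout neighbors
(Euclidean, region-blind); selections are made once on the reference block
(mov0, or the block-1 task data) and frozen. ROI peaks are computed on the
ROI-averaged trace, not averaged per-channel peaks.

## Statistics

* Sensor maps: Monte-Carlo permutation t-tests — sign flips of
  per-subject differences (paired) or group-label exchanges with Welch's t
  (independent; pooled-variance optional) — with
  `p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)` and per-channel Bonferroni
  (×channels, capped at 1; a max-statistic option exists). Alphas follow
  the protocol: 0.01 for block-1 task maps, 0.05 elsewhere. Under the
  null, Bonferroni over valid per-channel permutation p-values keeps the
  family-wise error at or below alpha; this is verified empirically.
* Wilcoxon signed-rank with exhaustive sign-pattern enumeration for
  n ≤ 12 (tie-averaged ranks) and the tie-corrected normal approximation
  otherwise; Kruskal–Wallis with tie correction and rank means;
  Spearman's rho with exact permutation p for n ≤ 8 and the t
  approximation otherwise. scipy implements these too and serves as an
  independent cross-check in the tests; the small-n exact paths are this
  package's own.
* Two-way mixed ANOVA (between-group × within-block) with partial η²,
  via pingouin behind the package's interface.

## Orchestration

`run_experiment` simulates a ROT-like and a MOT-like group and runs both
analysis arms. Planted effects in the default configuration encode the
qualitative pattern the analysis is meant to detect: both groups' mov3
gains a left-region ERS boost (×1.35), the ROT group additionally a
frontal (×1.5) and right (×1.25) boost plus a 1.3× directional-noise
increase in mov3 (performance cost of sustained adaptation); practice
tasks carry per-set ERS growth, stronger in block 1 than block 3. Subjects
whose mean raw beta power deviates more than 2 SD from their group are
excluded as a rule before group statistics. Per-subject seeds derive from
(master seed, group, index) so results are order-independent and
bit-reproducible; trial bookkeeping (presented = retained + excluded +
edge-dropped) is asserted per subject and block.

## Problem sizes

Default group sizes mirror the protocol (27 ROT / 14 MOT for the test
arm, 25/13 for the task arm, after exclusions). The scaled configuration
used by the validation utilities, the examples and the acceptance script
(`scaled_config`) runs 4–8 subjects per group, 24–64 channels, 30–160
trials per block, 0.5–2k permutations, and a decimation factor of 5 on
the power envelopes — sizes chosen so a complete experiment runs on a
single CPU core in minutes while keeping every statistical check
well-powered. Recovery checks quote the conditions they run at (50 trials
at snr 1 for depth recovery; 160 trials with a `peak_sharpness` 0.3
topography for peak-electrode recovery).

## Known limitations

* The kinematic onset estimator is tuned to bell-shaped speed profiles;
  multi-peaked or corrective movements would need a different onset rule
  (the generator never produces them).
* Independent-channel noise means sensor maps see somewhat higher
  effective SNR after ROI averaging than real recordings would give.
* The task arm simulates EEG only for the contrast sets; full-block task
  EEG is generated on demand but not by default.
* Preprocessing of continuous recordings (filtering, ICA, interpolation,
  re-referencing) is out of scope; epochs are assumed clean on input.
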