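# Methods

This document describes the scientific model implemented by `socialsync`, the
meaning and default value of every method parameter, what the synthetic data
generator emulates (and what it deliberately does not), and the numerical
choices that matter for reproducing results.

## 1. Scientific model

The pipeline quantifies *dynamic functional connectivity* among 16 regions of
interest (ROIs) of the macaque social brain — superior temporal sulcus (aSTS,
mSTS, pSTS), V4, gyral anterior and mid-cingulate cortex (ACCg, MCC), ventral
premotor cortex (PMv) and dorsolateral prefrontal cortex (dlPFC), in both
hemispheres — while the subject watches pseudo-random sequences of short video
clips. Clips show conspecific behaviour of one of six classes: `aggressive`,
`affiliative`, `ambiguous` (social interactions whose outcome is uncertain),
`single_actor`, `nonsocial` and `unclassified`; blank (fixation) periods
separate and bracket the clips.

For every pair of ROIs (120 edges) the pipeline computes **phase synchrony**
in a sliding window:

1. ROI time series are residualized against nuisance signals (CSF, reward
   deliveries, motion-outlier volumes) and band-passed to 0.01–0.25 Hz.
2. The instantaneous phase of each ROI is the angle of the analytic signal
   (Hilbert transform) of the filtered series, computed per run with mirror
   padding.
3. The synchrony of an edge in a window of `L` volumes is the phase-locking
   value (PLV): the magnitude of the mean unit phasor of the phase
   difference, `| mean_t exp(i(φ_a(t) − φ_b(t))) |`. A window of `L = 16`
   volumes slides in steps of 1 volume, so a run of `V` volumes yields
   `V − 15` windows.
4. Window series are cleaned by OLS regression on window means of four
   nuisance regressors (luminance, motion energy, gaze change, fixation
   fraction), arcsine-transformed for variance stabilisation, and averaged
   across repeated presentations of the same video content.

Windows are assigned to a stimulus condition by a **majority rule**: a window
belongs to a category if more than half of its (hemodynamically lagged)
volumes fall in clips of that category; windows with no majority are left
unassigned. Because only 20-s clips can dominate a 32-s window, the effective
sample for each social condition comes from its long clips.

Statistics proceed in three stages:

- **Edge selection.** Per edge, a mixed-design (split-plot) repeated-measures
  ANOVA of the session × condition mean-synchrony table tests the
  within-factor *condition* (affiliative / aggressive / ambiguous) with
  subject as the between factor and session as the observational unit. The
  one-tailed p-value is mapped to a z-score through the upper-tail normal
  quantile (`p = 0.5 → z = 0`). Edges with `z > 2.05` form the absolute
  suprathreshold network; the top 15% of edges by z (18 of 120) form the
  proportional network.
- **Network description.** Degree and eigenvector centrality of the
  suprathreshold network, plus the anatomical-group composition of
  state-specific (e.g. blank-period) networks thresholded proportionally.
- **Event-aligned timecourses.** Synchrony of edge groups
  (temporo-temporal, cingulate-temporal, …) is spline-interpolated onto a
  −4 s … +6 s grid around (lag-shifted) clip onsets at 0.5-s resolution,
  tested against the pre-onset baseline and contrasted between conditions
  (e.g. `ambiguous > others`) with Bonferroni correction per group.

## 2. Method parameters (`PipelineConfig`)

| Parameter | Default | Units | Why |
|---|---|---|---|
| `tr_s` | 2.0 | s | fMRI repetition time; all volume arithmetic derives from it. |
| `window_s` | 32.0 | s | Sliding-window length (16 volumes): long enough for a stable PLV estimate, short enough to resolve clip-scale dynamics. |
| `window_step_s` | 2.0 | s | One volume per step — maximal temporal resolution of the window series. |
| `band_lo_hz`, `band_hi_hz` | 0.01, 0.5 | Hz | Band of interest. 0.5 Hz equals the Nyquist frequency for TR = 2 s, so the default band reduces to a 0.01-Hz high-pass; a `band_hi_hz` below Nyquist engages a true band-pass. |
| `hrf_mean_lag_s`, `hrf_sd_s` | 3.0, 1.5 | s | Gamma hemodynamic response kernel used for all event convolution. |
| `fixation_min_frac` | 0.8 | – | Volumes in which the subject fixates less than 80% of the time are zeroed in stimulus regressors (the animal was not watching). |
| `outlier_sd_mult` | 2.5 | – | Volumes whose global signal change exceeds mean + 2.5 SD are flagged and excluded. |
| `z_threshold` | 2.05 | – | Absolute edge-selection threshold; one-tailed tail mass ≈ 0.0202. |
| `top_edge_frac` | 0.15 | – | Proportional threshold: ⌈0.15 × 120⌉ = 18 edges. |
| `align_pre_s`, `align_post_s` | 4.0, 6.0 | s | Extent of onset-aligned segments → a 21-point grid at 0.5-s steps. |
| `hemo_lag_s` | 2.0 | s | Hemodynamic delay applied to window-condition assignment and onset alignment. |
| `interp_step_s` | 0.5 | s | Cubic-spline grid step of aligned segments. |
| `behavior_rate_hz` | 25.0 | Hz | Sampling rate of eye traces and frame-level video features. |

All parameters are validated on construction and serialise to/from YAML
(`PipelineConfig.from_yaml` / `to_yaml`).

## 3. Synthetic data generator

The generator (`socialsync.synthetic`) is a first-class component: its
defaults *are* the emulated experimental conditions, and the statistical
properties of the pipeline (null calibration, truth recovery) are verified on
its output.

### Stimulus schedule

Four 220-s sequences, each made of 16 clips (eight 5-s, four 10-s, four 20-s)
and three 20-s blanks; 880 s of unique video. Category time shares follow the
default mix (aggressive 15%, affiliative 16%, ambiguous 14%, single actor
14%, nonsocial 18%, unclassified 23% of non-blank time) within ±3 percentage
points. Structural guarantees, all load-bearing for calibrated statistics:

- every sequence opens and closes with a blank, keeping all clips clear of
  run boundaries where analysis windows would be truncated;
- social clips are never adjacent, so windows of different social conditions
  never share volumes;
- each social category receives exactly four of the 20-s clips (equal
  effective window counts per condition);
- every ordered pair of social categories occurs between successive social
  clips.

A session presents the four sequences in a counterbalanced order, repeated
(default 4 repeats → 16 runs of 110 volumes).

### BOLD model

Node phases are generated per run and per base frequency (0.02 and 0.04 Hz,
amplitudes 1.0 and 0.7) by *common-phase mixing*: each node's phase is the
argument of `κ₀ · shared + (1 − κ₀) · R`, where `shared` is a session-wide
slow phase walk (diffusion 0.05 rad/volume), and `R` is the unit-normalised
resultant of the node's private fast phase walk (4.5 rad/volume) and
per-designated-edge phasors. A condition boost `Δκ` (default
`ambiguous: 0.4`) raises the coupling of 18 designated cingulate-temporal and
temporo-temporal edges while that condition's (HRF-convolved) envelope is
active, under the per-node budget constraint `κ₀ + Δκ ≤ 1`. White measurement
noise (SD 0.2 of the unit oscillation amplitude) and a weak stimulus-locked
drive (0.05) complete the signal.

### Confounds and behaviour

Frame-level luminance and motion energy have category-specific means (scaled
by `feature_separation`, default 0.15 — at zero the categories are
indistinguishable) plus smooth AR(1) noise; the video, and hence these
features, is fixed across sessions. Eye traces produce per-volume fixation
fractions that are Beta-distributed around each subject's mean (defaults
0.90 / 0.89 / 0.62 for the three subjects), gaze-change regressors, and
reward pulses only during maintained fixation. A slow CSF-like nuisance
series is added to the recorded time series.

### What the generator does **not** emulate

- No spatial structure: ROI coordinates are schematic, and there is no
  voxel-level simulation, coregistration or smoothing stage.
- No hemodynamic nonlinearity; the HRF is a fixed gamma kernel.
- No scanner drift or physiological (cardiac/respiratory) noise beyond the
  white and CSF terms.
- No learning or habituation across sessions; sessions are exchangeable
  draws.
- Phase dynamics are an abstract mixing model, not a biophysical (e.g.
  Kuramoto) ODE; coupling is imposed directly in phase space.

## 4. Numerical choices

- **Filtering**: 4th-order zero-phase Butterworth (`sosfiltfilt`) per run
  with 32-s mirror padding; the band upper edge is clamped strictly below
  Nyquist, and at/above Nyquist only the high-pass stage is applied.
- **PLV via cumulative sums**: windowed phasor means are computed with a
  cumulative-sum formulation, exactly equal (to 1e-12) to the direct mean
  over each window, at O(V) cost per edge.
- **ANOVA in closed form**: classic sums of squares, vectorised over edges;
  catastrophic-cancellation guards make all-equal tables yield exactly F = 0.
  An optional Greenhouse–Geisser correction (`gg_correction`) scales the
  degrees of freedom by the sphericity ε estimated from the pooled
  within-group covariance; it is off by default.
- **Eigenvector centrality**: dense symmetric eigendecomposition on the
  largest edge-bearing component, followed by one power-iteration polish so
  regular graphs (e.g. K₄) return exact values.
- **Determinism**: every random element derives from a single
  `numpy.random.SeedSequence`; sessions use spawned child sequences, so any
  session can be regenerated in isolation. Pipeline outputs are bit-identical
  across same-seed runs.
- **Arcsine transform**: values pushed outside [0, 1] by nuisance cleaning
  are clipped (count logged) before `arcsin`.

## 5. Limitations

- Statistical calibration is verified for the default design (3 subjects ×
  12 sessions, 16 runs); strongly unbalanced designs fall back on the same
  formulas but are not separately validated.
- The split-plot ANOVA assumes sphericity of the condition covariance;
  the default design satisfies it by construction (balanced window counts),
  but analyses of external data with unbalanced condition sampling should
  enable `gg_correction`.
- The white-noise synchrony floor of the real filter + Hilbert chain is
  ≈ 0.29 for 16-volume windows, above the iid-phase closed form
  √(π/64) ≈ 0.22, because band-passing induces serial correlation of the
  analytic signal within a window. Tests of the noise floor therefore
  compare against an oracle of the same chain rather than the iid constant.
- Majority-rule window assignment leaves roughly a third of windows
  unassigned (mixed content); this is intended, not data loss.
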