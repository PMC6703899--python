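# Methods

`catnap` analyzes single-cell calcium activity recorded by head-mounted
miniscopes across the sleep/wake cycle and cataplexy in narcoleptic
(orexin-deficient) and control mice.  The package takes per-cell
fluorescence traces (cells × frames, 10 frames/s) together with per-epoch
EEG/EMG summary features (4 s epochs) and produces normalized traces,
a scored hypnogram with cataplexy typing, state-tuned cell classes,
transient peak statistics, pairwise synchrony networks and transition
profiles.  A synthetic-session generator with full ground truth stands in
for raw recordings, which are out of scope (ROI extraction from movies is
assumed done upstream).

## Normalization

Raw fluorescence is converted per cell to ΔF/F with the background F0 taken
as the cell's full-recording trace mean, (ΔF/F)_i = (F_i − F0)/F0.  In
movie-based processing F0 is an average-projection frame; with movies out of
scope the per-cell trace mean is the exact per-ROI analogue.  ΔF/F is then
standardized per cell, Z = (ΔF/F − mean)/SD, using the population SD
(denominator N) over the full recording — the choice is arbitrary at these
trace lengths but is fixed and documented for reproducibility.  Flat cells
(SD = 0) raise an error rather than propagating NaNs into classification;
callers drop them explicitly.  Both statistics use the entire recording
including the odor-exposure period; restricting them to the undisturbed
period is a sensitivity axis the API leaves open (pass a sliced matrix).

## Sleep-state scoring

Epochs are scored from four features: delta power, theta power, EMG RMS and
a movement flag.  Decision rules, with thresholds in a config dataclass:

* EMG ≥ θ_wake → wake; AW if moving or EMG ≥ θ_active, else QW;
* EMG < θ_atonia and theta/delta ≥ θ_ratio and not moving → atonic
  theta-dominant candidate (REMS or cataplexy — context decides);
* otherwise delta > theta → NREMS, else QW.

Candidates are resolved by the four-criterion cataplexy rule: (1) at least
8 s (2 epochs) of atonia, (2) immobility throughout, (3) theta > delta
throughout, (4) at least 40 s (10 epochs) of uninterrupted wakefulness
immediately before the bout — or, for sequential cataplexy, onset within
40 s of the end of a qualifying bout with only wake epochs in the gap, in
which case the bout records the chain's first bout.  Non-qualifying
candidates become REMS when immediately preceded by NREMS and QW otherwise.
Default thresholds are the midpoints implied by the synthetic feature
model's state medians; on noise-free features scoring recovers the
generating hypnogram exactly (a round-trip identity covered by tests).

## HAW / AWO and SC / EC

After predator-odor onset, each AW bout is tested for hyperactivity against
the pooled mean Z of all pre-odor AW frames.  The test is a one-sided
one-sample t test over **per-cell bout means** — cells, not frames, are the
near-independent unit, and hyperactivity is directional.  p < 0.05 with an
elevated mean marks the bout HAW, otherwise AWO.  Cataplexy bouts are then
typed by the nearest preceding AW-family bout, skipping QW interludes and
earlier non-chained cataplexy bouts: HAW → emotion-induced cataplexy (EC);
undisturbed AW or AWO → spontaneous cataplexy (SC).  Chained bouts inherit
the type of their chain's first bout.  A bout whose wake context required
scanning past intervening sleep is flagged in the output rather than
silently resolved.  Statistical power is limited for very short (one-epoch
gap) HAW bouts; a missed HAW flag does not affect SC/EC typing of chained
bouts, which inherit from the chain root.

## ON-cell classification

For each cell, the mean Z is computed over all frames of each state's bouts
(AW restricted to undisturbed bouts; HAW/AWO/SC/EC tracked separately).
QW carries the lowest activity by construction, so the QW mean Z_QW serves
as baseline: a cell is ON in state S when mean_Z(S) ≥ Z_QW + 1, boundary
inclusive.  Exclusive reporting categories use the precedence REMS∧AW →
REMS/AW-ON, then AW, REMS, SC, NREMS, else unscored; EC-ON and HAW-ON are
kept as non-exclusive flags and crossed against the categories in the
composition table.  Cells ON in both SC and NREMS are reported as SC-ON
with the overlap given explicitly in the summary, since either exclusive
reading would hide it.  An ANOVA confirmation step (one-way, closed-form,
Bonferroni across states) verifies ON/non-ON separation.  Percentages are
rounded half-up to two decimals to match printed-table conventions.

## Peaks

Prominent transients are local maxima of the Z trace at or above 80% of the
cell's whole-recording maximum, with a 2 s minimum interval.  Plateaus
resolve to their leftmost frame and boundary frames are eligible.  Interval
conflicts are resolved by greedy amplitude priority (ties to the earlier
frame), which preserves the "prominent" semantics when two candidates fall
within the refractory window.  Frequencies are reported per minute of
scored state time; states with zero scored time are absent, not zero.
Distributional comparisons use the two-sample Kolmogorov–Smirnov D computed
over all pooled breakpoints, with the asymptotic Kolmogorov p; cells (not
bouts) are the observations.

## Synchrony

Within each bout of at least 100 frames (10 s — shorter bouts give
correlation estimates too noisy to interpret), Pearson R is computed for
every unordered cell pair and transformed to Z_R = ½[ln(1+R) − ln(1−R)].
|R| is clipped at 1 − 1e−6 so perfectly correlated pairs stay finite and in
the per-cell means.  The per-cell summary averages Z_R over partners with
R > 0 only; negative-R pairs stay in the matrices but not in the means.
Bout-level Z_R values are averaged unweighted within states, and a
closed-form two-way (group × state) ANOVA is reported for balanced layouts.
Pairs with R ≥ 0.6 become edges of the spatial connectivity map drawn on
cell centroids.  Note that Pearson R is invariant to additive shifts, so a
state can show high mean Z with low Z_R — the dissociation the synthetic EC
shared drive reproduces.

## Transition profiles

For each cataplexy bout of a chosen type, member cells' Z traces over the
bout are resampled to 101 points (0–100% inclusive) by linear
interpolation, averaged across cells first and then across bouts, so every
bout contributes equally regardless of duration.  A fixed 60 s pre-onset
window is kept at native resolution, right-aligned to onset and truncated
at the recording start.  Both segments are emitted so renderings with or
without a native-time lead-in are possible.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
every parameter exposed in dataclasses:

* **Hypnogram** — semi-Markov chain over AW/QW/NREMS/REMS with
  exponential bout durations (means 120/60/160/70 s; memoryless is the
  simplest defensible choice, truncated below at one epoch), REMS
  reachable only from NREMS (standard rodent architecture).  After wake
  runs ≥ 40 s, narcoleptic sessions insert cataplexy bouts (≥ 8 s, mean
  30 s) with per-opportunity hazard 0.25, tripled inside the odor window;
  chains continue with probability 0.25 across 4–36 s wake gaps.  Post-odor
  AW bouts are generated hyperactive (ground-truth HAW) with probability
  0.8.  Control sessions have hazard 0 by construction.
* **Epoch features** — state-conditioned lognormal delta/theta/EMG with
  shape σ = 0.2 around fixed medians; cataplexy shares the REMS atonic EMG
  parameter, making the two states feature-identical (only context
  separates them, as in real scoring).  σ = 0 gives the noise-free setting
  for round-trip tests.
* **Traces** — per cell, an inhomogeneous Poisson event train with
  class-specific rates per behavioral context (ON-state rates ≈ 0.35–0.6
  events/s against a 0.02 events/s QW floor), lognormal amplitudes,
  convolved with k(t) = exp(−t/τ_d) − exp(−t/τ_r), τ_r = 0.2 s,
  τ_d = 1.5 s (GCaMP6s-like kinetics at 10 frames/s; rise ≪ decay and
  transients span multiple frames), plus baseline 100 and Gaussian noise
  σ = 1.5.  During EC bouts each cell receives a mixture of private events
  and a thinned copy of one shared latent Poisson train (0.6 events/s)
  with inclusion probability equal to its coupling — one latent train with
  linear mixing is the simplest mechanism that produces EC hyper-synchrony.
  Cell classes (REMS-ON, AW-ON, REMS/AW-ON, NREMS-ON, SC-ON, odor-recruited
  unscored, flat unscored) follow fixed genotype-specific mixtures.
* **Determinism** — all randomness flows from the session seed through
  tagged seed sequences; per-cell substreams hash the cell id, so outputs
  are byte-identical across runs and insensitive to cell order.

What the generator does **not** emulate: photobleaching and slow drift,
movement artifacts, correlated baseline noise across cells, non-Poisson
burstiness, EEG waveforms (features only), and ROI crosstalk.  Passing
tests therefore demonstrate the correctness and calibration of the analysis
rules under the assumed generative structure, not robustness to real-data
artifacts.

## Problem sizes and numerical choices

Demo and test sessions are 2 h recordings (1800 epochs, 72 000 frames) with
40–60 cells and odor exposure in the second hour — enough for every state
and both cataplexy types to occur while keeping simulation-based tests
fast.  The HAW type-I calibration uses 500 direct null replicates of the
bout test; the synchrony null uses 30 replicates of 30 independent cells ×
2000 frames against the closed-form half-normal mean √(2/π(n−3)).
Floating CSV fields are written at 10 significant digits; interval
conventions are half-open and 0-based throughout; ANOVA/t statistics are
computed from closed-form sums of squares with reference distributions from
scipy, and degenerate layouts (zero within-group variance, unbalanced
two-way designs) are reported as such rather than forced.

## Known limitations

Single-session scope (multi-session aggregation is count pooling only); no
GLMM or mixed-effects modeling; no lagged cross-correlations or partial
correlations; the HAW test treats cells as independent units although they
share a brain; SC state means are computed only when SC bouts exist, never
imputed; asymptotic KS p-values are unreliable below ~5 observations and
are flagged.
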