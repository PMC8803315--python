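# Methods

`impulsekit` re-creates, on fully synthetic data with known ground truth, an
analysis chain for trait impulsivity: a cued Go/No-Go (GNG) task with
latent-trait agents, peri-event single-unit and LFP statistics with
permutation nulls, and node-wise functional-connectivity screens.  This note
describes the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not establish.

## Task and behavioral model

Each GNG trial runs precue → cue → outcome → inter-trial interval (ITI).
The precue period has uniform random duration on [9, 24] s; any port poke in
its final 3 s aborts the trial (jump to ITI).  The cue lasts up to 10 s: on
Go trials the first poke ends the cue and is rewarded (20 µl), on No-Go (NG)
trials the first poke ends the trial unrewarded (false alarm, FA) while a
full withhold is rewarded.  The ITI is 10 s.  A session schedules 30 Go and
30 NG trials in random order and stops at 40 min if the quota is not met.
By default an aborted trial is replaced by appending a trial of the same
type, so completed-trial denominators remain interpretable; the
non-replacing behavior is available via `TaskConfig(replace_aborted=False)`.

Agents carry a latent trait θ ∈ [0, 1].  Two logistic maps translate it
into behavior: the precue poke rate 0.5·σ(6(θ−0.5)) pokes/s (so per-trial
rates span the conventional none/low/mid/high categories with boundaries
0.15 and 0.3 pokes/s), and the FA probability 0.05 + 0.4·σ(6(θ−0.5))
(keeping even high-trait agents near the 45% FA training ceiling).  Precue
pokes form a Poisson process, so high-trait agents abort more trials — an
intended consequence of the protocol, which the replacement rule and the
session cap absorb exactly as the task logic dictates.

The default bimodal cohort draws a fixed number of animals per mode
(round(n·weight) from the high mode at θ≈0.8, the rest at θ≈0.2, SD 0.05,
order shuffled).  The stratified composition is deliberate: trait-split
recovery against a median split is only a well-posed question when the
latent composition matches the split fraction, and a cohort assembled from
equal numbers of high- and low-trait animals is the study design being
emulated.

**Metrics.** The precue response rate is pooled pokes ÷ pooled precue
seconds per session (the per-second unit is implied by the 0.15/0.3
category boundaries); trials ended by an abort poke are excluded from both
numerator and denominator by default (configurable).  %correct Go =
100·CorrectGo/(CorrectGo+Omission); %NG-with-FA =
100·FA/(FA+CorrectNoGo); zero denominators yield NaN plus a flag, never a
crash.  The compound impulsivity score is the mean of the within-cohort
fractional ranks of precue rate and %FA — scale-free and robust; a
quartile split labels scores ≥ 75th percentile HI and ≤ 25th LI, a median
split labels above/below with exact-cut ties flagged.

**Immobility.** The 0–100 motion measure (10 samples/s; low = still) is
smoothed with a centered 2 s moving average; samples ≤ 100−threshold
(threshold 80 → cut at 20) are immobile; gaps < 0.5 s are merged first and
runs < 1 s dropped second (the reverse order is selectable).  The synthetic
trace places the active level at 35 and the still level at 5 so the default
cut sits at the midpoint between levels, which keeps boundary bias near
zero; recovery is scored as the Jaccard overlap between extracted and
generated intervals.

## Single-unit statistics

Spike trains are inhomogeneous Poisson: intensity = baseline × product of
active event-locked gains (windows `[t+latency, t+latency+duration)`),
sampled exactly on the piecewise-constant rate; an optional refractory
period is enforced by thinning.  Units with fewer than 20 session-wide
spikes are excluded from analysis.

Rates are binned at 250 ms, Z-scored by the session-wide mean/SD of the
binned rate, then smoothed with a Gaussian window of total length 1.5 s
read as ±3 SD (SD = 0.25 s, one bin); smoothing-before-Z and raw-Z analysis
paths are both exposed.  Peri-event matrices cut one row per event on the
session bin grid (the grid edge nearest the event acts as t = 0, so
alignment error is at most half a bin); events whose window leaves the
session are dropped and counted.

**Cluster-based permutation test.** Per post-onset bin ([0, +1) s), a
two-sided one-sample t of the trial-wise baseline-corrected Z (bin minus
that trial's mean over [−2, −1) s) is computed; bins with p < 0.05 form
contiguous same-sign clusters scored by summed |t| (cluster mass — more
sensitive than extent; a bin-count statistic is selectable).  The null
flips the sign of whole baseline-corrected trial traces (valid for a
one-sample design) 5000 times by default and records each iteration's
maximal cluster mass; corrected p = (1 + #{null ≥ mass})/(n_iter + 1).
Units are labelled Up/Down when any cluster reaches corrected p < 0.05,
with direction from the largest significant cluster, else NonResponder.
Because sign flips leave sums of squares invariant, the permutation t
statistics reduce to one batched matrix product, which is what keeps
thousand-unit calibration studies cheap.

**Population shuffle null.** Whether a population's responsive-unit count
exceeds chance is tested by circularly shifting all event onsets by one
uniform offset per iteration (preserving inter-event structure;
independent jitter is selectable), recounting responsive units with the
identical pipeline, and comparing the observed count to the shuffled
distribution.  The "top 10%" criterion is applied in the tie-aware
permutation form: passed ⇔ (1 + #{null ≥ observed})/(1 + n_iter) ≤ 0.10.
For continuous statistics this is the same as "≥ the empirical 90th
percentile", but responsive counts are small integers with heavy ties, and
the raw percentile rule is measurably anti-conservative there (~2× the
nominal false-pass rate in our calibration runs); the percentile rule
remains available via `rule="percentile"`.  Peri-event gathering inside
this test treats the session as circular so every shift keeps the full
event count.

One modelling caveat: a perfectly regular event grid defeats a
circular-shift null (every shifted event keeps the same lag to the true
modulation), so the validation studies use jittered inter-event intervals,
as real task events are.

**PCA trajectories.** Trial-averaged peri-event time courses (−5 to +5 s)
of all units are concatenated across event types into a (time·events) ×
units matrix; components are fit once on the concatenation and each event's
time course is projected, so trajectories share one space.  Explained
variance ratios are reported in nonincreasing order; requesting more
components than the rank truncates with a warning.

## LFP statistics

Synthetic LFP is 1/f background noise plus narrowband Gaussian components
(theta 4–12, beta 15–30, gamma 30–90 Hz by default — conventional rodent
edges, fully configurable, since the band edges are an analysis choice);
event modulations scale a band's amplitude envelope by √(1+relative power
change) in a window around each event.  Spectral estimates use short-time
modified periodograms (Welch/Hann, 1 s segments, 50% overlap) restricted to
the record passband.

Event-locked spectrograms average the short-time power over events, then
Z-score each frequency row by its own mean/SD over the ±8 s peri-event
window (within-frequency normalization; the window length is an analysis
default, configurable).  Band time courses average Z across a band's rows
and within consecutive 2 s bins; the earliest bin serves as baseline.
Pre-event statistics use the raw (non-normalized) band power of the single
2 s bin preceding the event and the variance of raw band power across all
bins of the peri-event range; conditions are compared channel-paired with
a two-sided Wilcoxon signed-rank test.

## Functional-connectivity screens

Node series are multivariate AR(1) processes with stationary covariance
equal to a compound-symmetric base (unit variance, coupling 0.3) modified
by injected effects: a group effect adds a delta to every off-diagonal
coupling of one node's row/column for HI animals; an interaction effect
does the same only in the designated treatment × HI cell.  Innovations are
scaled by (1−a²) so the marginal covariance is exact; the process starts at
its stationary distribution and 10 further samples are discarded, leaving
230 time points by default.  Non-PSD modified covariances raise a
diagnostic error.

The group screen subtracts the HI and LI mean correlation matrices
(averaged on the raw r scale; Fisher-z averaging optional) and, per node,
tests the off-diagonal entries of its difference row against 0 with a
one-sample t, Bonferroni-corrected across nodes and ranked by |t| (sign
positive = HI couples more strongly).  Those 50 entries share the
group-mean sampling noise, so this screen's p values are descriptive — a
ranking and effect-direction device, which is how it is used and validated
here — not calibrated error rates: under a pure null it flags far more
than α.  The per-animal sensitivity variant (`variant="per_animal"`;
two-sample t across animals on per-animal node strength) is calibrated
under the null and is the one to use for inference.

The interaction screen takes per-node node strength (mean off-diagonal
correlation) per animal × treatment as the dependent variable of a
two-way mixed ANOVA (treatment within, group between), computed from sums
of squares for the one-within/one-between design and vectorized across
nodes; designs with a missing within-subject cell are rejected naming the
animal.  The interaction F is Bonferroni-corrected and ranks nodes.
Degenerate designs with zero error variance return F = 0 (no interaction
evidence) rather than NaN.

## Reproducibility and problem sizes

Every generator and permutation test is a pure function of (spec, seed);
the pipeline expands one global seed into per-stage seeds via
`numpy.random.SeedSequence(seed).spawn` in a fixed stage order, so stages
re-run independently yet reproducibly.  All times are seconds; event
windows are half-open [start, end).

The validation studies (tests and `scripts/acceptance.py`) run at sizes
chosen to give stable rates on a single CPU: 60-event sessions for unit
statistics, 1000 permutation iterations for per-unit calibration (scaled
from the 5000-iteration analysis default), 150 shuffle × 150 cluster
iterations inside the nested population study, 48-channel/30-event LFP
simulations sampled at 250 Hz (Nyquist comfortably above the highest
analyzed band; the generator default is 1 kHz), and 51-node, 5-vs-5
cohorts for the connectivity screens.

## What the synthetic validation does and does not show

The generators reproduce the *structure* of the study's data — trial logic
and trait-driven behavior, event-locked multiplicative rate changes,
band-limited oscillations with envelope modulations, AR(1) node series
with controlled covariance — under which calibration, power, and recovery
claims are exact and checkable.  They omit much of what makes real data
hard: non-Poisson spiking (bursting, slow drifts), behavioral
non-stationarity and learning within a session, volume conduction and
artifacts in LFP, hemodynamics and motion structure in node series, and
session-to-session variability within animals.  Passing tests therefore
demonstrate that the statistics are implemented correctly and behave as
designed under their own assumptions, not that those assumptions hold in
any particular real recording.

## Known limitations

- The group-difference screen's p values are descriptive (see above).
- Peri-event rows are cut on the session bin grid, so event alignment has
  ≤ 125 ms jitter at the default bin width.
- The sign-flip null assumes symmetric trial deviations; at very low
  firing rates (strongly skewed bins) per-bin levels can drift from
  nominal, though cluster-level calibration held at the rates tested.
- `BehaviorMetrics.distance` is an arbitrary-unit summary of the motion
  measure, not a calibrated path length.
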