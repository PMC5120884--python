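# Methods

This note documents the models behind each analysis stage and its
synthetic-data counterpart, the defaults that matter, and the choices made
where the underlying experimental procedures left the design open.

## Locomotion model and segmentation

**Generator.** Locomotion is a three-state semi-Markov process over
forward (F), reversal (R) and pause (P).  Dwell times are gamma-distributed
with per-state means (`dwell_mean_s`) and a common shape (`dwell_shape`,
default 1 = exponential); the embedded jump chain has no self-transitions.
The free-crawling default (F/R/P dwell means 40/2/2 s; F→R and F→P equally
likely, R and P mostly returning to F) gives an analytic forward time
fraction of 0.947, matching an exploring wild-type regime; a
`rid_ablated_spec` preset (dwells 4/2.5/2.5 s, forward speed 100 µm/s)
emulates loss of the forward-sustaining neuron (~60/20/20%).  With
exponential dwells the process is started in its stationary law (the
residual dwell of an exponential is exponential), so empirical state
fractions are unbiased at any recording length; for gamma shapes > 1 the
start is only approximately stationary, a negligible effect at the 3-min
default.

Within a bout the mean speed follows a half-sine envelope
(`speed_modulation`, default 0.2): worms accelerate into a bout and slow
before leaving it, so the velocity extremum of a bout sits near mid-bout
rather than at a noise-determined position.  Per-frame speed noise is
Gaussian (sd 10 µm/s); the heading performs Brownian rotation
(15°/√s); reversals reuse the heading and negate the along-axis
displacement (worms back up along their body axis).

**Segmentation.** Signed velocity is the centroid displacement projected
on the unit tail→head axis times the frame rate — the simplest
rotation-invariant reading of directionality — optionally box-smoothed
(default 5 frames).  Frames with |v| ≤ 20 µm/s are paused ("pause" is
otherwise undefined in tracking pipelines of this kind; the threshold is
config-exposed).  The minimum-bout rule accepts a candidate bout lasting
> 3 frames *or* ≥ 0.3 s (at 10 fps both give 3 frames).  Sub-minimum bouts
are absorbed in simultaneous rounds — each short bout is relabelled to the
flanking state when both flanks agree, to its single neighbour at the
recording edge, and to P otherwise — which keeps the outcome symmetric
under time reversal and prevents single-frame jitter from counting as an
initiation.  Irreducible sub-minimum pause remnants (left where the
velocity crosses zero at a direction change) are retained and do not
break transition adjacency downstream.  Frames with a degenerate body
axis are excluded from every denominator.  Bout intervals are half-open
`[start, end)` with 0-based frames.

## Calcium model and transition analysis

**Generator.** The latent activity a(t) is a first-order low-pass of a
movement drive x(t) delayed by an onset lag: exact per-frame update
`a += (1 − e^(−dt/τ))(x_lagged − a)`, so a unit step crosses 63% of its
plateau at lag + τ.  Two drives are provided: `"indicator"` (the binary
forward-state indicator, the analytically convenient model used in the
closed-form tests) and the default `"graded"` — the rectified forward
velocity normalised to its 90th percentile.  The graded drive reflects
that the neuron's activity scales with crawling vigour, which is what
makes the rate correlation (below) informative, and it reproduces the
observed phenomenology that the calcium peak trails the velocity rise by
several seconds: the within-bout speed envelope crests mid-bout (~10 s
into a typical forward bout) and the sensor follows with a short delay.
Sensor kinetics default to GCaMP6-like values (lag 0.5 s, τ 1.5 s).
Channels are GCaMP = F₀(1 + α·a)·m(t) + ε and RFP = R₀·m(t) + ε with a
shared multiplicative artifact m(t) = 1 + A·sin(2πft) (A = 0.1,
f = 0.25 Hz) and Gaussian noise (sd 1 on baselines of 100), so the
channel ratio is exactly artifact-free in the noiseless limit.

The calcium-session locomotion preset (`calcium_session_spec`) uses dwell
means 20/8/2 s with gamma shape 3: pad-constrained animals change
direction far more often than free crawlers, and bout durations have a
refractory rise that makes sub-second reversals rare.  Long-enough
reversals are what let the decay phase of the signal express itself
within a transition window.

**Analysis.** ΔF/F uses a 10th-percentile-of-ratio baseline (config
exposed; a pre-event-window mean is the alternative).  Transitions are
anchored at bout boundaries from the segmentation; for a reversal→forward
event the trough is the velocity minimum of the preceding reversal bout
and the peak the maximum of the following forward bout, the velocity rate
is (V_peak − V_trough)/Δframes, and the forward→reversal case uses the
mirrored sign convention (V_trough − V_peak)/Δframes, so accelerations
are positive and decelerations negative.  The calcium slope is the
least-squares ΔF/F slope over the same `[trough, peak]` frame support —
paired quantities share a support.  Events whose support leaves the
recording are dropped.  The rate correlation is Pearson's r over pooled
(rate, slope) pairs; per-kind correlations are also reported by the
analysis driver.  Event-aligned averages use a ±20 s window (config
exposed) and only events with a complete window.

## Optogenetic run/turn analysis

**Generator.** Sessions alternate laser OFF/ON with a 180-s half-period
(OFF first).  Run durations are exponential (mean `mean_run_s`, default
the forward dwell mean) scaled by the ON duration multiplier at the epoch
of the run's start; crawling speed is multiplied per-frame by the ON
speed multiplier, so velocity steps exactly at switches.  Turns are
pivots of 90–180° executed over 0.5 s (well above the turn criterion) at
half speed.

**Analysis.** Headings come from box-smoothed (0.5 s) centroid
displacements; sub-noise-floor steps leave the heading undefined.  A
frame is a turn when the circular heading difference across the endpoints
of a centred 1-s window exceeds 60°; a centred (rather than trailing)
window was chosen and is config-exposed, and the implementation is tested
frame-for-frame against an exhaustive sliding-window oracle.  Runs are
maximal unflagged intervals, attributed to the epoch of their start (a
split-at-boundary alternative is not provided; attribution by start is
the simpler reading and the bias vanishes as runs shorten relative to the
3-min epochs).  All runs in each phase enter the ON/OFF comparison.  The
phasic analysis averages velocity over the 10 s before and after each ON
switch (4 s for slow strains — a config value, not hard-coded per
genotype), includes only switches flanked by turn-free forward movement
over the whole window, and tests the per-switch differences with the
two-sided Wilcoxon matched-pairs signed-rank test.

## Subtractive enrichment

**Generator.** Gene baselines are gamma(0.7, 100); all 12 cell-type
profiles equal the baseline by default (`type_heterogeneity_sd` = 0), so
a non-planted gene has a true GFP+/AllCells ratio of exactly 1 and the
recovery ground truth is crisp; heterogeneity can be switched on.  The 50
planted target-cell-specific genes draw a higher-mean baseline
(gamma(2, 100)) — validated cell-specific markers are abundant
transcripts — and are expressed at `effect_size` (5) × baseline in the
target type and 0.02 × baseline elsewhere.  GFP+ mixes 5 types with
target weight 0.3; AllCells mixes all 12 with target weight 0.04 (one
labelled neuron among all cells of the animal), giving planted genes a
true wild-type ratio near 7, in the range of the published fold changes.
The mutant design removes the target type from both mixtures, collapsing
the planted ratio to ~1.  Counts are NB with dispersion 0.1 around
mixture means times log-normal(0, 0.3) library-size factors; replicates
are 3 (wild type) and 4 (mutant), matching the published design.

**Pipeline.** Size factors are median-of-ratios over genes nonzero in
every sample.  The differential test models normalised counts as NB with
a per-gene method-of-moments dispersion pooled across the two groups and
floored by the experiment-wide median of positive estimates — with 3–4
replicates the per-gene estimate is far too noisy on its own, and this
moderation is in the spirit of the classic count-based DE tools — and a
normal-reference Wald statistic on the log difference of group means
(half a normalised count keeps the log finite for empty groups).  Null
calibration is nominal (rejection 0.04–0.05 at p < 0.05 over 2000 null
genes), and a label-permutation reference for the same statistic is
bundled as an independent check: decisions at the 0.05 level concord
≥ 95% and p-value ranks agree (Spearman > 0.95), while mid-range p-values
can deviate by up to ~0.1 at n = 8 per group — the expected finite-sample
behaviour of a normal reference.  BH-FDR comes from statsmodels and is
tested against the brute-force step-up definition.  The enrichment call
is strict: q < 0.05 AND mean ratio > 1.  The ratio filter is the plain
mean quotient (the reading consistent with published fold-change tables);
a log2-quotient mode exists for completeness.  Fold changes are reported
on normalised means by default and raw means on request; genes all-zero
everywhere get p = 1 and are excluded from the size-factor reference.
Set subtraction reports shared / wt-only / mut-only / preferential
(symmetric difference) with the identities |shared| + |wt_only| = |wt|
etc. asserted in tests.

## Statistical tests

Two groups: Mann–Whitney U, exact for ≤ 12 tie-free observations per
group, tie-corrected normal approximation otherwise.  More groups:
Kruskal–Wallis, then Dunn's pairwise z with pooled mid-ranks and tie
correction, Bonferroni-adjusted by default (any statsmodels adjustment
name is accepted); Dunn's is implemented in-package.  Paired data:
two-sided Wilcoxon signed-rank after dropping zero differences, exact via
scipy for ≤ 12 tie-free differences, exact by full sign-assignment
enumeration with mid-ranks when ties are present, normal approximation
otherwise.  All tests are two-sided throughout (sidedness was otherwise
unspecified); correlations are computed on events pooled across animals,
with per-animal aggregation available in the driver.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the four data kinds — state
dynamics, ratiometric coupling with shared artifacts, epoch-modulated
runs, mixture-design counts — with parameters chosen once to mimic the
regimes the assays operate in.  They do not emulate tracking failures
beyond degenerate-axis frames, omega-turn self-occlusion, bleaching,
stage drift, or biological between-animal variability beyond seed-to-seed
dwell randomness.  Passing the recovery tests therefore demonstrates that
the analysis code measures what it claims on data whose ground truth is
known; it does not certify performance on recordings with artifact modes
the generators omit.

## Problem sizes and numerics

Default validation sizes — 10 animals × 3 min for behavioural recovery,
200 sessions for coupling-sign recovery, 100 random traces for the turn
oracle, 2000 genes for null calibration and planted recovery — were
chosen so the full suite and the acceptance script each run in seconds
while leaving the statistical margins wide (e.g. sign recovery at ~99%
against a 95% requirement).  Tolerances follow estimator noise: 3-SEM
bands for parameter recovery, exact or 1e-10 assertions for algebraic
identities (artifact cancellation, BH, Venn arithmetic).  Degenerate
inputs fail loudly and early: all-zero samples, zero-variance
correlations, empty epochs and all-untracked recordings are flagged or
raised with the offending name.
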