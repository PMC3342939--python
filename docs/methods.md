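# Methods

This note documents the models, conventions and numerical choices behind
`flysleep`, in the order data flow through the pipeline.

## Sleep scoring from activity counts

A fly's recording is a vector of non-negative beam-cross counts in 1-min
bins, anchored to clock time and annotated with the photoperiod (12:12
LD square wave phased to lights-on, or constant light/dark). Scoring is
purely definitional:

* **sleep bout** — maximal run of ≥ 5 consecutive zero-count minutes;
* **rest** — zero-count run of 1–4 minutes;
* **brief awakening** — wake run of exactly 1 minute not touching a
  recording boundary or data gap;
* **waking activity** — total counts divided by minutes *not inside a
  sleep bout* (rest minutes count as waking time), decoupling locomotor
  intensity from sleep amount;
* **sleep latency** — minutes from a lighting transition to the onset of
  the first sleep bout that *begins* at or after it (a bout already in
  progress does not count), missing if none begins before the next
  transition. Both lights-on and lights-off latencies are exposed, and
  per-fly summaries average over all complete transitions.
* **death call** — one past the last active minute, reported only when
  followed by ≥ 12 h of zero counts extending to the end of recording.

Conventions where published definitions are silent:

* All intervals are half-open `[start, end)` in minutes from recording
  start; time arithmetic is integer.
* Missing minutes (monitor dropouts, non-OK status codes) are NaN, never
  zero: a zero is biologically meaningful. Gaps produce no bout and
  censor their neighbours. A channel with > 5% missing minutes fails QC.
* Bouts crossing a lights transition are split at the transition for
  day/night metrics but counted once (phase `mixed`) in whole-recording
  counts, keeping day + night totals additive without double-counting.
* Censored bouts (touching a boundary or gap) count toward totals but
  are excluded from bout-length distributions, whose observed lengths
  are truncated.
* The circadian sleep profile is the per-minute-of-day fraction asleep
  averaged over recording days, smoothed with a centered 30-min window
  that wraps across the day (for even windows the extra minute falls
  before the center). It is indexed by clock minute-of-day.
* The first recording day is discarded by default before scoring
  (acclimation after CO₂ loading).

## Group statistics

The sleep partitioning score divides each fly's bout count by the mean
count of the control flies in its experimental cohort; the cohort and
control flags come from the design table and are never inferred. Control
group means are exactly 1 by construction (asserted in tests).

Engines are the standard ones — `scipy.stats` for Welch's t
(Welch–Satterthwaite df), the two-sample KS statistic and Fisher's exact
test; `statsmodels` OLS/`anova_lm` for ANOVA; `lifelines` for the
log-rank test. Package-owned conventions:

* KS p-values use the asymptotic distribution. Bout lengths are integer
  minutes, so ties are ubiquitous and an exact small-sample p is not
  well defined; sample sizes are reported alongside.
* Two-way ANOVA uses Type II sums of squares for unbalanced designs
  (identical to Type I when balanced, which is tested); empty design
  cells are an error naming the cell.
* Fisher's LSD after one-way ANOVA uses the pooled mean-square error and
  its residual df with no multiplicity correction (the definition of
  LSD); with two groups it reduces exactly to the pooled t-test.
* SEM uses the n−1 sample SD. Degenerate inputs have explicit behavior:
  two zero-variance groups with equal means give t = 0, p = 1; a
  constant response gives an all-zero ANOVA F table.

## Arousal and deprivation assays

The light-pulse assay probes sleep depth at ZT13 (1 h after lights-off),
when most flies are inside a sleep bout. Only flies asleep at pulse
onset are eligible. Latency is the index of the first minute with any
count, scanned over `pulse_start .. pulse_start + 180` inclusive — the
same window the non-responder rule checks, so a responder always has a
defined latency. A *non-responder* shows no counts for 3 h post-pulse
but is active in the 24 h after the next lights-on; post-pulse silence
that extends through the next day is excluded (indistinguishable from
death), and a formal death call always supersedes a non-responder call.
Post-pulse activity is summed over a configurable window (default
60 min).

Deprivation efficacy is 1 − (sleep during the deprivation window)/(sleep
in the same clock window 24 h earlier), floored at 0 with a flag;
rebound is the sleep difference between the 12 h after deprivation and
the matched window a day earlier.

## Video tracking

The background composite is the per-pixel median over sampled frames
(≥ 30 required); the median rejects the fly wherever it occupies a pixel
in fewer than half the sampled frames — which means short movies of
mostly-sleeping flies need either a longer stack for the composite or an
active fixture. Detection thresholds the absolute difference image
inside each tube ROI and takes the intensity-weighted centroid of the
largest connected component (8-connectivity, minimum area 4 px); the
threshold is a fixed configuration value calibrated once against the
synthetic noise model, not adapted per frame, for reproducibility.
Missed detections carry the last position forward with a flag; a fly
missing in > 1% of frames fails QC.

Video sleep requires *every* consecutive-frame displacement below 2 px
(per-frame movement, not net displacement) for ≥ 5 min. Feeding bouts
are maximal periods with the centroid within one body length
(default 2.5 mm, a typical adult body length) of the food end along the
tube axis. Pixel geometry is 0-based, origin top-left; mm↔px conversions
are exact inverses through `pixels_per_mm`.

## The activity generator

Each fly is an independent two-state discrete-time Markov chain over
{wake, sleep} at 1-min resolution. Transitions into minute *t* use the
hazards of minute *t*'s phase:

| parameter | default | meaning |
|---|---|---|
| `p_ws_day` | 0.02 | wake→sleep per minute, lights on |
| `p_ws_night` | 0.072 | wake→sleep per minute, lights off |
| `p_sw_day` | 0.025 | sleep→wake per minute, lights on |
| `p_sw_night` | 0.008 | sleep→wake per minute, lights off |
| `fragmentation_k` | 1.0 | joint multiplier on all four hazards |
| `lambda_wake` | 2.0 | mean beam crosses per waking minute |

Defaults (`p_ws_day = 0.02`, `p_sw_day = 0.025`, `p_ws_night = 0.072`,
`p_sw_night = 0.008`) give ~44% day sleep in ~20-min bouts, ~90% night
sleep in ~2-h bouts, roughly 12 scored bouts/day, and > 80% of flies
inside a sleep bout at ZT13 — a realistic male-fly architecture under
12:12 LD. The arousal hazard is phase-dependent because real day siesta
is shallow (short bouts) while night sleep is deep; a single shared
hazard cannot reproduce both the bout-length contrast and plausible
light-pulse non-responder fractions.

`fragmentation_k` scales all hazards jointly, so the within-phase
stationary sleep fraction `p_ws/(p_ws + p_sw)` is exactly invariant
while bout frequency scales with k — more sleep bouts at unchanged total
sleep and waking activity. This is the minimal parameterization of the
diet phenotype; diet enters the simulator only through k and the pulse
multiplier below, not through any mechanistic feeding model.

Waking minutes emit zero-truncated Poisson counts (`1 + Poisson(λ−1)`,
mean λ), sleeping and dead minutes emit zero, so the latent state is
exactly recoverable from counts and scoring correctness can be tested
separately from observation noise (`zero_truncated=False` restores plain
Poisson emission for robustness studies). One consequence of the ≥ 5-min
threshold: scored total sleep excludes latent sleep inside runs shorter
than 5 min, so while *latent* sleep is exactly k-invariant in
expectation, *scored* sleep drifts slightly (~0.5% at k = 2, ~3% at
k = 4) because heavier fragmentation puts more sleep into sub-threshold
runs. The expected scored bout rate is computed exactly by iterating the
chain's periodic steady state over the 1440-min day and summing
per-minute start rates times the 4-min survival product; with constant
hazards this reduces to `1440 · π_w · k·p_ws · (1 − k·p_sw)⁴`.

**Protocols.** The light pulse scales the sleep→wake hazard by
`(1 + multiplier)` during the pulse and the 3-h response horizon; the
multiplier is the per-diet arousal-threshold knob (defaults used in the
acceptance fixtures: 4.0 for the low-sugar-like diet, 0.1 for the
high-sugar-like one). Mechanical deprivation forces sleeping flies awake
each minute of the 12-h window with probability 0.98 (2-s shaking every
minute is nearly always effective), then multiplies `p_ws` by
`rebound_boost` (default 1.5) for 12 h — a transient homeostatic
sleep-pressure elevation.

**Randomness.** Every fly owns RNG substreams keyed by `(seed, fly)`,
with separate uniform streams for the two transition directions. Two
runs that differ only in parameters therefore share all threshold
comparisons — a common-random-numbers coupling, the standard
variance-reduction design for comparing simulator configurations (e.g.
k = 1 vs k = 2 cohorts); it also makes a protocol run identical to its
baseline up to the moment the protocol engages. Identical parameters
including seed give byte-identical emitted files.

## The trajectory generator and renderer

A semi-Markov process over {move, pause, feed, sleep} at 1 Hz in a
65 × 5 mm tube with food at x = 0: movement is a correlated random walk
(2.5 mm/s, 5%/s heading reversal, reflecting ends); stops at the end of
each move episode are feeding visits (walk to the food zone, dwell
exponentially, mean 90 s), sleep stops (≥ 330 s plus an exponential
tail) or short pauses (capped at 200 s so pauses can never satisfy the
video sleep threshold). Sleep stops occur only ≥ 3 body lengths from the
food, reached in full-speed steps so that the displacement into and out
of a sleep stop is never near the 2-px threshold — making ground-truth
immobility runs structurally identical under the displacement rule on
true and on detected positions. An optional `post_sleep_feed_p` sends
the fly straight to the food after a sleep stop, for testing post-sleep
food-approach recovery; wandering flies also reach the food by chance,
so recovery tests calibrate that baseline with `post_sleep_feed_p = 0`.

The renderer draws the fly as a dark elliptical Gaussian blob
(σ = 0.6 × 0.35 mm, amplitude 120 grey levels) on a flat 200-level
background with tube walls, adds Gaussian pixel noise (default σ = 3),
and emits uint8 frames plus the matching ROI at 4 px/mm. At these
defaults centroid tracking achieves ~0.1 px RMSE; the 0.5 px acceptance
bound leaves a wide margin.

## What the synthetic data do and do not show

The generators reproduce the *structure* the analysis relies on —
two-state bout statistics, circadian consolidation, diet-like
fragmentation, protocol responses, tube-confined trajectories — with
exact ground truth. They do not emulate inter-fly hazard heterogeneity,
ultradian rhythms, non-geometric bout-length tails, position-dependent
beam sensitivity, lighting drift or camera vignetting. Passing tests
therefore demonstrate correctness of the scoring and statistics under
the stated definitions, not robustness to every artifact of real
recordings; the QC gates (missing-minute fraction, detection fraction,
death calls) are the designed defense for real data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the suite
fast while leaving Monte-Carlo margins comfortable: 16–32 flies × 6
simulated days for architecture contrasts, 50–100 seeded replicates for
ordering/power checks, 10,000 replicates for type-I calibration,
1,000 random vectors for oracle equivalence, and 2,400-frame rendered
movies for the video pipeline.
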