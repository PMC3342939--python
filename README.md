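# flysleep

Sleep-architecture analysis for *Drosophila melanogaster* behavioral data:
per-minute beam-cross counts from Trikinetics-style Drosophila Activity
Monitors (DAM), and 1 frame/s video of flies in individual food/plug tubes.
It is written for chronobiology and sleep labs that need a tested, scriptable
replacement for ad-hoc sleep-scoring spreadsheets — in particular for
experiments where a treatment (diet, genotype, drug) re-partitions sleep
into more or fewer episodes without changing total sleep.

## What it computes

**Sleep scoring.** Fly sleep is defined behaviorally: a *sleep bout* is a
maximal run of ≥ 5 consecutive minutes with zero activity counts; shorter
inactivity runs (1–4 min) are *rest*, and a 1-minute wake run between
inactive periods is a *brief awakening*. Per fly and per phase (whole
recording / light / dark), the package reports total sleep, sleep-bout
count, mean bout length, rest and brief-awakening counts, waking activity
(beam crosses per non-sleep minute), sleep latency after lights-on/off, a
30-min moving-average circadian sleep profile, and an activity-derived
death time (no counts for ≥ 12 h through the end of recording).

**Architecture statistics.** The *sleep partitioning score* normalizes each
fly's bout count to the mean of its cohort's control group, so the control
mean is exactly 1. Bout-length distributions are compared with the
two-sample Kolmogorov–Smirnov test; group contrasts use Welch's t-test,
one-way ANOVA with Fisher's LSD, or two-way ANOVA with interaction
(Type II sums of squares); responder tables use Fisher's exact test and
tube lifespans the log-rank test.

**Arousal and deprivation assays.** For a 5-min light pulse delivered 1 h
after lights-off, the package scores eligibility (asleep at pulse onset),
latency to the first active minute, and *non-responders* (no activity for
3 h post-pulse but active the following day — distinguishing deep sleep
from death). For mechanical sleep deprivation it reports efficacy
(fraction of baseline sleep lost) and rebound (sleep gained versus the
matched clock window a day earlier).

**Video tracking.** Median-composite background subtraction and
largest-component centroid detection per tube ROI, with carried-forward
flagging of missed detections and a QC gate. Video sleep is < 2 px
centroid movement per frame sustained ≥ 5 min; a feeding bout is a period
within one body length of the food end.

**Synthetic data.** A two-state (wake/sleep) per-minute Markov generator
with phase-dependent hazards, a joint *fragmentation factor* `k` that
scales all hazards (more bouts, unchanged total sleep — the diet
phenotype by construction), zero-truncated Poisson waking counts, light
pulse / deprivation / rebound protocols, and a tube-trajectory simulator
rendered to noisy frame stacks. Every generator returns its ground truth,
so the whole pipeline is testable without recordings.

## Worked example

Simulate a two-diet experiment (low-sugar-like fragmentation `k = 2` vs a
high-sugar-like control `k = 1`, 16 flies per diet, 6 days with the first
discarded), score it, and run the group statistics:

```bash
flysleep simulate-dam --out demo/sim --groups "LS=2.0,HS=1.0" \
    --n-flies 16 --days 6 --seed 1
flysleep score --dam monitor1=demo/sim/monitor1.txt \
    --dam monitor2=demo/sim/monitor2.txt \
    --design demo/sim/design.csv --out demo/scored
flysleep stats --metrics demo/scored/metrics.csv \
    --design demo/sim/design.csv --out demo/stats
```

`demo/stats/group_summary.csv` then contains (mean ± SEM per diet):

```
diet  whole_sleep_bout_count_mean  whole_sleep_bout_count_sem  whole_total_sleep_min_mean  whole_waking_activity_mean
  HS                       63.625                    0.831039                   4791.8750                    1.992350
  LS                      119.500                    1.912677                   4699.0625                    1.963396
```

The LS-like diet nearly doubles the number of sleep bouts (119.5 vs 63.6
over five scored days) while total sleep differs by under 2% and waking
activity is unchanged — the sleep-partitioning phenotype. `tests.csv`
carries the Welch comparison of bout counts (t = −26.8, p ≈ 2 × 10⁻¹⁷),
and `partitioning_scores.csv` the normalized bout numbers (control mean
exactly 1.0; LS mean 1.88 here).

The same pipeline runs end-to-end from a YAML config (`flysleep run
--config config.yaml`), which also emits figures (bout-count bars,
bout-length distributions, circadian sleep profiles) and a manifest with
every seed and parameter. `flysleep simulate-video` and `flysleep
video-track` do the analogous round trip for the video pipeline.

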