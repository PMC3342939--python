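"""Figure generation for pipeline reports (matplotlib, Agg backend)."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_bout_count_bars(summary: pd.DataFrame, metric: str, by: str, path) -> None:
    """Group means with SEM error bars for one metric."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(
        summary[by].astype(str),
        summary[f"{metric}_mean"],
        yerr=summary[f"{metric}_sem"],
        capsize=4,
        color="#777777",
    )
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bout_length_distributions(dists: Mapping[str, pd.Series], path) -> None:
    """Empirical sleep-bout-length distributions per group (log-x)."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    for name, dist in dists.items():
        ax.plot(dist.index, dist.values, marker=".", ls="-", lw=0.8, label=name)
    ax.set_xscale("log")
    ax.set_xlabel("sleep bout length (min)")
    ax.set_ylabel("probability mass")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sleep_profiles(profiles: Mapping[str, np.ndarray], path) -> None:
    """Mean 30-min moving-average sleep fraction across the circadian day."""
    fig, ax = plt.subplots(figsize=(5, 3))
    minutes = np.arange(1440) / 60
    for name, prof in profiles.items():
        ax.plot(minutes, prof, lw=1.0, label=name)
    ax.set_xlabel("zeitgeber time (h)")
    ax.set_ylabel("fraction asleep")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_arousal_latency(latencies: Mapping[str, Sequence[float]], path) -> None:
    """Arousal latencies after the light pulse, one box per group."""
    fig, ax = plt.subplots(figsize=(4, 3))
    names = list(latencies)
    ax.boxplot([list(latencies[n]) for n in names], tick_labels=names)
    ax.set_ylabel("latency to activity (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
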