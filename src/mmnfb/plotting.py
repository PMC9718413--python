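"""Minimal plotting helpers (difference wave, MMN trajectory)."""

from __future__ import annotations

import numpy as np


def plot_difference_wave(dw, search_window_ms=(100.0, 250.0), ax=None):
    """Difference waveform with the MMN search window shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    t = (np.arange(dw.samples.shape[0]) - int(round(dw.pre_ms * dw.sample_rate / 1000.0))) \
        * 1000.0 / dw.sample_rate
    ax.plot(t, dw.samples, lw=1.2, color="k")
    ax.axvspan(*search_window_ms, alpha=0.15, color="tab:red")
    ax.axhline(0.0, lw=0.5, color="gray")
    ax.set_xlabel("time from onset (ms)")
    ax.set_ylabel("deviant - standard (µV)")
    ax.set_title(f"difference wave (n={dw.n_standard} std / {dw.n_deviant} dev)")
    return ax


def plot_mmn_trajectory(mmn_table, ax=None):
    """Group-mean normalized MMN per training day (one line per group)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for group, sub in mmn_table.groupby("group"):
        means = sub.groupby("day")["value"].mean()
        ax.plot(means.index, means.values, marker="o", label=group)
    ax.set_xlabel("training day")
    ax.set_ylabel("normalized MMN")
    ax.legend(fontsize=8)
    return ax
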