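"""Minimal matplotlib rendering of time courses and sweep curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analytic import MotifResponse, StationaryResponse

__all__ = ["plot_timecourse", "plot_sweep"]


def plot_timecourse(
    resp: MotifResponse | StationaryResponse, path: str | Path, n_samples: int = 800
):
    """Analog traces on top, digital/gate signals below."""
    if isinstance(resp, StationaryResponse):
        window, trajs, signal = (0.0, resp.period), resp.cycles, None
    else:
        window, trajs, signal = resp.window, resp.trajectories, resp.input_signal
    ts = np.linspace(window[0], window[1], n_samples)
    fig, (ax1, ax2) = plt.subplots(
        2, 1, sharex=True, figsize=(7, 4.5), height_ratios=[2, 1]
    )
    if signal is not None:
        ax1.plot(ts, np.asarray(signal(ts), float), "k-", lw=1, label="X")
    for gene, traj in trajs.items():
        ax1.plot(ts, np.asarray(traj(ts), float), lw=1.5, label=gene)
    ax1.set_ylabel("concentration")
    ax1.legend(loc="upper right", fontsize=8)
    for i, (name, dig) in enumerate(resp.digitals.items()):
        ax2.step(ts, np.asarray(dig.value(ts), float) * 0.8 + i, where="post",
                 lw=1, label=name)
    ax2.set_yticks([])
    ax2.set_xlabel("time (h)")
    ax2.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_sweep(frame: pd.DataFrame, path: str | Path, value: str = "z_mean"):
    """Stationary statistic versus period, one curve per input shape."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for shape, grp in frame.groupby("shape"):
        ax.semilogx(grp["period"], grp[value], marker="o", ms=3, label=shape)
    ax.set_xlabel("oscillation period (h)")
    ax.set_ylabel(value)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
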