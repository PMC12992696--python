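"""Small matplotlib helpers for the standard report figures."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .pose import kde_1d, moving_average  # noqa: E402

__all__ = ["plot_distance_timeseries", "plot_distance_kde"]


def plot_distance_timeseries(time_ns, series_by_label: dict, path: str | Path,
                             window: int = 20) -> Path:
    """Moving-average distance traces (default 20-frame window)."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for label, values in series_by_label.items():
        ax.plot(time_ns, moving_average(values, window), label=label, lw=1.2)
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("distance (Å)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_distance_kde(samples_by_label: dict, path: str | Path) -> Path:
    """Gaussian-KDE distance distributions, one curve per interaction."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, samples in samples_by_label.items():
        grid, dens = kde_1d(np.asarray(samples, dtype=float))
        ax.plot(grid, dens, label=label, lw=1.2)
    ax.set_xlabel("distance (Å)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
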