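"""Rendering of the three rated plot types and the QQ diagnostic.

Fixed figure sizes and axis conventions so rating files stay comparable
across runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .evaluate import BlandAltmanStats, MeanSDStats, VolcanoStats  # noqa: E402

FIGSIZE = (5.0, 4.0)


def plot_mean_sd(stats: MeanSDStats, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=FIGSIZE)
    ax.scatter(stats.rank_of_mean, stats.sd, s=6, alpha=0.6)
    order = np.argsort(stats.rank_of_mean)
    ax.plot(np.sort(stats.rank_of_mean), stats.trend, color="orange", lw=2)
    ax.set_xlabel("rank of mean")
    ax.set_ylabel("standard deviation")
    ax.set_title(title or "Mean-SD")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_bland_altman(stats: BlandAltmanStats, path: str | Path,
                      title: str = "") -> None:
    fig, ax = plt.subplots(figsize=FIGSIZE)
    ax.scatter(stats.pair_mean, stats.pair_diff, s=4, alpha=0.4)
    ax.axhline(0.0, color="blue", lw=1)
    ax.axhline(stats.mean_diff, color="green", lw=1.5)
    ax.axhline(stats.loa_low, color="orange", lw=1.5)
    ax.axhline(stats.loa_high, color="orange", lw=1.5)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("pair difference")
    ax.set_title(title or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_volcano(stats: Sequence[VolcanoStats], path: str | Path,
                 title: str = "") -> None:
    fig, ax = plt.subplots(figsize=FIGSIZE)
    x = [v.relative_effect for v in stats]
    y = [v.minus_log10_p for v in stats]
    ax.scatter(x, y, s=8, alpha=0.6)
    ax.axvline(0.5, color="grey", lw=1, ls="--")
    ax.set_xlabel("relative effect")
    ax.set_ylabel("-log10 p")
    ax.set_xlim(0, 1)
    ax.set_title(title or "Volcano")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_qq(z: np.ndarray, theo: np.ndarray, path: str | Path,
            title: str = "") -> None:
    fig, ax = plt.subplots(figsize=FIGSIZE)
    ax.scatter(theo, z, s=4, alpha=0.4)
    lim = [min(theo.min(), z.min()), max(theo.max(), z.max())]
    ax.plot(lim, lim, color="grey", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("standardized U statistics")
    ax.set_title(title or "QQ")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
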