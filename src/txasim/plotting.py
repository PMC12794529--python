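"""Concentration-time plots per regimen (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exposure import ConcentrationProfile


def plot_profiles(profiles_by_regimen: Mapping[str,
                                               Sequence[ConcentrationProfile]],
                  path: str | Path | None = None,
                  threshold: float | None = 10.0,
                  log_scale: bool = True):
    """Median (IQR band) noiseless concentration-time course per regimen.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, profiles in profiles_by_regimen.items():
        t = profiles[0].times
        c = np.vstack([p.c_true for p in profiles])
        q1, med, q3 = np.quantile(c, [0.25, 0.5, 0.75], axis=0)
        line, = ax.plot(t / 60.0, med, label=label)
        ax.fill_between(t / 60.0, q1, q3, alpha=0.15,
                        color=line.get_color(), linewidth=0)
    if threshold is not None:
        ax.axhline(threshold, linestyle="--", color="grey", linewidth=1,
                   label=f"{threshold:g} mg/L")
    if log_scale:
        ax.set_yscale("log")
        ax.set_ylim(bottom=1.0)
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("TXA concentration (mg/L)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
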