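"""Figures for run reports: decoding accuracy time courses and group-mean
ERP waveforms.  Display-only; measurements never pass through here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_decoding_curves", "plot_erp_waveforms"]


def plot_decoding_curves(curves: pd.DataFrame, path: str) -> None:
    """Group mean +- SE decoding accuracy vs window start time.

    Expects the long-format decoding_curves table (subject_id,
    window_start_ms, accuracy, shuffled_accuracy) merged with a per-subject
    ``group`` column.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    for (grp, kind), style in _curve_styles(curves):
        sub = curves if grp is None else curves[curves["group"] == grp]
        col = "accuracy" if kind == "real" else "shuffled_accuracy"
        agg = sub.groupby("window_start_ms")[col].agg(["mean", "sem"])
        label = f"{grp or 'all'} ({kind})"
        ax.plot(agg.index, agg["mean"], label=label, **style)
        ax.fill_between(agg.index, agg["mean"] - agg["sem"],
                        agg["mean"] + agg["sem"], alpha=0.2,
                        color=style.get("color"))
    ax.axhline(0.5, color="gray", lw=0.8, ls=":")
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("window start (ms relative to response)")
    ax.set_ylabel("classification accuracy")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _curve_styles(curves: pd.DataFrame):
    groups = sorted(curves["group"].unique()) if "group" in curves else [None]
    colors = ["C0", "C1", "C2"]
    for g, c in zip(groups, colors):
        yield (g, "real"), {"color": c}
        yield (g, "shuffled"), {"color": c, "ls": "--", "lw": 0.8}


def plot_erp_waveforms(waves: dict, times: np.ndarray, path: str,
                       electrode: str = "", units: str = "uV/m2") -> None:
    """Overlay condition-average waveforms ({label: 1-D array})."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, w in waves.items():
        ax.plot(times, w, label=label)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.axhline(0.0, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel(f"{electrode} amplitude ({units})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
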