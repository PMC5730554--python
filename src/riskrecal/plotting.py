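"""Observed-versus-expected calibration plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .gndd import GNDDResult


def plot_calibration(
    results: dict[str, GNDDResult],
    title: str = "",
    path: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Plot per-group observed (KM) risk against mean predicted risk for
    one or more models, with the identity line of perfect calibration.

    ``results`` maps a model label (e.g. a scheme name) to its GND result.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    hi = 0.0
    for label, res in results.items():
        x = res.rows["mean_predicted"]
        y = res.rows["observed_risk"]
        ax.plot(x, y, marker="o", ms=4, lw=1.2, label=label)
        hi = max(hi, float(x.max()), float(y.max()))
    hi = min(1.0, hi * 1.08 + 0.01)
    ax.plot([0, hi], [0, hi], color="0.4", lw=1, ls="--", zorder=0)
    ax.set_xlim(0, hi)
    ax.set_ylim(0, hi)
    ax.set_xlabel("Expected (mean predicted) risk")
    ax.set_ylabel("Observed (Kaplan-Meier) risk")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
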