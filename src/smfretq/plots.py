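"""Optional figure output: condition histograms with SEM bands, quartile
ticks, and trimodal-fit overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from smfretq.histograms import ConditionHistogram
from smfretq.occupancy import TrimodalFit

__all__ = ["plot_condition"]


def plot_condition(
    cond: ConditionHistogram,
    fit: TrimodalFit | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """Histogram with SEM band and quartile ticks; fit components if given."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = cond.bin_centers
    ax.bar(x, cond.mean_fractions, width=x[1] - x[0], color="0.7", edgecolor="none")
    ax.fill_between(
        x,
        cond.mean_fractions - cond.sem_fractions,
        cond.mean_fractions + cond.sem_fractions,
        color="0.4",
        alpha=0.3,
        step="mid",
        label="mean ± SEM",
    )
    for q, style in zip(cond.quartiles, (":", "-", ":")):
        ax.axvline(q, color="k", linestyle=style, linewidth=1)
    if fit is not None:
        for n in range(3):
            ax.plot(x, fit.model.component(n, x), linewidth=1)
        ax.plot(x, fit.model(x), "r-", linewidth=1.5, label="trimodal fit")
    ax.set_xlabel("FRET efficiency")
    ax.set_ylabel("fraction of frames")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
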