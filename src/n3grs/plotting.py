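"""Static figure export: predicted-probability curves with observed-GRS violins."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .association import ProbabilityCurve

_CLASS_COLORS = {"R": "tab:green", "NR": "tab:orange", "AR": "tab:red"}


def plot_response_curves(
    curve: ProbabilityCurve,
    grs_by_class: Optional[Mapping[str, Sequence[float]]] = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Per-class probability curves with 95% bands; optional horizontal
    violins of the observed GRS per class (independent of the y axis).

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cat in curve.categories:
        color = _CLASS_COLORS.get(cat, None)
        ax.plot(curve.grs_grid, curve.probabilities[cat], label=cat, color=color)
        ax.fill_between(
            curve.grs_grid, curve.ci_low[cat], curve.ci_high[cat],
            alpha=0.2, color="tab:blue", linewidth=0,
        )
    if grs_by_class:
        positions = np.linspace(0.9, 0.6, num=len(grs_by_class))
        for pos, (cat, values) in zip(positions, grs_by_class.items()):
            if len(values) < 2:
                continue
            vp = ax.violinplot(
                [np.asarray(values, float)], positions=[pos], vert=False,
                widths=0.12, showmedians=True,
            )
            for body in vp["bodies"]:
                body.set_facecolor(_CLASS_COLORS.get(cat, "grey"))
                body.set_alpha(0.4)
    ax.set_xlabel("Genetic risk score")
    ax.set_ylabel("Predicted probability")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(title="class", loc="center right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
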