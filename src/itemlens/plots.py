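"""Optional plotting layer over the numeric diagnostics.

Every quantity drawn here is materialised as numbers first (see
:mod:`itemlens.regressions`); these helpers only render them: the
empirical item-total regression as dots, the Rasch curve as a thin black
line, the interaction-model curve as a thicker grey line, curtains as
shaded tails of the total-score distribution, and per-option distractor
curves titled with the item label.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

from .regressions import DistractorCurveSet, RegressionCurveSet

__all__ = ["plot_itr", "plot_distractors"]


def plot_itr(curves: RegressionCurveSet, item: str, ax=None):
    """Three-way item-total regression plot for one item."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    k = list(curves.items).index(item)
    ax.axvspan(curves.grid[0] - 0.5, curves.curtain_low, color="0.9", zorder=0)
    ax.axvspan(curves.curtain_high, curves.grid[-1] + 0.5, color="0.9", zorder=0)
    ax.plot(curves.grid, curves.rasch[:, k], color="black", lw=1.0, label="Rasch/PCM")
    ax.plot(curves.grid, curves.im[:, k], color="0.5", lw=2.5, label="interaction model")
    ax.plot(curves.grid, curves.empirical[:, k], "o", color="crimson", ms=4, label="observed")
    ax.set_xlabel("total score")
    ax.set_ylabel("item score")
    ax.set_title(item)
    ax.legend(loc="upper left", frameon=False, fontsize=8)
    return ax


def plot_distractors(dset: DistractorCurveSet, ax=None):
    """Per-option probability-given-total-score curves for one item."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for oc in dset.options:
        style = "-" if oc.score > 0 else "--"
        ax.plot(dset.grid, oc.probability, style, label=f"{oc.option} (score {oc.score})")
    ax.set_xlabel("total score")
    ax.set_ylabel("P(option | total score)")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(dset.item)
    ax.legend(loc="best", frameon=False, fontsize=8)
    return ax
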