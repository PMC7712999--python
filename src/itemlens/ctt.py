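"""Classical test theory statistics.

The first diagnostic pass over a scored matrix: per-item facility (mean
score divided by the item maximum, so it reads as proportion-correct for
binary items), item-total and item-rest Pearson correlations, Cronbach's
alpha, and the distribution of the total score.  All variances use the
sample (P-1) convention, applied consistently to numerator and denominator
of alpha; correlations are insensitive to the choice.

Undefined correlations (constant item columns) propagate as NaN with an
attached diagnostic rather than aborting the run — a fully degenerate item
is already rejected at scoring-rule load, but a column can still be
constant in a particular dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScoredMatrix

__all__ = [
    "CTTReport",
    "item_facility",
    "item_total_and_rest_correlations",
    "cronbach_alpha",
    "score_distribution",
    "ctt_report",
]


def item_facility(matrix: ScoredMatrix) -> np.ndarray:
    """Mean item score divided by the item maximum; in [0, 1]."""
    return matrix.scores.mean(axis=0) / matrix.max_score


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def item_total_and_rest_correlations(matrix: ScoredMatrix):
    """Per-item (rit, rir) with diagnostics for undefined entries.

    rit correlates the item score with the total score; rir with the rest
    score (total minus the item).  Returns ``(rit, rir, diagnostics)``.
    """
    totals = matrix.totals
    I = matrix.n_items
    rit = np.empty(I)
    rir = np.empty(I)
    diagnostics: list[str] = []
    for k in range(I):
        x = matrix.scores[:, k]
        rit[k] = _pearson(x, totals)
        rir[k] = _pearson(x, totals - x)
        if np.isnan(rit[k]) or np.isnan(rir[k]):
            diagnostics.append(
                f"item {matrix.items[k]!r}: correlation undefined (constant item, total, or rest score)"
            )
    return rit, rir, diagnostics


def cronbach_alpha(matrix: ScoredMatrix) -> float:
    """alpha = I/(I-1) * (1 - sum_i var(x_i) / var(x_+)), sample variances."""
    I = matrix.n_items
    if I < 2:
        raise ValueError("Cronbach's alpha needs at least two items")
    var_total = float(np.var(matrix.totals, ddof=1))
    if var_total == 0.0:
        raise ValueError("total score has zero variance; alpha is undefined")
    var_items = np.var(matrix.scores, axis=0, ddof=1)
    return float(I / (I - 1) * (1.0 - var_items.sum() / var_total))


def score_distribution(matrix: ScoredMatrix) -> np.ndarray:
    """Counts n_s of every total score s = 0..sum(m_i), including zero counts."""
    return np.bincount(matrix.totals, minlength=matrix.S + 1)


@dataclass
class CTTReport:
    """Item-level and test-level classical statistics for one dataset."""

    items: tuple[str, ...]
    facility: np.ndarray
    rit: np.ndarray
    rir: np.ndarray
    alpha: float
    n_persons: int
    score_counts: np.ndarray
    diagnostics: tuple[str, ...] = ()

    def item_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "facility": self.facility,
                "rit": self.rit,
                "rir": self.rir,
                "n": self.n_persons,
            }
        )

    def test_level(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_persons": self.n_persons,
            "score_distribution": self.score_counts.tolist(),
            "diagnostics": list(self.diagnostics),
        }

    def to_csv(self, path) -> None:
        self.item_frame().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.test_level(), indent=2, sort_keys=True))


def ctt_report(matrix: ScoredMatrix) -> CTTReport:
    """Assemble the full CTT report for a scored matrix."""
    rit, rir, diagnostics = item_total_and_rest_correlations(matrix)
    return CTTReport(
        items=tuple(matrix.items.tolist()),
        facility=item_facility(matrix),
        rit=rit,
        rir=rir,
        alpha=cronbach_alpha(matrix),
        n_persons=matrix.n_persons,
        score_counts=score_distribution(matrix),
        diagnostics=tuple(diagnostics),
    )
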