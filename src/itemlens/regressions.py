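"""Diagnostic regressions on the total score.

Three surfaces live here:

* the empirical item-total regression (ITR): the mean item score among
  persons at each observed total score;
* the three-way comparison of empirical, Rasch/PCM and interaction-model
  ITRs on a common grid, with "curtains" marking the lower and upper tails
  of the total-score distribution so the eye concentrates on the region
  where the data actually live;
* distractor regressions: for each response alternative of an item, the
  probability of choosing it given the total score, obtained by estimating
  the density of the total score overall and per alternative and applying
  Bayes' rule.

All diagnostics are materialised as numbers first; plotting is a thin
optional layer (:mod:`itemlens.plots`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import ScoredMatrix, load_responses, load_scoring_rules
from .ctt import score_distribution
from .interaction import IMParams, im_itr_table
from .rasch import RaschParams, rasch_itr_table

__all__ = [
    "RegressionCurveSet",
    "DistractorCurveSet",
    "OptionCurve",
    "empirical_itr",
    "compare_itr",
    "curtains",
    "distractor_regression",
    "silverman_bandwidth",
]


def empirical_itr(matrix: ScoredMatrix, item: str):
    """Observed regression of one item's score on the total score.

    Returns ``(grid, mean, n)`` over the full grid 0..S; the mean is NaN at
    totals no person achieved.
    """
    k = matrix.item_index(item)
    totals = matrix.totals
    S = matrix.S
    grid = np.arange(S + 1)
    n = np.bincount(totals, minlength=S + 1)
    sums = np.bincount(totals, weights=matrix.scores[:, k], minlength=S + 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return grid, mean, n


def curtains(score_counts, lower: float = 0.05, upper: float = 0.95):
    """Total-score percentile positions masking the distribution's tails.

    Left-continuous inverse-CDF convention: the curtain at probability p is
    the smallest score s with F(s) >= p.
    """
    counts = np.asarray(score_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("empty score distribution")
    if not (0.0 < lower <= upper < 1.0):
        raise ValueError("curtain probabilities must satisfy 0 < lower <= upper < 1")
    cdf = np.cumsum(counts) / counts.sum()
    low = int(np.searchsorted(cdf, lower, side="left"))
    high = int(np.searchsorted(cdf, upper, side="left"))
    return low, high


@dataclass
class RegressionCurveSet:
    """Aligned empirical/Rasch/IM item-total regressions with curtain positions."""

    items: tuple[str, ...]
    grid: np.ndarray
    n_s: np.ndarray
    empirical: np.ndarray  # (S+1, I), NaN where n_s == 0
    rasch: np.ndarray
    im: np.ndarray
    curtain_low: int
    curtain_high: int

    def item_frame(self, item: str) -> pd.DataFrame:
        k = list(self.items).index(item)
        return pd.DataFrame(
            {
                "score": self.grid,
                "n": self.n_s,
                "empirical": self.empirical[:, k],
                "rasch": self.rasch[:, k],
                "im": self.im[:, k],
            }
        )

    def long_frame(self) -> pd.DataFrame:
        frames = []
        for item in self.items:
            f = self.item_frame(item)
            f.insert(0, "item", item)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def compare_itr(
    matrix: ScoredMatrix,
    rasch: RaschParams,
    im: IMParams,
    lower: float = 0.05,
    upper: float = 0.95,
) -> RegressionCurveSet:
    """Three item-total regressions on the common grid 0..S, with curtains.

    Both fits must come from this matrix (same items and category structure).
    """
    items = tuple(matrix.items.tolist())
    if rasch.items != items or im.items != items:
        raise ValueError("parameter items do not match matrix items")
    if not (np.array_equal(rasch.max_scores, matrix.max_score) and np.array_equal(im.max_scores, matrix.max_score)):
        raise ValueError("parameter category structure does not match matrix")
    S = matrix.S
    grid = np.arange(S + 1)
    counts = score_distribution(matrix)
    emp = np.empty((S + 1, matrix.n_items))
    for k, item in enumerate(items):
        _, mean, _ = empirical_itr(matrix, item)
        emp[:, k] = mean
    low, high = curtains(counts, lower, upper)
    return RegressionCurveSet(
        items=items,
        grid=grid,
        n_s=counts,
        empirical=emp,
        rasch=rasch_itr_table(rasch),
        im=im_itr_table(im),
        curtain_low=low,
        curtain_high=high,
    )


def silverman_bandwidth(totals) -> float:
    """Silverman's rule-of-thumb bandwidth on the total-score sample.

    One shared bandwidth for all response alternatives of an item, computed
    from the overall score distribution, so rarely chosen options are not
    over-smoothed relative to common ones.  Falls back to 0.5 score points
    for degenerate samples.
    """
    t = np.asarray(totals, dtype=float)
    n = t.size
    if n < 2:
        return 0.5
    sd = float(np.std(t, ddof=1))
    iqr = float(np.subtract(*np.percentile(t, [75, 25])))
    spread = [v for v in (sd, iqr / 1.34) if v > 0]
    if not spread:
        return 0.5
    return 0.9 * min(spread) * n ** (-1 / 5)


@dataclass
class OptionCurve:
    """One response alternative's probability-given-total-score curve."""

    option: str
    score: int
    marginal: float
    probability: np.ndarray


@dataclass
class DistractorCurveSet:
    """Per-option curves P(option | total score) for one item.

    Options never chosen are omitted; at every grid point the curves of the
    retained options sum to one (Bayes-rule normalisation).
    """

    item: str
    grid: np.ndarray
    options: tuple[OptionCurve, ...]
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for oc in self.options:
            rows.append(
                pd.DataFrame(
                    {
                        "item": self.item,
                        "option": oc.option,
                        "score": self.grid,
                        "probability": oc.probability,
                        "option_score": oc.score,
                        "marginal": oc.marginal,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def distractor_regression(records, rules, matrix: ScoredMatrix, item: str) -> DistractorCurveSet:
    """Nonparametric regression of each response alternative on the total score.

    For each chosen option a, a Gaussian kernel density f_a of the totals of
    the persons who chose it is estimated (shared Silverman bandwidth from
    the overall score distribution), and Bayes' rule gives
    ``P(a | s) = pi_a f_a(s) / sum_b pi_b f_b(s)`` on the integer grid 0..S.
    """
    rules = load_scoring_rules(rules)
    if item not in rules.items:
        raise KeyError(f"item {item!r} not in the scoring rules")
    df = load_responses(records)
    df = df[df["item"] == item]
    if df.empty:
        raise ValueError(f"no response records for item {item!r}")
    totals = dict(zip(matrix.persons.tolist(), matrix.totals.tolist()))
    try:
        t_by_person = np.array([totals[p] for p in df["person"]], dtype=float)
    except KeyError as e:
        raise ValueError(f"person {e.args[0]!r} has responses but no row in the scored matrix") from None

    grid = np.arange(matrix.S + 1)
    h = silverman_bandwidth(matrix.totals)
    labels = df["response"].to_numpy()
    chosen = [lab for lab in rules.labels(item) if (labels == lab).any()]
    P = len(labels)

    densities = {}
    marginals = {}
    for lab in chosen:
        t = t_by_person[labels == lab]
        marginals[lab] = t.size / P
        densities[lab] = norm.pdf(grid[:, None], loc=t[None, :], scale=h).mean(axis=1)
    denom = np.zeros(grid.size)
    for lab in chosen:
        denom += marginals[lab] * densities[lab]
    options = tuple(
        OptionCurve(
            option=lab,
            score=rules.score_of(item, lab),
            marginal=marginals[lab],
            probability=marginals[lab] * densities[lab] / denom,
        )
        for lab in chosen
    )
    return DistractorCurveSet(item=item, grid=grid, options=options, bandwidth=h)
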