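"""Conditional maximum likelihood (CML) estimation of the Rasch and partial
credit models, and their model-implied item-total regressions.

The binary Rasch model gives ``P(x_pi = 1 | theta_p) = logistic(theta_p -
beta_i)``; the partial credit model (PCM) extends it to ordered category
scores with cumulative category parameters ``beta_ij``.  Because the total
score is sufficient for ability, ability drops out of the likelihood of a
response pattern given its total, leaving a function of the item parameters
only — the conditional likelihood — whose normalising constants are
elementary symmetric functions of ``exp(-beta)``.

Persons with zero or perfect totals contribute constants to the conditional
likelihood and are dropped; items with a category never observed among the
remaining persons have no finite estimate and raise an error naming the
item.  The default identification shifts the estimate along the invariant
direction of the likelihood so that the mean over all item-category
parameters is zero (recorded in ``constraint_tag``; results can be
re-anchored by adding a constant times the category score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._optim import maximize_conditional
from .core import ScoredMatrix
from .esf import ESFTable

__all__ = ["RaschParams", "fit_rasch_cml", "rasch_itr", "rasch_itr_table"]


@dataclass(frozen=True)
class RaschParams:
    """Difficulty parameters of a Rasch/PCM fit.

    ``beta[i]`` holds the cumulative category parameters ``beta_ij`` for
    categories ``j = 1..m_i`` of item ``i`` (a single value for a binary
    item).  Category weights in the ESF machinery are ``exp(-beta_ij)``.
    """

    items: tuple[str, ...]
    beta: tuple[np.ndarray, ...]
    constraint_tag: str = "mean_zero"
    se: tuple[np.ndarray, ...] | None = None
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = float("nan")

    @property
    def max_scores(self) -> np.ndarray:
        return np.array([b.size for b in self.beta], dtype=int)

    @property
    def S(self) -> int:
        return int(self.max_scores.sum())

    @property
    def beta_flat(self) -> np.ndarray:
        return np.concatenate(self.beta)

    def weights(self) -> list[np.ndarray]:
        """Per-item category weights (1, exp(-beta_i1), ..., exp(-beta_im))."""
        return [np.concatenate(([1.0], np.exp(-np.asarray(b, dtype=float)))) for b in self.beta]

    def to_json_dict(self) -> dict:
        return {
            "items": list(self.items),
            "beta": [np.asarray(b).tolist() for b in self.beta],
            "constraint_tag": self.constraint_tag,
            "se": None if self.se is None else [np.asarray(s).tolist() for s in self.se],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json_dict(cls, d: dict) -> "RaschParams":
        return cls(
            items=tuple(d["items"]),
            beta=tuple(np.asarray(b, dtype=float) for b in d["beta"]),
            constraint_tag=d.get("constraint_tag", "mean_zero"),
            se=None if d.get("se") is None else tuple(np.asarray(s, dtype=float) for s in d["se"]),
            loglik=d.get("loglik", float("nan")),
            converged=d.get("converged", True),
            n_iter=d.get("n_iter", 0),
            grad_norm=d.get("grad_norm", float("nan")),
        )

    @classmethod
    def from_json(cls, path) -> "RaschParams":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    @classmethod
    def binary(cls, items, beta, **kw) -> "RaschParams":
        """Convenience constructor for binary items from a flat beta vector."""
        beta = np.asarray(beta, dtype=float)
        return cls(items=tuple(items), beta=tuple(np.array([b]) for b in beta), **kw)


def _offsets(max_scores: np.ndarray) -> np.ndarray:
    return np.concatenate(([0], np.cumsum(max_scores)))


def _interior_stats(matrix: ScoredMatrix):
    """Sufficient statistics over persons with interior totals."""
    totals = matrix.totals
    S = matrix.S
    keep = (totals > 0) & (totals < S)
    if not keep.any():
        raise ValueError("no persons with an interior total score (0 < x_+ < max); CML is degenerate")
    sub = matrix.scores[keep]
    for k, item in enumerate(matrix.items):
        counts = np.bincount(sub[:, k], minlength=int(matrix.max_score[k]) + 1)
        missing = np.flatnonzero(counts == 0)
        if missing.size:
            raise ValueError(
                f"item {item!r}: score category {int(missing[0])} never observed among persons "
                "with interior totals; its conditional estimate is not finite"
            )
    interior_scores, n_s = np.unique(totals[keep], return_counts=True)
    return sub, interior_scores.astype(int), n_s.astype(int)


def fit_rasch_cml(matrix: ScoredMatrix, *, gtol: float = 1e-8, max_iter: int = 100) -> RaschParams:
    """Fit the Rasch (binary) or partial credit (polytomous) model by CML.

    Maximises the conditional log-likelihood
    ``sum_p [ -sum_i beta_{i,x_pi} - ln gamma_{x_p+} ]`` over persons with
    interior totals; convergence at gradient max-norm ``gtol``.  Standard
    errors come from the observed conditional information.
    """
    m = matrix.max_score
    offs = _offsets(m)
    D = int(offs[-1])
    sub, scores_obs, n_s = _interior_stats(matrix)

    # flat category-indicator counts t_ij, j = 1..m_i
    t_flat = np.zeros(D)
    for k in range(matrix.n_items):
        counts = np.bincount(sub[:, k], minlength=int(m[k]) + 1)
        t_flat[offs[k] : offs[k + 1]] = counts[1:]

    def _weights(theta: np.ndarray) -> list[np.ndarray]:
        return [
            np.concatenate(([1.0], np.exp(-theta[offs[k] : offs[k + 1]])))
            for k in range(matrix.n_items)
        ]

    def nll_grad(theta: np.ndarray):
        tab = ESFTable(_weights(theta))
        nll = float(theta @ t_flat)
        g = t_flat.copy()
        for s, ns in zip(scores_obs, n_s):
            nll += ns * tab.log_gamma[s]
            p = np.concatenate([pi[1:] for pi in tab.category_probs(int(s))])
            g = g - ns * p
        return nll, g

    def hess(theta: np.ndarray):
        tab = ESFTable(_weights(theta))
        H = np.zeros((D, D))
        for s, ns in zip(scores_obs, n_s):
            _, cov = tab.indicator_moments(int(s))
            H += ns * cov
        return H

    x, n_iter, gn, _ = maximize_conditional(nll_grad, hess, np.zeros(D), gtol=gtol, max_newton=max_iter)

    # shift along the invariant direction (c * category score) to mean-zero
    direction = np.concatenate([np.arange(1, int(mi) + 1, dtype=float) for mi in m])
    x = x + (-x.sum() / direction.sum()) * direction

    f, _ = nll_grad(x)
    cov = np.linalg.pinv(hess(x), rcond=1e-12, hermitian=True)
    se_flat = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    beta = tuple(x[offs[k] : offs[k + 1]].copy() for k in range(matrix.n_items))
    se = tuple(se_flat[offs[k] : offs[k + 1]].copy() for k in range(matrix.n_items))
    return RaschParams(
        items=tuple(matrix.items.tolist()),
        beta=beta,
        constraint_tag="mean_zero",
        se=se,
        loglik=-f,
        converged=True,
        n_iter=n_iter,
        grad_norm=gn,
    )


def rasch_itr(params: RaschParams, s: int) -> np.ndarray:
    """Model item-total regression: E[x_i | x_+ = s] under the Rasch/PCM fit.

    Endpoints are exact: 0 at s = 0 and m_i at the maximum total.
    """
    S = params.S
    s = int(s)
    if not 0 <= s <= S:
        raise ValueError(f"total score {s} outside 0..{S}")
    if s == 0:
        return np.zeros(len(params.items))
    if s == S:
        return params.max_scores.astype(float)
    return ESFTable(params.weights()).expected_scores(s)


def rasch_itr_table(params: RaschParams) -> np.ndarray:
    """ITR values for every total score: array of shape (S+1, I)."""
    S = params.S
    tab = ESFTable(params.weights())
    out = np.empty((S + 1, len(params.items)))
    out[0] = 0.0
    out[S] = params.max_scores.astype(float)
    for s in range(1, S):
        out[s] = tab.expected_scores(s)
    return out
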