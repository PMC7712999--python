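"""Haberman's interaction model (IM), estimated conditionally on the sum score.

The IM is an exponential-family model for classical test theory in which the
effective difficulty of an item is linear in the total score:

    b_i(s) = beta_i + sigma_i * s,

so that given a total score ``s`` the response pattern follows a Rasch-type
conditional distribution with score-specific difficulties.  sigma_i = 0 for
every item recovers the Rasch model, which is therefore nested.  The three
parameter sets have a direct classical reading: at the conditional maximum
the model reproduces exactly the observed item facilities (via beta), the
observed item-score-by-total-score inner products — hence the item-total
correlations (via sigma) — and the total-score distribution (via the score
parameters lambda).  That triple is essentially everything classical test
theory asks of the data, which is what makes the IM a diagnostic rather
than a measurement model: its item-total regression bends to follow the
data wherever the Rasch curve cannot.

Polytomous generalisation: per-category parameters beta_ij plus a single
sigma_i per item entering as sigma_i * x_i * x_+, i.e. the category weight
at score group ``s`` is ``exp(-(beta_ij + sigma_i * j * s))``.  This is the
literal reading of the interaction term of the exponential-family form; see
docs/methods.md for the alternative pairwise form and why they differ for
polytomous scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._optim import maximize_conditional
from .core import ScoredMatrix
from .ctt import score_distribution
from .esf import ESFTable
from .rasch import RaschParams, _interior_stats, _offsets

__all__ = ["IMParams", "fit_interaction", "im_itr", "im_itr_table", "im_loglik", "expected_moments"]


@dataclass(frozen=True)
class IMParams:
    """Parameters of a fitted interaction model.

    ``beta[i]`` holds per-category difficulties (j = 1..m_i), ``sigma[i]``
    the item's interaction parameter, and ``lambda_`` the score parameters,
    stored as the observed total-score proportions n_s / P over the full
    grid 0..S (the model reproduces the score distribution exactly, so the
    proportions are the canonical representative).
    """

    items: tuple[str, ...]
    beta: tuple[np.ndarray, ...]
    sigma: np.ndarray
    lambda_: np.ndarray
    constraint_tag: str = "mean_zero_beta_sigma"
    se_sigma: np.ndarray | None = None
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

    def weights_at(self, s: int) -> list[np.ndarray]:
        """Category weights exp(-(beta_ij + sigma_i * j * s)) at score group s."""
        out = []
        for b, sig in zip(self.beta, self.sigma):
            j = np.arange(1, b.size + 1, dtype=float)
            out.append(np.concatenate(([1.0], np.exp(-(b + sig * j * s)))))
        return out

    def to_json_dict(self) -> dict:
        return {
            "items": list(self.items),
            "beta": [np.asarray(b).tolist() for b in self.beta],
            "sigma": np.asarray(self.sigma).tolist(),
            "lambda": np.asarray(self.lambda_).tolist(),
            "constraint_tag": self.constraint_tag,
            "se_sigma": None if self.se_sigma is None else np.asarray(self.se_sigma).tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json_dict(cls, d: dict) -> "IMParams":
        return cls(
            items=tuple(d["items"]),
            beta=tuple(np.asarray(b, dtype=float) for b in d["beta"]),
            sigma=np.asarray(d["sigma"], dtype=float),
            lambda_=np.asarray(d["lambda"], dtype=float),
            constraint_tag=d.get("constraint_tag", "mean_zero_beta_sigma"),
            se_sigma=None if d.get("se_sigma") is None else np.asarray(d["se_sigma"], dtype=float),
            loglik=d.get("loglik", float("nan")),
            converged=d.get("converged", True),
            n_iter=d.get("n_iter", 0),
            grad_norm=d.get("grad_norm", float("nan")),
        )

    @classmethod
    def from_json(cls, path) -> "IMParams":
        return cls.from_json_dict(json.loads(Path(path).read_text()))

    @classmethod
    def binary(cls, items, beta, sigma, lambda_, **kw) -> "IMParams":
        beta = np.asarray(beta, dtype=float)
        return cls(
            items=tuple(items),
            beta=tuple(np.array([b]) for b in beta),
            sigma=np.asarray(sigma, dtype=float),
            lambda_=np.asarray(lambda_, dtype=float),
            **kw,
        )


def _group_stats(matrix: ScoredMatrix):
    """Per interior score group: counts of category indicators."""
    sub, scores_obs, n_s = _interior_stats(matrix)
    m = matrix.max_score
    offs = _offsets(m)
    D = int(offs[-1])
    totals = sub.sum(axis=1)
    T = np.zeros((scores_obs.size, D))
    for gi, s in enumerate(scores_obs):
        block = sub[totals == s]
        for k in range(matrix.n_items):
            counts = np.bincount(block[:, k], minlength=int(m[k]) + 1)
            T[gi, offs[k] : offs[k + 1]] = counts[1:]
    return T, scores_obs, n_s, offs, D


def fit_interaction(matrix: ScoredMatrix, *, gtol: float = 1e-8, max_iter: int = 100) -> IMParams:
    """Fit the interaction model by conditional maximum likelihood.

    Requires the same regularity as the Rasch CML fit plus at least two
    distinct interior total scores (otherwise sigma is unidentified).
    After convergence the fitted expectations reproduce the observed item
    facilities and item-by-total inner products; lambda is set to the
    observed score distribution.
    """
    T, scores_obs, n_s, offs, D = _group_stats(matrix)
    if scores_obs.size < 2:
        raise ValueError(
            "interaction parameters are unidentified: all interior persons share "
            f"the single total score {int(scores_obs[0])}"
        )
    I = matrix.n_items
    m = matrix.max_score
    jvec = np.concatenate([np.arange(1, int(mi) + 1, dtype=float) for mi in m])
    # item-aggregation matrix: row i picks the j-weighted categories of item i
    B = np.zeros((I, D))
    for k in range(I):
        B[k, offs[k] : offs[k + 1]] = jvec[offs[k] : offs[k + 1]]

    t_beta = T.sum(axis=0)                                # total category counts
    u_item = T @ B.T                                      # (groups, I): sum_j j * t_ijs
    v_sigma = (scores_obs[:, None] * u_item).sum(axis=0)  # sum_s s * sum_p x_pi 1{x_p+ = s}

    def _split(theta):
        return theta[:D], theta[D:]

    def _weights(beta_flat, sigma, s):
        b_s = beta_flat + np.repeat(sigma, m) * jvec * s
        return [
            np.concatenate(([1.0], np.exp(-b_s[offs[k] : offs[k + 1]])))
            for k in range(I)
        ], b_s

    def nll_grad(theta):
        beta_flat, sigma = _split(theta)
        nll = 0.0
        g_beta = t_beta.copy()
        g_sigma = v_sigma.copy()
        for gi, (s, ns) in enumerate(zip(scores_obs, n_s)):
            w, b_s = _weights(beta_flat, sigma, s)
            tab = ESFTable(w)
            nll += float(b_s @ T[gi]) + ns * tab.log_gamma[s]
            p = np.concatenate([pi[1:] for pi in tab.category_probs(int(s))])
            g_beta = g_beta - ns * p
            g_sigma = g_sigma - float(s) * ns * (B @ p)
        return nll, np.concatenate((g_beta, g_sigma))

    def hess(theta):
        beta_flat, sigma = _split(theta)
        H = np.zeros((D + I, D + I))
        for s, ns in zip(scores_obs, n_s):
            w, _ = _weights(beta_flat, sigma, s)
            tab = ESFTable(w)
            _, C = tab.indicator_moments(int(s))
            sB = float(s) * B
            CBt = C @ sB.T
            H[:D, :D] += ns * C
            H[:D, D:] += ns * CBt
            H[D:, :D] += ns * CBt.T
            H[D:, D:] += ns * (sB @ CBt)
        return H

    x0 = np.zeros(D + I)
    x, n_iter, gn, _ = maximize_conditional(nll_grad, hess, x0, gtol=gtol, max_newton=max_iter)

    beta_flat, sigma = _split(x)
    # shift along the two invariant directions: beta_ij += c1 * j, sigma_i += c2
    beta_flat = beta_flat + (-beta_flat.sum() / jvec.sum()) * jvec
    sigma = sigma - sigma.mean()
    x = np.concatenate((beta_flat, sigma))

    f, _ = nll_grad(x)
    cov = np.linalg.pinv(hess(x), rcond=1e-12, hermitian=True)
    se_sigma = np.sqrt(np.clip(np.diag(cov)[D:], 0.0, None))
    counts = score_distribution(matrix)
    beta = tuple(beta_flat[offs[k] : offs[k + 1]].copy() for k in range(I))
    return IMParams(
        items=tuple(matrix.items.tolist()),
        beta=beta,
        sigma=sigma,
        lambda_=counts / counts.sum(),
        constraint_tag="mean_zero_beta_sigma",
        se_sigma=se_sigma,
        loglik=-f,
        converged=True,
        n_iter=n_iter,
        grad_norm=gn,
    )


def im_itr(params: IMParams, s: int) -> np.ndarray:
    """IM item-total regression: E[x_i | x_+ = s] with difficulties beta + sigma*s.

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
    return ESFTable(params.weights_at(s)).expected_scores(s)


def im_itr_table(params: IMParams) -> np.ndarray:
    """IM ITR values for every total score: array of shape (S+1, I)."""
    S = params.S
    return np.vstack([im_itr(params, s) for s in range(S + 1)])


def im_loglik(params: IMParams, matrix: ScoredMatrix) -> float:
    """Conditional log-likelihood of the data given the totals, at ``params``.

    At sigma = 0 this equals the Rasch conditional log-likelihood with the
    same beta; on a given dataset the fitted IM value is never below the
    fitted Rasch value (nesting).
    """
    if tuple(matrix.items.tolist()) != params.items:
        raise ValueError("parameter items do not match matrix items")
    if not np.array_equal(matrix.max_score, params.max_scores):
        raise ValueError("parameter category structure does not match matrix")
    T, scores_obs, n_s, offs, D = _group_stats(matrix)
    m = matrix.max_score
    jvec = np.concatenate([np.arange(1, int(mi) + 1, dtype=float) for mi in m])
    beta_flat = np.concatenate(params.beta)
    total = 0.0
    for gi, (s, ns) in enumerate(zip(scores_obs, n_s)):
        b_s = beta_flat + np.repeat(params.sigma, m) * jvec * s
        w = [
            np.concatenate(([1.0], np.exp(-b_s[offs[k] : offs[k + 1]])))
            for k in range(matrix.n_items)
        ]
        tab = ESFTable(w)
        total += -float(b_s @ T[gi]) - ns * tab.log_gamma[s]
    return float(total)


def expected_moments(params: IMParams, matrix: ScoredMatrix) -> dict:
    """Model-expected CTT moments given the observed score distribution.

    Returns expected per-item facilities, expected item-by-total inner
    products sum_p x_pi * x_p+, and the expected score counts — the three
    observables the IM reproduces exactly at its conditional maximum.
    """
    counts = score_distribution(matrix)
    itr = im_itr_table(params)
    n_s = counts.astype(float)
    facility = (n_s[:, None] * itr).sum(axis=0) / (matrix.n_persons * params.max_scores)
    s_grid = np.arange(counts.size, dtype=float)
    cross = (n_s[:, None] * s_grid[:, None] * itr).sum(axis=0)
    return {
        "facility": facility,
        "cross_moment": cross,
        "score_counts": params.lambda_ * matrix.n_persons,
    }
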