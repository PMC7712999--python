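"""Elementary symmetric function (ESF) kernel.

Conditional-likelihood inference for Rasch-family models needs, for every
total score ``s``, the elementary symmetric function

    gamma_s = sum over response patterns x with sum(x) = s of
              prod_i w_i[x_i]

where ``w_i[j]`` is the weight a model attaches to category ``j`` of item
``i`` (``w_i[0] = 1`` under the conventional parameterisations, e.g.
``w_i[1] = exp(-beta_i)`` for a binary Rasch item).  ``gamma_s`` is the
normalising constant of the distribution of a response pattern given its
total score; ratios of item-deleted tables to the full table yield the
conditional category probabilities that drive estimation, the model
item-total regressions and conditional simulation.

The table is computed by sequential polynomial multiplication (the stable
"sum" algorithm), never by pattern enumeration.  Coefficients are kept in
linear space with an explicit log scale factor so that long tests do not
overflow.  Item-deleted tables use the division-free forward-backward
scheme (prefix and suffix products) rather than numerically fragile
polynomial division.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["ESFTable", "elementary_symmetric"]


def _conv(a: np.ndarray, loga: float, b: np.ndarray, logb: float):
    """Multiply two scaled polynomials; renormalise so coefficients stay O(1)."""
    c = np.convolve(a, b)
    m = float(c.max())
    return c / m, loga + logb + float(np.log(m))


class ESFTable:
    """Elementary symmetric functions of per-item category weights.

    Parameters
    ----------
    weights
        One 1-D array per item with ``m_i + 1`` strictly positive entries:
        the weight of each score category ``0..m_i``.
    """

    def __init__(self, weights: Sequence[np.ndarray]):
        ws = []
        for k, w in enumerate(weights):
            w = np.atleast_1d(np.asarray(w, dtype=float))
            if w.ndim != 1 or w.size < 2:
                raise ValueError(f"item {k}: need weights for at least categories 0 and 1")
            if not np.all(np.isfinite(w)) or np.any(w <= 0.0):
                raise ValueError(f"item {k}: category weights must be positive and finite")
            ws.append(w)
        if not ws:
            raise ValueError("at least one item is required")
        self.weights = ws
        self.n_items = len(ws)
        self.max_scores = np.array([w.size - 1 for w in ws], dtype=int)
        self.S = int(self.max_scores.sum())

        # prefix[k] = product over items [0, k); suffix[k] = product over [k, I)
        pre = [(np.ones(1), 0.0)]
        for w in ws:
            pre.append(_conv(*pre[-1], w, 0.0))
        acc = [(np.ones(1), 0.0)]
        for w in reversed(ws):
            acc.append(_conv(w, 0.0, *acc[-1]))
        self._pre = pre
        self._suf = [acc[self.n_items - k] for k in range(self.n_items + 1)]
        g, lg = pre[-1]
        self.log_gamma = np.log(g) + lg
        self._del_cache: dict[int, np.ndarray] = {}
        self._pair_cache: dict[tuple[int, int], np.ndarray] = {}

    # ------------------------------------------------------------------ tables
    @property
    def gamma(self) -> np.ndarray:
        """The ESF values gamma_0..gamma_S in natural scale."""
        return np.exp(self.log_gamma)

    def log_gamma_deleted(self, i: int) -> np.ndarray:
        """log gamma^(-i): table over the remaining items (length S - m_i + 1)."""
        if i not in self._del_cache:
            g, lg = _conv(*self._pre[i], *self._suf[i + 1])
            self._del_cache[i] = np.log(g) + lg
        return self._del_cache[i]

    def log_gamma_deleted_pair(self, i: int, k: int) -> np.ndarray:
        """log gamma^(-i,-k): table with both items removed (i != k)."""
        if i == k:
            raise ValueError("pair-deleted table needs two distinct items")
        i, k = sorted((i, k))
        key = (i, k)
        if key not in self._pair_cache:
            g, lg = self._pre[i]
            for t in range(i + 1, k):
                g, lg = _conv(g, lg, self.weights[t], 0.0)
            g, lg = _conv(g, lg, *self._suf[k + 1])
            self._pair_cache[key] = np.log(g) + lg
        return self._pair_cache[key]

    def log_gamma_suffix(self, k: int) -> np.ndarray:
        """log ESF table of items k..I-1 (used for sequential conditional sampling)."""
        g, lg = self._suf[k]
        return np.log(g) + lg

    # --------------------------------------------------------- conditionals
    def _check_s(self, s: int) -> int:
        s = int(s)
        if not 0 <= s <= self.S:
            raise ValueError(f"total score {s} outside the achievable range 0..{self.S}")
        return s

    def category_probs(self, s: int) -> list[np.ndarray]:
        """P(x_i = j | x_+ = s) for every item i and category j = 0..m_i."""
        s = self._check_s(s)
        lgs = self.log_gamma[s]
        out = []
        for i, w in enumerate(self.weights):
            lgd = self.log_gamma_deleted(i)
            p = np.zeros(w.size)
            for j in range(w.size):
                r = s - j
                if 0 <= r < lgd.size:
                    p[j] = w[j] * np.exp(lgd[r] - lgs)
            out.append(p)
        return out

    def expected_scores(self, s: int) -> np.ndarray:
        """E[x_i | x_+ = s] for every item."""
        return np.array(
            [float(np.dot(np.arange(w.size), p)) for w, p in zip(self.weights, self.category_probs(s))]
        )

    def indicator_moments(self, s: int):
        """Mean and covariance of the category indicators 1{x_i = j}, j >= 1, given x_+ = s.

        The covariance matrix is the per-person contribution to the observed
        conditional information of exponential-family models whose sufficient
        statistics are linear in these indicators.
        """
        s = self._check_s(s)
        probs = self.category_probs(s)
        offs = np.concatenate(([0], np.cumsum(self.max_scores)))
        D = int(offs[-1])
        mu = np.concatenate([p[1:] for p in probs])
        M = np.zeros((D, D))
        lgs = self.log_gamma[s]
        for i in range(self.n_items):
            oi, mi = offs[i], int(self.max_scores[i])
            M[oi : oi + mi, oi : oi + mi] = np.diag(probs[i][1:])
            for k in range(i + 1, self.n_items):
                ok, mk = offs[k], int(self.max_scores[k])
                lgp = self.log_gamma_deleted_pair(i, k)
                blk = np.zeros((mi, mk))
                for a in range(1, mi + 1):
                    for b in range(1, mk + 1):
                        r = s - a - b
                        if 0 <= r < lgp.size:
                            blk[a - 1, b - 1] = (
                                self.weights[i][a] * self.weights[k][b] * np.exp(lgp[r] - lgs)
                            )
                M[oi : oi + mi, ok : ok + mk] = blk
                M[ok : ok + mk, oi : oi + mi] = blk.T
        return mu, M - np.outer(mu, mu)


def elementary_symmetric(eps) -> ESFTable:
    """Build an :class:`ESFTable` from per-item parameters.

    ``eps`` is either a sequence of positive scalars (binary items; ``eps_i``
    is the weight of a correct response, category 0 having weight 1) or a
    sequence of full per-category weight arrays ``(w_i0, ..., w_im)``.

    >>> elementary_symmetric([1.0, 1.0]).gamma
    array([1., 2., 1.])
    """
    ws = []
    for e in eps:
        a = np.atleast_1d(np.asarray(e, dtype=float))
        ws.append(np.concatenate(([1.0], a)) if a.size == 1 else a)
    return ESFTable(ws)
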