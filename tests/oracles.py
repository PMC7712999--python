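"""Independent brute-force oracles used only by the test suite.

Everything here deliberately avoids the package's ESF/optimisation code
paths: elementary symmetric functions by exhaustive pattern enumeration,
conditional likelihoods expanded pattern by pattern, a generic optimiser
over the enumeration-based likelihood, and textbook sum formulas for the
classical statistics.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize


def esf_enumerate(weights) -> np.ndarray:
    """gamma_s by exhaustive enumeration of all response patterns."""
    weights = [np.asarray(w, dtype=float) for w in weights]
    S = sum(w.size - 1 for w in weights)
    g = np.zeros(S + 1)
    for pat in itertools.product(*[range(w.size) for w in weights]):
        g[sum(pat)] += math.prod(w[j] for w, j in zip(weights, pat))
    return g


def expected_given_total_enumerate(weights, s: int) -> np.ndarray:
    """E[x_i | x_+ = s] by exhaustive enumeration."""
    weights = [np.asarray(w, dtype=float) for w in weights]
    num = np.zeros(len(weights))
    den = 0.0
    for pat in itertools.product(*[range(w.size) for w in weights]):
        if sum(pat) != s:
            continue
        wgt = math.prod(w[j] for w, j in zip(weights, pat))
        den += wgt
        num += wgt * np.array(pat, dtype=float)
    return num / den


def rasch_conditional_nll_enumerate(beta, scores) -> float:
    """Binary Rasch conditional NLL over interior persons, by enumeration."""
    beta = np.asarray(beta, dtype=float)
    weights = [np.array([1.0, e]) for e in np.exp(-beta)]
    g = esf_enumerate(weights)
    tot = scores.sum(axis=1)
    keep = (tot > 0) & (tot < beta.size)
    ll = 0.0
    for row in scores[keep]:
        ll += -float(beta @ row) - math.log(g[row.sum()])
    return -ll


def fit_rasch_enumerate(scores) -> np.ndarray:
    """Independent CML maximiser: enumeration likelihood + generic optimisers
    over I-1 free parameters (the last beta closes the sum to zero)."""
    I = scores.shape[1]

    def nll(free):
        beta = np.concatenate([free, [-free.sum()]])
        return rasch_conditional_nll_enumerate(beta, scores)

    res = minimize(nll, np.zeros(I - 1), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000})
    res = minimize(nll, res.x, method="BFGS", options={"gtol": 1e-11, "maxiter": 2000})
    beta = np.concatenate([res.x, [-res.x.sum()]])
    return beta - beta.mean()


def im_conditional_nll_enumerate(beta, sigma, scores) -> float:
    """Binary interaction-model conditional NLL, expanded person by person."""
    beta = np.asarray(beta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    I = beta.size
    tot = scores.sum(axis=1)
    keep = (tot > 0) & (tot < I)
    ll = 0.0
    for row in scores[keep]:
        s = int(row.sum())
        b = beta + sigma * s
        g = esf_enumerate([np.array([1.0, e]) for e in np.exp(-b)])
        ll += -float(b @ row) - math.log(g[s])
    return -ll


def pearson_textbook(x, y) -> float:
    """Pearson correlation via the raw-sums textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x * x).sum() - x.sum() ** 2 / n
    syy = (y * y).sum() - y.sum() ** 2 / n
    return sxy / math.sqrt(sxx * syy)


def alpha_textbook(scores) -> float:
    """Cronbach's alpha by explicit sample-variance sums."""
    n, I = scores.shape

    def var(v):
        v = np.asarray(v, dtype=float)
        return float(((v - v.mean()) ** 2).sum() / (n - 1))

    tot = scores.sum(axis=1)
    return I / (I - 1) * (1.0 - sum(var(scores[:, k]) for k in range(I)) / var(tot))


def quantile_inverted_cdf(values, p: float):
    """Smallest observed value x with F(x) >= p."""
    v = np.sort(np.asarray(values))
    k = math.ceil(p * v.size) - 1
    return v[max(k, 0)]
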