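"""Shared optimisation helper: quasi-Newton warm start + exact Newton polish.

The conditional negative log-likelihoods of the Rasch/PCM and interaction
models are convex (log-sum-exp of linear functions) with analytic gradient
(observed minus expected sufficient statistics) and Hessian (the observed
conditional information, a sum of per-score covariance matrices).  The
likelihoods are flat along the identification directions, so the Hessian
is solved with a pseudo-inverse; the gradient lies in the identified
subspace and Newton steps stay there.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["maximize_conditional"]


def maximize_conditional(nll_grad, hess, x0, *, gtol=1e-8, max_newton=100):
    """Minimise a convex NLL; return (x, n_iter, grad_norm, trace).

    Convergence is declared at gradient max-norm <= ``gtol``; failure to
    converge raises RuntimeError carrying the gradient-norm trace.
    """
    res = minimize(
        nll_grad,
        np.asarray(x0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-6},
    )
    x = res.x
    f, g = nll_grad(x)
    trace = []
    for it in range(max_newton):
        gn = float(np.max(np.abs(g)))
        trace.append(gn)
        if gn <= gtol:
            return x, it, gn, trace
        H = hess(x)
        step = -np.linalg.pinv(H, rcond=1e-12, hermitian=True) @ g
        t = 1.0
        while True:
            fx, gx = nll_grad(x + t * step)
            if fx <= f + 1e-10 * (1.0 + abs(f)):
                break
            t /= 2.0
            if t < 1e-12:
                raise RuntimeError(
                    "conditional ML line search failed; gradient max-norm trace: "
                    + ", ".join(f"{v:.3e}" for v in trace)
                )
        x = x + t * step
        f, g = fx, gx
    gn = float(np.max(np.abs(g)))
    if gn <= gtol:
        return x, max_newton, gn, trace
    raise RuntimeError(
        f"conditional ML did not converge (final gradient max-norm {gn:.3e} > {gtol:g}); "
        "trace: " + ", ".join(f"{v:.3e}" for v in trace[-10:])
    )
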