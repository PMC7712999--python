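"""Fit the Rasch model by conditional maximum likelihood and recover truth.

Simulates binary responses from known difficulties (spaced -2..2 across 12
items, abilities standard normal, 3000 persons), fits by CML — conditioning
on each person's total score so no ability distribution is assumed — and
compares estimates with the generating values.
"""

import numpy as np

from itemlens import AbilitySpec, fit_rasch_cml, simulate_rasch

beta = np.linspace(-2.0, 2.0, 12)
matrix = simulate_rasch(beta, AbilitySpec(n_persons=3000), seed=42)
fit = fit_rasch_cml(matrix)

print("item   true beta   estimate   SE")
for item, b_true, b_hat, se in zip(matrix.items, beta - beta.mean(), fit.beta_flat,
                                   np.concatenate(fit.se)):
    print(f"{item}   {b_true:+9.3f}  {b_hat:+9.3f}  {se:.3f}")
rmse = np.sqrt(np.mean((fit.beta_flat - (beta - beta.mean())) ** 2))
print(f"\nRMSE(beta): {rmse:.3f}   (converged in {fit.n_iter} Newton steps, "
      f"gradient max-norm {fit.grad_norm:.1e})")
print("Estimates carry the mean-zero identification; differences, not levels, matter.")
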