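"""The interaction model: an exponential-family model for classical test theory.

Effective item difficulty is linear in the total score, b_i(s) = beta_i +
sigma_i * s; sigma_i = 0 for every item gives back the Rasch model.  At its
conditional maximum the model reproduces the observed item facilities, the
item-score-by-total-score inner products (hence the item-total
correlations) and the total-score distribution EXACTLY — everything
classical test theory asks of the data.  This example verifies the moment
reproduction numerically and shows how the planted exercise item's sigma
stands apart from its well-behaved peers.
"""

import numpy as np

from itemlens import (
    AbilitySpec,
    expected_moments,
    fit_interaction,
    item_facility,
    score_responses,
    simulate_choices,
    spm01_exercise_scenario,
)

records, rules, _ = simulate_choices(spm01_exercise_scenario(), AbilitySpec(n_persons=3000), seed=11)
matrix = score_responses(records, rules)
im = fit_interaction(matrix)

mom = expected_moments(im, matrix)
print("moment reproduction (fitted expectation vs observed):")
print(f"  max |facility error|        : {np.max(np.abs(mom['facility'] - item_facility(matrix))):.2e}")
cross = (matrix.scores * matrix.totals[:, None]).sum(axis=0)
print(f"  max rel cross-moment error  : {np.max(np.abs(mom['cross_moment'] - cross) / cross):.2e}")

print("\nitem     sigma      z = sigma/SE")
for item, s, se in zip(im.items, im.sigma, im.se_sigma):
    print(f"{item}  {s:+8.3f}   {s / se:+8.1f}")
print(
    "\nitem01's sigma is the clear maximum: its effective difficulty falls with\n"
    "the total score far more slowly than its peers' — the signature of an\n"
    "item that discriminates much less than the Rasch model expects."
)
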