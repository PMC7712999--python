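"""Distractor regressions: P(response alternative | total score) by Bayes' rule.

For each alternative of an item, the density of the total score among the
persons who chose it is estimated with a Gaussian kernel (one shared
Silverman bandwidth); Bayes' rule then gives each alternative's probability
given the total score.  On the planted exercise item one distractor rules
the low totals — low-ability persons effectively toss a coin between it and
the key — while the key's curve rises with the total score.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from itemlens import (
    AbilitySpec,
    distractor_regression,
    score_responses,
    simulate_choices,
    spm01_exercise_scenario,
)
from itemlens.plots import plot_distractors

records, rules, _ = simulate_choices(spm01_exercise_scenario(), AbilitySpec(n_persons=3000), seed=11)
matrix = score_responses(records, rules)

d = distractor_regression(records, rules, matrix, "item01")
print(f"item01, kernel bandwidth {d.bandwidth:.2f} score points")
print("option  score  marginal   P(option | total=2)   P(option | total=10)")
for oc in sorted(d.options, key=lambda o: -o.marginal):
    print(f"  {oc.option}      {oc.score}     {oc.marginal:6.3f}        "
          f"{oc.probability[2]:6.3f}                {oc.probability[10]:6.3f}")
print("\nOptions never chosen are omitted entirely.  The score-0 option with the\n"
      "large marginal is the dominant distractor: popular at low totals, gone at high.")

out = Path("scratch")
out.mkdir(exist_ok=True)
ax = plot_distractors(d)
ax.figure.savefig(out / "distractors_item01.png", dpi=120)
plt.close(ax.figure)
print(f"plot written to {out}/distractors_item01.png")
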