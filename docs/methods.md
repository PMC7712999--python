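# Methods

## Data model and contracts

Every analysis starts from a complete enumeration of scoring rules: each
admissible response of each item maps to a non-negative integer score with
0 the lowest score of every item, and every item has at least two distinct
score values.  Raw records are long-format (person, item, response)
triples.  Responses outside the enumeration and missing person×item cells
are **errors**, never silent zeros: the package targets complete-data
analysis, and zero-scoring omissions would corrupt facilities,
correlations and alpha alike.  Person and item order is lexicographic
everywhere, so identical inputs give byte-identical outputs.  Labels are
compared as exact strings after whitespace trimming, without case folding,
because answer keys are label-exact.

## Classical statistics

Facility is the mean item score divided by the item maximum (proportion
correct for binary items).  `rit`/`rir` are Pearson correlations of the
item score with the total and with the rest score (total minus item).
Cronbach's alpha uses sample (P−1) variances in both the numerator and the
denominator; only the consistency of the convention matters, and
correlations are insensitive to it.  Undefined correlations (constant
columns) propagate as NaN with a diagnostic instead of aborting: a fully
degenerate item is already rejected at rule load, but a column can still
be constant in a particular sample.

## Conditional estimation

### Elementary symmetric functions

The conditional likelihoods of all fitted models normalise through
elementary symmetric functions γ_s of the per-item category weights
(w_ij = exp(−β_ij) for the Rasch/PCM case).  γ is computed by sequential
polynomial multiplication — the stable "sum" algorithm — in linear space
with an explicit log scale factor, so tests far longer than 12 items do
not overflow.  Item-deleted tables γ^(−i) come from the division-free
forward–backward (prefix/suffix product) scheme; pair-deleted tables,
needed for conditional covariances, multiply the remaining items directly
and are cached.  Conditional category probabilities are
P(x_i = j | x_+ = s) = w_ij · γ^(−i)_{s−j} / γ_s.

### Rasch / partial credit model

Persons with zero or perfect totals contribute constants to the
conditional likelihood and are dropped; any item with a score category
never observed among the remaining persons has no finite conditional
estimate and raises an error naming the item.  The negative conditional
log-likelihood is convex with analytic gradient (observed minus expected
category counts) and Hessian equal to the observed conditional information
Σ_s n_s Cov_s(indicators).  Optimisation is an L-BFGS warm start followed
by damped exact Newton steps; convergence is declared at gradient max-norm
1e−8 (in count units), which Newton reaches at machine precision in a few
steps.  The likelihood is flat along the direction β_ij += c·j (the
ability-location shift); the fitted parameters are shifted along it so the
mean over all item-category parameters is zero (`constraint_tag:
mean_zero`).  Standard errors come from the pseudo-inverse of the observed
conditional information.

### Interaction model

The interaction model makes effective difficulty linear in the total
score: at score group s the category weight is exp(−(β_ij + σ_i·j·s)), a
Rasch model whose difficulty depends on item and score.  Given at least
two distinct interior total scores (otherwise σ is unidentified and the
fit refuses), the conditional likelihood factorises over score groups and
is maximised the same way (L-BFGS + Newton on analytic gradient/Hessian).
Two flat directions exist — β_ij += c₁·j and σ_i += c₂, both absorbed by
the score-group normalisation — and both are centred to mean zero after
convergence.  λ_s is stored as the observed total-score proportion n_s/P:
the model reproduces the score distribution exactly, so the proportions
are the canonical representative, and no downstream consumer needs
smoothed values for unobserved interior scores (the simulator draws totals
from λ itself).

**Moment reproduction.**  The stationarity conditions of the conditional
likelihood are precisely that fitted expected category counts equal
observed counts per item, and fitted expected Σ_p x_pi·x_p+ equals its
observed value.  Together with λ this reproduces the facilities, the
item-total covariances (hence `rit`), and the score distribution — the
tests verify all three to 1e−6 and they hold to ~1e−12 in practice.

**Sign of σ.**  With difficulty parameterised as above, an item that
discriminates *more* than the Rasch expectation needs its effective
difficulty to fall as the total rises (σ < 0), and a *low*-discrimination
item sits above the mean-zero-centred pack (σ > 0).  So in the planted
exercise-item scenario the affected item's σ̂ is the clear **maximum**,
many standard errors from zero — marked separation in the
low-discrimination direction is the diagnostic, not the sign in isolation.

**Polytomous generalisation.**  One σ_i per item enters as σ_i·x_i·x_+
alongside per-category β_ij.  An alternative pairwise form
Σ_{j>i}(σ_i+σ_j)x_i x_j differs from this one by self-interaction terms
σ_i·x_i² that are non-constant for polytomous scores (for binary items
the two coincide up to reparameterisation); this implementation commits to
the x_i·x_+ form, which keeps the sufficient statistics the item-total
inner products.

## Item-total regressions and curtains

Model ITRs are E[x_i | x_+ = s] from the ESF machinery (for the IM,
re-evaluated at each score's own difficulties); endpoints are exact by
construction and returned exactly (0 at s = 0, m_i at s = S), and the
per-item values sum to s at every s.  The empirical ITR is the mean item
score at each observed total with its group size attached.  Curtains are
the 5th and 95th percentiles of the total-score distribution under the
left-continuous inverse-CDF convention (smallest s with F(s) ≥ p);
diagnostics concentrate between them, where the data live.

Flagging (defaults chosen as conventions, not findings): `LOW_RIR` at
rir < 0.35 — on a profile like the published 12-item form this floor
flags exactly the anomalous opening item; `IM_RASCH_GAP` when the maximum
inter-curtain gap between the two model curves exceeds 0.15;
`NONMONOTONE_EMPIRICAL` when the n_s-weighted least-squares slope of the
empirical ITR between the curtains is negative (the wrong-answer-key
signature).

## Distractor regressions

For each response alternative a of an item, a Gaussian kernel density
f_a(s) of the totals of the persons who chose a is estimated, and Bayes'
rule gives P(a|s) = π_a f_a(s) / Σ_b π_b f_b(s) on the integer grid 0..S.
The bandwidth is Silverman's rule on the **overall** score distribution,
shared across alternatives so rarely chosen options are not over-smoothed
relative to common ones (fallback 0.5 score points for degenerate
samples); the estimator sits behind a single function so alternatives are
pluggable.  Alternatives never chosen are omitted from output rather than
drawn at zero.  Curves sum to one at every grid point by construction.

## The simulator

The simulator defines the study conditions under which everything is
tested:

* **Rasch/PCM matrices**: category probabilities ∝ exp(jθ − β_ij),
  abilities Normal(0, 1) unless given explicitly.  Reference recovery
  setting: 12 binary items, β spaced −2..2, P = 3000.
* **IM matrices**: a total is drawn from λ, then a pattern from
  P(x | x_+ = s) by exact sequential item-wise sampling with suffix-ESF
  ratios — no MCMC, and the drawn pattern's total equals s by
  construction.
* **Multiple-choice records**: multinomial-logit choices with option
  utilities linear in ability (intercept + slope·θ), 8 options per item.
  Clean items use key slope 1.7 and flat distractors at utility −2, which
  on a 12-item form yields rir ≈ 0.45–0.52 and alpha ≈ 0.8 — the
  discrimination profile of a serviceable cognitive test.  Presets:
  - `spm01_exercise`: key (1.8, +0.45) against one dominant distractor
    (1.8 at θ≈−1, slope −0.45): low-ability persons face a near coin toss,
    rir drops to ≈ 0.35, and σ̂ separates by ≈ +0.19;
  - `wrong_key`: the scoring rule keys a distractor with slope −0.6 while
    the real best option has slope 1.7 → negative interior empirical
    slope;
  - `midpeak_distractor`: key (−1.0, 2.2), one distractor (0.4, 0.6) whose
    popularity peaks at middling totals, one (0.6, −1.2) owning the low
    end;
  - `spm_ls`: 12 items, 8 options, 499 persons by default; facilities for
    items 2–12 follow a declining profile from 0.91 to 0.32 via the
    logistic-normal approximation, item 1 is the exercise item.

All draws flow through one seeded NumPy generator; identical seeds give
identical outputs.

What the simulator does **not** emulate: multidimensionality, response
times, person misfit (copying, fatigue), missingness, multi-form linking.
Passing tests therefore demonstrate correctness of the estimators and the
diagnostic logic under clean unidimensional conditions, not robustness of
the diagnostics to every real-world pathology.

## Verification design and tolerances

* ESF vs exhaustive enumeration over all 2^12 patterns: relative 1e−12.
* CML fit vs an independent maximiser (enumeration-based likelihood,
  Nelder–Mead + BFGS) at I = 3, P = 200: absolute 1e−6.
* Recovery: RMSE(β̂) < 0.1 at the reference setting.
* IM moment reproduction: 1e−6 (holds to ~1e−12).
* σ checks use ±3 conditional-information standard errors elementwise.
* Stochastic curve checks are calibrated to their own sampling noise
  rather than blanket constants: empirical-vs-model ITR cells use exact
  per-cell 99% binomial bands with the *count* of violating cells bounded
  by the 99.5% binomial envelope of the nominal 1% rate (a simultaneous
  check across ~120 cells); distractor flatness uses a 4-standard-error
  envelope per score cell (cells with n_s ≥ 100 inside the curtains); the
  empirical-to-IM consistency smoke test at P = 20 000 uses an n-weighted
  RMS ≤ 0.02.
* Problem sizes throughout (P = 200..20 000, I = 3..12) were chosen so the
  whole suite exercises every code path in well under a minute of
  simulation time while keeping Monte-Carlo noise far from the asserted
  margins.

## Known limitations

* Complete data only; no multi-booklet/incomplete designs (the conditional
  machinery extends, but the data contracts deliberately do not).
* The IM's 2PL connection (the 2PL as a low-rank approximation) is noted
  here but not implemented; no 2PL/3PL fitting.
* Conditional SEs ignore the identification constraint's covariance
  adjustment beyond the pseudo-inverse projection; adequate for the ±3 SE
  diagnostics they serve.
* The distractor estimator is a fixed-bandwidth Gaussian KDE on a bounded
  integer grid; boundary bias near totals 0 and S is visible outside the
  curtains, which is one more reason diagnostics are read between them.
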