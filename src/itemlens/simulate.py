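"""Synthetic response data: Rasch/PCM/IM matrices and raw multiple-choice records.

Every estimator and diagnostic in the package is testable without external
data.  Scored matrices are drawn from the Rasch model, the partial credit
model, or a fitted interaction model (totals from the score distribution,
then exact sequential conditional sampling via ESF ratios — no MCMC).  Raw
multiple-choice records come from multinomial-logit choice scenarios whose
option utilities are linear in ability; four named presets reproduce the
classic diagnostic phenomenologies:

* ``clean`` — well-behaved items: the key's choice probability rises with
  ability, distractors share the remainder evenly;
* ``spm01_exercise`` — one item where low-ability persons effectively toss
  a coin between the key and a single dominant distractor (the signature of
  an opening item answered before the examinee has warmed up);
* ``wrong_key`` — the scoring rule keys a distractor, producing a negative
  interior slope in the empirical item-total regression;
* ``midpeak_distractor`` — a distractor whose popularity peaks at middling
  ability, like the middle category of a partial credit item;
* ``spm_ls`` — a 12-item, 8-option form shaped like the last series of
  Raven's Standard Progressive Matrices: facilities declining with position
  except for an underperforming first item.

All randomness flows through one seeded NumPy generator; identical seeds
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core import ScoredMatrix, ScoringRule, ScoringRules
from .esf import ESFTable
from .interaction import IMParams
from .rasch import RaschParams

__all__ = [
    "AbilitySpec",
    "OptionBehaviour",
    "ItemScenario",
    "ChoiceScenario",
    "simulate_rasch",
    "simulate_im",
    "simulate_choices",
    "clean_scenario",
    "spm01_exercise_scenario",
    "wrong_key_scenario",
    "midpeak_scenario",
    "spm_ls_scenario",
    "scenario_by_name",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class AbilitySpec:
    """Latent-ability sample: Normal(mean, sd) draws or an explicit list."""

    n_persons: int = 499
    mean: float = 0.0
    sd: float = 1.0
    thetas: np.ndarray | None = None

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.thetas is not None:
            t = np.asarray(self.thetas, dtype=float)
            if t.size < 1:
                raise ValueError("explicit theta list is empty")
            return t
        if self.n_persons < 1:
            raise ValueError("need at least one person")
        if self.sd <= 0:
            raise ValueError("ability sd must be positive")
        return rng.normal(self.mean, self.sd, size=self.n_persons)


def _item_ids(n: int) -> np.ndarray:
    return np.array([f"item{k + 1:02d}" for k in range(n)])


def _person_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"p{k + 1:0{width}d}" for k in range(n)])


def _as_beta_list(params) -> tuple[list[np.ndarray], list[str] | None]:
    if isinstance(params, RaschParams):
        return [np.asarray(b, dtype=float) for b in params.beta], list(params.items)
    arr = [np.atleast_1d(np.asarray(b, dtype=float)) for b in params]
    return arr, None


def simulate_rasch(beta, abilities: AbilitySpec, seed=0) -> ScoredMatrix:
    """Draw a scored matrix from the Rasch / partial credit model.

    ``beta`` is a flat difficulty vector (binary items), a list of
    per-category parameter arrays (PCM), or a fitted :class:`RaschParams`.
    Category probabilities are ``P(x = j | theta) ∝ exp(j*theta - beta_j)``.
    """
    rng = _rng(seed)
    betas, items = _as_beta_list(beta)
    thetas = abilities.draw(rng)
    P, I = thetas.size, len(betas)
    items = np.array(items) if items is not None else _item_ids(I)
    scores = np.empty((P, I), dtype=int)
    for k, b in enumerate(betas):
        j = np.arange(b.size + 1, dtype=float)
        b_full = np.concatenate(([0.0], b))
        logits = j[None, :] * thetas[:, None] - b_full[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(P)
        scores[:, k] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return ScoredMatrix(
        persons=_person_ids(P),
        items=items,
        scores=scores,
        max_score=np.array([b.size for b in betas]),
    )


def simulate_im(params: IMParams, n_persons: int, seed=0) -> ScoredMatrix:
    """Draw a scored matrix from a fitted interaction model.

    A total score is drawn from the lambda-implied score distribution, then
    a response pattern from P(x | x_+ = s) by exact sequential item-wise
    sampling with ESF ratios at the score-specific difficulties.
    """
    rng = _rng(seed)
    lam = np.asarray(params.lambda_, dtype=float)
    lam = lam / lam.sum()
    S = params.S
    if lam.size != S + 1:
        raise ValueError("lambda must cover the full score grid 0..S")
    m = params.max_scores
    I = len(params.items)
    totals = rng.choice(S + 1, size=n_persons, p=lam)
    scores = np.empty((n_persons, I), dtype=int)
    for s in np.unique(totals):
        s = int(s)
        rows = np.flatnonzero(totals == s)
        if s == 0:
            scores[rows] = 0
            continue
        if s == S:
            scores[rows] = m
            continue
        tab = ESFTable(params.weights_at(s))
        r = np.full(rows.size, s)  # remaining total over items k..I-1
        for k in range(I):
            w = tab.weights[k]
            lg_rest = tab.log_gamma_suffix(k + 1)
            lg_here = tab.log_gamma_suffix(k)
            probs = np.zeros((rows.size, w.size))
            for j in range(w.size):
                rem = r - j
                ok = (rem >= 0) & (rem < lg_rest.size)
                probs[ok, j] = w[j] * np.exp(lg_rest[rem[ok]] - lg_here[r[ok]])
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(rows.size)
            j_drawn = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            scores[rows, k] = j_drawn
            r = r - j_drawn
    return ScoredMatrix(
        persons=_person_ids(n_persons),
        items=np.array(list(params.items)),
        scores=scores,
        max_score=m,
    )


# --------------------------------------------------------------------- choices
@dataclass(frozen=True)
class OptionBehaviour:
    """Logistic-linear utility of one response alternative: intercept + slope * theta."""

    intercept: float
    slope: float


@dataclass(frozen=True)
class ItemScenario:
    """One multiple-choice item: option utilities and the keyed (score-1) option."""

    item_id: str
    key: str
    options: Mapping[str, OptionBehaviour]

    def __post_init__(self):
        if self.key not in self.options:
            raise ValueError(f"item {self.item_id!r}: key {self.key!r} not among its options")
        if len(self.options) < 2:
            raise ValueError(f"item {self.item_id!r}: need at least two options")


@dataclass(frozen=True)
class ChoiceScenario:
    """A full multiple-choice form: one :class:`ItemScenario` per item."""

    name: str
    items: tuple[ItemScenario, ...]

    def rules(self) -> ScoringRules:
        return ScoringRules(
            ScoringRule(it.item_id, opt, int(opt == it.key))
            for it in self.items
            for opt in it.options
        )


def simulate_choices(scenario: ChoiceScenario, abilities: AbilitySpec, seed=0):
    """Draw raw option choices for every person x item.

    Options are drawn from the multinomial with probabilities proportional
    to ``exp(intercept + slope * theta)``.  Returns ``(records, rules,
    manifest)``: the long-format records DataFrame, the key-based binary
    scoring rules, and a manifest dict with the generating truth.
    """
    rng = _rng(seed)
    thetas = abilities.draw(rng)
    P = thetas.size
    persons = _person_ids(P)
    rows_person, rows_item, rows_resp = [], [], []
    for it in scenario.items:
        labels = list(it.options)
        U = np.array([[b.intercept, b.slope] for b in it.options.values()])
        logits = U[:, 0][None, :] + thetas[:, None] * U[:, 1][None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(P)
        idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        rows_person.append(persons)
        rows_item.append(np.full(P, it.item_id))
        rows_resp.append(np.array(labels, dtype=object)[idx])
    records = pd.DataFrame(
        {
            "person": np.concatenate(rows_person),
            "item": np.concatenate(rows_item),
            "response": np.concatenate(rows_resp).astype(str),
        }
    )
    manifest = {
        "scenario": scenario.name,
        "n_persons": int(P),
        "items": [
            {
                "item": it.item_id,
                "key": it.key,
                "options": {o: [b.intercept, b.slope] for o, b in it.options.items()},
            }
            for it in scenario.items
        ],
    }
    return records, scenario.rules(), manifest


# ---------------------------------------------------------------- presets
_N_OPTIONS = 8


def _clean_item(item_id: str, difficulty_intercept: float, n_options: int = _N_OPTIONS,
                key: str | None = None, key_slope: float = 1.7) -> ItemScenario:
    """Well-behaved item: key utility rises with theta, flat distractors.

    With K - 1 flat distractors at intercept -2 the key probability is a
    logistic in ``key_slope * theta + difficulty_intercept``, i.e. a Rasch
    item when every item shares the same slope.  The default slope 1.7 on a
    unit-normal ability gives the item-rest correlations (~0.45) and alpha
    (~0.8) of a serviceable 12-item cognitive test.
    """
    labels = [str(j + 1) for j in range(n_options)]
    key = key if key is not None else labels[0]
    options = {
        lab: (OptionBehaviour(difficulty_intercept, key_slope) if lab == key else OptionBehaviour(-2.0, 0.0))
        for lab in labels
    }
    return ItemScenario(item_id, key, options)


def _spread_intercepts(n: int, low: float = -2.0, high: float = 2.0) -> np.ndarray:
    """Difficulty intercepts from easy to hard along the test."""
    return np.linspace(high, low, n)


def clean_scenario(n_items: int = 12, n_options: int = _N_OPTIONS) -> ChoiceScenario:
    """All items well-behaved, difficulties spread from easy to hard."""
    a = _spread_intercepts(n_items)
    items = tuple(
        _clean_item(iid, a[k], n_options, key=str(k % n_options + 1))
        for k, iid in enumerate(_item_ids(n_items))
    )
    return ChoiceScenario("clean", items)


def _exercise_item(item_id: str, n_options: int = _N_OPTIONS) -> ItemScenario:
    """Opening item answered as a warm-up: low-ability persons effectively
    toss a coin between the key and one dominant distractor."""
    labels = [str(j + 1) for j in range(n_options)]
    key, dom = labels[0], labels[1]
    options = {}
    for lab in labels:
        if lab == key:
            options[lab] = OptionBehaviour(1.8, 0.5)
        elif lab == dom:
            options[lab] = OptionBehaviour(0.9, -0.5)
        else:
            options[lab] = OptionBehaviour(-2.5, 0.0)
    return ItemScenario(item_id, key, options)


def spm01_exercise_scenario(n_items: int = 12, n_options: int = _N_OPTIONS) -> ChoiceScenario:
    """Clean form except the first item, which shows the exercise-item pathology."""
    a = _spread_intercepts(n_items)
    ids = _item_ids(n_items)
    items = [_exercise_item(ids[0], n_options)]
    items += [
        _clean_item(ids[k], a[k], n_options, key=str(k % n_options + 1))
        for k in range(1, n_items)
    ]
    return ChoiceScenario("spm01_exercise", tuple(items))


def _wrong_key_item(item_id: str, n_options: int = _N_OPTIONS) -> ItemScenario:
    """The scoring rule keys a distractor that is popular at low ability."""
    labels = [str(j + 1) for j in range(n_options)]
    good, keyed = labels[0], labels[1]
    options = {}
    for lab in labels:
        if lab == good:
            options[lab] = OptionBehaviour(0.5, 1.7)
        elif lab == keyed:
            options[lab] = OptionBehaviour(0.5, -0.6)
        else:
            options[lab] = OptionBehaviour(-2.0, 0.0)
    return ItemScenario(item_id, keyed, options)


def wrong_key_scenario(n_items: int = 12, n_options: int = _N_OPTIONS, bad_position: int = 5) -> ChoiceScenario:
    """Clean form with one mis-keyed item (0-based ``bad_position``)."""
    a = _spread_intercepts(n_items)
    ids = _item_ids(n_items)
    items = []
    for k in range(n_items):
        if k == bad_position:
            items.append(_wrong_key_item(ids[k], n_options))
        else:
            items.append(_clean_item(ids[k], a[k], n_options, key=str(k % n_options + 1)))
    return ChoiceScenario("wrong_key", tuple(items))


def _midpeak_item(item_id: str, n_options: int = _N_OPTIONS) -> ItemScenario:
    """Hard item with a distractor peaking at middling ability."""
    labels = [str(j + 1) for j in range(n_options)]
    key, mid, low = labels[0], labels[1], labels[2]
    options = {}
    for lab in labels:
        if lab == key:
            options[lab] = OptionBehaviour(-1.0, 2.2)
        elif lab == mid:
            options[lab] = OptionBehaviour(0.4, 0.6)
        elif lab == low:
            options[lab] = OptionBehaviour(0.6, -1.2)
        else:
            options[lab] = OptionBehaviour(-2.0, 0.0)
    return ItemScenario(item_id, key, options)


def midpeak_scenario(n_items: int = 12, n_options: int = _N_OPTIONS, bad_position: int = 8) -> ChoiceScenario:
    """Clean form with one mid-peaking-distractor item (0-based position)."""
    a = _spread_intercepts(n_items)
    ids = _item_ids(n_items)
    items = []
    for k in range(n_items):
        if k == bad_position:
            items.append(_midpeak_item(ids[k], n_options))
        else:
            items.append(_clean_item(ids[k], a[k], n_options, key=str(k % n_options + 1)))
    return ChoiceScenario("midpeak_distractor", tuple(items))


# facility profile of the 12-item SPM-LS-shaped preset: very easy early items
# declining to hard late items
_SPM_FACILITIES = np.array([0.91, 0.87, 0.83, 0.79, 0.74, 0.68, 0.60, 0.52, 0.43, 0.36, 0.32])


def spm_ls_scenario(n_options: int = _N_OPTIONS) -> ChoiceScenario:
    """A 12-item, 8-option form shaped like the SPM-LS: facilities declining
    with position, except the first item which behaves as an exercise item."""
    ids = _item_ids(12)
    items = [_exercise_item(ids[0], n_options)]
    # logistic intercept that reproduces the marginal facility under
    # theta ~ N(0, 1): divide the logit by sqrt(1 + slope^2 / 1.702^2)
    slope = 1.7
    scale = np.sqrt(1.0 + (slope / 1.702) ** 2)
    for k, f in enumerate(_SPM_FACILITIES, start=1):
        a = scale * np.log(f / (1 - f)) + np.log(n_options - 1) - 2.0
        items.append(_clean_item(ids[k], a, n_options, key=str(k % n_options + 1)))
    return ChoiceScenario("spm_ls", tuple(items))


_SCENARIOS = {
    "clean": clean_scenario,
    "spm01_exercise": spm01_exercise_scenario,
    "wrong_key": wrong_key_scenario,
    "midpeak_distractor": midpeak_scenario,
    "spm_ls": spm_ls_scenario,
}


def scenario_by_name(name: str, **kwargs) -> ChoiceScenario:
    """Look up a named preset scenario."""
    key = name.replace("-", "_")
    if key not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}")
    return _SCENARIOS[key](**kwargs)
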