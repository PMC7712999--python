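"""Scoring rules, response records and the scored response matrix.

Every analysis starts from a complete enumeration of the scoring rules:
each admissible response of each item is mapped to a non-negative integer
score, with 0 as the lowest score of every item.  Raw responses arrive in
long format (person, item, response) and are turned into a complete
persons x items integer score matrix.  Responses outside the enumeration
and missing person x item cells are data defects and raise errors; they
are never silently scored 0, which would corrupt every downstream
statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "ScoringRule",
    "ScoringRules",
    "ScoredMatrix",
    "load_scoring_rules",
    "load_responses",
    "score_responses",
    "identity_rules",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class ScoringRule:
    """One admissible (item, response) pair and its integer score."""

    item_id: str
    response_label: str
    score: int


class ScoringRules:
    """Validated collection of scoring rules.

    Invariants enforced on construction: (item, response) pairs are unique,
    the minimum score of every item is exactly 0, every item has at least
    two distinct score values, and scores are non-negative integers.
    Response labels are compared as exact strings after whitespace trimming
    (no case folding: answer keys are label-exact).
    """

    def __init__(self, rules: Iterable[ScoringRule]):
        score_map: dict[tuple[str, str], int] = {}
        for r in rules:
            item = str(r.item_id).strip()
            label = str(r.response_label).strip()
            score = int(r.score)
            if score != float(r.score):
                raise ValueError(f"item {item!r}, response {label!r}: score must be an integer")
            if score < 0:
                raise ValueError(f"item {item!r}, response {label!r}: negative score {score}")
            key = (item, label)
            if key in score_map:
                raise ValueError(f"duplicate scoring rule for item {item!r}, response {label!r}")
            score_map[key] = score
        if not score_map:
            raise ValueError("no scoring rules supplied")
        by_item: dict[str, dict[str, int]] = {}
        for (item, label), score in score_map.items():
            by_item.setdefault(item, {})[label] = score
        for item, labels in by_item.items():
            scores = set(labels.values())
            if min(scores) != 0:
                raise ValueError(
                    f"item {item!r}: minimum score is {min(scores)}, not 0 "
                    "(every item's lowest score must be 0)"
                )
            if len(scores) < 2:
                raise ValueError(f"degenerate item {item!r}: all responses score the same")
        self._by_item = {item: dict(labels) for item, labels in sorted(by_item.items())}

    # ------------------------------------------------------------------ access
    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self._by_item)

    def labels(self, item: str) -> tuple[str, ...]:
        return tuple(self._by_item[item])

    def max_score(self, item: str) -> int:
        return max(self._by_item[item].values())

    def score_of(self, item: str, label: str) -> int:
        try:
            return self._by_item[item][label]
        except KeyError:
            raise KeyError(
                f"item {item!r}, response {label!r} is not in the scoring-rule enumeration"
            ) from None

    def has(self, item: str, label: str) -> bool:
        return item in self._by_item and label in self._by_item[item]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_item.values())

    def __iter__(self):
        for item, labels in self._by_item.items():
            for label, score in labels.items():
                yield ScoringRule(item, label, score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.item_id, r.response_label, r.score) for r in self],
            columns=["item", "response", "score"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoringRules":
        missing = {"item", "response", "score"} - set(df.columns)
        if missing:
            raise ValueError(f"rules table lacks columns: {sorted(missing)}")
        return cls(
            ScoringRule(str(row.item), str(row.response), int(row.score))
            for row in df.itertuples(index=False)
        )


def load_scoring_rules(source: Union[PathLike, pd.DataFrame, Iterable[ScoringRule]]) -> ScoringRules:
    """Read scoring rules from a delimited text file (columns item, response, score),
    a DataFrame, or an iterable of :class:`ScoringRule`."""
    if isinstance(source, ScoringRules):
        return source
    if isinstance(source, pd.DataFrame):
        return ScoringRules.from_frame(source)
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
        df["score"] = df["score"].astype(int)
        return ScoringRules.from_frame(df)
    return ScoringRules(source)


def load_responses(source: Union[PathLike, pd.DataFrame]) -> pd.DataFrame:
    """Read long-format response records (columns person, item, response)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    missing = {"person", "item", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"response table lacks columns: {sorted(missing)}")
    for col in ("person", "item", "response"):
        df[col] = df[col].astype(str).str.strip()
    return df[["person", "item", "response"]]


@dataclass
class ScoredMatrix:
    """Complete persons x items integer score matrix with per-item maxima.

    ``totals`` (the person sum scores) are always row sums by construction;
    all cells satisfy ``0 <= x_pi <= m_i`` and there are no missing cells.
    """

    persons: np.ndarray
    items: np.ndarray
    scores: np.ndarray
    max_score: np.ndarray

    def __post_init__(self):
        self.persons = np.asarray(self.persons, dtype=str)
        self.items = np.asarray(self.items, dtype=str)
        self.scores = np.asarray(self.scores)
        self.max_score = np.asarray(self.max_score, dtype=int)
        if not np.issubdtype(self.scores.dtype, np.integer):
            as_int = self.scores.astype(int)
            if not np.array_equal(as_int, self.scores):
                raise ValueError("scores must be integers")
            self.scores = as_int
        if self.scores.shape != (self.persons.size, self.items.size):
            raise ValueError("score matrix shape does not match persons x items")
        if self.max_score.shape != (self.items.size,):
            raise ValueError("max_score must have one entry per item")
        if np.any(self.max_score < 1):
            raise ValueError("every item needs a maximum score of at least 1")
        if np.any(self.scores < 0) or np.any(self.scores > self.max_score[None, :]):
            raise ValueError("scores outside the admissible 0..m_i range")
        if len(set(self.persons.tolist())) != self.persons.size:
            raise ValueError("duplicate person identifiers")
        if len(set(self.items.tolist())) != self.items.size:
            raise ValueError("duplicate item identifiers")

    # ------------------------------------------------------------------ views
    @property
    def n_persons(self) -> int:
        return int(self.persons.size)

    @property
    def n_items(self) -> int:
        return int(self.items.size)

    @property
    def S(self) -> int:
        """Maximum achievable total score."""
        return int(self.max_score.sum())

    @property
    def totals(self) -> np.ndarray:
        return self.scores.sum(axis=1)

    def item_index(self, item: str) -> int:
        idx = np.flatnonzero(self.items == item)
        if idx.size == 0:
            raise KeyError(f"item {item!r} not in matrix")
        return int(idx[0])

    def column(self, item: str) -> np.ndarray:
        return self.scores[:, self.item_index(item)]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format with the integer score serving as the response label."""
        P, I = self.scores.shape
        return pd.DataFrame(
            {
                "person": np.repeat(self.persons, I),
                "item": np.tile(self.items, P),
                "response": self.scores.ravel().astype(str),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.persons, name="person"), columns=self.items)

    def to_csv(self, path: PathLike, sidecar: bool = True) -> None:
        path = Path(path)
        self.to_frame().to_csv(path)
        if sidecar:
            meta = {
                "items": self.items.tolist(),
                "max_score": self.max_score.tolist(),
                "n_persons": self.n_persons,
                "max_total": self.S,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: PathLike) -> "ScoredMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            max_score = np.asarray(meta["max_score"], dtype=int)
        else:
            max_score = df.to_numpy().max(axis=0).astype(int)
            max_score = np.maximum(max_score, 1)
        return cls(
            persons=df.index.astype(str).to_numpy(),
            items=df.columns.astype(str).to_numpy(),
            scores=df.to_numpy(),
            max_score=max_score,
        )


def identity_rules(matrix: ScoredMatrix) -> ScoringRules:
    """Scoring rules mapping the string form of each admissible score to itself."""
    return ScoringRules(
        ScoringRule(item, str(j), j)
        for item, m in zip(matrix.items, matrix.max_score)
        for j in range(int(m) + 1)
    )


def score_responses(records, rules) -> ScoredMatrix:
    """Score long-format response records against a scoring-rule enumeration.

    Raises on duplicate (person, item) records, on response labels outside
    the enumeration (naming the item and label), and on missing person x item
    cells (listing offenders) — inadmissible or absent responses are data
    defects, not scores of 0.  Person and item order in the result is
    lexicographic, so outputs are reproducible.
    """
    df = load_responses(records)
    rules = load_scoring_rules(rules)

    dup = df.duplicated(subset=["person", "item"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["person", "item"]].drop_duplicates().head(5)
        listing = ", ".join(f"({p}, {i})" for p, i in pairs.itertuples(index=False))
        raise ValueError(f"duplicate (person, item) records: {listing}")

    unknown = [
        (item, label)
        for item, label in df[["item", "response"]].drop_duplicates().itertuples(index=False)
        if not rules.has(item, label)
    ]
    if unknown:
        listing = "; ".join(f"item {i!r}, response {r!r}" for i, r in unknown[:5])
        raise ValueError(f"responses outside the scoring-rule enumeration: {listing}")

    persons = np.array(sorted(df["person"].unique()))
    items = np.array(sorted(df["item"].unique()))
    pivot = df.pivot(index="person", columns="item", values="response")
    pivot = pivot.reindex(index=persons, columns=items)
    if pivot.isna().any().any():
        offenders = [
            f"person {p!r} missing item {i!r}"
            for p in pivot.index
            for i in pivot.columns[pivot.loc[p].isna()]
        ]
        head = "; ".join(offenders[:10])
        more = f" (+{len(offenders) - 10} more)" if len(offenders) > 10 else ""
        raise ValueError(f"incomplete response matrix: {head}{more}")

    scores = np.empty(pivot.shape, dtype=int)
    for k, item in enumerate(items):
        col = pivot[item].to_numpy()
        scores[:, k] = [rules.score_of(item, label) for label in col]
    max_score = np.array([rules.max_score(item) for item in items], dtype=int)
    return ScoredMatrix(persons=persons, items=items, scores=scores, max_score=max_score)
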