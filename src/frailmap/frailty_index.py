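"""Deficit-accumulation frailty index: scoring and ordered categorisation.

A frailty index is the fraction of a fixed list of health "deficits" an
individual exhibits.  Each deficit item maps an observed level to a value in
[0, 1] (binary items map 0/1 directly; graded items such as
none/some/severe map to intermediate values).  The score for a respondent
is the sum of item values divided by the total number of items in the
schema — the denominator is always the full schema size; missing values
must be resolved by imputation *before* scoring.

Scores are categorised with closed upper bounds: robust (score <= 0.24),
pre-frail (0.24 < score <= 0.36), frail (score > 0.36).  The cut-points are
configurable but these defaults follow the established literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .strata import CATEGORIES

__all__ = [
    "DeficitItem",
    "DeficitSchema",
    "CutPoints",
    "score_respondent",
    "categorize",
    "score_table",
]


@dataclass(frozen=True)
class DeficitItem:
    """One deficit item: a name, its kind, and its level -> value mapping."""

    name: str
    kind: str = "binary"  # "binary" or "graded"
    mapping: Mapping[float, float] = field(
        default_factory=lambda: {0: 0.0, 1: 1.0}
    )

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "graded"):
            raise ValueError(f"item {self.name!r}: kind must be binary|graded")
        vals = list(self.mapping.values())
        if not vals:
            raise ValueError(f"item {self.name!r}: empty mapping")
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError(
                f"item {self.name!r}: mapped values must lie in [0, 1]"
            )

    def map_value(self, level: float) -> float:
        """Map an observed level to its deficit value in [0, 1]."""
        try:
            return float(self.mapping[level])
        except KeyError:
            raise ValueError(
                f"item {self.name!r}: level {level!r} not in mapping"
            ) from None


@dataclass(frozen=True)
class DeficitSchema:
    """Ordered list of deficit items defining the index denominator."""

    items: tuple[DeficitItem, ...]

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("schema needs at least one item")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValueError("item names must be unique")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def names(self) -> list[str]:
        return [it.name for it in self.items]

    @classmethod
    def default(cls, n_items: int = 30) -> "DeficitSchema":
        """Default schema: ``n_items`` binary items deficit_001..deficit_NNN."""
        return cls(
            items=tuple(
                DeficitItem(name=f"deficit_{i + 1:03d}") for i in range(n_items)
            )
        )

    @classmethod
    def from_yaml(cls, path) -> "DeficitSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        items = tuple(
            DeficitItem(
                name=str(entry["name"]),
                kind=entry.get("kind", "binary"),
                mapping={float(k): float(v) for k, v in entry["mapping"].items()},
            )
            for entry in raw["items"]
        )
        return cls(items=items)

    def to_yaml(self, path) -> None:
        payload = {
            "items": [
                {
                    "name": it.name,
                    "kind": it.kind,
                    "mapping": {float(k): float(v) for k, v in it.mapping.items()},
                }
                for it in self.items
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class CutPoints:
    """Category cut-points; comparisons use closed upper bounds exactly."""

    robust_max: float = 0.24
    prefrail_max: float = 0.36

    def __post_init__(self) -> None:
        if not (0.0 < self.robust_max < self.prefrail_max < 1.0):
            raise ValueError(
                "cut-points must satisfy 0 < robust_max < prefrail_max < 1; "
                f"got robust_max={self.robust_max}, prefrail_max={self.prefrail_max}"
            )


def score_respondent(
    deficit_values: Sequence[float], schema: DeficitSchema
) -> float:
    """Score one respondent: (sum of item values) / (number of schema items).

    ``deficit_values`` must already be on the [0, 1] value scale (i.e. after
    applying each item's mapping) and contain no missing entries — scoring
    runs on imputation-completed data.
    """
    values = np.asarray(deficit_values, dtype=float)
    if values.shape != (len(schema),):
        raise ValueError(
            f"expected {len(schema)} deficit values, got {values.shape}"
        )
    if np.isnan(values).any():
        raise ValueError(
            "missing deficit value present; impute before scoring"
        )
    if ((values < 0) | (values > 1)).any():
        raise ValueError("deficit values must lie in [0, 1]")
    return float(values.sum() / len(schema))


def categorize(score: float, cuts: CutPoints = CutPoints()) -> str:
    """Assign the ordered category for a frailty score.

    robust iff score <= robust_max; pre_frail iff robust_max < score <=
    prefrail_max; frail otherwise.  Boundaries are inclusive on the upper
    side with no tolerance.
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score must lie in [0, 1], got {score}")
    if score <= cuts.robust_max:
        return "robust"
    if score <= cuts.prefrail_max:
        return "pre_frail"
    return "frail"


def score_table(
    survey: pd.DataFrame,
    schema: DeficitSchema,
    cuts: CutPoints = CutPoints(),
) -> pd.DataFrame:
    """Score every respondent of a complete survey table.

    Returns a copy of ``survey`` with two added columns, ``frailty_score``
    and ``frailty_category`` (ordered categorical robust < pre_frail <
    frail).  Raises naming the offending row if any deficit cell is missing.
    """
    missing_cols = [c for c in schema.names if c not in survey.columns]
    if missing_cols:
        raise ValueError(f"survey lacks deficit columns: {missing_cols}")
    values = survey[schema.names].to_numpy(dtype=float)
    bad = np.isnan(values).any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"missing deficit value in row {row} "
            f"(id={survey.iloc[row].get('id', row)!r}); impute before scoring"
        )
    # map observed levels item by item (binary identity mapping is the
    # common case and is left untouched for speed)
    mapped = values.copy()
    for j, item in enumerate(schema.items):
        if item.kind == "binary" and dict(item.mapping) == {0: 0.0, 1: 1.0}:
            continue
        col = np.empty_like(mapped[:, j])
        for i, level in enumerate(values[:, j]):
            col[i] = item.map_value(level)
        mapped[:, j] = col
    scores = mapped.sum(axis=1) / len(schema)
    out = survey.copy()
    out["frailty_score"] = scores
    cat = np.where(
        scores <= cuts.robust_max,
        "robust",
        np.where(scores <= cuts.prefrail_max, "pre_frail", "frail"),
    )
    out["frailty_category"] = pd.Categorical(
        cat, categories=list(CATEGORIES), ordered=True
    )
    return out
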