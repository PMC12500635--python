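"""Better/worse coefficients, sensitivity, arc screening, and priority ranking.

The satisfaction-increase coefficient (Better / SI) and the dissatisfaction
coefficient (Worse / DSI) summarise an item's tally over the four
substantive categories:

    Better = (A + O) / (A + O + M + I)
    Worse  = -(O + M) / (A + O + M + I)

Reverse and questionable counts are excluded from both numerator and
denominator.  The sensitivity R = sqrt(Better^2 + Worse^2) — the Euclidean
norm of the point (SI, |DSI|) — ranks improvement urgency; quarter-circle
arcs at the element radius (0.707) and key-element radius (1.061) partition
the SI-|DSI| plane into deferred / element / key-improvement zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import ItemTally, KanoCategory

__all__ = [
    "ScreeningConfig",
    "ItemResult",
    "better_coefficient",
    "worse_coefficient",
    "sensitivity",
    "screen",
    "prioritize",
    "attribute_census",
    "KanoPrioritizer",
]

#: Arc radii as conventionally printed; 0.707 ~ sqrt(2)/2 and 1.061 ~ 3*sqrt(2)/4.
DEFAULT_ELEMENT_RADIUS = 0.707
DEFAULT_KEY_RADIUS = 1.061

ZONE_KEY = "key"
ZONE_ELEMENT = "element"
ZONE_DEFERRED = "deferred"


@dataclass(frozen=True)
class ScreeningConfig:
    """Radii of the element and key-element selection arcs."""

    element_radius: float = DEFAULT_ELEMENT_RADIUS
    key_radius: float = DEFAULT_KEY_RADIUS

    def __post_init__(self) -> None:
        if not 0 < self.element_radius < self.key_radius:
            raise ValueError(
                f"need 0 < element_radius < key_radius, got "
                f"({self.element_radius}, {self.key_radius})"
            )


@dataclass
class ItemResult:
    """Scored, screened and (optionally) ranked result for one item."""

    item_id: str
    attribute: KanoCategory | None = None
    better: float = float("nan")
    worse: float = float("nan")
    sensitivity: float = float("nan")
    rank: int | None = None
    zone: str | None = None
    distance_to_key_line: float = float("nan")
    tie_flag: bool = False
    label: str | None = None
    dimension: str | None = None


def _substantive_counts(tally: ItemTally | Mapping) -> tuple[int, int, int, int]:
    get = tally.counts.get if isinstance(tally, ItemTally) else tally.get

    def _g(sym: str) -> int:
        key = KanoCategory(sym)
        v = get(key, None)
        if v is None:
            v = get(sym, 0) if not isinstance(tally, ItemTally) else 0
        return int(v or 0)

    return _g("A"), _g("O"), _g("M"), _g("I")


def better_coefficient(tally: ItemTally | Mapping) -> float:
    """Satisfaction-increase coefficient (A+O)/(A+O+M+I), in [0, 1]."""
    a, o, m, i = _substantive_counts(tally)
    denom = a + o + m + i
    if denom < 1:
        raise ValueError("all responses are reverse/questionable; coefficient undefined")
    return (a + o) / denom


def worse_coefficient(tally: ItemTally | Mapping) -> float:
    """Dissatisfaction coefficient -(O+M)/(A+O+M+I), in [-1, 0]."""
    a, o, m, i = _substantive_counts(tally)
    denom = a + o + m + i
    if denom < 1:
        raise ValueError("all responses are reverse/questionable; coefficient undefined")
    return -(o + m) / denom


def sensitivity(better: float, worse: float) -> float:
    """Euclidean-norm sensitivity R = sqrt(better^2 + worse^2), in [0, sqrt(2)]."""
    return math.hypot(better, worse)


def screen(r: float, config: ScreeningConfig | None = None) -> tuple[str, float]:
    """Zone and signed radial distance to the key-element arc.

    The perpendicular distance from a point to an origin-centred arc is the
    radial difference, so ``distance = R - key_radius``: positive (right of
    the key-element line) means immediate-improvement priority.
    """
    config = config or ScreeningConfig()
    distance = r - config.key_radius
    if r > config.key_radius:
        zone = ZONE_KEY
    elif r > config.element_radius:
        zone = ZONE_ELEMENT
    else:
        zone = ZONE_DEFERRED
    return zone, distance


def prioritize(results: Sequence[ItemResult]) -> list[ItemResult]:
    """Rank results by descending sensitivity; ties break on item_id.

    Ranks are assigned 1..k; exact sensitivity ties are flagged on every
    tied member.  The returned list is in rank order.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot prioritize an empty collection")
    ordered = sorted(results, key=lambda r: (-r.sensitivity, r.item_id))
    by_r: dict[float, int] = {}
    for r in ordered:
        by_r[r.sensitivity] = by_r.get(r.sensitivity, 0) + 1
    for rank, r in enumerate(ordered, start=1):
        r.rank = rank
        if by_r[r.sensitivity] > 1:
            r.tie_flag = True
    return ordered


def attribute_census(
    attributes: Iterable[KanoCategory | str | ItemResult],
) -> dict[str, int]:
    """Count items per substantive category (plus R/Q when present)."""
    counts = {c.value: 0 for c in (KanoCategory.MUST_BE, KanoCategory.ONE_DIMENSIONAL,
                                   KanoCategory.ATTRACTIVE, KanoCategory.INDIFFERENT)}
    for a in attributes:
        if isinstance(a, ItemResult):
            a = a.attribute
        if a is None:
            continue
        sym = KanoCategory(a).value
        counts[sym] = counts.get(sym, 0) + 1
    return counts


class KanoPrioritizer(BaseEstimator, TransformerMixin):
    """Score, screen and rank items from tallies or better/worse pairs.

    ``fit``/``transform`` accept either a tally table (columns
    ``A, O, M, I`` and optionally ``R, Q, attribute``) or a coefficient
    table (columns ``better, worse``), indexed or keyed by ``item_id``.
    ``transform`` returns the result table with sensitivity, rank, zone
    and signed distance to the key-element arc.

    Parameters
    ----------
    element_radius, key_radius : float
        Radii of the element and key-element screening arcs (defaults
        0.707 and 1.061).

    Attributes
    ----------
    results_ : pd.DataFrame
        Rank-ordered result table from the last ``fit``.
    census_ : dict
        Item count per attribute, when attributes were available.
    """

    def __init__(
        self,
        element_radius: float = DEFAULT_ELEMENT_RADIUS,
        key_radius: float = DEFAULT_KEY_RADIUS,
    ):
        self.element_radius = element_radius
        self.key_radius = key_radius

    def _screening(self) -> ScreeningConfig:
        return ScreeningConfig(self.element_radius, self.key_radius)

    @staticmethod
    def _coerce(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of tallies or better/worse coefficients")
        df = X.copy()
        if "item_id" in df.columns:
            df = df.set_index("item_id")
        df.index.name = "item_id"
        if {"better", "worse"}.issubset(df.columns):
            return df
        if {"A", "O", "M", "I"}.issubset(df.columns):
            denom = df[["A", "O", "M", "I"]].sum(axis=1)
            if (denom < 1).any():
                bad = list(df.index[denom < 1])
                raise ValueError(
                    f"items with only reverse/questionable responses: {bad}; "
                    "coefficients undefined"
                )
            df = df.assign(
                better=(df["A"] + df["O"]) / denom,
                worse=-(df["O"] + df["M"]) / denom,
            )
            return df
        raise ValueError(
            "X needs either columns {'better','worse'} or tally columns {'A','O','M','I'}"
        )

    def fit(self, X, y=None) -> "KanoPrioritizer":
        cfg = self._screening()
        df = self._coerce(X)
        if df.empty:
            raise ValueError("cannot prioritize an empty collection")
        r = np.hypot(df["better"].to_numpy(float), df["worse"].to_numpy(float))
        df = df.assign(sensitivity=r)
        df = df.sort_values(
            ["sensitivity", "item_id"], ascending=[False, True], kind="mergesort"
        )
        df["rank"] = np.arange(1, len(df) + 1)
        dup = df["sensitivity"].duplicated(keep=False)
        df["tie_flag"] = dup.to_numpy()
        zones, dists = zip(*(screen(v, cfg) for v in df["sensitivity"]))
        df["zone"] = list(zones)
        df["distance_to_key_line"] = list(dists)
        self.results_ = df
        if "attribute" in df.columns:
            self.census_ = attribute_census(df["attribute"])
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "results_")
        return self.results_.copy()

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def item_results(self) -> list[ItemResult]:
        """Fitted results as domain objects, in rank order."""
        check_is_fitted(self, "results_")
        out = []
        for item_id, row in self.results_.iterrows():
            out.append(
                ItemResult(
                    item_id=item_id,
                    attribute=KanoCategory(row["attribute"]) if "attribute" in row and pd.notna(row.get("attribute")) else None,
                    better=float(row["better"]),
                    worse=float(row["worse"]),
                    sensitivity=float(row["sensitivity"]),
                    rank=int(row["rank"]),
                    zone=str(row["zone"]),
                    distance_to_key_line=float(row["distance_to_key_line"]),
                    tie_flag=bool(row["tie_flag"]),
                    label=row.get("label"),
                    dimension=row.get("dimension"),
                )
            )
        return out
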