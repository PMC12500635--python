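"""Kano classification core: Likert coding, the 5x5 evaluation matrix,
per-item tallies, and modal attribute assignment.

The Kano method asks each respondent a *functional* ("how would you feel if
the service were present?") and a *dysfunctional* ("... if it were absent?")
question about every item, each answered on a five-level scale coded
1 = "Like" through 5 = "Dislike".  Each answer pair maps through a fixed
5x5 evaluation matrix to one of six categories:

* M (must-be), O (one-dimensional), A (attractive), I (indifferent) —
  the four substantive attributes that enter the better/worse coefficients;
* R (reverse) and Q (questionable) — inverted or inconsistent answer
  patterns, excluded from the coefficient denominators.

An item's attribute is the modal category over all respondents.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KanoCategory",
    "SUBSTANTIVE_CATEGORIES",
    "LIKERT_LABELS",
    "ResponsePair",
    "ItemTally",
    "AttributeAssignment",
    "encode_label",
    "decode_code",
    "classify_pair",
    "tally_item",
    "assign_attribute",
    "evaluation_matrix_frame",
    "KanoClassifier",
]


class KanoCategory(str, Enum):
    """The six Kano categories."""

    MUST_BE = "M"
    ONE_DIMENSIONAL = "O"
    ATTRACTIVE = "A"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories that carry better/worse coefficients.
SUBSTANTIVE_CATEGORIES: tuple[KanoCategory, ...] = (
    KanoCategory.MUST_BE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.ATTRACTIVE,
    KanoCategory.INDIFFERENT,
)

#: Modal tie-break precedence: a must-be miss is costliest, so ties resolve
#: conservatively toward M, then O, A, I, with R and Q last.
CATEGORY_PRECEDENCE: tuple[KanoCategory, ...] = (
    KanoCategory.MUST_BE,
    KanoCategory.ONE_DIMENSIONAL,
    KanoCategory.ATTRACTIVE,
    KanoCategory.INDIFFERENT,
    KanoCategory.REVERSE,
    KanoCategory.QUESTIONABLE,
)

#: Canonical five-level response options and their numeric codes.
LIKERT_LABELS: dict[str, int] = {
    "like": 1,
    "take it for granted": 2,
    "indifferent": 3,
    "reluctant": 4,
    "dislike": 5,
}

_CODE_TO_LABEL = {v: k for k, v in LIKERT_LABELS.items()}

# Evaluation matrix keyed [functional code][dysfunctional code]; codes run
# 1="Like" ... 5="Dislike" on both axes.
_EVAL: dict[int, dict[int, KanoCategory]] = {
    5: {5: "Q", 4: "R", 3: "R", 2: "R", 1: "R"},
    4: {5: "M", 4: "I", 3: "I", 2: "I", 1: "R"},
    3: {5: "M", 4: "I", 3: "I", 2: "I", 1: "R"},
    2: {5: "M", 4: "I", 3: "I", 2: "I", 1: "R"},
    1: {5: "O", 4: "A", 3: "A", 2: "A", 1: "Q"},
}
_EVAL = {f: {d: KanoCategory(c) for d, c in row.items()} for f, row in _EVAL.items()}


def encode_label(label: str) -> int:
    """Map a response option string to its numeric code 1-5.

    Matching is case-insensitive and ignores surrounding whitespace.
    Raises ``ValueError`` naming the offending string for anything else.
    """
    key = str(label).strip().casefold()
    try:
        return LIKERT_LABELS[key]
    except KeyError:
        raise ValueError(
            f"unknown response option {label!r}; expected one of "
            f"{sorted(LIKERT_LABELS)} or a code 1-5"
        ) from None


def decode_code(code: int) -> str:
    """Inverse of :func:`encode_label` (canonical lower-case label)."""
    try:
        return _CODE_TO_LABEL[int(code)]
    except (KeyError, ValueError):
        raise ValueError(f"response code must be an integer in 1..5, got {code!r}") from None


def _check_code(code: object, name: str) -> int:
    if isinstance(code, bool) or not isinstance(code, (int, np.integer)):
        raise ValueError(f"{name} code must be an integer in 1..5, got {code!r}")
    code = int(code)
    if not 1 <= code <= 5:
        raise ValueError(f"{name} code must be in 1..5, got {code}")
    return code


def classify_pair(functional: int, dysfunctional: int) -> KanoCategory:
    """Classify one (functional, dysfunctional) answer pair.

    Both codes use the 1="Like" ... 5="Dislike" scale.  The mapping is the
    standard Kano evaluation matrix: e.g. (Like, Dislike) -> O,
    (Like, Like) -> Q, (Take it for granted, Dislike) -> M.
    """
    f = _check_code(functional, "functional")
    d = _check_code(dysfunctional, "dysfunctional")
    return _EVAL[f][d]


def evaluation_matrix_frame() -> pd.DataFrame:
    """The full 25-cell evaluation matrix as a DataFrame.

    Rows are functional codes, columns dysfunctional codes, both 1..5.
    """
    return pd.DataFrame(
        [[_EVAL[f][d].value for d in range(1, 6)] for f in range(1, 6)],
        index=pd.Index(range(1, 6), name="functional"),
        columns=pd.Index(range(1, 6), name="dysfunctional"),
    )


@dataclass(frozen=True)
class ResponsePair:
    """One respondent's paired answers to one item."""

    respondent_id: str
    item_id: str
    functional: int
    dysfunctional: int

    def __post_init__(self) -> None:
        _check_code(self.functional, "functional")
        _check_code(self.dysfunctional, "dysfunctional")

    @property
    def category(self) -> KanoCategory:
        return classify_pair(self.functional, self.dysfunctional)


@dataclass(frozen=True)
class ItemTally:
    """Category counts for one item over all its response pairs."""

    item_id: str
    counts: Mapping[KanoCategory, int]
    n_pairs: int = field(default=0)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        n = self.n_pairs or total
        if n < 1:
            raise ValueError(f"item {self.item_id!r}: tally needs at least one pair")
        if total != n:
            raise ValueError(
                f"item {self.item_id!r}: counts sum to {total}, expected n_pairs={n}"
            )
        object.__setattr__(self, "n_pairs", n)
        full = {c: int(self.counts.get(c, 0)) for c in KanoCategory}
        if any(v < 0 for v in full.values()):
            raise ValueError(f"item {self.item_id!r}: negative count")
        object.__setattr__(self, "counts", full)

    def __getitem__(self, category: KanoCategory | str) -> int:
        return self.counts[KanoCategory(category)]


@dataclass(frozen=True)
class AttributeAssignment:
    """Modal attribute for an item, with stability diagnostics."""

    category: KanoCategory
    tied: bool  #: exact tie on the top count, broken by precedence
    unstable: bool  #: top-two margin below ``unstable_margin`` of n_pairs


def tally_item(pairs: Sequence[ResponsePair] | Iterable[ResponsePair]) -> ItemTally:
    """Count Kano categories over the response pairs of a single item."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot tally an empty collection of pairs")
    item_ids = {p.item_id for p in pairs}
    if len(item_ids) != 1:
        raise ValueError(f"pairs span multiple items: {sorted(item_ids)}")
    counts = Counter(p.category for p in pairs)
    return ItemTally(item_id=pairs[0].item_id, counts=dict(counts), n_pairs=len(pairs))


def assign_attribute(tally: ItemTally, unstable_margin: float = 0.05) -> AttributeAssignment:
    """Assign the modal Kano category of a tally.

    Ties on the maximal count are broken by the fixed precedence
    M > O > A > I > R > Q and flagged.  The assignment is additionally
    flagged ``unstable`` when the top two counts differ by less than
    ``unstable_margin`` of the number of pairs.
    """
    ordered = sorted(
        KanoCategory,
        key=lambda c: (-tally.counts[c], CATEGORY_PRECEDENCE.index(c)),
    )
    top, second = ordered[0], ordered[1]
    tied = tally.counts[top] == tally.counts[second]
    unstable = (tally.counts[top] - tally.counts[second]) < unstable_margin * tally.n_pairs
    return AttributeAssignment(category=top, tied=tied, unstable=unstable)


def _pairs_to_frame(X) -> pd.DataFrame:
    required = ["respondent_id", "item_id", "functional", "dysfunctional"]
    if isinstance(X, pd.DataFrame):
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise ValueError(f"response table is missing columns {missing}")
        return X[required].copy()
    pairs = list(X)
    if pairs and isinstance(pairs[0], ResponsePair):
        return pd.DataFrame(
            [(p.respondent_id, p.item_id, p.functional, p.dysfunctional) for p in pairs],
            columns=required,
        )
    raise TypeError(
        "X must be a DataFrame with columns "
        "respondent_id,item_id,functional,dysfunctional or a sequence of ResponsePair"
    )


class KanoClassifier(BaseEstimator):
    """Classify survey items into Kano categories from paired responses.

    Follows the scikit-learn estimator protocol: ``fit`` consumes the
    respondent-level data and exposes the per-item results as fitted
    attributes; ``predict`` returns the attribute for (new or fitted)
    item ids.

    Parameters
    ----------
    unstable_margin : float, default=0.05
        Fraction of an item's pair count below which the top-two category
        margin marks the modal assignment as unstable.

    Attributes
    ----------
    items_ : pd.Index
        Item identifiers, in first-seen order.
    tally_frame_ : pd.DataFrame
        Per-item counts over the six categories plus ``n`` pairs.
    attributes_ : pd.Series
        Modal category symbol (``"M"/"O"/"A"/"I"/"R"/"Q"``) per item.
    tie_flags_, unstable_flags_ : pd.Series of bool
        Modal-tie and narrow-margin diagnostics per item.
    """

    def __init__(self, unstable_margin: float = 0.05):
        self.unstable_margin = unstable_margin

    def fit(self, X, y=None) -> "KanoClassifier":
        df = _pairs_to_frame(X)
        if df.empty:
            raise ValueError("no response pairs supplied")
        for col in ("functional", "dysfunctional"):
            codes = df[col].to_numpy()
            bad = ~np.isin(codes, [1, 2, 3, 4, 5])
            if bad.any():
                first = df.index[bad][0]
                raise ValueError(
                    f"column {col!r} contains out-of-range code "
                    f"{df.loc[first, col]!r} (row index {first})"
                )
        cats = np.array(
            [[_EVAL[f][d].value for d in range(1, 6)] for f in range(1, 6)], dtype=object
        )
        df = df.assign(
            category=cats[
                df["functional"].to_numpy(dtype=int) - 1,
                df["dysfunctional"].to_numpy(dtype=int) - 1,
            ]
        )
        order = list(dict.fromkeys(df["item_id"]))
        tab = (
            df.pivot_table(
                index="item_id", columns="category", values="respondent_id", aggfunc="count"
            )
            .reindex(order)
            .reindex(columns=[c.value for c in KanoCategory], fill_value=0)
            .fillna(0)
            .astype(int)
        )
        tab["n"] = tab.sum(axis=1)
        self.items_ = pd.Index(order, name="item_id")
        self.tally_frame_ = tab

        attrs, ties, unstable = {}, {}, {}
        for item_id, row in tab.iterrows():
            tally = ItemTally(
                item_id=item_id,
                counts={KanoCategory(c): int(row[c]) for c in "MOAIRQ"},
                n_pairs=int(row["n"]),
            )
            a = assign_attribute(tally, unstable_margin=self.unstable_margin)
            attrs[item_id] = a.category.value
            ties[item_id] = a.tied
            unstable[item_id] = a.unstable
        self.attributes_ = pd.Series(attrs, name="attribute").reindex(order)
        self.tie_flags_ = pd.Series(ties, name="tie_flag").reindex(order)
        self.unstable_flags_ = pd.Series(unstable, name="unstable_flag").reindex(order)
        modal_rq = self.attributes_[self.attributes_.isin(["R", "Q"])]
        if len(modal_rq):
            warnings.warn(
                f"items with modal reverse/questionable category: "
                f"{', '.join(modal_rq.index)}",
                UserWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X=None) -> pd.Series:
        """Modal attribute per item id; default: all fitted items."""
        check_is_fitted(self, "attributes_")
        if X is None:
            return self.attributes_.copy()
        return self.attributes_.reindex(pd.Index(X, name="item_id"))

    def tallies(self) -> list[ItemTally]:
        """Fitted per-item tallies as domain objects."""
        check_is_fitted(self, "tally_frame_")
        return [
            ItemTally(
                item_id=item_id,
                counts={KanoCategory(c): int(row[c]) for c in "MOAIRQ"},
                n_pairs=int(row["n"]),
            )
            for item_id, row in self.tally_frame_.iterrows()
        ]
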