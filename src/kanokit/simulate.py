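"""Synthetic respondent-panel generator.

The study design this emulates is a paired-question Kano survey: each of
``n_respondents`` answers the functional and dysfunctional question for
every catalogued item.  No response-generating model accompanies the
classification matrix, so the generator is defined by inverting it: each
item carries a designed ("true") substantive attribute, and a noise-free
respondent answers with a pair drawn uniformly from the matrix cells that
classify to that attribute.  With probability ``noise_rate`` a pair is
instead corrupted: each of its two codes is replaced by an independent
uniform draw over 1..5, which produces reverse/questionable patterns at a
controllable rate.

Sample-size defaults follow the multivariate rule of thumb of 5-10
respondents per item (215-430 for the 43-item catalog; the packaged
default of 240 mirrors a typical realised panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import KanoCategory, ResponsePair, SUBSTANTIVE_CATEGORIES, classify_pair

__all__ = [
    "SimulationConfig",
    "archetype_response",
    "simulate_panel",
    "write_responses",
    "recommended_sample_size",
    "CONSISTENT_CELLS",
]

# (functional, dysfunctional) matrix cells classifying to each substantive
# attribute; codes 1="Like" ... 5="Dislike".
CONSISTENT_CELLS: dict[KanoCategory, tuple[tuple[int, int], ...]] = {
    KanoCategory.MUST_BE: ((2, 5), (3, 5), (4, 5)),
    KanoCategory.ONE_DIMENSIONAL: ((1, 5),),
    KanoCategory.ATTRACTIVE: ((1, 2), (1, 3), (1, 4)),
    KanoCategory.INDIFFERENT: tuple((f, d) for f in (2, 3, 4) for d in (2, 3, 4)),
}

for _attr, _cells in CONSISTENT_CELLS.items():
    assert all(classify_pair(f, d) is _attr for f, d in _cells)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one synthetic survey panel.

    Parameters
    ----------
    n_respondents : int
        Panel size (>= 1).
    items : sequence of (item_id, true_attribute)
        The instrument: unique item ids with their designed substantive
        attribute (one of M, O, A, I; R and Q arise only through noise).
    noise_rate : float in [0, 1]
        Per-pair probability of corruption by uniform code replacement.
    seed : int
        Seed of the generator's private RNG; identical configs give
        identical panels.
    """

    n_respondents: int
    items: tuple[tuple[str, KanoCategory], ...]
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError(f"n_respondents must be >= 1, got {self.n_respondents}")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        items = tuple((str(i), KanoCategory(a)) for i, a in self.items)
        if not items:
            raise ValueError("items must be non-empty")
        ids = [i for i, _ in items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        bad = [i for i, a in items if a not in SUBSTANTIVE_CATEGORIES]
        if bad:
            raise ValueError(
                f"true attributes must be substantive (M/O/A/I); offending items: {bad}"
            )
        object.__setattr__(self, "items", items)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a design from a YAML or JSON mapping.

        Expected keys: ``n_respondents``, ``items`` (list of
        ``[item_id, attribute]`` pairs or ``{item_id: ..., attribute: ...}``
        mappings), optional ``noise_rate`` and ``seed``.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        items = []
        for entry in raw.get("items", []):
            if isinstance(entry, dict):
                items.append((entry["item_id"], entry["attribute"]))
            else:
                item_id, attr = entry
                items.append((item_id, attr))
        return cls(
            n_respondents=int(raw["n_respondents"]),
            items=tuple(items),
            noise_rate=float(raw.get("noise_rate", 0.0)),
            seed=int(raw.get("seed", 0)),
        )


def archetype_response(
    true_attribute: KanoCategory | str, rng: np.random.Generator | None = None
) -> tuple[int, int]:
    """A noise-free (functional, dysfunctional) pair for an attribute.

    Drawn uniformly over the matrix cells consistent with the attribute,
    so ``classify_pair(*archetype_response(a)) == a`` by construction.
    """
    attr = KanoCategory(true_attribute)
    if attr not in CONSISTENT_CELLS:
        raise ValueError(f"true attribute must be one of M/O/A/I, got {attr.value!r}")
    cells = CONSISTENT_CELLS[attr]
    rng = rng if rng is not None else np.random.default_rng()
    f, d = cells[int(rng.integers(len(cells)))]
    return f, d


def simulate_panel(config: SimulationConfig) -> list[ResponsePair]:
    """Generate the full panel of ``n_respondents x len(items)`` pairs.

    Pairs are emitted item-major (all respondents for the first item,
    then the second, ...), respondent ids ``r0001`` upward.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents
    width = max(4, len(str(n)))
    respondents = [f"r{j + 1:0{width}d}" for j in range(n)]
    out: list[ResponsePair] = []
    for item_id, attr in config.items:
        cells = np.array(CONSISTENT_CELLS[attr], dtype=int)
        idx = rng.integers(len(cells), size=n)
        f = cells[idx, 0].copy()
        d = cells[idx, 1].copy()
        noisy = rng.random(n) < config.noise_rate
        k = int(noisy.sum())
        if k:
            f[noisy] = rng.integers(1, 6, size=k)
            d[noisy] = rng.integers(1, 6, size=k)
        out.extend(
            ResponsePair(respondents[j], item_id, int(f[j]), int(d[j])) for j in range(n)
        )
    return out


def write_responses(pairs: Sequence[ResponsePair], destination) -> Path:
    """Write pairs to a long-format CSV (round-trips through the reader)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("refusing to write an empty response collection")
    df = pd.DataFrame(
        [(p.respondent_id, p.item_id, p.functional, p.dysfunctional) for p in pairs],
        columns=["respondent_id", "item_id", "functional", "dysfunctional"],
    )
    destination = Path(destination)
    df.to_csv(destination, index=False)
    return destination


def recommended_sample_size(n_items: int) -> tuple[int, int]:
    """(minimum, maximum) panel size: 5 and 10 respondents per item."""
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    return 5 * n_items, 10 * n_items
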