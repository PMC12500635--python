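"""Shared fixtures: the published priority table reference and small panels."""

from __future__ import annotations

import pandas as pd
import pytest

import kanokit as kk

# Published per-item sensitivity (percent, as printed) and priority order,
# used to check end-stage reproduction from the packaged coefficient fixture.
PUBLISHED_PRIORITY_TABLE: dict[str, tuple[float, int]] = {
    "A1": (96.70, 1), "A2": (82.80, 6), "A3": (61.90, 31), "A4": (61.70, 32),
    "A5": (35.30, 42), "A6": (86.70, 5), "A7": (67.60, 13),
    "B1": (64.40, 25), "B2": (36.60, 40), "B3": (93.90, 3), "B4": (96.50, 2),
    "B5": (40.50, 36), "B6": (66.60, 14), "B7": (32.90, 43), "B8": (65.60, 18),
    "B9": (65.40, 19), "B10": (46.10, 35), "B11": (65.00, 22), "B12": (63.20, 27),
    "B13": (39.40, 39), "B14": (62.60, 28), "B15": (36.50, 41), "B16": (39.50, 38),
    "B17": (62.00, 30),
    "C1": (66.00, 15), "C2": (61.40, 33), "C3": (39.80, 37), "C4": (65.00, 23),
    "C5": (65.90, 16), "C6": (70.40, 8), "C7": (62.50, 29), "C8": (82.70, 7),
    "C9": (65.80, 17),
    "D1": (68.00, 9), "D2": (91.50, 4), "D3": (67.80, 11), "D4": (65.20, 21),
    "D5": (65.30, 20),
    "E1": (63.60, 26), "E2": (67.90, 10), "E3": (59.70, 34), "E4": (64.40, 24),
    "E5": (67.70, 12),
}


@pytest.fixture(scope="session")
def table4() -> pd.DataFrame:
    return kk.load_table4_fixture()


@pytest.fixture(scope="session")
def instrument_profile(table4) -> tuple[tuple[str, kk.KanoCategory], ...]:
    """The 43-item design profile (item_id, published attribute)."""
    return tuple((i, kk.KanoCategory(a)) for i, a in table4["attribute"].items())


@pytest.fixture()
def small_panel() -> list[kk.ResponsePair]:
    """Tiny deterministic noise-free panel: one item per attribute."""
    cfg = kk.SimulationConfig(
        n_respondents=12,
        items=(("m1", "M"), ("o1", "O"), ("a1", "A"), ("i1", "I")),
        noise_rate=0.0,
        seed=42,
    )
    return kk.simulate_panel(cfg)
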