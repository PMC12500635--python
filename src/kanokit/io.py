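"""Readers, writers and packaged fixtures.

Long-format response CSVs carry one row per (respondent, item) with the
functional and dysfunctional answers either as numeric codes 1-5 or as the
canonical option labels ("Like" ... "Dislike").  The packaged fixtures are
the 43-item instrument catalog and its published attribute / better-worse
coefficient table, stored with the coefficients as two-decimal percent
strings and parsed to fractions on load.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import ResponsePair, encode_label

__all__ = [
    "read_responses",
    "read_score_matrix",
    "load_table4_fixture",
    "load_catalog",
    "parse_percent",
    "fixture_sha256",
    "write_results_csv",
    "write_report_json",
]

RESPONSE_COLUMNS = ["respondent_id", "item_id", "functional", "dysfunctional"]


def _coerce_code(value, column: str, line_no: int) -> int:
    s = str(value).strip()
    if s.lstrip("+-").isdigit():
        code = int(s)
        if not 1 <= code <= 5:
            raise ValueError(f"line {line_no}: {column} code {code} out of range 1..5")
        return code
    try:
        return encode_label(s)
    except ValueError as e:
        raise ValueError(f"line {line_no}: {e}") from None


def read_responses(path) -> list[ResponsePair]:
    """Read a long-format response CSV into validated pairs.

    Codes may be numeric (1-5) or canonical option labels; errors cite the
    1-based file line (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pairs: list[ResponsePair] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header occupies line 1
        if any(pd.isna(getattr(row, c)) for c in RESPONSE_COLUMNS):
            raise ValueError(f"{path}: line {line_no}: incomplete row")
        pairs.append(
            ResponsePair(
                respondent_id=str(row.respondent_id).strip(),
                item_id=str(row.item_id).strip(),
                functional=_coerce_code(row.functional, "functional", line_no),
                dysfunctional=_coerce_code(row.dysfunctional, "dysfunctional", line_no),
            )
        )
    return pairs


def read_score_matrix(path) -> pd.DataFrame:
    """Read a wide respondents x items score CSV (first column = respondent id)."""
    df = pd.read_csv(path)
    return df.set_index(df.columns[0])


def parse_percent(text: str) -> float:
    """Parse a percent string like ``"70.04%"`` or ``"-66.67%"`` to a fraction."""
    s = str(text).strip().replace("−", "-")  # tolerate typographic minus
    if not s.endswith("%"):
        raise ValueError(f"expected a percent string ending in '%', got {text!r}")
    return float(s[:-1]) / 100.0


def _packaged(name: str):
    return resources.files("kanokit.data").joinpath(name)


def fixture_sha256(name: str = "table4_fixture.csv") -> str:
    """Content hash of a packaged fixture (pinned in the test suite)."""
    return hashlib.sha256(_packaged(name).read_bytes()).hexdigest()


def load_catalog(path=None) -> pd.DataFrame:
    """The item catalog (item_id, label, dimension); packaged 43-item default."""
    if path is not None:
        df = pd.read_csv(Path(path))
    else:
        with resources.as_file(_packaged("catalog_43items.csv")) as p:
            df = pd.read_csv(p)
    required = {"item_id", "label", "dimension"}
    if not required.issubset(df.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    if df["item_id"].duplicated().any():
        raise ValueError("catalog item_ids must be unique")
    return df


def load_table4_fixture() -> pd.DataFrame:
    """The published 43-item attribute and better/worse coefficient table.

    Returns a DataFrame indexed by ``item_id`` with columns ``label``,
    ``dimension``, ``attribute``, and the coefficients ``better`` (fraction
    in [0,1]) and ``worse`` (fraction in [-1,0]) parsed exactly from the
    stored two-decimal percent strings.
    """
    with resources.as_file(_packaged("table4_fixture.csv")) as p:
        df = pd.read_csv(p)
    if len(df) != 43:
        raise ValueError(f"packaged coefficient fixture corrupt: {len(df)} rows, expected 43")
    df["better"] = df["better"].map(parse_percent)
    df["worse"] = df["worse"].map(parse_percent)
    return df.set_index("item_id")


def write_results_csv(results: pd.DataFrame, path) -> Path:
    """Write a scored/ranked result table; full precision, UTF-8, comma CSV."""
    path = Path(path)
    results.to_csv(path, index=True)
    return path


def write_report_json(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    try:
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
    except ImportError:  # pragma: no cover
        pass
    if hasattr(o, "value"):
        return o.value
    raise TypeError(f"not JSON serialisable: {type(o)}")
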