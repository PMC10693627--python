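"""PANSS domain sums, remission status and the summed remission score.

Domains: positive P1-P7, negative N1-N7, general G1-G16, each item an
integer 1-7.  Remission status requires a rating of mild or less (<= 3)
simultaneously on P1, P2, P3, N1, N4, N6, G5 and G9; the remission score
is the sum of those eight items.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "POSITIVE_ITEMS",
    "NEGATIVE_ITEMS",
    "GENERAL_ITEMS",
    "REMISSION_ITEMS",
    "panss_domains",
    "remission_status",
    "remission_score",
    "score_panss",
]

POSITIVE_ITEMS = tuple(f"P{i}" for i in range(1, 8))
NEGATIVE_ITEMS = tuple(f"N{i}" for i in range(1, 8))
GENERAL_ITEMS = tuple(f"G{i}" for i in range(1, 17))
ALL_ITEMS = POSITIVE_ITEMS + NEGATIVE_ITEMS + GENERAL_ITEMS

# severity criterion items: delusions, conceptual disorganisation,
# hallucinatory behaviour, blunted affect, social withdrawal, lack of
# spontaneity, mannerisms/posturing, unusual thought content
REMISSION_ITEMS = ("P1", "P2", "P3", "N1", "N4", "N6", "G5", "G9")
REMISSION_CUTOFF = 3


def _validate_item(name: str, value) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValidationError(f"item {name} is missing")
    v = int(value)
    if v != value or not 1 <= v <= 7:
        raise ValidationError(f"item {name} must be an integer in 1..7, got {value!r}")
    return v


def panss_domains(record: Mapping) -> tuple[int, int, int]:
    """(positive, negative, general) domain sums of one assessment."""
    pos = sum(_validate_item(i, record[i]) for i in POSITIVE_ITEMS)
    neg = sum(_validate_item(i, record[i]) for i in NEGATIVE_ITEMS)
    gen = sum(_validate_item(i, record[i]) for i in GENERAL_ITEMS)
    return pos, neg, gen


def remission_status(record: Mapping) -> bool:
    """True iff all eight criterion items are rated mild or less (<= 3)."""
    return all(_validate_item(i, record[i]) <= REMISSION_CUTOFF for i in REMISSION_ITEMS)


def remission_score(record: Mapping) -> int:
    """Sum of the eight remission criterion items (range 8-56)."""
    return sum(_validate_item(i, record[i]) for i in REMISSION_ITEMS)


def score_panss(items: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of an item-level table.

    Expects columns subject_id, week, P1..P7, N1..N7, G1..G16 and returns
    the table with positive/negative/general sums, remission_status and
    remission_score appended.  Rows with any missing criterion item get a
    missing remission status/score (no imputation).
    """
    missing_cols = [c for c in ("subject_id", "week") + ALL_ITEMS if c not in items.columns]
    if missing_cols:
        raise ValidationError(f"PANSS table missing columns: {missing_cols}")
    if (items["week"] < 0).any():
        raise ValidationError("week must be >= 0")
    out = items.copy()
    vals = out[list(ALL_ITEMS)]
    present = vals.notna()
    bad = present & (~vals.isin(range(1, 8)))
    if bad.any().any():
        names = bad.any()[bad.any()].index.tolist()
        raise ValidationError(f"items outside 1..7 in columns: {names}")
    out["positive"] = vals[list(POSITIVE_ITEMS)].sum(axis=1, min_count=7)
    out["negative"] = vals[list(NEGATIVE_ITEMS)].sum(axis=1, min_count=7)
    out["general"] = vals[list(GENERAL_ITEMS)].sum(axis=1, min_count=16)
    crit = vals[list(REMISSION_ITEMS)]
    complete = crit.notna().all(axis=1)
    status = pd.Series(pd.NA, index=out.index, dtype="boolean")
    status[complete] = (crit[complete] <= REMISSION_CUTOFF).all(axis=1)
    out["remission_status"] = status
    score = crit.sum(axis=1, min_count=8)
    out["remission_score"] = score.astype("Int64")
    return out
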