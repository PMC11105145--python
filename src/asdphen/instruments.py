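"""Mapping diagnostic-instrument results to ASD / Probable ASD / Not ASD.

Cutoffs (scores compared as exact decimals, no rounding):

* ASDS   — >110 ASD; 90–110 inclusive Probable ASD; else Not ASD
* CARS   — categories Severe / Mild to Moderate / NOS are ASD; else Not ASD
* GADS   — High or Probable are ASD; Borderline is Probable ASD; else Not ASD
* GARS   — >110 ASD; 80–110 inclusive Probable ASD; else Not ASD
* GARS2  — >=85 ASD; else Not ASD
* MCHAT  — >=2 ASD; else Not ASD
* ADOS   — already a binary ASD / Not ASD result, passed through

Aggregation across a child's tests is any-test-positive; whether a
Probable ASD result counts as positive is an explicit policy because
conventions differ.  Duplicate (even conflicting) administrations are all
kept.
"""

from __future__ import annotations

import enum
import numbers
from typing import List, Optional, Sequence

import pandas as pd

from .types import InstrumentResult


class InstrumentLabel(str, enum.Enum):
    ASD = "ASD"
    ProbableASD = "ProbableASD"
    NotASD = "NotASD"


NUMERIC_INSTRUMENTS = frozenset({"ASDS", "GARS", "GARS2", "MCHAT"})
CATEGORICAL_INSTRUMENTS = frozenset({"CARS", "GADS", "ADOS"})
KNOWN_INSTRUMENTS = NUMERIC_INSTRUMENTS | CATEGORICAL_INSTRUMENTS

_CARS_ASD = frozenset({"severe", "mild to moderate", "nos"})
_GADS_ASD = frozenset({"high", "probable", "high/probable"})
_ADOS_MAP = {"asd": InstrumentLabel.ASD, "notasd": InstrumentLabel.NotASD,
             "not asd": InstrumentLabel.NotASD, "no asd": InstrumentLabel.NotASD}


def _norm(value) -> str:
    return str(value).strip().lower()


def map_result(r: InstrumentResult) -> InstrumentLabel:
    """Map one instrument administration to its label by the cutoffs above.

    Unknown instruments and unknown category strings raise ``ValueError``;
    numeric instruments require a numeric value.
    """
    inst = r.instrument.strip().upper()
    if inst not in KNOWN_INSTRUMENTS:
        raise ValueError(f"unknown instrument {r.instrument!r}")
    if inst in NUMERIC_INSTRUMENTS:
        if isinstance(r.value, bool) or not isinstance(r.value, numbers.Real):
            raise ValueError(f"{inst} requires a numeric score, got {r.value!r}")
        v = float(r.value)
        if inst == "ASDS":
            if v > 110:
                return InstrumentLabel.ASD
            return InstrumentLabel.ProbableASD if 90 <= v <= 110 else InstrumentLabel.NotASD
        if inst == "GARS":
            if v > 110:
                return InstrumentLabel.ASD
            return InstrumentLabel.ProbableASD if 80 <= v <= 110 else InstrumentLabel.NotASD
        if inst == "GARS2":
            return InstrumentLabel.ASD if v >= 85 else InstrumentLabel.NotASD
        # MCHAT
        return InstrumentLabel.ASD if v >= 2 else InstrumentLabel.NotASD

    cat = _norm(r.value)
    if inst == "CARS":
        if cat in _CARS_ASD:
            return InstrumentLabel.ASD
        if cat in {"not asd", "no asd", "notasd", "none", "minimal"}:
            return InstrumentLabel.NotASD
        raise ValueError(f"unknown CARS category {r.value!r}")
    if inst == "GADS":
        if cat in _GADS_ASD:
            return InstrumentLabel.ASD
        if cat == "borderline":
            return InstrumentLabel.ProbableASD
        if cat in {"not asd", "no asd", "notasd", "low", "unlikely"}:
            return InstrumentLabel.NotASD
        raise ValueError(f"unknown GADS category {r.value!r}")
    # ADOS
    if cat in _ADOS_MAP:
        return _ADOS_MAP[cat]
    raise ValueError(f"unknown ADOS result {r.value!r}")


def aggregate_tests(
    results: Sequence[InstrumentResult],
    probable_policy: str = "as_asd",
) -> Optional[bool]:
    """Any-test-positive aggregation across a child's instrument results.

    ``probable_policy`` decides whether a Probable ASD result counts toward
    the positive decision (``"as_asd"``) or not (``"as_not_asd"``).
    Duplicate administrations are never collapsed.  Returns ``None`` when no
    test was administered.
    """
    if probable_policy not in {"as_asd", "as_not_asd"}:
        raise ValueError(f"unknown probable_policy {probable_policy!r}")
    if not results:
        return None
    positive = {InstrumentLabel.ASD}
    if probable_policy == "as_asd":
        positive.add(InstrumentLabel.ProbableASD)
    return any(map_result(r) in positive for r in results)


def mapping_table() -> pd.DataFrame:
    """The cutoff table as a DataFrame, for CSV export / audit."""
    rows = [
        ("ASDS", "score > 110", "ASD"),
        ("ASDS", "90 <= score <= 110", "ProbableASD"),
        ("ASDS", "score < 90", "NotASD"),
        ("CARS", "Severe / Mild to Moderate / NOS", "ASD"),
        ("CARS", "other category", "NotASD"),
        ("GADS", "High / Probable", "ASD"),
        ("GADS", "Borderline", "ProbableASD"),
        ("GADS", "other category", "NotASD"),
        ("GARS", "score > 110", "ASD"),
        ("GARS", "80 <= score <= 110", "ProbableASD"),
        ("GARS", "score < 80", "NotASD"),
        ("GARS2", "score >= 85", "ASD"),
        ("GARS2", "score < 85", "NotASD"),
        ("MCHAT", "score >= 2", "ASD"),
        ("MCHAT", "score < 2", "NotASD"),
        ("ADOS", "ASD", "ASD"),
        ("ADOS", "Not ASD", "NotASD"),
    ]
    return pd.DataFrame(rows, columns=["instrument", "condition", "label"])


def labels_for_record(results: Sequence[InstrumentResult]) -> List[InstrumentLabel]:
    """Per-administration labels in input order (audit helper)."""
    return [map_result(r) for r in results]
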