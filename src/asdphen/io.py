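"""Readers and writers for the corpus, prediction, and report formats.

Formats (all plain text, UTF-8):

* corpus: JSON Lines, one object per sentence
  ``{"record_id", "sentence_id", "ordinal", "text", "gold_labels": [...]}``,
  in record order then sentence ordinal.  Label arrays are sorted so
  serialization is canonical and round-trips byte-for-byte.
* record side file: a single JSON array of
  ``{"record_id", "gold_case", "instrument_results": [...]}`` objects.
* predictions: JSON Lines ``{"predictor_id", "sentence_id", "labels": [...]}``,
  sorted by (predictor_id, sentence_id); sentences with empty label sets are
  omitted (absence means the empty set).
* metrics: CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .types import (
    ALL_CRITERIA,
    Criterion,
    InstrumentResult,
    PredictionSet,
    Record,
    Sentence,
    parse_criterion,
)


class CorpusFormatError(ValueError):
    """Raised when a corpus/prediction file violates the format contract."""


def _dump(obj: dict) -> str:
    return json.dumps(obj, ensure_ascii=False, separators=(",", ":"))


def _sorted_labels(labels: Iterable[Criterion]) -> List[str]:
    return sorted(c.value for c in labels)


# ---------------------------------------------------------------------------
# corpus


def read_corpus(path, side_path=None) -> List[Record]:
    """Read a JSON-lines corpus (and optional record side file) into Records.

    Sentences are attached to records in file order.  Malformed lines and
    unknown criterion strings raise :class:`CorpusFormatError` naming the
    offending line / string.
    """
    path = Path(path)
    records: Dict[str, Record] = {}
    seen_ids: Set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON ({e.msg})") from None
            try:
                labels = {parse_criterion(c) for c in obj.get("gold_labels", [])}
                sent = Sentence(
                    sentence_id=str(obj["sentence_id"]),
                    record_id=str(obj["record_id"]),
                    ordinal=int(obj["ordinal"]),
                    text=str(obj["text"]),
                    gold_labels=labels,
                )
            except ValueError as e:
                raise CorpusFormatError(f"{path}:{lineno}: {e}") from None
            except KeyError as e:
                raise CorpusFormatError(f"{path}:{lineno}: missing field {e}") from None
            if sent.sentence_id in seen_ids:
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate sentence_id {sent.sentence_id!r}"
                )
            seen_ids.add(sent.sentence_id)
            rec = records.setdefault(sent.record_id, Record(record_id=sent.record_id))
            if any(s.ordinal == sent.ordinal for s in rec.sentences):
                raise CorpusFormatError(
                    f"{path}:{lineno}: duplicate ordinal {sent.ordinal} in record "
                    f"{sent.record_id!r}"
                )
            rec.sentences.append(sent)

    out = list(records.values())
    if side_path is not None:
        _read_side_file(out, side_path)
    return out


def _read_side_file(records: List[Record], side_path) -> None:
    side_path = Path(side_path)
    entries = json.loads(side_path.read_text(encoding="utf-8"))
    by_id = {r.record_id: r for r in records}
    for entry in entries:
        rid = str(entry["record_id"])
        rec = by_id.setdefault(rid, Record(record_id=rid))
        if rec not in records:
            records.append(rec)
        rec.gold_case = entry.get("gold_case")
        rec.instrument_results = [
            InstrumentResult(
                instrument=str(ir["instrument"]),
                value=ir["value"],
                age_at_test=ir.get("age_at_test"),
            )
            for ir in entry.get("instrument_results", [])
        ]


def write_corpus(records: Sequence[Record], path, side_path=None) -> None:
    """Serialize records to the canonical corpus format (deterministic bytes)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            for sent in rec.sentences:
                fh.write(
                    _dump(
                        {
                            "record_id": sent.record_id,
                            "sentence_id": sent.sentence_id,
                            "ordinal": sent.ordinal,
                            "text": sent.text,
                            "gold_labels": _sorted_labels(sent.gold_labels),
                        }
                    )
                    + "\n"
                )
    if side_path is not None:
        write_record_side_file(records, side_path)


def write_record_side_file(records: Sequence[Record], side_path) -> None:
    entries = []
    for rec in records:
        entries.append(
            {
                "record_id": rec.record_id,
                "gold_case": rec.gold_case,
                "instrument_results": [
                    {
                        "instrument": ir.instrument,
                        "value": ir.value,
                        "age_at_test": ir.age_at_test,
                    }
                    for ir in rec.instrument_results
                ],
            }
        )
    Path(side_path).write_text(
        json.dumps(entries, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# predictions


def write_predictions(preds: Sequence[PredictionSet], path) -> None:
    """Write prediction sets sorted by (predictor_id, sentence_id).

    Output is byte-for-byte reproducible; duplicate predictor ids are an
    error.
    """
    ids = [p.predictor_id for p in preds]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate predictor_id(s): {dupes}")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_dump({"format": "asdphen-predictions", "predictors": sorted(ids)}) + "\n")
        for pred in sorted(preds, key=lambda p: p.predictor_id):
            for sid in sorted(pred.labels_by_sentence):
                labels = pred.labels_by_sentence[sid]
                if not labels:
                    continue
                fh.write(
                    _dump(
                        {
                            "predictor_id": pred.predictor_id,
                            "sentence_id": sid,
                            "labels": _sorted_labels(labels),
                        }
                    )
                    + "\n"
                )


def read_predictions(path) -> List[PredictionSet]:
    path = Path(path)
    preds: Dict[str, PredictionSet] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise CorpusFormatError(f"{path}:{lineno}: malformed JSON ({e.msg})") from None
            if lineno == 1 and obj.get("format") == "asdphen-predictions":
                for pid in obj.get("predictors", []):
                    preds.setdefault(pid, PredictionSet(predictor_id=pid))
                continue
            try:
                pid = str(obj["predictor_id"])
                sid = str(obj["sentence_id"])
                labels = {parse_criterion(c) for c in obj["labels"]}
            except ValueError as e:
                raise CorpusFormatError(f"{path}:{lineno}: {e}") from None
            except KeyError as e:
                raise CorpusFormatError(f"{path}:{lineno}: missing field {e}") from None
            preds.setdefault(pid, PredictionSet(predictor_id=pid)).labels_by_sentence[
                sid
            ] = labels
    return sorted(preds.values(), key=lambda p: p.predictor_id)


# ---------------------------------------------------------------------------
# summaries / validation


def corpus_summary(records: Sequence[Record]) -> pd.DataFrame:
    """Record, sentence, and per-criterion labeled-sentence counts.

    A sentence with two labels contributes once to each label's count.
    Returned as a one-row DataFrame with columns ``records``, ``sentences``,
    and one column per criterion code.
    """
    counts = {c.value: 0 for c in ALL_CRITERIA}
    n_sent = 0
    for rec in records:
        for sent in rec.sentences:
            n_sent += 1
            for c in sent.gold_labels:
                counts[c.value] += 1
    row = {"records": len(records), "sentences": n_sent, **counts}
    return pd.DataFrame([row])


def validate_gold_cases(records: Sequence[Record]) -> List[str]:
    """Check stored gold case labels against the DSM-5 rule on gold labels.

    Returns human-readable violation messages (empty list = consistent).
    Violations are reported, never silently fixed: a stored case label that
    disagrees with the rule usually means incomplete sentence annotation.
    """
    problems = []
    for rec in records:
        if rec.gold_case is None:
            continue
        implied = rec.gold_case_from_labels()
        if bool(rec.gold_case) != implied:
            problems.append(
                f"record {rec.record_id!r}: gold_case={rec.gold_case} but DSM-5 rule "
                f"on gold labels {sorted(c.value for c in rec.gold_criteria)} "
                f"implies {implied}"
            )
    return problems


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    """Export a metrics table as CSV (2-decimal display is left to callers)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
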