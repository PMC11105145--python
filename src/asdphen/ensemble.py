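"""Sentence-level ensembles and record-level DSM-5 case labeling.

Two combiners are supported:

* ``majority_vote`` — a sentence keeps a label iff strictly more than half
  of the member predictors assign it.  For two members this means
  unanimity ("majority" is only well defined strictly), which makes the
  two-member majority ensemble the most conservative configuration.
* ``inclusive_or`` — the union of the members' labels.

Majority-vote labels are always a subset of inclusive-or labels for the
same members, so at the case level the OR ensemble can never have lower
sensitivity and the majority ensemble can never have lower specificity.

The case decision applies the DSM-5 rule to the union of a record's
combined sentence labels and always retains the evidence sentences per
criterion — the transparency surface of the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

from .types import (
    ALL_CRITERIA,
    Criterion,
    PredictionSet,
    Record,
    meets_dsm5_rule,
)

COMBINERS = ("majority_vote", "inclusive_or")


@dataclass(frozen=True)
class EnsembleSpec:
    """Member predictor ids plus the combiner name."""

    members: Tuple[str, ...]
    combiner: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate ensemble members: {self.members}")
        if self.combiner not in COMBINERS:
            raise ValueError(f"combiner must be one of {COMBINERS}, got {self.combiner!r}")

    @property
    def name(self) -> str:
        short = {"majority_vote": "maj", "inclusive_or": "or"}[self.combiner]
        return f"{short}({','.join(self.members)})"


def six_ensembles(
    all_members: Sequence[str], ml_members: Sequence[str], top_two: Sequence[str]
) -> List[EnsembleSpec]:
    """The standard comparison grid: {all four, all-ML, top-two} x
    {majority vote, inclusive or}."""
    out = []
    for members in (all_members, ml_members, top_two):
        for combiner in COMBINERS:
            out.append(EnsembleSpec(members=tuple(members), combiner=combiner))
    return out


@dataclass
class CaseDecision:
    """Record-level decision with its supporting evidence sentences."""

    record_id: str
    criteria_present: Set[Criterion]
    label: bool
    evidence: Dict[Criterion, List[str]] = field(default_factory=dict)


def combine(preds: Sequence[PredictionSet], spec: EnsembleSpec) -> PredictionSet:
    """Combine member predictions per sentence according to ``spec``.

    majority_vote keeps a label iff its vote count is strictly greater than
    ``n_members / 2``; inclusive_or takes the union.  Missing members are
    an error.
    """
    by_id = {p.predictor_id: p for p in preds}
    missing = [m for m in spec.members if m not in by_id]
    if missing:
        raise ValueError(f"missing ensemble member predictions: {missing}")
    members = [by_id[m] for m in spec.members]
    n = len(members)
    sentence_ids: Set[str] = set()
    for m in members:
        sentence_ids.update(m.labels_by_sentence)
    out = PredictionSet(predictor_id=spec.name)
    for sid in sentence_ids:
        votes: Dict[Criterion, int] = {}
        for m in members:
            for c in m.labels_for(sid):
                votes[c] = votes.get(c, 0) + 1
        if spec.combiner == "inclusive_or":
            labels = {c for c, v in votes.items() if v >= 1}
        else:
            labels = {c for c, v in votes.items() if v > n / 2}
        if labels:
            out.labels_by_sentence[sid] = labels
    return out


def label_case(record: Record, combined: PredictionSet) -> CaseDecision:
    """DSM-5 case decision for one record from combined sentence labels.

    ``criteria_present`` is the union of the combined labels over the
    record's sentences; the count of examples per criterion does not affect
    the decision, only presence does.  Every present criterion carries its
    evidence sentence ids.
    """
    evidence: Dict[Criterion, List[str]] = {}
    for sent in record.sentences:
        for c in combined.labels_for(sent.sentence_id):
            evidence.setdefault(c, []).append(sent.sentence_id)
    criteria = set(evidence)
    return CaseDecision(
        record_id=record.record_id,
        criteria_present=criteria,
        label=meets_dsm5_rule(criteria),
        evidence={c: sorted(ids) for c, ids in evidence.items()},
    )


def run_pipeline(
    records: Sequence[Record],
    predictions: Sequence[PredictionSet],
    spec: EnsembleSpec,
) -> List[CaseDecision]:
    """Combine member predictions and label every record."""
    combined = combine(predictions, spec)
    return [label_case(rec, combined) for rec in records]


def decisions_as_cases(decisions: Sequence[CaseDecision]) -> Dict[str, bool]:
    return {d.record_id: d.label for d in decisions}


# ---------------------------------------------------------------------------
# export


def write_decisions_json(decisions: Sequence[CaseDecision], path) -> None:
    payload = [
        {
            "record_id": d.record_id,
            "label": d.label,
            "criteria_present": sorted(c.value for c in d.criteria_present),
            "evidence": {c.value: ids for c, ids in sorted(
                d.evidence.items(), key=lambda kv: kv[0].value)},
        }
        for d in decisions
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_decisions_json(path) -> List[CaseDecision]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for d in payload:
        evidence = {Criterion(c): list(ids) for c, ids in d.get("evidence", {}).items()}
        out.append(
            CaseDecision(
                record_id=d["record_id"],
                criteria_present={Criterion(c) for c in d["criteria_present"]},
                label=bool(d["label"]),
                evidence=evidence,
            )
        )
    return out


def write_case_report(
    decisions: Sequence[CaseDecision],
    records: Sequence[Record],
    path,
) -> None:
    """Human-readable report: per record, each criterion with its quoted
    evidence sentences — the reviewable output a clinician would inspect."""
    sent_text = {
        s.sentence_id: s.text for rec in records for s in rec.sentences
    }
    lines: List[str] = []
    for d in decisions:
        verdict = "ASD" if d.label else "No ASD"
        lines.append(f"Record {d.record_id}: {verdict}")
        lines.append(
            "  criteria with evidence: "
            + (", ".join(sorted(c.value for c in d.criteria_present)) or "(none)")
        )
        for c in ALL_CRITERIA:
            ids = d.evidence.get(c)
            if not ids:
                continue
            lines.append(f"  [{c.value}]")
            for sid in ids:
                lines.append(f'    {sid}: "{sent_text.get(sid, "<unknown sentence>")}"')
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
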