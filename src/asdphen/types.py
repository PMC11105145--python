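"""Core domain types shared by every pipeline stage.

The unit of annotation is a single clinical-note sentence; each sentence may
carry zero or more DSM-5 criterion labels (A1-A3 social-communication
deficits, B1-B4 restricted/repetitive behaviors).  Records group the
sentences of one surveillance record and carry an optional gold case label
plus any diagnostic-instrument results recorded for the child.

The record-level ASD decision rule lives here (:func:`meets_dsm5_rule`)
because both the corpus validator and the ensemble stage need it: a case is
ASD when all three A criteria and at least two of the four B criteria have
at least one documented example sentence.  The *number* of examples per
criterion is irrelevant to the rule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import AbstractSet, Dict, FrozenSet, List, Optional, Set, Union


class Criterion(str, enum.Enum):
    """The seven DSM-5 criterion codes used for sentence labeling."""

    A1 = "A1"
    A2 = "A2"
    A3 = "A3"
    B1 = "B1"
    B2 = "B2"
    B3 = "B3"
    B4 = "B4"

    @property
    def group(self) -> str:
        """``"A"`` for social-communication criteria, ``"B"`` for behaviors."""
        return self.value[0]

    def __str__(self) -> str:  # serialize as the bare code
        return self.value


A_CRITERIA: FrozenSet[Criterion] = frozenset({Criterion.A1, Criterion.A2, Criterion.A3})
B_CRITERIA: FrozenSet[Criterion] = frozenset(
    {Criterion.B1, Criterion.B2, Criterion.B3, Criterion.B4}
)
ALL_CRITERIA: tuple = tuple(Criterion)


def parse_criterion(code: str) -> Criterion:
    """Convert a string to a :class:`Criterion`, rejecting unknown codes."""
    try:
        return Criterion(code)
    except ValueError:
        raise ValueError(f"unknown criterion {code!r}; expected one of "
                         f"{[c.value for c in Criterion]}") from None


def meets_dsm5_rule(criteria: AbstractSet[Criterion]) -> bool:
    """Record-level ASD decision from the set of criteria with evidence.

    True iff all of A1, A2, A3 are present and at least two distinct B
    criteria are present.  Evidence counts beyond one example per criterion
    do not matter.
    """
    crits = set(criteria)
    return A_CRITERIA <= crits and len(crits & B_CRITERIA) >= 2


@dataclass
class InstrumentResult:
    """One administration of an autism-specific diagnostic instrument.

    ``value`` is a numeric total score for score-based instruments
    (ASDS, GARS, GARS2, MCHAT) or a category string for categorical ones
    (CARS, GADS, ADOS).
    """

    instrument: str
    value: Union[float, str]
    age_at_test: Optional[float] = None


@dataclass
class Sentence:
    """A single pre-segmented sentence with its gold criterion labels."""

    sentence_id: str
    record_id: str
    ordinal: int
    text: str
    gold_labels: Set[Criterion] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ordinal < 0:
            raise ValueError(f"ordinal must be non-negative, got {self.ordinal}")
        self.gold_labels = {
            c if isinstance(c, Criterion) else parse_criterion(c) for c in self.gold_labels
        }


@dataclass
class Record:
    """One surveillance record: its sentences, gold case label, instruments."""

    record_id: str
    sentences: List[Sentence] = field(default_factory=list)
    gold_case: Optional[bool] = None
    instrument_results: List[InstrumentResult] = field(default_factory=list)

    @property
    def gold_criteria(self) -> Set[Criterion]:
        """Union of gold criterion labels over the record's sentences."""
        out: Set[Criterion] = set()
        for s in self.sentences:
            out |= s.gold_labels
        return out

    def gold_case_from_labels(self) -> bool:
        """Case label implied by the gold sentence labels via the DSM-5 rule."""
        return meets_dsm5_rule(self.gold_criteria)


@dataclass
class PredictionSet:
    """Sentence-level criterion labels assigned by one predictor.

    ``labels_by_sentence`` maps sentence_id to the assigned label set; a
    sentence absent from the map has the empty label set.
    """

    predictor_id: str
    labels_by_sentence: Dict[str, Set[Criterion]] = field(default_factory=dict)

    def labels_for(self, sentence_id: str) -> Set[Criterion]:
        return self.labels_by_sentence.get(sentence_id, set())

    def nonempty(self) -> Dict[str, Set[Criterion]]:
        """The mapping restricted to sentences with at least one label."""
        return {k: v for k, v in self.labels_by_sentence.items() if v}


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the derived margins.

    P/N are actual positives/negatives, PP/PN predicted positives/negatives.
    """

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP

    @property
    def PP(self) -> int:
        return self.TP + self.FP

    @property
    def PN(self) -> int:
        return self.TN + self.FN

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    """The five evaluation metrics; ``None`` marks an undefined (0/0) value."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]
    specificity: Optional[float]

    def as_dict(self, zero_fill: bool = False) -> Dict[str, Optional[float]]:
        """Plain-dict view; ``zero_fill`` prints undefined values as 0.0
        (the convention used when a predictor assigns no labels at all)."""
        d = {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
        }
        if zero_fill:
            d = {k: (0.0 if v is None else v) for k, v in d.items()}
        return d
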