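"""Synthetic labeled clinical-note corpora for end-to-end testing.

Real sentence-level DSM-5 annotations of surveillance records are not
redistributable, so this module generates corpora with the same *statistical
shape*: ~150 records of a few hundred sentences each, per-criterion labeled-
sentence prevalences in the 0.4%-2.5% range, roughly half of records meeting
the DSM-5 case rule, and sentence text built from criterion cue phrases
embedded in templated clinical filler.  Text realism is deliberately limited
to cue-phrase templating — the goal is a learnable, rule-matchable signal at
desk scale, not clinical fidelity.

Per-record label structure uses a criterion-activation model: each record
independently "activates" each criterion (a child either does or does not
exhibit that behavior class), and only active criteria emit labeled
sentences, at a within-record rate chosen so the configured *marginal*
prevalence is preserved.  Case labels are always derived from the realized
sentence labels via the DSM-5 rule — never forced — so the corpus validator
holds by construction and case balance is controlled only through the
activation probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    ALL_CRITERIA,
    A_CRITERIA,
    Criterion,
    InstrumentResult,
    PredictionSet,
    Record,
    Sentence,
    meets_dsm5_rule,
)

# Canonical cue phrasings per criterion (EHR-style wording); each phrasing is
# also covered by the shipped demo ruleset so the rule parser is a working
# predictor on generated corpora.
DEFAULT_CRITERION_LEXICONS: Dict[Criterion, Tuple[str, ...]] = {
    Criterion.A1: (
        "appeared indifferent to his peers",
        "has poor pragmatic language skills",
        "did not initiate any interactions",
        "does not respond to his name",
    ),
    Criterion.A2: (
        "does not make eye contact",
        "makes poor eye contact",
        "does not use gestures to communicate",
        "shows limited facial expressions",
    ),
    Criterion.A3: (
        "played by himself during free play",
        "prefers to play by himself",
        "has difficulty making friends",
        "shows no interest in other children",
    ),
    Criterion.B1: (
        "repeats the same sentence over and over",
        "repeats phrases that are said",
        "flaps his hands when excited",
        "lines up his toys in long rows",
    ),
    Criterion.B2: (
        "becomes very upset if the routine is changed",
        "insists on sameness at home and school",
        "has difficulty adapting to changing situations",
        "tantrums whenever the schedule changes",
    ),
    Criterion.B3: (
        "is fixated on superheroes",
        "plays with the same things over and over",
        "has an intense interest in road signs",
        "became preoccupied with spinning objects",
    ),
    Criterion.B4: (
        "is sensitive to unexpected noises",
        "covers his ears at loud sounds",
        "has unusual responses to sensory experiences",
        "avoids certain textures",
    ),
}

# Neutral clinical filler; contains no demo-ruleset cue term.
DEFAULT_BACKGROUND_PHRASES: Tuple[str, ...] = (
    "Reason for referral: developmental evaluation requested by the school.",
    "He was seen today for a follow-up visit.",
    "ARCHE Autism Evaluation.",
    "Vision and hearing screenings were within normal limits.",
    "Mother reported an unremarkable medical history.",
    "He walked happily into the exam room.",
    "Growth parameters were at the 50th percentile.",
    "The family recently moved to the area.",
    "Teacher reports he enjoys music class.",
    "He ate a full breakfast before the appointment.",
    "Immunizations are up to date.",
    "The clinic will send a copy of this report to the pediatrician.",
    "She smiled when greeted by the examiner.",
    "Standardized testing was attempted in the morning session.",
    "Father accompanied the child to the visit.",
)

_PREFIXES: Tuple[str, ...] = (
    "",
    "Mother reports that the child",
    "Teacher indicated that the child",
    "During the evaluation, the child",
    "Per parent report, the child",
    "At school, the child",
    "The examiner observed that the child",
)

# Table-scale marginal prevalences: per-criterion labeled-sentence
# proportions of a ~34k-sentence training corpus (0.4%-2.5%).
STUDY_PREVALENCE: Dict[Criterion, float] = {
    Criterion.A1: 855 / 34313,
    Criterion.A2: 471 / 34313,
    Criterion.A3: 524 / 34313,
    Criterion.B1: 539 / 34313,
    Criterion.B2: 338 / 34313,
    Criterion.B3: 146 / 34313,
    Criterion.B4: 697 / 34313,
}

# Per-record activation probabilities: A criteria common, B criteria less so,
# chosen so that roughly half of generated records *realize* the DSM-5 rule
# once within-record sampling losses are accounted for (low-prevalence
# criteria sometimes emit no sentence in an active record).
DEFAULT_ACTIVATION: Dict[Criterion, float] = {
    c: (0.91 if c in A_CRITERIA else 0.57) for c in ALL_CRITERIA
}


@dataclass
class SyntheticConfig:
    """Generator configuration; the seed fully determines the output."""

    n_records: int = 150
    sentences_per_record_mean: float = 229.0
    sentences_per_record_dispersion: float = 20.0  # negative-binomial shape
    prevalence: Mapping[Criterion, float] = field(
        default_factory=lambda: dict(STUDY_PREVALENCE)
    )
    activation: Mapping[Criterion, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATION)
    )
    criterion_lexicons: Mapping[Criterion, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_LEXICONS)
    )
    background_phrases: Sequence[str] = DEFAULT_BACKGROUND_PHRASES
    cue_noise: float = 0.02  # cue sentence left unlabeled (annotation noise)
    cross_talk: float = 0.02  # foreign cue phrase added to a labeled sentence
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.sentences_per_record_mean <= 0 or self.sentences_per_record_dispersion <= 0:
            raise ValueError("sentences_per_record parameters must be positive")
        total = 0.0
        for c in ALL_CRITERIA:
            p = float(self.prevalence.get(c, 0.0))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{c.value}] must be in [0,1], got {p}")
            total += p
            a = float(self.activation.get(c, 1.0))
            if not 0.0 < a <= 1.0 and p > 0:
                raise ValueError(f"activation[{c.value}] must be in (0,1], got {a}")
        if total > 1.0:
            raise ValueError(f"prevalences sum to {total:.3f} > 1")
        for name in ("cue_noise", "cross_talk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def small_config(seed: int = 0) -> SyntheticConfig:
    """Scaled-down preset for fast desk-scale runs and tests.

    Fewer, shorter records with boosted prevalences so each active criterion
    still realizes a few example sentences per record and each criterion has
    enough positive sentences (~100 in ~3800) to train on.
    """
    return SyntheticConfig(
        n_records=64,
        sentences_per_record_mean=60.0,
        sentences_per_record_dispersion=30.0,
        prevalence={
            Criterion.A1: 0.050,
            Criterion.A2: 0.045,
            Criterion.A3: 0.045,
            Criterion.B1: 0.040,
            Criterion.B2: 0.035,
            Criterion.B3: 0.030,
            Criterion.B4: 0.040,
        },
        seed=seed,
    )


def _sentence_text(
    rng: np.random.Generator,
    cues: List[str],
    cfg: SyntheticConfig,
) -> str:
    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    body = " and ".join(cues)
    if prefix:
        return f"{prefix} {body}."
    return body[0].upper() + body[1:] + "."


def generate_corpus(cfg: SyntheticConfig) -> List[Record]:
    """Generate a labeled corpus under ``cfg``; same seed, same corpus.

    Each record activates criteria independently; sentences of active
    criteria are drawn at a within-record rate ``prevalence / (activation *
    (1 - cue_noise))`` so the realized gold-label proportion matches the
    configured marginal prevalence.  ``gold_case`` is the DSM-5 rule applied
    to the realized gold labels.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    active_crits = [c for c in ALL_CRITERIA if cfg.prevalence.get(c, 0.0) > 0]
    within_rate: Dict[Criterion, float] = {}
    for c in active_crits:
        rate = cfg.prevalence[c] / (cfg.activation[c] * (1.0 - cfg.cue_noise))
        if rate > 1.0:
            raise ValueError(
                f"within-record rate for {c.value} exceeds 1 "
                f"(prevalence {cfg.prevalence[c]:.4f} / activation {cfg.activation[c]:.2f})"
            )
        within_rate[c] = rate

    # negative binomial via gamma-Poisson mixture
    shape = cfg.sentences_per_record_dispersion
    records: List[Record] = []
    for i in range(cfg.n_records):
        rid = f"r{i:04d}"
        lam = rng.gamma(shape, cfg.sentences_per_record_mean / shape)
        n_sent = max(5, int(rng.poisson(lam)))
        # keep criterion iteration in fixed list order: the rng draw for a
        # criterion must not depend on set-iteration order of the process
        active = [c for c in active_crits if rng.random() < cfg.activation[c]]
        sentences: List[Sentence] = []
        for j in range(n_sent):
            drawn = [c for c in active if rng.random() < within_rate[c]]
            gold = set(drawn)
            if drawn and rng.random() < cfg.cue_noise:
                gold = set()  # annotation noise: cue text, no gold label
            cues = [
                str(rng.choice(np.asarray(cfg.criterion_lexicons[c], dtype=object)))
                for c in drawn
            ]
            if drawn and rng.random() < cfg.cross_talk:
                others = [c for c in active_crits if c not in drawn]
                if others:
                    foreign = others[rng.integers(len(others))]
                    cues.append(
                        str(
                            rng.choice(
                                np.asarray(cfg.criterion_lexicons[foreign], dtype=object)
                            )
                        )
                    )
            if cues:
                text = _sentence_text(rng, cues, cfg)
            else:
                text = str(
                    rng.choice(np.asarray(cfg.background_phrases, dtype=object))
                )
            sentences.append(
                Sentence(
                    sentence_id=f"{rid}-s{j:04d}",
                    record_id=rid,
                    ordinal=j,
                    text=text,
                    gold_labels=gold,
                )
            )
        rec = Record(record_id=rid, sentences=sentences)
        rec.gold_case = rec.gold_case_from_labels()
        records.append(rec)
    return records


def case_balance(records: Sequence[Record]) -> float:
    """Fraction of records whose gold case label is ASD (balance report)."""
    if not records:
        return float("nan")
    return sum(1 for r in records if r.gold_case) / len(records)


def gold_prediction_set(records: Sequence[Record]) -> PredictionSet:
    """The gold labels viewed as a (perfect) PredictionSet."""
    pred = PredictionSet(predictor_id="gold")
    for rec in records:
        for sent in rec.sentences:
            if sent.gold_labels:
                pred.labels_by_sentence[sent.sentence_id] = set(sent.gold_labels)
    return pred


def degrade_predictions(
    gold: PredictionSet,
    fn_rate: float,
    fp_rate: float,
    seed: int,
    sentence_ids: Optional[Sequence[str]] = None,
) -> PredictionSet:
    """Noisy copy of a prediction set (seeded, reproducible).

    Each present (sentence, label) pair is dropped with ``fn_rate``; each
    absent pair over ``sentence_ids`` (default: the sentences present in
    ``gold``) is added with ``fp_rate``.
    """
    for name, v in (("fn_rate", fn_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    rng = np.random.default_rng(seed)
    universe = sorted(sentence_ids if sentence_ids is not None else gold.labels_by_sentence)
    out = PredictionSet(predictor_id=f"{gold.predictor_id}+noise")
    for sid in universe:
        present = gold.labels_for(sid)
        kept = set()
        for c in ALL_CRITERIA:
            if c in present:
                if rng.random() >= fn_rate:
                    kept.add(c)
            elif fp_rate > 0 and rng.random() < fp_rate:
                kept.add(c)
        if kept:
            out.labels_by_sentence[sid] = kept
    return out


def attach_instrument_results(
    records: Sequence[Record],
    seed: int,
    coverage: float = 0.85,
    agreement: float = 0.75,
) -> None:
    """Attach plausible diagnostic-instrument results in place.

    Each record receives 1-3 test administrations with probability
    ``coverage``; each administration agrees with the gold case label with
    probability ``agreement`` (instruments are imperfect, which is the point
    of the comparison).
    """
    rng = np.random.default_rng(seed)
    positive = {
        "ASDS": lambda: float(rng.integers(111, 131)),
        "GARS": lambda: float(rng.integers(111, 131)),
        "GARS2": lambda: float(rng.integers(85, 111)),
        "MCHAT": lambda: float(rng.integers(2, 9)),
        "CARS": lambda: str(rng.choice(["Severe", "Mild to Moderate", "NOS"])),
        "GADS": lambda: str(rng.choice(["High", "Probable"])),
        "ADOS": lambda: "ASD",
    }
    negative = {
        "ASDS": lambda: float(rng.integers(60, 90)),
        "GARS": lambda: float(rng.integers(50, 80)),
        "GARS2": lambda: float(rng.integers(50, 85)),
        "MCHAT": lambda: float(rng.integers(0, 2)),
        "CARS": lambda: "Not ASD",
        "GADS": lambda: str(rng.choice(["Not ASD", "Low"])),
        "ADOS": lambda: "Not ASD",
    }
    names = sorted(positive)
    for rec in records:
        rec.instrument_results = []
        if rng.random() >= coverage:
            continue
        gold = bool(rec.gold_case)
        for _ in range(int(rng.integers(1, 4))):
            inst = names[rng.integers(len(names))]
            agrees = rng.random() < agreement
            label = gold if agrees else not gold
            value = (positive if label else negative)[inst]()
            rec.instrument_results.append(
                InstrumentResult(
                    instrument=inst,
                    value=value,
                    age_at_test=float(np.round(rng.uniform(2.0, 9.0), 1)),
                )
            )


def simulate_redundancy(
    k: int,
    fn_rate: float,
    n_records: int = 200,
    seed: int = 0,
    fp_rate: float = 0.0,
) -> float:
    """Case-label accuracy when each present criterion has ``k`` examples.

    Builds abstract records (half meeting the DSM-5 rule), drops each
    criterion example independently with ``fn_rate``, relabels cases from
    the surviving labels, and returns the fraction of records whose case
    label is unchanged.  With independent misses, a criterion disappears
    only when all ``k`` of its examples are missed (probability
    ``fn_rate**k``), which is why case accuracy recovers quickly as
    redundancy grows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    a_list = sorted(A_CRITERIA, key=lambda c: c.value)
    b_list = sorted((c for c in ALL_CRITERIA if c not in A_CRITERIA),
                    key=lambda c: c.value)
    correct = 0
    for i in range(n_records):
        def pick_b(n: int) -> set:
            idx = rng.choice(len(b_list), size=n, replace=False)
            return {b_list[i] for i in idx}

        if rng.random() < 0.5:  # qualifying record
            crits = set(A_CRITERIA) | pick_b(int(rng.integers(2, 5)))
        else:  # non-qualifying: drop one A or keep <2 B
            if rng.random() < 0.5:
                a_drop = a_list[rng.integers(3)]
                crits = (set(A_CRITERIA) - {a_drop}) | pick_b(int(rng.integers(2, 5)))
            else:
                crits = set(A_CRITERIA) | pick_b(int(rng.integers(0, 2)))
        gold_case = meets_dsm5_rule(crits)
        surviving = set()
        for c in sorted(crits, key=lambda c: c.value):
            hits = int(np.sum(rng.random(k) >= fn_rate))
            if hits > 0:
                surviving.add(c)
        if fp_rate > 0:
            for c in ALL_CRITERIA:
                if c not in crits and rng.random() < 1 - (1 - fp_rate) ** k:
                    surviving.add(c)
        if meets_dsm5_rule(surviving) == gold_case:
            correct += 1
    return correct / n_records
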