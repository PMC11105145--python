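"""Rule-based sentence labeler: lexicon-driven pattern rules per criterion.

A rule is an ordered sequence of slots matched against the lowercased,
punctuation-stripped token sequence of a sentence:

* a bare word — literal token
* ``"quoted phrase"`` — literal contiguous token sequence
* ``@name`` — any phrase of the named lexicon (contiguous tokens)
* ``~N`` — a gap of up to N skipped tokens before the next slot

An optional ``!name`` guard names a lexicon whose presence anywhere in the
sentence blocks the rule (rule-local negation handling: negated and
affirmative cues are both criterion evidence, so polarity belongs to the
rule, not to a global negation detector).

File formats
------------
Lexicons (``*.lex``)::

    # comment
    [negation]
    not
    does not

    [eye_contact]
    eye contact

Rules (``*.rules``), one per line::

    A2_no_eye_contact  A2 : @negation ~4 @eye_contact
    A3_solitary_play   A3 : @play_verb ~2 @solitary !group_play

Matching is backtracking and exhaustive over slot alignments, so an
optimized engine must agree with a naive rule-by-rule scan.  Adding a rule
can only add labels (monotonicity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .types import Criterion, PredictionSet, Record, parse_criterion

_TOKEN_RE = re.compile(r"\S+")
_EDGE_PUNCT = ".,;:!?()[]{}\"'`“”‘’—–-…/\\"


class RuleSyntaxError(ValueError):
    """Raised for malformed rule / lexicon files or unresolved references."""


def tokenize(text: str) -> List[Tuple[str, int, int]]:
    """Lowercased tokens with character offsets; edge punctuation stripped."""
    out = []
    for m in _TOKEN_RE.finditer(text):
        raw, start = m.group(), m.start()
        tok = raw.strip(_EDGE_PUNCT)
        if not tok:
            continue
        lead = len(raw) - len(raw.lstrip(_EDGE_PUNCT))
        out.append((tok.lower(), start + lead, start + lead + len(tok)))
    return out


def _phrase_tokens(phrase: str) -> Tuple[str, ...]:
    return tuple(t for t, _, _ in tokenize(phrase))


@dataclass(frozen=True)
class Lexicon:
    """A named list of lowercase cue phrases (deduplicated, non-empty)."""

    name: str
    terms: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise RuleSyntaxError(f"lexicon {self.name!r} has no terms")
        lowered = tuple(dict.fromkeys(t.strip().lower() for t in self.terms if t.strip()))
        object.__setattr__(self, "terms", lowered)

    @property
    def token_phrases(self) -> Tuple[Tuple[str, ...], ...]:
        return tuple(_phrase_tokens(t) for t in self.terms)


@dataclass(frozen=True)
class LiteralSlot:
    tokens: Tuple[str, ...]


@dataclass(frozen=True)
class LexiconSlot:
    name: str


@dataclass(frozen=True)
class GapSlot:
    max_skip: int

    def __post_init__(self) -> None:
        if self.max_skip < 0:
            raise RuleSyntaxError(f"gap bound must be non-negative, got {self.max_skip}")


Slot = Union[LiteralSlot, LexiconSlot, GapSlot]


@dataclass(frozen=True)
class Rule:
    rule_id: str
    criterion: Criterion
    slots: Tuple[Slot, ...]
    guard: Optional[str] = None  # lexicon name blocking the match


@dataclass
class RuleSet:
    rules: List[Rule] = field(default_factory=list)
    lexicons: Dict[str, Lexicon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rules:
            if r.rule_id in seen:
                raise RuleSyntaxError(f"duplicate rule_id {r.rule_id!r}")
            seen.add(r.rule_id)
            for slot in r.slots:
                if isinstance(slot, LexiconSlot) and slot.name not in self.lexicons:
                    raise RuleSyntaxError(
                        f"rule {r.rule_id!r} references unknown lexicon {slot.name!r}"
                    )
            if r.guard is not None and r.guard not in self.lexicons:
                raise RuleSyntaxError(
                    f"rule {r.rule_id!r} guard references unknown lexicon {r.guard!r}"
                )

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_lexicons(self) -> int:
        return len(self.lexicons)


# ---------------------------------------------------------------------------
# DSL loading


def load_lexicons(path) -> Dict[str, Lexicon]:
    lexicons: Dict[str, Lexicon] = {}
    name: Optional[str] = None
    terms: List[str] = []

    def flush() -> None:
        nonlocal name, terms
        if name is not None:
            if name in lexicons:
                raise RuleSyntaxError(f"duplicate lexicon {name!r}")
            lexicons[name] = Lexicon(name=name, terms=tuple(terms))
        name, terms = None, []

    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            name = line[1:-1].strip()
            if not name:
                raise RuleSyntaxError(f"{path}:{lineno}: empty lexicon name")
        else:
            if name is None:
                raise RuleSyntaxError(f"{path}:{lineno}: term outside any [lexicon] section")
            terms.append(line)
    flush()
    return lexicons


_RULE_LINE_RE = re.compile(r"^(\S+)\s+(\S+)\s*:\s*(.*)$")
_SLOT_RE = re.compile(r'"([^"]+)"|(~\d+)|(@\S+)|(!\S+)|(\S+)')


def _parse_rule_line(line: str, where: str) -> Rule:
    m = _RULE_LINE_RE.match(line)
    if not m:
        raise RuleSyntaxError(f"{where}: expected 'rule_id CRITERION : slots', got {line!r}")
    rule_id, crit_str, body = m.groups()
    try:
        criterion = parse_criterion(crit_str)
    except ValueError as e:
        raise RuleSyntaxError(f"{where}: {e}") from None
    slots: List[Slot] = []
    guard: Optional[str] = None
    for sm in _SLOT_RE.finditer(body):
        quoted, gap, lexref, guardref, bare = sm.groups()
        if quoted is not None:
            toks = _phrase_tokens(quoted)
            if not toks:
                raise RuleSyntaxError(f"{where}: empty quoted phrase")
            slots.append(LiteralSlot(tokens=toks))
        elif gap is not None:
            slots.append(GapSlot(max_skip=int(gap[1:])))
        elif lexref is not None:
            slots.append(LexiconSlot(name=lexref[1:]))
        elif guardref is not None:
            if guard is not None:
                raise RuleSyntaxError(f"{where}: multiple guards")
            guard = guardref[1:]
        else:
            slots.append(LiteralSlot(tokens=_phrase_tokens(bare)))
    if not any(not isinstance(s, GapSlot) for s in slots):
        raise RuleSyntaxError(f"{where}: rule {rule_id!r} has no matchable slot")
    return Rule(rule_id=rule_id, criterion=criterion, slots=tuple(slots), guard=guard)


def load_ruleset(rules_path, lexicons_path) -> RuleSet:
    """Load and cross-resolve a rules file and a lexicons file."""
    lexicons = load_lexicons(lexicons_path)
    rules: List[Rule] = []
    for lineno, line in enumerate(
        Path(rules_path).read_text(encoding="utf-8").splitlines(), 1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rules.append(_parse_rule_line(line, where=f"{rules_path}:{lineno}"))
    return RuleSet(rules=rules, lexicons=lexicons)


def demo_ruleset() -> RuleSet:
    """The demonstration ruleset shipped with the package.

    Covers one or more rules per criterion, keyed to canonical EHR cue
    phrasings ("does not make eye contact", "played by himself", ...).  The
    engine, not this particular rule list, is the deliverable: production
    deployments supply their own rule and lexicon files.
    """
    base = resources.files("asdphen") / "rulesets"
    with resources.as_file(base / "demo.rules") as rp, resources.as_file(
        base / "demo.lex"
    ) as lp:
        return load_ruleset(rp, lp)


# ---------------------------------------------------------------------------
# matching


def _match_phrase(
    tokens: Sequence[Tuple[str, int, int]], i: int, phrase: Tuple[str, ...]
) -> bool:
    if i + len(phrase) > len(tokens):
        return False
    return all(tokens[i + k][0] == phrase[k] for k in range(len(phrase)))


def _match_slots(
    tokens: Sequence[Tuple[str, int, int]],
    i: int,
    slots: Tuple[Slot, ...],
    si: int,
    lexicons: Dict[str, Lexicon],
    spans: List[Tuple[int, int]],
) -> Optional[List[Tuple[int, int]]]:
    """Backtracking alignment of slots[si:] starting at token i."""
    if si == len(slots):
        return spans
    slot = slots[si]
    if isinstance(slot, GapSlot):
        for skip in range(slot.max_skip + 1):
            if i + skip > len(tokens):
                break
            got = _match_slots(tokens, i + skip, slots, si + 1, lexicons, spans)
            if got is not None:
                return got
        return None
    if isinstance(slot, LiteralSlot):
        options = [slot.tokens]
    else:
        options = sorted(lexicons[slot.name].token_phrases, key=len, reverse=True)
    for phrase in options:
        if _match_phrase(tokens, i, phrase):
            span = (tokens[i][1], tokens[i + len(phrase) - 1][2])
            got = _match_slots(
                tokens, i + len(phrase), slots, si + 1, lexicons, spans + [span]
            )
            if got is not None:
                return got
    return None


def _guard_blocks(tokens, rule: Rule, lexicons: Dict[str, Lexicon]) -> bool:
    if rule.guard is None:
        return False
    for phrase in lexicons[rule.guard].token_phrases:
        for i in range(len(tokens)):
            if _match_phrase(tokens, i, phrase):
                return True
    return False


def match_sentence(
    text: str, rs: RuleSet
) -> Tuple[Set[Criterion], List[Tuple[str, str, List[Tuple[int, int]]]]]:
    """Criteria whose rules match the sentence, with matched character spans.

    Returns ``(criteria, matches)`` where each match is
    ``(rule_id, criterion_code, [(start, end), ...])``.  Matching is
    case-insensitive over whitespace tokens; empty text yields an empty
    result.
    """
    tokens = tokenize(text)
    criteria: Set[Criterion] = set()
    matches: List[Tuple[str, str, List[Tuple[int, int]]]] = []
    for rule in rs.rules:
        if _guard_blocks(tokens, rule, rs.lexicons):
            continue
        for i in range(len(tokens) + 1):
            got = _match_slots(tokens, i, rule.slots, 0, rs.lexicons, [])
            if got is not None:
                criteria.add(rule.criterion)
                matches.append((rule.rule_id, rule.criterion.value, got))
                break
    return criteria, matches


def extract_lexicon_terms(text: str, rs: RuleSet) -> List[str]:
    """Lexicon terms present in the sentence, in order of first occurrence.

    Deduplicated by term string; used as the side input of the hybrid
    classifier.
    """
    tokens = tokenize(text)
    hits: List[Tuple[int, str]] = []
    seen: Set[str] = set()
    for lex in rs.lexicons.values():
        for term, phrase in zip(lex.terms, lex.token_phrases):
            if term in seen:
                continue
            for i in range(len(tokens)):
                if _match_phrase(tokens, i, phrase):
                    hits.append((i, term))
                    seen.add(term)
                    break
    hits.sort(key=lambda h: h[0])
    return [term for _, term in hits]


def all_lexicon_terms(rs: RuleSet) -> List[str]:
    """Sorted vocabulary of all lexicon terms (hybrid side-input features)."""
    out: Set[str] = set()
    for lex in rs.lexicons.values():
        out.update(lex.terms)
    return sorted(out)


def parse_corpus(records: Sequence[Record], rs: RuleSet) -> PredictionSet:
    """Apply :func:`match_sentence` to every sentence; predictor_id 'parser'."""
    pred = PredictionSet(predictor_id="parser")
    for rec in records:
        for sent in rec.sentences:
            criteria, _ = match_sentence(sent.text, rs)
            if criteria:
                pred.labels_by_sentence[sent.sentence_id] = criteria
    return pred
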