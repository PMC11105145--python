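"""Rule engine semantics: DSL loading, matching, spans, oracle agreement."""

import numpy as np
import pytest

import asdphen as ap
from asdphen.rules import (
    GapSlot,
    Lexicon,
    LexiconSlot,
    LiteralSlot,
    Rule,
    RuleSet,
    RuleSyntaxError,
    all_lexicon_terms,
    load_ruleset,
    tokenize,
)
from asdphen.synthetic import DEFAULT_CRITERION_LEXICONS

# Example sentences per criterion in typical EHR phrasing.
EXAMPLE_SENTENCES = {
    "A1": [
        "He appeared fairly indifferent to his peers and did not initiate any interactions.",
        "Both parent and teacher rate him as having poor pragmatic language skills.",
    ],
    "A2": [
        "Does not use appropriate social communication eye contact, etc..",
        "Does not make eye contact.",
    ],
    "A3": [
        "During free play, he played by himself with blocks and miniature replications of road signs.",
        "At home, mother reports he prefers to play by himself.",
    ],
    "B1": [
        "Mother's concerns include that she seems to repeat word a lot and will say the same sentence over and over and over again.",
        "She repeats phrases that are said. She is prone to engage in repetitive activities.",
    ],
    "B2": [
        "Both at home and school, he becomes very upset if the routine is changed.",
        "His mother reports that he has difficulty adapting to changing situations.",
    ],
    "B3": [
        "She became fixated on her simple back and forth movement with the objects.",
        "She plays with the same things over and over she is described to be fixated on superheroes",
    ],
    "B4": [
        "He was observed to be sensitive to unexpected noises by covering his ears.",
        "He demonstrates unusual responses to sensory experiences.",
    ],
}


def oracle_match(text: str, rule: Rule, rs: RuleSet) -> bool:
    """Breadth-first reachable-position matcher (independent of the engine's
    backtracking implementation)."""
    toks = [t for t, _, _ in tokenize(text)]
    if rule.guard is not None:
        for ph in rs.lexicons[rule.guard].token_phrases:
            for i in range(len(toks)):
                if toks[i : i + len(ph)] == list(ph):
                    return False
    for start in range(len(toks) + 1):
        cur = {start}
        for slot in rule.slots:
            nxt = set()
            for i in cur:
                if isinstance(slot, GapSlot):
                    nxt.update(
                        i + k for k in range(slot.max_skip + 1) if i + k <= len(toks)
                    )
                else:
                    options = (
                        [slot.tokens]
                        if isinstance(slot, LiteralSlot)
                        else rs.lexicons[slot.name].token_phrases
                    )
                    for ph in options:
                        if toks[i : i + len(ph)] == list(ph):
                            nxt.add(i + len(ph))
            cur = nxt
            if not cur:
                break
        if cur:
            return True
    return False


def oracle_criteria(text: str, rs: RuleSet):
    return {r.criterion for r in rs.rules if oracle_match(text, r, rs)}


class TestLoading:
    def test_demo_ruleset_covers_every_criterion(self, demo_rs):
        assert demo_rs.n_rules >= 7
        covered = {r.criterion for r in demo_rs.rules}
        assert covered == set(ap.ALL_CRITERIA)

    def test_unresolved_lexicon_names_rule(self, tmp_path):
        (tmp_path / "r.rules").write_text("R1 A1 : @missing\n")
        (tmp_path / "l.lex").write_text("[other]\nterm\n")
        with pytest.raises(RuleSyntaxError, match="R1"):
            load_ruleset(tmp_path / "r.rules", tmp_path / "l.lex")

    def test_duplicate_rule_id_rejected(self, tmp_path):
        (tmp_path / "r.rules").write_text("R1 A1 : @lex\nR1 A2 : @lex\n")
        (tmp_path / "l.lex").write_text("[lex]\nterm\n")
        with pytest.raises(RuleSyntaxError, match="duplicate rule_id"):
            load_ruleset(tmp_path / "r.rules", tmp_path / "l.lex")

    def test_empty_lexicon_rejected(self):
        with pytest.raises(RuleSyntaxError, match="no terms"):
            Lexicon(name="x", terms=())


class TestMatching:
    @pytest.mark.parametrize(
        "criterion,text",
        [(c, t) for c, texts in EXAMPLE_SENTENCES.items() for t in texts],
    )
    def test_example_sentences_receive_their_criterion(self, demo_rs, criterion, text):
        got, matches = ap.match_sentence(text, demo_rs)
        assert ap.Criterion(criterion) in got
        # spans point at real character offsets of the matched text
        for _, _, spans in matches:
            for start, end in spans:
                assert 0 <= start < end <= len(text)

    def test_negated_eye_contact_labeled_a2(self, demo_rs):
        got, _ = ap.match_sentence("Does not make eye contact.", demo_rs)
        assert got == {ap.Criterion.A2}

    def test_empty_text_empty_result(self, demo_rs):
        assert ap.match_sentence("", demo_rs) == (set(), [])

    def test_multi_criterion_sentence_gets_both_labels(self, demo_rs):
        text = "He prefers to play by himself and is fixated on superheroes."
        got, _ = ap.match_sentence(text, demo_rs)
        assert {ap.Criterion.A3, ap.Criterion.B3} <= got
        assert got == oracle_criteria(text, demo_rs)

    def test_gap_bound_is_respected(self):
        rs = RuleSet(
            rules=[Rule("g", ap.Criterion.A1,
                        (LiteralSlot(("a",)), GapSlot(2), LiteralSlot(("b",))))],
            lexicons={},
        )
        assert ap.match_sentence("a x x b", rs)[0] == {ap.Criterion.A1}
        assert ap.match_sentence("a x x x b", rs)[0] == set()

    def test_guard_lexicon_blocks_match(self):
        rs = RuleSet(
            rules=[Rule("solo", ap.Criterion.A3,
                        (LexiconSlot("play"), GapSlot(2), LexiconSlot("alone")),
                        guard="group")],
            lexicons={
                "play": Lexicon("play", ("plays", "played")),
                "alone": Lexicon("alone", ("by himself", "alone")),
                "group": Lexicon("group", ("with peers",)),
            },
        )
        assert ap.match_sentence("He plays by himself.", rs)[0] == {ap.Criterion.A3}
        assert ap.match_sentence("He plays by himself or with peers.", rs)[0] == set()

    def test_matching_is_case_and_punctuation_insensitive(self, demo_rs):
        got, _ = ap.match_sentence("DOES NOT MAKE EYE CONTACT!!!", demo_rs)
        assert ap.Criterion.A2 in got

    def test_generator_cues_are_parseable(self, demo_rs):
        for criterion, cues in DEFAULT_CRITERION_LEXICONS.items():
            for cue in cues:
                got, _ = ap.match_sentence(cue, demo_rs)
                assert criterion in got, (criterion, cue)


class TestOracleEquivalence:
    def test_engine_equals_naive_scan_on_random_sentences(self, demo_rs):
        rng = np.random.default_rng(7)
        pool = []
        for lex in demo_rs.lexicons.values():
            for term in lex.terms:
                pool.extend(term.split())
        filler = ["the", "child", "was", "seen", "today", "school", "visit",
                  "report", "normal", "mother", "notes", "clinic"]
        vocab = pool + filler
        for _ in range(300):
            n = int(rng.integers(1, 15))
            words = [vocab[rng.integers(len(vocab))] for _ in range(n)]
            if rng.random() < 0.5:  # splice in a full lexicon phrase
                lex = list(demo_rs.lexicons.values())[rng.integers(demo_rs.n_lexicons)]
                words[rng.integers(n) :][:0] = lex.terms[
                    rng.integers(len(lex.terms))
                ].split()
            text = " ".join(words)
            got, _ = ap.match_sentence(text, demo_rs)
            assert got == oracle_criteria(text, demo_rs), text

    def test_adding_a_rule_never_removes_labels(self, demo_rs):
        texts = [t for ts in EXAMPLE_SENTENCES.values() for t in ts]
        extra = Rule("extra", ap.Criterion.B4, (LiteralSlot(("today",)),))
        bigger = RuleSet(rules=demo_rs.rules + [extra], lexicons=dict(demo_rs.lexicons))
        for text in texts:
            before, _ = ap.match_sentence(text, demo_rs)
            after, _ = ap.match_sentence(text, bigger)
            assert before <= after


class TestLexiconTerms:
    def test_no_terms_empty_list(self, demo_rs):
        assert ap.extract_lexicon_terms("the weather was pleasant", demo_rs) == []

    def test_direct_lookup(self, demo_rs):
        terms = ap.extract_lexicon_terms("he repeats phrases that are said", demo_rs)
        assert "repeats" in terms

    def test_terms_deduplicated_in_first_occurrence_order(self, demo_rs):
        text = "no eye contact and no eye contact again with poor eye contact"
        terms = ap.extract_lexicon_terms(text, demo_rs)
        assert terms.count("eye contact") == 1
        assert terms.index("no") < terms.index("eye contact")

    def test_vocabulary_is_sorted_union(self, demo_rs):
        vocab = all_lexicon_terms(demo_rs)
        assert vocab == sorted(vocab)
        assert "eye contact" in vocab


class TestParseCorpus:
    def test_empty_ruleset_labels_nothing(self, small_corpus):
        rs = RuleSet(rules=[], lexicons={})
        pred = ap.parse_corpus(small_corpus[:3], rs)
        assert pred.labels_by_sentence == {}

    def test_agrees_with_match_sentence(self, small_corpus, demo_rs):
        records = small_corpus[:3]
        pred = ap.parse_corpus(records, demo_rs)
        assert pred.predictor_id == "parser"
        for rec in records:
            for sent in rec.sentences:
                expect, _ = ap.match_sentence(sent.text, demo_rs)
                assert pred.labels_for(sent.sentence_id) == expect
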