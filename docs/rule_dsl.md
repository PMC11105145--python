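# Rule DSL

The rule-based parser is driven by two plain-text files: a **lexicon file**
defining named term lists and a **rule file** defining per-criterion
patterns over those lists.

## Grammar

```
lexicon-file   ::= (comment | blank | section)*
section        ::= "[" name "]" NEWLINE (term NEWLINE)+
term           ::= phrase                      ; one phrase per line

rule-file      ::= (comment | blank | rule)*
rule           ::= rule-id WS criterion WS ":" WS slot+ guard? NEWLINE
criterion      ::= "A1" | "A2" | "A3" | "B1" | "B2" | "B3" | "B4"
slot           ::= literal | quoted | lexref | gap
literal        ::= WORD                        ; single literal token
quoted         ::= '"' phrase '"'              ; literal token sequence
lexref         ::= "@" name                    ; any phrase of the lexicon
gap            ::= "~" INTEGER                 ; skip up to N tokens
guard          ::= "!" name                    ; blocking lexicon

comment        ::= "#" ...
phrase         ::= WORD (WS WORD)*
```

## Matching semantics

* Sentences are tokenized on whitespace; tokens are lowercased and stripped
  of leading/trailing punctuation. Matching is therefore case- and
  punctuation-insensitive.
* A rule matches if its slots align, in order, with consecutive tokens
  starting at any position. A gap slot `~N` permits zero to N skipped
  tokens before the next slot. Alignment is backtracking and exhaustive, so
  an engine optimization can never change the result of a naive
  rule-by-rule scan.
* A lexicon slot matches any of its phrases as a contiguous token sequence.
* A guard (`!name`) blocks the rule whenever any phrase of the guard
  lexicon occurs anywhere in the sentence. Guards are per-rule because
  polarity is evidence-specific: "does not make eye contact" is positive
  A2 evidence, so a global negation detector would be wrong.
* A sentence receives a criterion label iff at least one of that
  criterion's rules matches; multiple criteria may match one sentence.

## Example

```
# lexicons
[negation]
not
does not

[eye_contact]
eye contact

# rules
A2_no_eye_contact  A2 : @negation ~4 @eye_contact
```

matches "Does not use appropriate social communication eye contact" (four
skipped tokens between the negation and the lexicon phrase).

The shipped demo ruleset (`src/asdphen/rulesets/demo.{rules,lex}`) covers
typical EHR cue phrasings for all seven criteria. It is a demonstration:
the engine and the DSL are the deliverable, and production deployments are
expected to supply their own, much larger, rule and lexicon files.
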