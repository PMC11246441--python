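"""Packaged worked example for the pattern-derivation algorithm.

The sentence "sciatica in low back pain is usually caused by disc
herniation" with its gold basic-UD parse is the canonical walk-through: the
shortest dependency path from "sciatica" to "herniation" drops everything
off the path ("in low back pain", "is usually", the bare "by disc") and
linearizes to::

    [symptom placeholder] : <nsubjpass : lemm=cause : >nmod_by : [disease placeholder]

Matching the derived pattern back on the sentence captures one pair, with
the etiology phrase-expanded to "disc herniation".
"""

from __future__ import annotations

from .corpus import ParsedSentence, Token

SCIATICA_PATTERN_TEXT = (
    "[symptom placeholder] : <nsubjpass : lemm=cause : >nmod_by : "
    "[disease placeholder]"
)


def sciatica_example_sentence() -> ParsedSentence:
    """Gold parse of the worked-example sentence."""
    rows = [
        # index, surface, lemma, upos, head, deprel
        (1, "sciatica", "sciatica", "NOUN", 8, "nsubjpass"),
        (2, "in", "in", "ADP", 5, "case"),
        (3, "low", "low", "ADJ", 5, "amod"),
        (4, "back", "back", "NOUN", 5, "compound"),
        (5, "pain", "pain", "NOUN", 1, "nmod"),
        (6, "is", "be", "AUX", 8, "auxpass"),
        (7, "usually", "usually", "ADV", 8, "advmod"),
        (8, "caused", "cause", "VERB", 0, "root"),
        (9, "by", "by", "ADP", 11, "case"),
        (10, "disc", "disc", "NOUN", 11, "compound"),
        (11, "herniation", "herniation", "NOUN", 8, "nmod"),
    ]
    return ParsedSentence(
        sent_id="sciatica-example",
        doc_id="examples",
        tokens=tuple(Token(*row) for row in rows),
    )
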