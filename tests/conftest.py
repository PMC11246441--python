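import random

import pytest
from hypothesis import settings

from etiominer.corpus import Corpus, ParsedSentence, Token
from etiominer.examples import sciatica_example_sentence

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def sciatica_sentence() -> ParsedSentence:
    return sciatica_example_sentence()


def random_tree_sentence(rng: random.Random, n: int, sent_id: str = "rand") -> ParsedSentence:
    """A random dependency tree over ``n`` tokens (uniform attachment)."""
    order = list(range(1, n + 1))
    rng.shuffle(order)
    head_of = {order[0]: 0}
    for pos, idx in enumerate(order[1:], start=1):
        head_of[idx] = order[rng.randrange(pos)]
    deprels = ["nsubj", "dobj", "nmod", "amod", "compound", "advmod", "conj"]
    tokens = tuple(
        Token(
            index=i,
            surface=f"w{i}",
            lemma=f"w{i}",
            upos="NOUN",
            head=head_of[i],
            deprel="root" if head_of[i] == 0 else rng.choice(deprels),
        )
        for i in range(1, n + 1)
    )
    return ParsedSentence(sent_id, "random", tokens)


def flat_sentence(text: str, sent_id: str) -> ParsedSentence:
    """A syntax-free sentence (first token root, rest attached flat)."""
    words = text.split()
    tokens = tuple(
        Token(
            index=i,
            surface=w,
            lemma=w.lower(),
            upos="PUNCT" if not any(ch.isalnum() for ch in w) else "NOUN",
            head=0 if i == 1 else 1,
            deprel="root" if i == 1 else "dep",
        )
        for i, w in enumerate(words, start=1)
    )
    return ParsedSentence(sent_id, "flat", tokens)


def flat_corpus(texts: list[str]) -> Corpus:
    return Corpus([flat_sentence(t, f"flat{i}") for i, t in enumerate(texts)])
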