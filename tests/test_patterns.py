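import random

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from etiominer.corpus import Corpus, ParsedSentence, Token, search_cooccurrence
from etiominer.errors import PatternParseError
from etiominer.examples import SCIATICA_PATTERN_TEXT
from etiominer.patterns import (
    PatternElement,
    SyntacticPattern,
    expand_phrase,
    generate_pattern,
    linearize,
    load_patterns,
    match,
    parse_pattern,
    save_patterns,
    shortest_dependency_path,
)
from etiominer.synthetic import (
    CAUSAL_TEMPLATES,
    DEFAULT_ETIOLOGIES,
    DEFAULT_SYMPTOMS,
    GeneratorConfig,
    generate,
)

from conftest import random_tree_sentence


class TestShortestPath:
    def test_worked_example_path(self, sciatica_sentence):
        path = shortest_dependency_path(sciatica_sentence, 1, 11)
        assert path.nodes == (1, 8, 11)
        assert path.edges == (("nsubjpass", "up"), ("nmod", "down"))

    def test_directly_governed_pair(self, sciatica_sentence):
        path = shortest_dependency_path(sciatica_sentence, 10, 11)
        assert path.nodes == (10, 11)
        assert path.edges == (("compound", "up"),)

    def test_matches_bfs_oracle_on_random_trees(self):
        rng = random.Random(11)
        for trial in range(10):
            sent = random_tree_sentence(rng, 12, f"p{trial}")
            graph = nx.Graph(
                (t.index, t.head) for t in sent.tokens if t.head != 0
            )
            for _ in range(20):
                a, b = rng.sample(range(1, 13), 2)
                ours = shortest_dependency_path(sent, a, b)
                oracle = nx.shortest_path(graph, a, b)
                assert list(ours.nodes) == oracle

    def test_identical_endpoints_rejected(self, sciatica_sentence):
        with pytest.raises(ValueError):
            shortest_dependency_path(sciatica_sentence, 3, 3)


class TestGeneratePattern:
    def test_worked_example_linearization(self, sciatica_sentence):
        pattern = generate_pattern(sciatica_sentence, (1, 1), (10, 11))
        assert pattern.text_form == SCIATICA_PATTERN_TEXT
        assert not pattern.anchor_free
        assert pattern.source_sent_id == "sciatica-example"

    def test_off_path_tokens_never_appear(self, sciatica_sentence):
        pattern = generate_pattern(sciatica_sentence, (1, 1), (10, 11))
        for word in ("pain", "low", "back", "usually", "be", "disc"):
            assert word not in pattern.text_form

    def test_directly_connected_endpoints_anchor_free(self):
        # "sciatica with herniation": herniation nmod-> sciatica (case "with")
        tokens = (
            Token(1, "sciatica", "sciatica", "NOUN", 0, "root"),
            Token(2, "with", "with", "ADP", 3, "case"),
            Token(3, "herniation", "herniation", "NOUN", 1, "nmod"),
        )
        sent = ParsedSentence("trap", "", tokens)
        pattern = generate_pattern(sent, (1, 1), (3, 3))
        assert pattern.anchor_free
        assert pattern.text_form == (
            "[symptom placeholder] : >nmod_with : [disease placeholder]"
        )

    def test_induce_template_pattern(self):
        config = GeneratorConfig(
            n_sentences=1,
            symptom_vocab=("sciatica",),
            etiology_vocab=("endometriosis",),
            template_mix={"induce": 1.0},
            noise_rate=0.0,
            abbrev_rate=0.0,
            rng_seed=7,
        )
        corpus, gold = generate(config)
        ((sid, s_span, e_span, _),) = gold.relations
        pattern = generate_pattern(corpus.sentence(sid), s_span, e_span)
        assert pattern.text_form == (
            "[symptom placeholder] : <dobj : lemm=induce : >nsubj : "
            "[disease placeholder]"
        )

    def test_length_matches_bfs_oracle(self):
        rng = random.Random(3)
        for trial in range(10):
            sent = random_tree_sentence(rng, 9, f"len{trial}")
            graph = nx.Graph((t.index, t.head) for t in sent.tokens if t.head != 0)
            a, b = rng.sample(range(1, 10), 2)
            pattern = generate_pattern(sent, (a, a), (b, b))
            n_nodes = len(nx.shortest_path(graph, a, b))
            # elements = nodes + edges = 2*n_nodes - 1
            assert len(pattern.elements) == 2 * n_nodes - 1


_LABELS = ["nsubj", "nsubjpass", "dobj", "nmod", "nmod_by", "nmod_with", "amod", "conj"]
_pattern_strategy = st.builds(
    lambda reverse, steps: _build_pattern(reverse, steps),
    st.booleans(),
    st.lists(
        st.tuples(
            st.sampled_from(_LABELS),
            st.sampled_from(["up", "down"]),
            st.from_regex(r"[a-z]{1,8}", fullmatch=True),
        ),
        min_size=1,
        max_size=4,
    ),
)


def _build_pattern(reverse: bool, steps) -> SyntacticPattern:
    roles = ("etiology", "symptom") if reverse else ("symptom", "etiology")
    elements = [PatternElement(kind="placeholder", role=roles[0])]
    for pos, (label, direction, lemma) in enumerate(steps):
        elements.append(PatternElement(kind="edge", label=label, direction=direction))
        if pos < len(steps) - 1:
            elements.append(PatternElement(kind="anchor", lemma=lemma))
    elements.append(PatternElement(kind="placeholder", role=roles[1]))
    return SyntacticPattern(tuple(elements))


class TestLinearization:
    def test_worked_example_round_trip(self):
        assert parse_pattern(SCIATICA_PATTERN_TEXT).text_form == SCIATICA_PATTERN_TEXT

    @pytest.mark.parametrize(
        "bad",
        ["", "   ", "[symptom placeholder]", "lemm=cause : >nmod",
         "[symptom placeholder] : nsubj : [disease placeholder]",
         "[symptom placeholder] : <nsubj : [symptom placeholder]"],
    )
    def test_malformed_text_rejected(self, bad):
        with pytest.raises(PatternParseError):
            parse_pattern(bad)

    @given(_pattern_strategy)
    def test_parse_linearize_identity(self, pattern):
        round_tripped = parse_pattern(linearize(pattern))
        assert round_tripped.elements == pattern.elements

    def test_pattern_file_round_trip(self, tmp_path):
        patterns = [
            parse_pattern(SCIATICA_PATTERN_TEXT),
            parse_pattern("[symptom placeholder] : <dobj : lemm=induce : >nsubj : [disease placeholder]"),
        ]
        path = tmp_path / "patterns.txt"
        save_patterns(patterns, path)
        path.write_text("# a comment\n" + path.read_text())
        loaded = load_patterns(path)
        assert [p.text_form for p in loaded] == [p.text_form for p in patterns]


class TestMatch:
    def test_worked_example_capture_expanded(self, sciatica_sentence):
        pattern = parse_pattern(SCIATICA_PATTERN_TEXT)
        captures = match(pattern, sciatica_sentence)
        assert len(captures) == 1
        cap = captures[0]
        assert cap.symptom_text == "sciatica"
        assert cap.etiology_text == "disc herniation"
        assert (cap.symptom_head, cap.etiology_head) == (1, 11)

    def test_missing_anchor_lemma_no_match(self, sciatica_sentence):
        pattern = parse_pattern(
            "[symptom placeholder] : <nsubjpass : lemm=provoke : >nmod_by : "
            "[disease placeholder]"
        )
        assert match(pattern, sciatica_sentence) == []

    def test_case_suffix_requires_matching_case_child(self, sciatica_sentence):
        pattern = parse_pattern(
            "[symptom placeholder] : <nsubjpass : lemm=cause : >nmod_with : "
            "[disease placeholder]"
        )
        assert match(pattern, sciatica_sentence) == []

    def test_gold_template_sentences_exactly_matched(self):
        """A template's pattern matches exactly the sentences instantiating it."""
        corpus, gold = generate(GeneratorConfig(n_sentences=50, rng_seed=9))
        by_template: dict[str, set[str]] = {}
        pattern_of: dict[str, str] = {}
        for sid, s_span, e_span, template in gold.relations:
            by_template.setdefault(template, set()).add(sid)
            pattern_of.setdefault(
                template,
                generate_pattern(corpus.sentence(sid), s_span, e_span).text_form,
            )
        for template, expected_ids in by_template.items():
            pattern = parse_pattern(pattern_of[template])
            matched = {s.sent_id for s in corpus if match(pattern, s)}
            assert matched == expected_ids, template

    def test_generation_matching_round_trip_on_corpus(self):
        """match(generate_pattern(m), m.sentence) recovers m's span heads."""
        from etiominer.corpus import head_of_span

        corpus, _ = generate(GeneratorConfig(n_sentences=120, rng_seed=21))
        n_checked = 0
        for symptom in DEFAULT_SYMPTOMS:
            for etiology in DEFAULT_ETIOLOGIES:
                for m in search_cooccurrence(corpus, symptom, etiology):
                    pattern = generate_pattern(m.sentence, m.span_a, m.span_b)
                    heads = {
                        (c.symptom_head, c.etiology_head)
                        for c in match(pattern, m.sentence)
                    }
                    expected = (
                        head_of_span(m.sentence, m.span_a),
                        head_of_span(m.sentence, m.span_b),
                    )
                    assert expected in heads
                    n_checked += 1
        assert n_checked > 50


class TestExpandPhrase:
    def test_compound_child(self, sciatica_sentence):
        assert expand_phrase(sciatica_sentence, 11) == (10, 11)

    def test_token_without_dependents(self, sciatica_sentence):
        assert expand_phrase(sciatica_sentence, 10) == (10, 10)

    def test_case_marked_nmod_not_absorbed(self, sciatica_sentence):
        # "sciatica" has an nmod dependent "pain", but with a case child "in"
        assert expand_phrase(sciatica_sentence, 1) == (1, 1)

    def test_contiguity_break_stops_expansion(self):
        # "disc , lumbar herniation": "disc" attaches to "herniation" but the
        # intervening comma is outside the subtree, breaking contiguity
        tokens = (
            Token(1, "disc", "disc", "NOUN", 4, "compound"),
            Token(2, ",", ",", "PUNCT", 4, "punct"),
            Token(3, "lumbar", "lumbar", "ADJ", 4, "amod"),
            Token(4, "herniation", "herniation", "NOUN", 0, "root"),
        )
        sent = ParsedSentence("gap", "", tokens)
        assert expand_phrase(sent, 4) == (3, 4)
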