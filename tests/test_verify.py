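import pytest

from etiominer.corpus import Corpus
from etiominer.synthetic import GeneratorConfig, generate
from etiominer.verify import (
    GENERATION_PROMPT,
    RANKING_PROMPT,
    VETTING_PROMPT,
    DecodingParams,
    EvidenceCandidate,
    MockBackend,
    RetrievalConfig,
    TfidfEmbedder,
    generate_etiologies,
    rank_evidence,
    retrieve_evidence,
    verify_all,
    vet_evidence,
)

from conftest import flat_corpus


class TestPrompts:
    def test_generation_prompt_rare_etiologies_clause(self):
        prompt = GENERATION_PROMPT.format(symptom="sciatica")
        assert "even the most rare ones" in prompt
        assert "sciatica etiologies" in prompt
        assert prompt.endswith("write done when you finish listing all etiologies.")

    def test_ranking_prompt_membership_clause(self):
        prompt = RANKING_PROMPT.format(etiology="x", symptom="y", sentences="s")
        assert "Only select sentences from the list below, do not add new sentences." in prompt
        assert "which 3 sentences" in prompt
        assert "0 sentences (an empty list)" in prompt

    def test_vetting_prompt_succinct_clause(self):
        prompt = VETTING_PROMPT.format(etiology="x", symptom="y", sentence="z")
        assert "reply with yes or no only" in prompt

    def test_decoding_defaults(self):
        params = DecodingParams()
        assert (params.temperature, params.max_tokens, params.top_p) == (1.0, 4096, 1.0)


class TestGenerateEtiologies:
    def test_parses_names_and_strips_done(self):
        backend = MockBackend(lambda p: "disc herniation\npiriformis syndrome\ndone")
        assert generate_etiologies("sciatica", backend) == [
            "disc herniation",
            "piriformis syndrome",
        ]

    def test_case_insensitive_dedup_keeps_first(self):
        backend = MockBackend(lambda p: "Lymphoma\nlymphoma\ndone")
        assert generate_etiologies("jaundice", backend) == ["Lymphoma"]

    def test_bullets_and_blanks_stripped(self):
        backend = MockBackend(lambda p: "- gout\n\n2) sepsis\n* flu\nDone.")
        assert generate_etiologies("fever", backend) == ["gout", "sepsis", "flu"]

    def test_best_of_runs_by_count(self):
        responses = iter(["a\ndone", "a\nb\nc\ndone", "a\nb\ndone"])
        backend = MockBackend(lambda p: next(responses))
        assert generate_etiologies("x", backend, n_runs=3) == ["a", "b", "c"]


_TOY_TEXTS = [
    "sciatica is often caused by disc herniation in adults .",
    "disc herniation rarely presents without sciatica .",
    "jaundice follows hepatitis infection .",
    "low back pain is common in runners .",
    "an etiology survey of sciatica found many causes .",
]


class TestRetrieveEvidence:
    def test_hard_constraints_keep_only_dual_phrase_sentences(self):
        corpus = flat_corpus(_TOY_TEXTS)
        candidates = retrieve_evidence("sciatica", "disc herniation", corpus)
        assert {c.sent_id for c in candidates} == {"flat0", "flat1"}
        for c in candidates:
            assert "sciatica" in c.sentence_text.lower()
            assert "disc herniation" in c.sentence_text.lower()

    def test_without_constraints_all_sentences_survive(self):
        corpus = flat_corpus(_TOY_TEXTS)
        config = RetrievalConfig(hard_constraints=False)
        candidates = retrieve_evidence("sciatica", "disc herniation", corpus, config)
        assert len(candidates) == 5

    def test_top_n_equals_brute_force_max(self):
        corpus = flat_corpus(_TOY_TEXTS)
        config = RetrievalConfig(top_n=1, hard_constraints=False)
        (best,) = retrieve_evidence("sciatica", "disc herniation", corpus, config)
        scores = TfidfEmbedder().score(
            "an etiology for sciatica", [s.text for s in corpus]
        )
        oracle = max(
            zip(scores, (s.sent_id for s in corpus)), key=lambda t: (t[0], t[1])
        )
        assert best.score == pytest.approx(oracle[0])

    def test_ties_broken_by_sent_id(self):
        corpus = flat_corpus(["alpha beta .", "alpha beta ."])
        candidates = retrieve_evidence(
            "gamma", "delta", corpus, RetrievalConfig(hard_constraints=False)
        )
        assert [c.sent_id for c in candidates] == ["flat0", "flat1"]


def _candidates(texts):
    return [EvidenceCandidate(t, f"c{i}", 1.0 - 0.1 * i) for i, t in enumerate(texts)]


class TestRankEvidence:
    def test_three_valid_items(self):
        cands = _candidates(["s one", "s two", "s three", "s four"])
        response = repr(
            [{"sent": c.sentence_text, "reason": f"r{i}"} for i, c in enumerate(cands[:3])]
        )
        ranked = rank_evidence("x", "y", cands, MockBackend(lambda p: response))
        assert [s for s, _ in ranked] == ["s one", "s two", "s three"]

    def test_fabricated_sentence_dropped(self):
        cands = _candidates(["s one", "s two"])
        response = repr(
            [
                {"sent": "s one", "reason": "a"},
                {"sent": "invented out of thin air", "reason": "b"},
                {"sent": "s two", "reason": "c"},
            ]
        )
        ranked = rank_evidence("x", "y", cands, MockBackend(lambda p: response))
        assert [s for s, _ in ranked] == ["s one", "s two"]

    def test_empty_array_allowed(self):
        ranked = rank_evidence("x", "y", _candidates(["s"]), MockBackend(lambda p: "[]"))
        assert ranked == []

    def test_unparseable_response_yields_empty_not_crash(self):
        backend = MockBackend(lambda p: "I'd rather chat about the weather.")
        assert rank_evidence("x", "y", _candidates(["s"]), backend) == []

    def test_code_fences_tolerated(self):
        response = '```python\n[{"sent": "s", "reason": "r"}]\n```'
        ranked = rank_evidence("x", "y", _candidates(["s"]), MockBackend(lambda p: response))
        assert ranked == [("s", "r")]

    def test_no_candidates_short_circuits(self):
        backend = MockBackend(lambda p: (_ for _ in ()).throw(AssertionError))
        assert rank_evidence("x", "y", [], backend) == []


class TestVetEvidence:
    @pytest.mark.parametrize(
        ("response", "verdict"),
        [("Yes.", "yes"), ("no", "no"), ("YES", "yes"), ("It depends", "no")],
    )
    def test_normalization(self, response, verdict):
        backend = MockBackend(lambda p: response)
        assert vet_evidence("x", "y", "s", backend) == verdict


def _pipeline_backend():
    def responder(prompt: str) -> str:
        if prompt.startswith("Provide an exhaustive list"):
            return "disc herniation\nhepatitis\nunicorn fever\ndone"
        if prompt.startswith("From the list of sentences"):
            sentences = prompt.rsplit("\n\n", 1)[1].splitlines()
            return repr([{"sent": s, "reason": "explicit"} for s in sentences[:2]])
        if prompt.startswith("Can the following sentence"):
            return "no" if "hepatitis" in prompt else "yes"
        raise AssertionError(f"unexpected prompt: {prompt[:40]}")

    return MockBackend(responder)


class TestVerifyAll:
    def _corpus(self):
        corpus, _ = generate(GeneratorConfig(n_sentences=50, rng_seed=5))
        return corpus

    def test_funnel_and_subset(self):
        report = verify_all("sciatica", _pipeline_backend(), self._corpus())
        generated = {"disc herniation", "hepatitis", "unicorn fever"}
        assert {v.name for v in report.verified} <= generated
        assert (
            report.funnel.generated
            >= report.funnel.with_candidates
            >= report.funnel.verified
        )
        assert report.funnel.generated == 3
        assert report.failures == []

    def test_hard_constraints_hold_on_all_evidence(self):
        report = verify_all("sciatica", _pipeline_backend(), self._corpus())
        assert report.verified  # at least one etiology survives
        for item in report.verified:
            for sentence, _, verdict in item.evidence:
                assert verdict == "yes"
                assert "sciatica" in sentence.lower()
                assert item.name.lower() in sentence.lower()

    def test_vetting_failure_drops_etiology(self):
        report = verify_all("jaundice", _pipeline_backend(), self._corpus())
        assert all(v.name != "hepatitis" for v in report.verified)

    def test_no_phrase_cooccurrence_verifies_nothing(self):
        corpus = flat_corpus(["completely unrelated sentence ."])
        report = verify_all("sciatica", _pipeline_backend(), corpus)
        assert report.verified == [] and report.funnel.with_candidates == 0

    def test_bit_deterministic(self):
        r1 = verify_all("sciatica", _pipeline_backend(), self._corpus())
        r2 = verify_all("sciatica", _pipeline_backend(), self._corpus())
        assert [(v.name, v.evidence) for v in r1.verified] == [
            (v.name, v.evidence) for v in r2.verified
        ]
        assert (r1.funnel.generated, r1.funnel.with_candidates, r1.funnel.verified) == (
            r2.funnel.generated,
            r2.funnel.with_candidates,
            r2.funnel.verified,
        )
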