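"""Prompt assembly, response parsing, scripted backend, classification."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cognote.corpus import ConfigurationError, NoteSection
from cognote.prompting import (
    EFFECTIVE_PARSEABLE,
    EFFECTIVE_UNPARSEABLE,
    NOT_EFFECTIVE,
    ParsedVerdict,
    PromptTemplate,
    ScriptedBackend,
    ScriptedBackendConfig,
    assemble_prompt,
    build_error_instructions,
    classify_sections,
    default_templates,
    effective_response_rate,
    parse_response,
    selection_accuracy,
    template_selection_report,
)
from cognote.synthetic import GeneratorConfig, generate_corpus
from cognote.ensemble import PredictionSet

from conftest import tiny_corpus

SECTION = NoteSection("sx", "px", "Patient has dementia and memory loss.", 1)


def make_backend(lexicon, bank, **kw):
    return ScriptedBackend(ScriptedBackendConfig(lexicon=lexicon, phrase_bank=bank, **kw))


class TestAssemblePrompt:
    def test_minimal_template_is_task_plus_target(self):
        t = PromptTemplate("t", "Decide the thing.")
        prompt = assemble_prompt(t, SECTION)
        assert prompt.startswith("## Task\nDecide the thing.")
        assert prompt.rstrip().endswith(SECTION.text)
        assert "## Guidance" not in prompt and "## Examples" not in prompt

    def test_block_order_is_fixed(self):
        t = PromptTemplate("t", "Task.", additional_guidance="Guide.", few_shot_slot=True)
        prompt = assemble_prompt(t, SECTION, [("ex", 1)], error_instructions="Careful.")
        positions = [prompt.index(h) for h in ("## Task", "## Guidance", "## Examples",
                                               "## Cautions from prior errors", "## Target section")]
        assert positions == sorted(positions)

    def test_five_examples_rendered_in_order(self):
        t = PromptTemplate("t", "Task.", few_shot_slot=True)
        examples = [(f"example text {i}", i % 2) for i in range(5)]
        prompt = assemble_prompt(t, SECTION, examples)
        idx = [prompt.index(f"example text {i}") for i in range(5)]
        assert idx == sorted(idx)
        assert prompt.count("Example ") == 5

    def test_purity(self):
        t = PromptTemplate("t", "Task.", few_shot_slot=True)
        args = (t, SECTION, [("e", 0)], "watch out")
        assert assemble_prompt(*args) == assemble_prompt(*args)

    def test_examples_without_slot_rejected(self):
        t = PromptTemplate("t", "Task.", few_shot_slot=False)
        with pytest.raises(ConfigurationError, match="few-shot"):
            assemble_prompt(t, SECTION, [("e", 1)])

    def test_prompt_always_requests_json_judgment_and_keywords(self):
        prompt = assemble_prompt(PromptTemplate("t", "Task."), SECTION)
        assert "JSON" in prompt and "keywords" in prompt and "cognitive" in prompt.lower()


class TestParseResponse:
    def test_json_verdict_is_parseable(self):
        v = parse_response('{"cognitive_decline":"yes","keywords":["memory loss"]}')
        assert v.category == EFFECTIVE_PARSEABLE
        assert v.label == 1 and v.keywords == ("memory loss",)

    def test_free_text_answer_is_unparseable(self):
        v = parse_response("Decline present. Keywords: memory, MoCA")
        assert v.category == EFFECTIVE_UNPARSEABLE
        assert v.label is None and v.keywords is None

    def test_refusal_is_not_effective(self):
        assert parse_response("I am unable to help with that.").category == NOT_EFFECTIVE

    @pytest.mark.parametrize(
        "value,expected",
        [("yes", 1), ("No", 0), ("TRUE", 1), ("false", 0), (1, 1), (0, 0)],
    )
    def test_judgment_normalization(self, value, expected):
        raw = json.dumps({"judgment": value, "keywords": ["k"]})
        v = parse_response(raw)
        assert v.category == EFFECTIVE_PARSEABLE and v.label == expected

    def test_json_embedded_in_prose(self):
        v = parse_response('Sure! Here it is: {"cognitive_decline": "no", "keywords": []} Hope that helps.')
        assert v.category == EFFECTIVE_PARSEABLE and v.label == 0 and v.keywords == ()

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(max_size=300))
    def test_never_throws_and_categories_partition(self, raw):
        v = parse_response(raw)
        assert v.category in (EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE, NOT_EFFECTIVE)

    def test_verdict_invariant_enforced(self):
        with pytest.raises(ValueError):
            ParsedVerdict(NOT_EFFECTIVE, 1, ("k",), "raw")


class TestEffectiveResponseRate:
    def _verdicts(self, categories):
        return [
            ParsedVerdict(c, 0 if c == EFFECTIVE_PARSEABLE else None,
                          () if c == EFFECTIVE_PARSEABLE else None, "")
            for c in categories
        ]

    def test_eight_of_ten(self):
        cats = [EFFECTIVE_PARSEABLE] * 5 + [EFFECTIVE_UNPARSEABLE] * 3 + [NOT_EFFECTIVE] * 2
        assert effective_response_rate(self._verdicts(cats)) == pytest.approx(0.80)

    def test_extremes(self):
        assert effective_response_rate(self._verdicts([EFFECTIVE_PARSEABLE] * 4)) == 1.0
        assert effective_response_rate(self._verdicts([NOT_EFFECTIVE] * 4)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_response_rate([])

    def test_parseable_only_mode(self):
        cats = [EFFECTIVE_PARSEABLE, EFFECTIVE_UNPARSEABLE]
        assert effective_response_rate(self._verdicts(cats), count_unparseable=False) == 0.5


class TestScriptedBackend:
    def test_keyword_section_yields_positive_json(self, lexicon, bank):
        backend = make_backend(lexicon, bank)
        prompt = assemble_prompt(default_templates()["t2-task-only"], SECTION)
        v = parse_response(backend.complete(prompt))
        assert v.category == EFFECTIVE_PARSEABLE and v.label == 1
        assert "dementia" in v.keywords

    def test_deterministic_bytes(self, lexicon, bank):
        backend = make_backend(lexicon, bank, flip_rate_overall=0.5, format_break_rate=0.3)
        prompt = assemble_prompt(default_templates()["t2-task-only"], SECTION)
        assert backend.complete(prompt) == backend.complete(prompt)

    def test_mute_rate_one_is_never_effective(self, lexicon, bank):
        backend = make_backend(lexicon, bank, mute_rate=1.0)
        prompt = assemble_prompt(default_templates()["t2-task-only"], SECTION)
        assert parse_response(backend.complete(prompt)).category == NOT_EFFECTIVE

    def test_rate_validation(self, lexicon, bank):
        with pytest.raises(ConfigurationError, match="mute_rate"):
            make_backend(lexicon, bank, mute_rate=1.5)

    def test_contract_error_on_foreign_prompt(self, lexicon, bank):
        from cognote.prompting import PromptContractError

        with pytest.raises(PromptContractError):
            make_backend(lexicon, bank).complete("What is the weather?")


class TestClassifySections:
    def test_zero_flip_zero_hard_negatives_is_exact(self, lexicon, bank):
        corpus = generate_corpus(
            GeneratorConfig(n_sections=120, hard_negative_share=0.0, seed=21,
                            length_log_mean=5.0, length_log_sd=0.6, length_max=2000),
            bank,
        )
        backend = make_backend(lexicon, bank)
        preds, log = classify_sections(backend, default_templates()["t2-task-only"], corpus)
        assert selection_accuracy(preds, corpus) == 1.0
        assert all(rec["flag"] == "" for rec in log)

    def test_mute_backend_falls_back_to_negative_with_flags(self, lexicon, bank):
        corpus = generate_corpus(GeneratorConfig(n_sections=20, seed=22), bank)
        backend = make_backend(lexicon, bank, mute_rate=1.0)
        preds, log = classify_sections(backend, default_templates()["t2-task-only"], corpus)
        assert set(preds.predictions.values()) == {0}
        assert all(rec["flag"] == "fallback_negative" for rec in log)

    def test_hard_negatives_understood_at_flip_zero(self, lexicon, bank):
        corpus = generate_corpus(
            GeneratorConfig(n_sections=150, hard_negative_share=0.5, seed=23), bank
        )
        backend = make_backend(lexicon, bank)
        preds, _ = classify_sections(backend, default_templates()["t2-task-only"], corpus)
        assert selection_accuracy(preds, corpus) == 1.0


class TestSelectionAccuracy:
    def test_all_correct_and_all_wrong(self):
        gold = tiny_corpus([1, 0, 1])
        right = PredictionSet("m", {"s0": 1, "s1": 0, "s2": 1})
        wrong = PredictionSet("m", {"s0": 0, "s1": 1, "s2": 0})
        assert selection_accuracy(right, gold) == 1.0
        assert selection_accuracy(wrong, gold) == 0.0

    def test_172_of_200(self):
        gold = tiny_corpus([1] * 100 + [0] * 100)
        preds = {f"s{i}": (1 if i < 100 else 0) for i in range(200)}
        for i in list(range(86, 100)) + list(range(100, 114)):
            preds[f"s{i}"] = 1 - preds[f"s{i}"]
        assert selection_accuracy(PredictionSet("m", preds), gold) == pytest.approx(0.86)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            selection_accuracy(PredictionSet("m", {"nope": 1}), tiny_corpus([1]))


class TestErrorInstructions:
    def test_deterministic_and_category_aware(self, bank):
        sec = NoteSection("e1", "p", "No evidence of memory loss or related concerns at this visit.", 0)
        cases = [(sec, 0, 1)]
        text1 = build_error_instructions(cases, phrase_bank=bank)
        text2 = build_error_instructions(cases, phrase_bank=bank)
        assert text1 == text2
        assert "negated" in text1

    def test_three_categories_three_cautions(self, bank):
        secs = [
            NoteSection("e1", "p", "Cognitive function improvement noted since the last visit.", 0),
            NoteSection("e2", "p", "Temporary forgetfulness attributed to codeine started last week.", 0),
            NoteSection("e3", "p", "Possible subtle memory changes of uncertain significance; will monitor.", 0),
        ]
        text = build_error_instructions([(s, 0, 1) for s in secs], phrase_bank=bank)
        assert sum(line.startswith("- ") for line in text.splitlines()) == 3

    def test_empty_error_list_rejected(self):
        with pytest.raises(ValueError):
            build_error_instructions([])

    def test_cautions_suppress_category_flips_and_raise_accuracy(self, lexicon, bank):
        """Targeted cautions disable the backend's category errors, so
        selection accuracy strictly increases on a corpus rich in them."""
        corpus = generate_corpus(
            GeneratorConfig(n_sections=300, hard_negative_share=0.8, seed=31), bank
        )
        backend = make_backend(
            lexicon, bank, per_category_flip={"negated": 0.9, "uncertain": 0.9}, seed=5
        )
        template = default_templates()["t2-task-only"]
        base, _ = classify_sections(backend, template, corpus)
        base_acc = selection_accuracy(base, corpus)
        errors = [
            (s, s.label, base.predictions[s.section_id])
            for s in corpus.sections
            if base.predictions[s.section_id] != s.label
        ]
        instructions = build_error_instructions(errors, phrase_bank=bank)
        fixed, _ = classify_sections(backend, template, corpus, error_instructions=instructions)
        assert selection_accuracy(fixed, corpus) > base_acc


class TestTemplateSelection:
    def test_report_ranks_by_effectiveness_then_accuracy(self, lexicon, bank):
        corpus = generate_corpus(GeneratorConfig(n_sections=40, seed=41), bank)
        probe = corpus.subset(corpus.section_ids[:10], name="probe")
        backend = make_backend(lexicon, bank)
        report = template_selection_report(backend, default_templates(), probe, corpus)
        assert set(report.columns) == {"template_id", "effective_response_rate", "accuracy"}
        err = report["effective_response_rate"].to_numpy()
        assert (err[:-1] >= err[1:]).all()
        assert len(report) == len(default_templates())
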