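"""The mean + 2 SD keyword-selection rule and its three model channels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cognote.corpus import KeywordLexicon, LexiconEntry
from cognote.interpretation import (
    attention_keywords,
    gain_keywords,
    llm_keywords,
    mean2sd_select,
    merge_keyword_report,
    render_keyword_table,
)


class TestMean2SdSelect:
    def test_constant_vector_selects_nothing(self):
        assert mean2sd_select([5, 5, 5]) == set()

    def test_small_spread_selects_nothing(self):
        assert mean2sd_select([1, 2, 3]) == set()  # threshold 2 + 2*1 = 4

    def test_single_outlier_selected(self):
        # mean ~1.95, sample SD ~4.36 → threshold ~10.7 < 21.
        values = [1.0] * 20 + [21.0]
        assert mean2sd_select(values) == {20}

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            mean2sd_select([1.0])

    def test_agrees_with_brute_force_oracle(self, rng):
        """Exact agreement with an independent mean/SD computation on 1,000
        random vectors."""
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            values = rng.normal(0, 1, size=n) * rng.choice([1, 10, 100])
            got = mean2sd_select(values)
            mean = sum(values) / n
            sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
            oracle = {i for i, v in enumerate(values) if v > mean + 2 * sd}
            assert got == oracle

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        st.sampled_from([0.25, 0.5, 2.0, 8.0, 64.0]),  # powers of two scale exactly
    )
    def test_scale_invariance(self, values, scale):
        assert mean2sd_select(values) == mean2sd_select([v * scale for v in values])


class TestLlmKeywords:
    def _log(self, keyword_lists):
        return [
            {"section_id": f"s{i}", "keywords": kws, "category": "effective_parseable"}
            for i, kws in enumerate(keyword_lists)
        ]

    def test_dominant_citation_selected(self):
        # 'dementia' cited in 30 verdicts, 15 other keywords ~twice each.
        lists = [["dementia"]] * 30 + [[f"kw{i % 15}"] for i in range(30)]
        table = llm_keywords(self._log(lists))
        selected = set(table[table["selected"]]["keyword"])
        assert selected == {"dementia"}

    def test_uniform_citations_select_nothing(self):
        table = llm_keywords(self._log([["a"], ["b"], ["c"]]))
        assert not table["selected"].any()

    def test_case_folding_and_trimming(self):
        table = llm_keywords(self._log([[" Memory  Loss "], ["memory loss"]]))
        assert table["keyword"].tolist() == ["memory loss"]
        assert table["importance"].tolist() == [2.0]

    def test_no_parseable_verdicts_warns_empty(self):
        log = [{"section_id": "s0", "keywords": None, "category": "not_effective"}]
        with pytest.warns(UserWarning, match="parseable"):
            table = llm_keywords(log)
        assert len(table) == 0

    def test_empty_keyword_lists_give_empty_table(self):
        assert len(llm_keywords(self._log([[], [], []]))) == 0


class TestAttentionKeywords:
    class FakeTraceModel:
        """Deterministic traces: one peaked section per planted token."""

        def __init__(self, traces):
            self.traces = traces

        def attention_trace(self, section):
            return self.traces[section.section_id]

    def test_uniform_attention_selects_no_token(self):
        from conftest import tiny_corpus

        corpus = tiny_corpus([1])
        model = self.FakeTraceModel({"s0": (["a", "b", "c", "d"], np.full(4, 0.25))})
        assert len(attention_keywords(model, corpus, floor=1)) == 0

    def test_single_heavy_token_selected(self):
        from conftest import tiny_corpus

        corpus = tiny_corpus([1, 1])
        tokens = [f"t{i}" for i in range(19)] + ["peak"]
        weights = np.full(20, 0.1 / 19)
        weights[19] = 0.9
        model = self.FakeTraceModel({
            "s0": (tokens, weights),
            "s1": (tokens, weights),
        })
        table = attention_keywords(model, corpus, floor=2)
        assert table["keyword"].tolist() == ["peak"]
        assert table["importance"].tolist() == [2.0]

    def test_floor_filters_rare_tokens(self):
        from conftest import tiny_corpus

        corpus = tiny_corpus([1])
        tokens = ["x"] * 19 + ["peak"]
        weights = np.full(20, 0.1 / 19)
        weights[19] = 0.9
        model = self.FakeTraceModel({"s0": (tokens, weights)})
        assert len(attention_keywords(model, corpus, floor=2)) == 0

    def test_separable_fixture_recovers_planted_token(self, net_model, separable):
        table = attention_keywords(net_model, separable)
        assert "dementia" in set(table[table["selected"]]["keyword"])

    def test_unfitted_model_rejected(self):
        from conftest import tiny_corpus

        with pytest.raises(ValueError, match="attention"):
            attention_keywords(object(), tiny_corpus([1]))


class TestGainKeywords:
    def test_separable_fixture_selects_planted_keyword(self, trees_model):
        table = gain_keywords(trees_model)
        assert "dementia" in set(table[table["selected"]]["keyword"])

    def test_label_independent_noise_selects_almost_nothing(self, rng):
        """Trained on pure noise, the mean+2SD gain rule stays near-empty
        (≤ 2 selections in each of a handful of seeded runs)."""
        from cognote.trees import train_boosted_trees
        from conftest import tiny_corpus

        words = [f"w{i}" for i in range(30)]
        grid = {"n_estimators": (20,), "max_depth": (3,), "learning_rate": (0.3,)}
        for seed in range(5):
            r = np.random.default_rng(seed)
            texts = [" ".join(r.choice(words, size=15)) for _ in range(120)]
            labels = [int(r.random() < 0.4) for _ in range(120)]
            if len(set(labels)) < 2:
                continue
            model = train_boosted_trees(tiny_corpus(labels, texts=texts), grid=grid, seed=seed)
            table = gain_keywords(model)
            assert table["selected"].sum() <= 2

    def test_constant_gains_select_nothing(self):
        class FakeGains:
            gain_table = pd.Series([3.0, 3.0, 3.0], index=["a", "b", "c"])

        assert not gain_keywords(FakeGains())["selected"].any()

    def test_missing_gain_table_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            gain_keywords(object())


class TestMergeReport:
    def _lex(self):
        return KeywordLexicon(
            [LexiconEntry("memory", False, "expert"), LexiconEntry("cognit", True, "expert")]
        )

    def test_empty_model_tables_leave_expert_rows(self):
        report = merge_keyword_report([], self._lex())
        assert set(report["source"]) == {"expert"}
        assert report["selected"].all()
        assert set(report["keyword"]) == {"memory", "cognit-"}

    def test_same_keyword_from_two_sources_keeps_two_rows(self):
        t1 = pd.DataFrame({"keyword": ["dementia"], "source": "llm", "importance": [9.0], "selected": [True]})
        t2 = pd.DataFrame({"keyword": ["dementia"], "source": "boosted_trees", "importance": [5.0], "selected": [True]})
        report = merge_keyword_report([t1, t2], self._lex())
        assert (report["keyword"] == "dementia").sum() == 2

    def test_tsv_round_trip(self, tmp_path):
        t1 = pd.DataFrame({"keyword": ["dementia"], "source": "llm", "importance": [9.0], "selected": [True]})
        report = merge_keyword_report([t1], self._lex())
        path = tmp_path / "kw.tsv"
        report.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, report)

    def test_rendered_table_has_four_model_rows(self):
        text = render_keyword_table(merge_keyword_report([], self._lex()))
        for title in ("Expert Curated", "Boosted Trees", "Attention Network", "LLM"):
            assert title in text
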