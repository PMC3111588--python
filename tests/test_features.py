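import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmbdeid.corpus_io import Corpus, Message
from mmbdeid.features import (
    assemble,
    base_features,
    border_features,
    border_statistics,
    extract_corpus_features,
    lexicon_features,
    tfidf_rank_features,
    tfidf_scores,
)
from mmbdeid.lexicon import Lexicon
from mmbdeid.preprocess import tokenize

from _oracles import naive_tfidf


def _tok(text, index=0, n=1, is_punct=False):
    from mmbdeid.preprocess import TokenSpan

    return TokenSpan(
        text=text,
        start=0,
        end=len(text),
        index=index,
        is_punct=is_punct,
        distance_from_start=index,
        distance_from_end=n - 1 - index,
    )


class TestBaseFeatures:
    def test_capitalized_name_token(self):
        f = base_features(_tok("Kathy"))
        assert f["lower"] == "kathy"
        assert f["length"] == 5
        assert f["isCapitalized"] and not f["isLower"]
        assert f["prefix2"] == "ka" and f["suffix2"] == "hy"
        assert f["prefix3"] == "kat" and f["suffix3"] == "thy"

    def test_single_character_has_no_affixes(self):
        f = base_features(_tok("a"))
        assert f["length"] == 1
        assert "prefix2" not in f and "suffix2" not in f and "suffix3" not in f

    def test_all_caps(self):
        f = base_features(_tok("WWW"))
        assert f["isUpper"]
        assert not (f["isLower"] or f["isCapitalized"] or f["isMixed"])

    def test_exactly_one_case_flag_for_alphabetic(self):
        for text in ["lower", "UPPER", "Title", "MiXeD", "aB"]:
            f = base_features(_tok(text))
            assert (
                sum([f["isLower"], f["isUpper"], f["isCapitalized"], f["isMixed"]])
                == 1
            )

    def test_case_flags_all_false_for_digits_and_punct(self):
        for text, punct in [("123", False), (",", True)]:
            f = base_features(_tok(text, is_punct=punct))
            assert not any(
                [f["isLower"], f["isUpper"], f["isCapitalized"], f["isMixed"]]
            )

    def test_edge_flags(self):
        f = base_features(_tok("hi", index=0, n=10))
        assert f["win1FromStart"] and not f["win1FromEnd"]
        g = base_features(_tok("bye", index=9, n=10))
        assert g["win1FromEnd"] and not g["win2FromStart"]


class TestLexiconFeatures:
    @pytest.fixture()
    def lex(self):
        return {
            "honorific": Lexicon("honorific", ["mr", "mrs", "dr"]),
            "proper_name": Lexicon("proper_name", ["kathy"]),
        }

    def test_exact_membership(self, lex):
        f = lexicon_features(_tok("mrs"), lex)
        assert f["isHonorific"]

    def test_fuzzy_membership_one_edit(self, lex):
        f = lexicon_features(_tok("kathi"), lex)
        assert not f["isProperName"]
        assert f["editDist1ProperName"] and f["editDist2ProperName"]

    def test_unrelated_token_all_false(self, lex):
        f = lexicon_features(_tok("zzzzzzzz"), lex)
        assert not any(v for v in f.values())

    def test_punctuation_all_false(self, lex):
        f = lexicon_features(_tok(",", is_punct=True), lex)
        assert not any(v for v in f.values())


class TestTfIdf:
    def test_hand_computed_example(self):
        docs = {"doc1": ["lisa", "lisa", "hugs", "hugs"], "doc2": ["hugs", "tx"]}
        stats = tfidf_scores(docs)
        # (2 / sqrt(4)) * ln(2/1)
        assert stats["doc1"]["lisa"].score == pytest.approx(math.log(2), abs=1e-12)
        assert stats["doc1"]["hugs"].score == 0.0
        assert stats["doc1"]["lisa"].rank == 1

    def test_token_in_all_documents_scores_zero(self):
        docs = {"a": ["x", "y"], "b": ["x"], "c": ["x", "z"]}
        stats = tfidf_scores(docs)
        for d in stats:
            assert stats[d]["x"].score == 0.0

    def test_single_document_all_zero(self):
        stats = tfidf_scores({"only": ["a", "b", "a"]})
        assert all(s.score == 0.0 for s in stats["only"].values())

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            tfidf_scores({})

    def test_ranks_are_a_permutation(self):
        docs = {"d": ["a", "b", "b", "c"], "e": ["c"]}
        stats = tfidf_scores(docs)
        assert sorted(s.rank for s in stats["d"].values()) == [1, 2, 3]

    @given(st.integers(0, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_oracle_on_random_corpora(self, seed):
        rng = random.Random(seed)
        vocab = ["a", "b", "c", "d", "e", "f", "g"]
        docs = {
            f"d{i}": [rng.choice(vocab) for _ in range(rng.randint(1, 30))]
            for i in range(rng.randint(1, 5))
        }
        expected = naive_tfidf(docs)
        got = tfidf_scores(docs)
        for d in docs:
            for tok, score in expected[d].items():
                assert got[d][tok].score == pytest.approx(score, abs=1e-12)

    def test_rank_improves_with_count(self):
        """Adding occurrences of a token never worsens its rank."""
        base = ["a", "b", "b", "c", "c", "c"]
        docs1 = {"d": base, "e": ["z"]}
        docs2 = {"d": base + ["a", "a", "a"], "e": ["z"]}
        r1 = tfidf_scores(docs1)["d"]["a"].rank
        r2 = tfidf_scores(docs2)["d"]["a"].rank
        assert r2 <= r1


class TestRankBuckets:
    def _stats(self, rank, n):
        from mmbdeid.features import TfIdfStats

        d = {}
        for i in range(n):
            tok = f"t{i}"
            d[tok] = TfIdfStats(tf=0.0, n_documents=2, doc_freq=1, score=0.0, rank=i + 1)
        d["probe"] = TfIdfStats(tf=0.0, n_documents=2, doc_freq=1, score=0.0, rank=rank)
        return d

    def test_rank3_of_500(self):
        stats = self._stats(3, 500)
        f = tfidf_rank_features(_tok("probe"), stats, stats)
        assert f["boardTfidfInTop10"] and f["boardTfidfInTop1pct"]

    def test_rank11_of_2000(self):
        stats = self._stats(11, 2000)
        f = tfidf_rank_features(_tok("probe"), stats, stats)
        assert not f["boardTfidfInTop10"] and f["boardTfidfInTop1pct"]

    def test_rank1_of_1(self):
        stats = {"probe": self._stats(1, 0)["probe"]}
        f = tfidf_rank_features(_tok("probe"), stats, stats)
        assert f["boardTfidfInTop10"] and f["boardTfidfInTop1pct"]

    def test_missing_token_is_pipeline_error(self):
        stats = self._stats(1, 5)
        with pytest.raises(KeyError):
            tfidf_rank_features(_tok("absent"), stats, stats)


class TestBorderStatistics:
    def test_planted_signoff_dominates(self):
        msgs = [
            Message(f"m{i}", "b", "t", "u", f"words filler here more\n\nkay")
            for i in range(8)
        ]
        corpus = Corpus(msgs)
        tokens = {m.message_id: tokenize(m.body) for m in corpus}
        table = border_statistics(corpus, tokens)
        assert table.rank["kay"] <= 5
        f = border_features(_tok("kay"), table)
        assert f["borderInTop5"]

    def test_single_occurrence_scores_zero(self):
        corpus = Corpus([Message("m", "b", "t", "u", "one two three four five")])
        tokens = {"m": tokenize(corpus.messages[0].body)}
        table = border_statistics(corpus, tokens)
        assert table.stats["one"].score == 0.0  # ln(1) = 0

    def test_border_count_bounded_by_total(self, full_run):
        feats = full_run["deid"].extract(full_run["test_corpus"])
        table = border_statistics(full_run["test_corpus"], feats.tokens)
        for s in table.stats.values():
            assert 0 <= s.border_count <= s.total_count


class TestAssemble:
    def test_single_token_has_no_context(self):
        out = assemble([{"a": 1}])
        assert out == [{"a": 1}]

    def test_middle_token_gets_four_neighbors(self):
        own = [{"t": i} for i in range(5)]
        out = assemble(own)
        mid = out[2]
        assert mid["t"] == 2
        assert mid["-2:t"] == 0 and mid["-1:t"] == 1
        assert mid["+1:t"] == 3 and mid["+2:t"] == 4

    def test_feature_count_arithmetic(self):
        own = [{"a": 1, "b": 2} for _ in range(5)]
        out = assemble(own)
        assert len(out[2]) == 2 + 4 * 2
        assert len(out[0]) == 2 + 2 * 2  # only right context at the edge


def test_extraction_deterministic(small_run, lexicons):
    corpus = small_run["test_corpus"]
    f1 = extract_corpus_features(corpus, lexicons)
    f2 = extract_corpus_features(corpus, lexicons)
    assert f1.features == f2.features
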