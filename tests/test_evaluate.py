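import pytest

from mmbdeid.corpus_io import AnnotatedToken
from mmbdeid.evaluate import (
    EvalReport,
    error_taxonomy,
    intercoder_agreement,
    labels_from_annotations,
    lenient_recode,
    score,
)
from mmbdeid.lexicon import Lexicon
from mmbdeid.preprocess import tokenize


def _tokens(text):
    return {"m1": tokenize(text)}


class TestScore:
    def test_direct_arithmetic(self):
        toks = _tokens("a b c d e f g h")
        gold = {"m1": ["PROPER_NAME"] * 4 + ["OTHER"] * 4}
        pred = {"m1": ["USERNAME"] * 3 + ["OTHER", "PROPER_NAME"] + ["OTHER"] * 3}
        rep = score(gold, pred, toks)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 1, 3)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.75)

    def test_f_equals_precision_when_equal(self):
        rep = EvalReport.from_counts(tp=3, fp=1, fn=1, tn=3)
        assert rep.f_score == pytest.approx(rep.precision)

    def test_degenerate_all_negative(self):
        toks = _tokens("a b c")
        gold = pred = {"m1": ["OTHER"] * 3}
        rep = score(gold, pred, toks)
        assert rep.specificity == 1.0
        assert rep.precision == 1.0
        assert "precision" in rep.zero_denominator

    def test_punctuation_excluded(self):
        toks = _tokens("kathy , !")
        gold = {"m1": ["PROPER_NAME", "OTHER", "OTHER"]}
        pred = {"m1": ["PROPER_NAME", "PROPER_NAME", "OTHER"]}
        rep = score(gold, pred, toks)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (1, 0, 0, 0)

    def test_either_name_label_is_a_hit(self):
        toks = _tokens("kathy")
        rep = score({"m1": ["PROPER_NAME"]}, {"m1": ["USERNAME"]}, toks)
        assert rep.tp == 1

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            score({"m1": ["OTHER"]}, {"m1": ["OTHER"]}, _tokens("a b"))

    def test_self_consistency_on_pipeline_output(self, small_run):
        rep = small_run["deid"].evaluate(
            small_run["test_corpus"], small_run["test_gold"]
        )
        assert rep.recall == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))


class TestLenientRecode:
    def test_short_substring_of_long_username(self):
        toks = _tokens("sun is here")
        gold = {"m1": ["USERNAME", "OTHER", "OTHER"]}
        out = lenient_recode(gold, toks, {"m1": ["sunshinegirl2024"]})
        assert out["m1"][0] == "OTHER"

    def test_long_token_unchanged(self):
        toks = _tokens("sunshine is here")
        gold = {"m1": ["USERNAME", "OTHER", "OTHER"]}
        out = lenient_recode(gold, toks, {"m1": ["sunshinegirl2024"]})
        assert out["m1"][0] == "USERNAME"

    def test_strict_doubling_inequality(self):
        """'kay' in 'kaygal' (6 = 2*3, not >) stays a name."""
        toks = _tokens("kay waves")
        gold = {"m1": ["USERNAME", "OTHER"]}
        out = lenient_recode(gold, toks, {"m1": ["kaygal"]})
        assert out["m1"][0] == "USERNAME"

    def test_explicit_flags_recode(self):
        toks = _tokens("abc here")
        gold = {"m1": ["PROPER_NAME", "OTHER"]}
        out = lenient_recode(gold, toks, {}, flagged=[("m1", 0)])
        assert out["m1"][0] == "OTHER"

    def test_never_adds_names(self):
        toks = _tokens("a b c")
        gold = {"m1": ["OTHER", "USERNAME", "OTHER"]}
        out = lenient_recode(gold, toks, {"m1": ["somebody99"]})
        n_names = sum(l != "OTHER" for l in out["m1"])
        assert n_names <= 1


class TestIntercoderAgreement:
    def test_worked_example(self):
        # 81/83 = 97.59 -> 97.6 ; 81/82 = 98.78 -> 98.8
        assert intercoder_agreement(83, 82, 81) == (97.6, 98.8)

    def test_perfect_agreement(self):
        assert intercoder_agreement(10, 10, 10) == (100.0, 100.0)

    def test_plain_arithmetic(self):
        assert intercoder_agreement(4, 2, 1) == (25.0, 50.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            intercoder_agreement(0, 5, 0)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            intercoder_agreement(3, 3, 4)


class TestErrorTaxonomy:
    @pytest.fixture()
    def lexicons(self):
        return {
            "common_word": Lexicon("common_word", ["boo", "girl"]),
            "proper_name": Lexicon("proper_name", ["kathy"]),
            "medical_word": Lexicon("medical_word", ["mastectomy"]),
            "drug_word": Lexicon("drug_word", ["tamoxifen"]),
        }

    def test_fn_common_word_bucket(self, lexicons):
        toks = _tokens("boo said hi")
        gold = {"m1": ["USERNAME", "OTHER", "OTHER"]}
        pred = {"m1": ["OTHER"] * 3}
        tax = error_taxonomy(gold, pred, toks, lexicons)
        assert tax["false_negatives"]["counts"] == {"ambiguous_common_word": 1}

    def test_fp_medical_bucket(self, lexicons):
        toks = _tokens("mastectomy scheduled")
        gold = {"m1": ["OTHER", "OTHER"]}
        pred = {"m1": ["PROPER_NAME", "OTHER"]}
        tax = error_taxonomy(gold, pred, toks, lexicons)
        assert tax["false_positives"]["counts"] == {"medical": 1}

    def test_no_errors_empty_tables(self, lexicons):
        toks = _tokens("kathy waves")
        gold = pred = {"m1": ["PROPER_NAME", "OTHER"]}
        tax = error_taxonomy(gold, pred, toks, lexicons)
        assert tax["false_negatives"]["total"] == 0
        assert tax["false_positives"]["total"] == 0

    def test_bucket_counts_sum_to_error_totals(self, lexicons, small_run):
        deid = small_run["deid"]
        corpus = small_run["test_corpus"]
        feats, pred = deid.tag(corpus)
        gold = labels_from_annotations(small_run["test_gold"], feats.tokens)
        rep = score(gold, pred, feats.tokens)
        tax = error_taxonomy(gold, pred, feats.tokens, lexicons)
        assert tax["false_negatives"]["total"] == rep.fn
        assert tax["false_positives"]["total"] == rep.fp
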