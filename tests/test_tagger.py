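import pytest

from mmbdeid.corpus_io import NAME_LABELS
from mmbdeid.evaluate import labels_from_annotations
from mmbdeid.lexicon import Lexicon
from mmbdeid.preprocess import tokenize
from mmbdeid.tagger import (
    TaggerConfig,
    drug_untag,
    feature_strings,
    marginals,
    threshold_tag,
    train,
)


class TestThresholdTag:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            ({"PROPER_NAME": 0.03, "USERNAME": 0.04, "OTHER": 0.93}, "USERNAME"),
            ({"PROPER_NAME": 0.02, "USERNAME": 0.02, "OTHER": 0.96}, "OTHER"),
            # boundary: cumulative mass exactly at threshold is NOT tagged
            ({"PROPER_NAME": 0.05, "USERNAME": 0.00, "OTHER": 0.95}, "OTHER"),
            ({"PROPER_NAME": 0.9, "USERNAME": 0.05, "OTHER": 0.05}, "PROPER_NAME"),
            # tie above threshold goes to PROPER_NAME
            ({"PROPER_NAME": 0.3, "USERNAME": 0.3, "OTHER": 0.4}, "PROPER_NAME"),
        ],
    )
    def test_cumulative_threshold_rule(self, dist, expected):
        assert threshold_tag([dist]) == [expected]

    def test_threshold_monotonicity(self):
        """Lowering the threshold can only grow the name-tagged set."""
        import random

        rng = random.Random(3)
        dists = []
        for _ in range(200):
            p1, p2 = rng.random() * 0.5, rng.random() * 0.5
            z = p1 + p2
            if z > 1:
                p1, p2 = p1 / z, p2 / z
            dists.append(
                {"PROPER_NAME": p1, "USERNAME": p2, "OTHER": 1 - p1 - p2}
            )
        tagged = {}
        for thr in (0.005, 0.05, 0.5):
            labs = threshold_tag(dists, TaggerConfig(name_threshold=thr))
            tagged[thr] = {i for i, l in enumerate(labs) if l in NAME_LABELS}
        assert tagged[0.5] <= tagged[0.05] <= tagged[0.005]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            TaggerConfig(name_threshold=0.0)


class TestDrugUntag:
    drug = Lexicon("drug_word", ["tamoxifen", "doxycycline"])

    def test_drug_name_untagged(self):
        toks = tokenize("tamoxifen")
        assert drug_untag(["PROPER_NAME"], toks, self.drug) == ["OTHER"]

    def test_drug_nickname_not_untagged(self):
        """Only exact members are untagged: 'doxy' stays a name."""
        toks = tokenize("doxy")
        assert drug_untag(["USERNAME"], toks, self.drug) == ["USERNAME"]

    def test_never_adds_name_labels(self):
        toks = tokenize("hello tamoxifen world")
        labs = ["OTHER", "OTHER", "OTHER"]
        assert drug_untag(labs, toks, self.drug) == labs

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            drug_untag(["OTHER"], tokenize("a b"), self.drug)


class TestFeatureStrings:
    def test_flags_and_values(self):
        out = feature_strings({"isName": True, "isDrug": False, "lower": "kathy"})
        assert "isName" in out and "lower=kathy" in out
        assert all("isDrug" not in s for s in out)
        assert "bias" in out


class TestTraining:
    def test_misaligned_streams_name_the_message(self):
        with pytest.raises(ValueError, match="m7"):
            train({"m7": [{"a": 1}, {"b": 2}]}, {"m7": ["OTHER"]})

    def test_zero_name_labels_warns_but_trains(self):
        feats = {"m1": [{"w": "x"}, {"w": "y"}]}
        labs = {"m1": ["OTHER", "OTHER"]}
        with pytest.warns(UserWarning, match="no name labels"):
            model = train(feats, labs, TaggerConfig(max_iter=5))
        assert model.crf.w_state is not None

    def test_training_set_recall_high(self, small_run):
        """The fitted model recovers nearly all names it was trained on."""
        deid = small_run["deid"]
        rep = deid.evaluate(small_run["train_corpus"], small_run["train_gold"])
        assert rep.recall >= 0.95

    def test_retrain_same_seed_identical_tagging(self, small_run):
        from mmbdeid.pipeline import train_deidentifier

        deid2 = train_deidentifier(
            small_run["train_corpus"],
            small_run["train_gold"],
            TaggerConfig(max_iter=60),
        )
        _, labels1 = small_run["deid"].tag(small_run["test_corpus"])
        _, labels2 = deid2.tag(small_run["test_corpus"])
        assert labels1 == labels2

    def test_marginals_sum_to_one(self, small_run):
        deid = small_run["deid"]
        corpus = small_run["test_corpus"]
        feats = deid.extract(corpus)
        mid = corpus.messages[0].message_id
        dists = marginals(deid.model, feats.features[mid])
        for d in dists:
            assert sum(d.values()) == pytest.approx(1.0, abs=1e-9)

    def test_name_like_token_gets_name_mass(self, small_run):
        """A token in greeting position with name-list membership should
        carry more name mass than filler tokens do."""
        deid = small_run["deid"]
        corpus = small_run["test_corpus"]
        feats = deid.extract(corpus)
        gold = labels_from_annotations(small_run["test_gold"], feats.tokens)
        name_mass, other_mass = [], []
        for m in corpus.messages[:10]:
            dists = marginals(deid.model, feats.features[m.message_id])
            for d, g, t in zip(
                dists, gold[m.message_id], feats.tokens[m.message_id]
            ):
                p = d["PROPER_NAME"] + d["USERNAME"]
                if g in NAME_LABELS:
                    name_mass.append(p)
                elif not t.is_punct:
                    other_mass.append(p)
        assert name_mass and other_mass
        assert sum(name_mass) / len(name_mass) > sum(other_mass) / len(other_mass)
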