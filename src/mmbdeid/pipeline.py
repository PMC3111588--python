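"""End-to-end orchestration: preprocess -> features -> CRF -> threshold
-> drug untag -> scrub, bundled behind one object so the CLI, tests and
scripts all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus_io import AnnotatedToken, Corpus
from .evaluate import EvalReport, labels_from_annotations, score
from .features import CorpusFeatures, extract_corpus_features
from .lexicon import Lexicon, load_lexicons
from .scrub import scrub_corpus
from .tagger import TaggerConfig, TaggerModel, drug_untag, marginals, threshold_tag, train

__all__ = ["Deidentifier", "train_deidentifier"]


@dataclass
class Deidentifier:
    """A trained de-identification pipeline."""

    model: TaggerModel
    lexicons: dict[str, Lexicon]

    def extract(self, corpus: Corpus) -> CorpusFeatures:
        return extract_corpus_features(corpus, self.lexicons)

    def tag(
        self,
        corpus: Corpus,
        feats: CorpusFeatures | None = None,
        threshold: float | None = None,
    ) -> tuple[CorpusFeatures, dict[str, list[str]]]:
        """Label every token of every message; returns the features used
        (so callers can reuse tokens/identifier spans) and the labels."""
        feats = feats or self.extract(corpus)
        config = self.model.config
        if threshold is not None:
            config = TaggerConfig(
                name_threshold=threshold,
                labels=config.labels,
                c2=config.c2,
                max_iter=config.max_iter,
                min_feature_count=config.min_feature_count,
                seed=config.seed,
            )
        labels: dict[str, list[str]] = {}
        drug = self.lexicons["drug_word"]
        for m in corpus:
            toks = feats.tokens[m.message_id]
            dists = marginals(self.model, feats.features[m.message_id])
            labs = threshold_tag(dists, config)
            # a lone punctuation mark is never a name, whatever the CRF says
            labs = [
                "OTHER" if tok.is_punct else lab for tok, lab in zip(toks, labs)
            ]
            labels[m.message_id] = drug_untag(labs, toks, drug)
        return feats, labels

    def scrub(
        self, corpus: Corpus, collapse_names: bool = False,
        threshold: float | None = None,
    ) -> Corpus:
        feats, labels = self.tag(corpus, threshold=threshold)
        return scrub_corpus(
            corpus, feats.identifiers, feats.tokens, labels,
            collapse_names=collapse_names,
        )

    def evaluate(
        self,
        corpus: Corpus,
        gold: Sequence[AnnotatedToken],
        threshold: float | None = None,
    ) -> EvalReport:
        feats, predicted = self.tag(corpus, threshold=threshold)
        gold_labels = labels_from_annotations(gold, feats.tokens)
        return score(gold_labels, predicted, feats.tokens)


def train_deidentifier(
    corpus: Corpus,
    gold: Sequence[AnnotatedToken],
    config: TaggerConfig | None = None,
    lexicons: Mapping[str, Lexicon] | None = None,
) -> Deidentifier:
    """Extract features over the training corpus and fit the CRF."""
    lex = dict(lexicons) if lexicons is not None else load_lexicons()
    feats = extract_corpus_features(corpus, lex)
    gold_labels = labels_from_annotations(gold, feats.tokens)
    model = train(feats.features, gold_labels, config)
    return Deidentifier(model=model, lexicons=lex)
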