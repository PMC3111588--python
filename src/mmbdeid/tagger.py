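"""CRF name tagging: training, marginal inference, recall-oriented
thresholding, and drug-name untagging.

The classifier distinguishes three token labels: PROPER_NAME, USERNAME
and OTHER. Because missing a name is far more costly than scrubbing a
harmless token, tagging is not argmax: any token whose *cumulative*
probability of being a name — the sum of the PROPER_NAME and USERNAME
marginals — exceeds a threshold (default 0.05) is tagged with whichever
name label is more likely. A final pass untags tokens that are exact
(case-insensitive) members of the drug list, since drug names are the
medically informative tokens a researcher most wants kept; fuzzy drug
matching is deliberately not used, as nicknames like "doxy" are genuinely
ambiguous with usernames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import NAME_LABELS
from .crf import LinearChainCRF
from .lexicon import Lexicon
from .preprocess import TokenSpan

__all__ = [
    "TAG_LABELS",
    "TaggerConfig",
    "TaggerModel",
    "feature_strings",
    "train",
    "marginals",
    "threshold_tag",
    "drug_untag",
]

#: The classifier's label set. Structured identifiers never reach the
#: CRF (their spans are excised before tokenization), so three labels
#: suffice; the scheme is deliberately not BIO — names here are single
#: tokens, not spans.
TAG_LABELS = ("PROPER_NAME", "USERNAME", "OTHER")

#: Feature-schema identifier embedded in saved models; predictions with a
#: model built for a different schema are refused.
FEATURE_SCHEMA_VERSION = "mmbdeid-feat-1"


@dataclass
class TaggerConfig:
    """Knobs for training and tagging.

    ``name_threshold`` is the cumulative name-probability cutoff: lower
    values trade precision for recall. 0.05 is the recall-oriented
    operating point; 0.5 would be plain argmax-style tagging.
    """

    name_threshold: float = 0.05
    labels: tuple[str, ...] = TAG_LABELS
    c2: float = 0.1
    max_iter: int = 120
    min_feature_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.name_threshold < 1.0:
            raise ValueError("name_threshold must be in (0, 1)")


@dataclass
class TaggerModel:
    """A trained CRF plus the config and feature-schema it was built with."""

    crf: LinearChainCRF
    config: TaggerConfig
    schema_version: str = FEATURE_SCHEMA_VERSION

    def save(self, path) -> None:
        self.crf.save(path)

    @classmethod
    def load(cls, path, config: TaggerConfig | None = None) -> "TaggerModel":
        crf = LinearChainCRF.load(path)
        cfg = config or TaggerConfig(
            c2=crf.c2, max_iter=crf.max_iter, min_feature_count=crf.min_feature_count
        )
        return cls(crf=crf, config=cfg)


def feature_strings(vector: Mapping) -> list[str]:
    """Flatten a feature dict to the CRF's string features.

    True flags contribute their bare name, False flags are omitted
    (absence is informative enough for a log-linear model with the
    always-on bias), and valued features contribute ``name=value``.
    """
    out = ["bias"]
    for k, v in vector.items():
        if v is True:
            out.append(k)
        elif v is False:
            continue
        else:
            out.append(f"{k}={v}")
    return out


def train(
    features: Mapping[str, Sequence[Mapping]],
    labels: Mapping[str, Sequence[str]],
    config: TaggerConfig | None = None,
) -> TaggerModel:
    """Train the CRF on aligned per-message feature and label streams.

    ``features`` and ``labels`` map message ids to equal-length per-token
    sequences; a length mismatch raises ``ValueError`` naming the
    message. Training is deterministic for fixed inputs and config.
    """
    config = config or TaggerConfig()
    X: list[list[list[str]]] = []
    y: list[list[str]] = []
    n_names = 0
    for mid, vecs in features.items():
        if mid not in labels:
            raise ValueError(f"message {mid!r}: features present but labels missing")
        labs = list(labels[mid])
        if len(labs) != len(vecs):
            raise ValueError(
                f"message {mid!r}: {len(vecs)} feature vectors vs {len(labs)} labels"
            )
        X.append([feature_strings(v) for v in vecs])
        y.append(labs)
        n_names += sum(1 for lab in labs if lab in NAME_LABELS)
    if n_names == 0:
        warnings.warn(
            "no name labels in training data; name marginals may degenerate",
            stacklevel=2,
        )
    crf = LinearChainCRF(
        c2=config.c2,
        max_iter=config.max_iter,
        min_feature_count=config.min_feature_count,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the n_names check above already warned
        crf.fit(X, y, labels=config.labels)
    return TaggerModel(crf=crf, config=config)


def marginals(
    model: TaggerModel, features: Sequence[Mapping]
) -> list[dict[str, float]]:
    """Per-token marginal tag distributions for one message.

    Each entry maps every label to its probability; the probabilities of
    a token sum to 1.
    """
    if model.schema_version != FEATURE_SCHEMA_VERSION:
        raise ValueError(
            f"model feature schema {model.schema_version!r} does not match "
            f"this package's {FEATURE_SCHEMA_VERSION!r}"
        )
    X = [feature_strings(v) for v in features]
    P = model.crf.predict_marginals(X)
    labs = model.crf.labels
    return [dict(zip(labs, row)) for row in P]


def threshold_tag(
    dists: Sequence[Mapping[str, float]], config: TaggerConfig | None = None
) -> list[str]:
    """Tag tokens whose cumulative name probability exceeds the threshold.

    The comparison is strictly greater-than; above threshold the more
    likely of the two name labels wins, with ties going to PROPER_NAME.
    """
    config = config or TaggerConfig()
    out = []
    for d in dists:
        p_proper = d.get("PROPER_NAME", 0.0)
        p_user = d.get("USERNAME", 0.0)
        if p_proper + p_user > config.name_threshold:
            out.append("PROPER_NAME" if p_proper >= p_user else "USERNAME")
        else:
            out.append("OTHER")
    return out


def drug_untag(
    labels: Sequence[str],
    tokens: Sequence[TokenSpan],
    drug_lexicon: Lexicon,
) -> list[str]:
    """Untag name-tagged tokens that are exact drug-list members.

    Only removes name labels, never adds one; matching is exact and
    case-insensitive.
    """
    if len(labels) != len(tokens):
        raise ValueError("labels and tokens are misaligned")
    return [
        "OTHER" if lab in NAME_LABELS and tok.text in drug_lexicon else lab
        for lab, tok in zip(labels, tokens)
    ]
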