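"""Placeholder substitution: the final de-identification step.

Every detected identifier — regex-found e-mail/phone/URL spans and
CRF-tagged name/username tokens — is replaced by a bracketed placeholder
naming its class; everything else, including whitespace and line
structure, is preserved byte-for-byte. PROPER_NAME and USERNAME map to
distinct placeholders by default so downstream consumers can tell them
apart; ``collapse_names=True`` folds both to ``[NAME]``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .corpus_io import Corpus, Message, NAME_LABELS
from .preprocess import IdentifierSpan, TokenSpan

__all__ = ["PLACEHOLDERS", "scrub_message", "scrub_corpus"]

PLACEHOLDERS = {
    "PROPER_NAME": "[NAME]",
    "USERNAME": "[USERNAME]",
    "EMAIL": "[EMAIL]",
    "PHONE": "[PHONE]",
    "URL": "[URL]",
}

_PLACEHOLDER_WORDS = {"NAME", "USERNAME", "EMAIL", "PHONE", "URL"}


def _is_placeholder_token(body: str, token: TokenSpan) -> bool:
    """True when the token is the class word of an existing placeholder
    (``[NAME]`` etc.), so re-scrubbing already-scrubbed text is a no-op."""
    return (
        token.text in _PLACEHOLDER_WORDS
        and token.start > 0
        and body[token.start - 1] == "["
        and token.end < len(body)
        and body[token.end] == "]"
    )


def scrub_message(
    message: Message,
    identifier_spans: Sequence[IdentifierSpan],
    tokens: Sequence[TokenSpan],
    labels: Sequence[str],
    collapse_names: bool = False,
) -> str:
    """Produce the de-identified body of one message.

    ``labels`` is the per-token output of the tagger, aligned with
    ``tokens``. Overlapping replacement spans indicate an upstream bug
    and raise ``ValueError``.
    """
    if len(tokens) != len(labels):
        raise ValueError(f"message {message.message_id!r}: tokens/labels misaligned")
    body = message.body
    repl: list[tuple[int, int, str]] = []
    for sp in identifier_spans:
        repl.append((sp.start, sp.end, PLACEHOLDERS[sp.kind]))
    for tok, lab in zip(tokens, labels):
        if lab in NAME_LABELS and not _is_placeholder_token(body, tok):
            ph = "[NAME]" if collapse_names else PLACEHOLDERS[lab]
            repl.append((tok.start, tok.end, ph))
    repl.sort()
    out = []
    cursor = 0
    for start, end, ph in repl:
        if start < cursor:
            raise ValueError(
                f"message {message.message_id!r}: overlapping replacements at {start}"
            )
        out.append(body[cursor:start])
        out.append(ph)
        cursor = end
    out.append(body[cursor:])
    return "".join(out)


def scrub_corpus(
    corpus: Corpus,
    identifiers: Mapping[str, Sequence[IdentifierSpan]],
    tokens: Mapping[str, Sequence[TokenSpan]],
    labels: Mapping[str, Sequence[str]],
    collapse_names: bool = False,
) -> Corpus:
    """Scrub every message, returning a new corpus with bodies replaced."""
    return Corpus(
        Message(
            message_id=m.message_id,
            board_id=m.board_id,
            thread_id=m.thread_id,
            author=m.author,
            body=scrub_message(
                m,
                identifiers.get(m.message_id, ()),
                tokens.get(m.message_id, ()),
                labels.get(m.message_id, ()),
                collapse_names=collapse_names,
            ),
        )
        for m in corpus
    )
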