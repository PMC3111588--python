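"""Structured-identifier detection and tokenization.

E-mail addresses, URLs and phone numbers are found first by regular
expression; the remaining text is then split into tokens at whitespace
and at every punctuation mark, each punctuation character becoming its
own single-character token. Identifier spans are never tokenized, so the
downstream name classifier only ever sees free text.

The e-mail pattern is ``[\\w.]+@\\w+(\\.\\w+)*`` and the phone pattern
``(\\d\\d\\d[-._ ]?)+\\d\\d\\d\\d``. The e-mail tail is interpreted with a
literal dot (``(\\.\\w+)*``): an unescaped dot there would swallow
arbitrary characters after the host, which is not what an e-mail address
looks like. Phone matching runs after e-mail/URL removal so digit runs
inside URLs are not mistaken for phone numbers. All three patterns can be
overridden per identifier kind.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "EMAIL_PATTERN",
    "PHONE_PATTERN",
    "URL_PATTERN",
    "IdentifierSpan",
    "TokenSpan",
    "find_structured_identifiers",
    "tokenize",
    "preprocess_message",
]

EMAIL_PATTERN = r"[\w.]+@\w+(?:\.\w+)*"
PHONE_PATTERN = r"(?:\d\d\d[-._ ]?)+\d\d\d\d"
# Not printed in the original description; scheme-or-www heuristic.
URL_PATTERN = r"(?:https?://|www\.)[\w.-]+(?:/[^\s]*)?"

#: Detection precedence on overlap.
_KIND_ORDER = ("EMAIL", "URL", "PHONE")

_DEFAULT_PATTERNS = {
    "EMAIL": EMAIL_PATTERN,
    "URL": URL_PATTERN,
    "PHONE": PHONE_PATTERN,
}

_WORD_RE = re.compile(r"\w+")


@dataclass(frozen=True)
class IdentifierSpan:
    """A regex-detected identifier: ``body[start:end]`` of the given kind."""

    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown identifier kind {self.kind!r}")


@dataclass(frozen=True)
class TokenSpan:
    """A token with character offsets and message-position bookkeeping.

    ``distance_from_start + distance_from_end`` equals the message token
    count minus one for every token; ``is_punct`` marks single
    punctuation-mark tokens, which carry features and serve as context but
    are excluded from all corpus statistics.
    """

    text: str
    start: int
    end: int
    index: int
    is_punct: bool
    distance_from_start: int
    distance_from_end: int


def is_punct_char(ch: str) -> bool:
    """True for any punctuation or symbol character (Unicode P* / S* plus
    anything ASCII that is neither word character nor whitespace)."""
    if ch.isspace() or _WORD_RE.fullmatch(ch):
        return False
    cat = unicodedata.category(ch)
    return cat.startswith(("P", "S")) or not ch.isalnum()


def find_structured_identifiers(
    body: str, patterns: Mapping[str, str] | None = None
) -> list[IdentifierSpan]:
    """Locate e-mail, URL and phone spans in ``body``.

    Matches are maximal and leftmost per kind; on overlap the precedence
    is EMAIL > URL > PHONE (each later kind only matches text not already
    claimed). Returns spans sorted by start offset.
    """
    pats = dict(_DEFAULT_PATTERNS)
    if patterns:
        pats.update(patterns)
    claimed = [False] * len(body)
    spans: list[IdentifierSpan] = []
    for kind in _KIND_ORDER:
        for m in re.finditer(pats[kind], body):
            s, e = m.span()
            if s == e or any(claimed[s:e]):
                continue
            spans.append(IdentifierSpan(s, e, kind))
            for i in range(s, e):
                claimed[i] = True
    spans.sort(key=lambda sp: sp.start)
    return spans


def _segment_tokens(text: str, offset: int) -> Iterable[tuple[str, int, int, bool]]:
    """Split free text into (text, start, end, is_punct) pieces."""
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif _WORD_RE.match(ch):
            m = _WORD_RE.match(text, i)
            assert m is not None
            yield text[i : m.end()], offset + i, offset + m.end(), False
            i = m.end()
        else:
            # any non-word non-space character is a one-character token
            yield ch, offset + i, offset + i + 1, True
            i += 1


def tokenize(body: str, identifiers: Sequence[IdentifierSpan] = ()) -> list[TokenSpan]:
    """Tokenize ``body`` at whitespace and punctuation, skipping identifier
    spans entirely.

    Word tokens are maximal ``\\w+`` runs; every other non-space character
    is a single-character punctuation token. Offsets always satisfy
    ``token.text == body[token.start:token.end]``.
    """
    idents = sorted(identifiers, key=lambda sp: sp.start)
    pieces: list[tuple[str, int, int, bool]] = []
    cursor = 0
    for sp in idents:
        pieces.extend(_segment_tokens(body[cursor : sp.start], cursor))
        cursor = sp.end
    pieces.extend(_segment_tokens(body[cursor:], cursor))

    n = len(pieces)
    return [
        TokenSpan(
            text=t,
            start=s,
            end=e,
            index=i,
            is_punct=p,
            distance_from_start=i,
            distance_from_end=n - 1 - i,
        )
        for i, (t, s, e, p) in enumerate(pieces)
    ]


def preprocess_message(
    body: str, patterns: Mapping[str, str] | None = None
) -> tuple[list[IdentifierSpan], list[TokenSpan]]:
    """Run identifier detection then tokenization on one message body."""
    idents = find_structured_identifiers(body, patterns)
    return idents, tokenize(body, idents)
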