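"""Reading, writing and segmenting message-board corpora.

A corpus is a JSON-lines file, one message per line, with the fields
``board_id``, ``thread_id``, ``message_id``, ``author`` and ``body``.
Gold annotations are a TSV of ``(message_id, token_index, label)`` rows,
with the token index pinned to this package's tokenizer (recorded in a
header line so annotation files cannot silently drift across tokenizer
revisions).

Beyond I/O this module provides the two document segmentations the
structure features are computed over: all messages of one board as a
document, and all messages of one author as a document.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LABELS",
    "NAME_LABELS",
    "TOKENIZER_VERSION",
    "Message",
    "Corpus",
    "AnnotatedToken",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_annotations",
    "write_annotations",
    "board_documents",
    "user_documents",
]

#: Closed label set for gold and predicted tags.
LABELS = ("PROPER_NAME", "USERNAME", "EMAIL", "PHONE", "URL", "OTHER")

#: The two labels that count as a "name" for tagging and evaluation.
NAME_LABELS = frozenset({"PROPER_NAME", "USERNAME"})

#: Identifier recorded in annotation-file headers; bump when tokenization
#: rules change, since token indices are only meaningful for one tokenizer.
TOKENIZER_VERSION = "mmbdeid-tok-1"

_FIELDS = ("board_id", "thread_id", "message_id", "author", "body")


class CorpusFormatError(ValueError):
    """A corpus or annotation file violates the expected record format."""


@dataclass(frozen=True)
class Message:
    """One forum post.

    ``author`` is the username shown on the board; it seeds the username
    word lists. ``body`` is raw text and may span multiple lines.
    """

    message_id: str
    board_id: str
    thread_id: str
    author: str
    body: str

    def __post_init__(self) -> None:
        if not self.author:
            raise ValueError(f"message {self.message_id!r}: empty author")


@dataclass(frozen=True)
class AnnotatedToken:
    """A gold or predicted label for one token of one message."""

    message_id: str
    token_index: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.token_index < 0:
            raise ValueError("token_index must be non-negative")


class Corpus:
    """An ordered collection of messages with board/author/thread indices."""

    def __init__(self, messages: Iterable[Message] = ()):
        self.messages: list[Message] = []
        self.by_id: dict[str, Message] = {}
        self.by_board: "OrderedDict[str, list[Message]]" = OrderedDict()
        self.by_author: "OrderedDict[str, list[Message]]" = OrderedDict()
        self.by_thread: "OrderedDict[str, list[Message]]" = OrderedDict()
        for m in messages:
            self.add(m)

    def add(self, message: Message) -> None:
        if message.message_id in self.by_id:
            raise CorpusFormatError(
                f"duplicate message_id {message.message_id!r}"
            )
        self.messages.append(message)
        self.by_id[message.message_id] = message
        self.by_board.setdefault(message.board_id, []).append(message)
        self.by_author.setdefault(message.author, []).append(message)
        self.by_thread.setdefault(message.thread_id, []).append(message)

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    def thread_authors(self, thread_id: str) -> list[str]:
        """Usernames that posted in a thread, in first-post order."""
        seen: dict[str, None] = {}
        for m in self.by_thread.get(thread_id, []):
            seen.setdefault(m.author)
        return list(seen)


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus file, preserving record order.

    Raises :class:`CorpusFormatError` naming the offending line for
    malformed records, missing fields, or duplicate message ids.
    """
    corpus = Corpus()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: not valid JSON: {exc}"
                ) from exc
            if not isinstance(rec, dict):
                raise CorpusFormatError(f"{path}:{lineno}: record is not an object")
            missing = [f for f in _FIELDS if f not in rec]
            if missing:
                raise CorpusFormatError(
                    f"{path}:{lineno}: missing field(s) {', '.join(missing)}"
                )
            try:
                msg = Message(
                    message_id=str(rec["message_id"]),
                    board_id=str(rec["board_id"]),
                    thread_id=str(rec["thread_id"]),
                    author=str(rec["author"]),
                    body=str(rec["body"]),
                )
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                corpus.add(msg)
            except CorpusFormatError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON lines, field-for-field round-trippable."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in corpus:
            fh.write(
                json.dumps(
                    {
                        "board_id": m.board_id,
                        "thread_id": m.thread_id,
                        "message_id": m.message_id,
                        "author": m.author,
                        "body": m.body,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> list[AnnotatedToken]:
    """Read a token-label TSV; tolerates the tokenizer-version header."""
    out: list[AnnotatedToken] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == ["message_id", "token_index", "label"]:
                continue
            if len(parts) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            mid, idx, label = parts
            try:
                out.append(AnnotatedToken(mid, int(idx), label))
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_annotations(annotations: Iterable[AnnotatedToken], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tokenizer={TOKENIZER_VERSION}\n")
        fh.write("message_id\ttoken_index\tlabel\n")
        for a in annotations:
            fh.write(f"{a.message_id}\t{a.token_index}\t{a.label}\n")


def _concat(messages: Sequence[Message], tokens_by_message: Mapping[str, Sequence]) -> list:
    stream: list = []
    for m in messages:
        stream.extend(tokens_by_message.get(m.message_id, ()))
    return stream


def board_documents(
    corpus: Corpus, tokens_by_message: Mapping[str, Sequence]
) -> dict[str, list]:
    """Group every board's messages into one token-stream document.

    ``tokens_by_message`` maps message_id to that message's token sequence
    (as produced by :mod:`mmbdeid.preprocess`); every token lands in
    exactly one board document.
    """
    return {
        board: _concat(msgs, tokens_by_message)
        for board, msgs in corpus.by_board.items()
    }


def user_documents(
    corpus: Corpus, tokens_by_message: Mapping[str, Sequence]
) -> dict[str, list]:
    """Group every author's messages into one token-stream document."""
    return {
        author: _concat(msgs, tokens_by_message)
        for author, msgs in corpus.by_author.items()
    }
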