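"""Per-token feature vectors for the name classifier.

Two families of features are built. Surface features would help find
names in any text: the token itself and lower-cased, its length, case
class, 2/3-character affixes, distance from the message edges, and exact
and fuzzy word-list membership. Structure features exploit how message
boards are organized: tf-idf rank of the token when all messages of a
board (or all posts of one author) are pooled into a document — names
are document-specific, filler is corpus-wide — and the corpus-wide
likelihood that the token sits near a paragraph border, where greetings
and sign-offs live. Each token's vector also carries the features of its
two left and two right neighbors, prefixed by their offset.

tf-idf follows ``score(i, j) = (count(i in j) / sqrt(|j|)) * ln(N / n_i)``
with ``N`` the number of documents and ``n_i`` the number containing
token ``i``; tokens are lower-cased and punctuation excluded before
counting, and ranks break score ties lexicographically. The border
statistic for a token is ``(border_count / total_count) * ln(total_count)``
where a border occurrence is one within ``near_k`` tokens of a
paragraph's first or last token.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import Corpus, board_documents, user_documents
from .lexicon import (
    Lexicon,
    build_all_user_lexicon,
    build_user_variant_lexicon,
)
from .preprocess import IdentifierSpan, TokenSpan, preprocess_message

__all__ = [
    "TfIdfStats",
    "BorderStats",
    "BorderTable",
    "CorpusFeatures",
    "base_features",
    "lexicon_features",
    "tfidf_scores",
    "tfidf_rank_features",
    "border_statistics",
    "border_features",
    "assemble",
    "extract_corpus_features",
    "format_feature_dump",
]

#: Tokens this close to a paragraph's first/last token count as border
#: occurrences (greetings and sign-offs occupy short opening/closing lines).
DEFAULT_NEAR_K = 3

#: Which bucket cutoffs are emitted for each ranked statistic.
TFIDF_TOP_N = 10
TFIDF_TOP_FRACTION = 0.01
BORDER_TOP_N = 5
BORDER_TOP_FRACTION = 0.10

_LEXICON_FLAGS = {
    "proper_name": "ProperName",
    "common_word": "Common",
    "stop_word": "StopWord",
    "medical_word": "Medical",
    "drug_word": "Drug",
    "honorific": "Honorific",
    "all_user": "Username",
    "user_variant": "UserVariant",
}

_MAX_DIST_FEATURE = 5  # edge-distance values are capped at this


@dataclass(frozen=True)
class TfIdfStats:
    """tf-idf bookkeeping for one token in one document."""

    tf: float  #: count in document / sqrt(document token count)
    n_documents: int  #: N, total documents in the segmentation
    doc_freq: int  #: n_i, documents containing the token
    score: float  #: tf * ln(N / n_i)
    rank: int  #: 1-based rank within document, descending score


@dataclass(frozen=True)
class BorderStats:
    token: str
    border_count: int
    total_count: int
    score: float


class BorderTable:
    """Corpus-wide paragraph-border likelihood ranking."""

    def __init__(self, stats: Mapping[str, BorderStats]):
        self.stats = dict(stats)
        ordered = sorted(self.stats.values(), key=lambda s: (-s.score, s.token))
        self.rank = {s.token: i + 1 for i, s in enumerate(ordered)}

    def __len__(self) -> int:
        return len(self.stats)


def base_features(token: TokenSpan) -> dict:
    """Surface features of one token: identity, length, case, affixes,
    and distance from the message edges."""
    text = token.text
    f: dict = {
        "token": text,
        "lower": text.lower(),
        "length": len(text),
        "isPunct": token.is_punct,
    }
    is_lower = is_upper = is_cap = is_mixed = False
    if text.isalpha():
        if text.islower():
            is_lower = True
        elif text.isupper() and len(text) > 1:
            is_upper = True
        elif text[0].isupper() and text[1:].islower():
            is_cap = True
        else:
            is_mixed = True
    f["isLower"] = is_lower
    f["isUpper"] = is_upper
    f["isCapitalized"] = is_cap
    f["isMixed"] = is_mixed
    if len(text) >= 2:
        f["prefix2"] = text[:2].lower()
        f["suffix2"] = text[-2:].lower()
    if len(text) >= 3:
        f["prefix3"] = text[:3].lower()
        f["suffix3"] = text[-3:].lower()
    ds, de = token.distance_from_start, token.distance_from_end
    f["distFromStart"] = min(ds, _MAX_DIST_FEATURE)
    f["distFromEnd"] = min(de, _MAX_DIST_FEATURE)
    f["win1FromStart"] = ds <= 1
    f["win2FromStart"] = ds <= 2
    f["win1FromEnd"] = de <= 1
    f["win2FromEnd"] = de <= 2
    return f


def lexicon_features(token: TokenSpan, lexicons: Mapping[str, Lexicon]) -> dict:
    """Exact and fuzzy (edit distance 1 and 2) word-list membership flags.

    Punctuation tokens get all-false flags; fuzzy flags are inclusive of
    exact members so they are monotone in the distance bound.
    """
    f: dict = {}
    for name, suffix in _LEXICON_FLAGS.items():
        lex = lexicons.get(name)
        if lex is None:
            continue
        if token.is_punct:
            f[f"is{suffix}"] = False
            f[f"editDist1{suffix}"] = False
            f[f"editDist2{suffix}"] = False
        else:
            f[f"is{suffix}"] = token.text in lex
            d1 = lex.possible_member(token.text, 1)
            f[f"editDist1{suffix}"] = d1
            f[f"editDist2{suffix}"] = d1 or lex.possible_member(token.text, 2)
    return f


def tfidf_scores(
    documents: Mapping[str, Sequence[str]],
) -> dict[str, dict[str, TfIdfStats]]:
    """Score and rank every token of every document.

    ``documents`` maps a document key (board id or author) to its token
    stream, already lower-cased with punctuation removed. A token found
    in every document scores exactly 0 (``ln(N/N)``), as does everything
    in a single-document corpus.
    """
    if not documents:
        raise ValueError("tfidf_scores: empty document collection")
    n_docs = len(documents)
    doc_freq: Counter = Counter()
    counts: dict[str, Counter] = {}
    for key, stream in documents.items():
        c = Counter(stream)
        counts[key] = c
        doc_freq.update(c.keys())
    out: dict[str, dict[str, TfIdfStats]] = {}
    for key, c in counts.items():
        norm = math.sqrt(sum(c.values())) if c else 1.0
        scored = {
            tok: (cnt / norm) * math.log(n_docs / doc_freq[tok])
            for tok, cnt in c.items()
        }
        ranked = sorted(scored, key=lambda t: (-scored[t], t))
        out[key] = {
            tok: TfIdfStats(
                tf=c[tok] / norm,
                n_documents=n_docs,
                doc_freq=doc_freq[tok],
                score=scored[tok],
                rank=r + 1,
            )
            for r, tok in enumerate(ranked)
        }
    return out


def _rank_flags(rank: int, n_distinct: int, top_n: int, top_frac: float) -> tuple[bool, bool]:
    return rank <= top_n, rank <= math.ceil(top_frac * n_distinct)


def tfidf_rank_features(
    token: TokenSpan,
    board_doc_stats: Mapping[str, TfIdfStats],
    user_doc_stats: Mapping[str, TfIdfStats],
) -> dict:
    """Rank-bucket flags for the two tf-idf segmentations.

    A non-punctuation token missing from its own document's statistics
    indicates an upstream inconsistency and raises ``KeyError``.
    """
    if token.is_punct:
        return {
            "boardTfidfInTop10": False,
            "boardTfidfInTop1pct": False,
            "userTfidfInTop10": False,
            "userTfidfInTop1pct": False,
        }
    t = token.text.lower()
    if t not in board_doc_stats or t not in user_doc_stats:
        raise KeyError(
            f"token {t!r} missing from tf-idf statistics; "
            "feature pipeline and tokenization are out of sync"
        )
    b10, b1 = _rank_flags(
        board_doc_stats[t].rank, len(board_doc_stats), TFIDF_TOP_N, TFIDF_TOP_FRACTION
    )
    u10, u1 = _rank_flags(
        user_doc_stats[t].rank, len(user_doc_stats), TFIDF_TOP_N, TFIDF_TOP_FRACTION
    )
    return {
        "boardTfidfInTop10": b10,
        "boardTfidfInTop1pct": b1,
        "userTfidfInTop10": u10,
        "userTfidfInTop1pct": u1,
    }


def _paragraph_ranges(body: str) -> list[tuple[int, int]]:
    """Character ranges of maximal runs of non-blank lines."""
    ranges: list[tuple[int, int]] = []
    pos = 0
    start: int | None = None
    end = 0
    for line in body.splitlines(keepends=True):
        stripped = line.strip()
        if stripped:
            if start is None:
                start = pos
            end = pos + len(line.rstrip("\n"))
        else:
            if start is not None:
                ranges.append((start, end))
                start = None
        pos += len(line)
    if start is not None:
        ranges.append((start, end))
    return ranges


def border_statistics(
    corpus: Corpus,
    tokens_by_message: Mapping[str, Sequence[TokenSpan]],
    near_k: int = DEFAULT_NEAR_K,
) -> BorderTable:
    """Corpus-wide counts of how often each token appears near a
    paragraph border, scored by ``(border/total) * ln(total)``."""
    border: Counter = Counter()
    total: Counter = Counter()
    for message in corpus:
        tokens = [
            t for t in tokens_by_message.get(message.message_id, ()) if not t.is_punct
        ]
        for t in tokens:
            total[t.text.lower()] += 1
        for pstart, pend in _paragraph_ranges(message.body):
            para = [t for t in tokens if t.start >= pstart and t.end <= pend]
            near = para[:near_k] + para[max(0, len(para) - near_k) :]
            for t in {id(x): x for x in near}.values():
                border[t.text.lower()] += 1
    stats = {
        tok: BorderStats(
            token=tok,
            border_count=border.get(tok, 0),
            total_count=cnt,
            score=(border.get(tok, 0) / cnt) * math.log(cnt),
        )
        for tok, cnt in total.items()
    }
    return BorderTable(stats)


def border_features(token: TokenSpan, table: BorderTable) -> dict:
    if token.is_punct:
        return {"borderInTop5": False, "borderInTop10pct": False}
    rank = table.rank.get(token.text.lower())
    if rank is None:
        return {"borderInTop5": False, "borderInTop10pct": False}
    top5, top10pct = _rank_flags(rank, len(table), BORDER_TOP_N, BORDER_TOP_FRACTION)
    return {"borderInTop5": top5, "borderInTop10pct": top10pct}


def assemble(own_vectors: Sequence[dict]) -> list[dict]:
    """Merge in each token's neighborhood: the own features of tokens at
    offsets -2..-1, +1..+2 are copied in under an offset prefix. Context
    features are simply absent beyond the message edges."""
    n = len(own_vectors)
    out: list[dict] = []
    for i in range(n):
        merged = dict(own_vectors[i])
        for off in (-2, -1, 1, 2):
            j = i + off
            if 0 <= j < n:
                prefix = f"{off:+d}:"
                for k, v in own_vectors[j].items():
                    merged[prefix + k] = v
        out.append(merged)
    return out


@dataclass
class CorpusFeatures:
    """Everything the tagger and scrubber need, keyed by message id."""

    features: dict[str, list[dict]] = field(default_factory=dict)
    tokens: dict[str, list[TokenSpan]] = field(default_factory=dict)
    identifiers: dict[str, list[IdentifierSpan]] = field(default_factory=dict)


def extract_corpus_features(
    corpus: Corpus,
    lexicons: Mapping[str, Lexicon],
    near_k: int = DEFAULT_NEAR_K,
    patterns: Mapping[str, str] | None = None,
) -> CorpusFeatures:
    """Run the full feature pipeline over a corpus.

    Preprocesses every message, computes the board- and author-level
    tf-idf tables and the border table over the whole corpus, builds the
    username lexicons (all users corpus-wide; username variants per
    thread), and assembles context-expanded feature vectors per token.
    Deterministic: identical corpus and lexicons give an identical
    feature stream.
    """
    out = CorpusFeatures()
    content: dict[str, list[str]] = {}
    for m in corpus:
        idents, tokens = preprocess_message(m.body, patterns)
        out.identifiers[m.message_id] = idents
        out.tokens[m.message_id] = tokens
        content[m.message_id] = [t.text.lower() for t in tokens if not t.is_punct]

    board_stats = tfidf_scores(board_documents(corpus, content))
    user_stats = tfidf_scores(user_documents(corpus, content))
    border_table = border_statistics(corpus, out.tokens, near_k)

    lex: dict[str, Lexicon] = dict(lexicons)
    lex["all_user"] = build_all_user_lexicon(m.author for m in corpus)
    names = lex.get("proper_name")
    words = lex.get("common_word")
    thread_variants: dict[str, Lexicon] = {
        tid: build_user_variant_lexicon(corpus.thread_authors(tid), names, words)
        for tid in corpus.by_thread
    }

    for m in corpus:
        lex["user_variant"] = thread_variants[m.thread_id]
        bstats = board_stats[m.board_id]
        ustats = user_stats[m.author]
        own = []
        for t in out.tokens[m.message_id]:
            vec = base_features(t)
            vec.update(lexicon_features(t, lex))
            vec.update(tfidf_rank_features(t, bstats, ustats))
            vec.update(border_features(t, border_table))
            own.append(vec)
        out.features[m.message_id] = assemble(own)
    return out


def format_feature_dump(features: Mapping[str, Sequence[dict]]) -> str:
    """TSV-ish dump: one token per line as feature=value pairs, one blank
    line between messages (CRF-suite style)."""
    blocks = []
    for mid in features:
        lines = [
            "\t".join(f"{k}={v}" for k, v in vec.items()) for vec in features[mid]
        ]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
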