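"""Word lists, fuzzy membership, and username-variant derivation.

Eight lists feed the classifier's membership features: proper names,
common words, stop words, medical terms, drug names, honorifics, all
usernames of the board, and per-thread username variants. Membership is
case-insensitive. "Possible" membership is membership within one or two
edits, where edit distance is the Damerau–Levenshtein distance in its
optimal-string-alignment form: insertions, deletions, substitutions and
adjacent transpositions, with no substring edited twice. Fuzzy matching
is what lets a misspelled name ("kathi" for "kathy", "lard" for "lars")
still light up the name lists.

Fuzzy queries are served from a deletion-neighborhood index: at load
time every entry's set of strings reachable by up to ``max_dist``
character deletions is keyed to the entry, and a query token's own
deletion neighborhood is intersected with the key set; surviving
candidates are confirmed with the exact distance. For distances 1–2 this
is equivalent to a full scan (any two strings within k edits share a
member of each other's k-deletion neighborhoods) but runs in near-constant
time per query.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "LEXICON_NAMES",
    "Lexicon",
    "damerau_levenshtein",
    "username_variants",
    "load_lexicons",
    "bundled_lexicon_dir",
]

#: The list roles the feature set expects. ``all_user`` is built from a
#: corpus' author fields and ``user_variant`` per thread at feature time;
#: the other six load from word-list files.
LEXICON_NAMES = (
    "proper_name",
    "common_word",
    "stop_word",
    "medical_word",
    "drug_word",
    "honorific",
    "all_user",
    "user_variant",
)

FILE_LEXICON_NAMES = LEXICON_NAMES[:6]

_MAX_FUZZY_DIST = 2
#: Variants shorter than this are not emitted by username_variants.
MIN_VARIANT_LEN = 3


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment Damerau–Levenshtein distance.

    Counts insertions, deletions, substitutions and transpositions of
    adjacent characters, each costing 1, with the restriction that no
    substring is edited more than once.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    # three rolling rows: i-2, i-1, i
    prev2 = [0] * (lb + 1)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ai == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def _within_distance(a: str, b: str, k: int) -> bool:
    """``damerau_levenshtein(a, b) <= k`` with cheap early exits."""
    if abs(len(a) - len(b)) > k:
        return False
    return damerau_levenshtein(a, b) <= k


def _deletions(s: str, k: int) -> set[str]:
    """All strings reachable from ``s`` by at most ``k`` deletions."""
    out = {s}
    frontier = {s}
    for _ in range(k):
        nxt = set()
        for t in frontier:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1 :])
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


class Lexicon:
    """A named word list with exact and edit-distance membership queries."""

    def __init__(self, name: str, entries: Iterable[str]):
        self.name = name
        self.entries: frozenset[str] = frozenset(
            e.strip().lower() for e in entries if e.strip()
        )
        # deletion-neighborhood index: neighborhood string -> candidate entries
        self._delete_index: dict[str, list[str]] = {}
        for entry in self.entries:
            for key in _deletions(entry, _MAX_FUZZY_DIST):
                self._delete_index.setdefault(key, []).append(entry)
        self._fuzzy_cache: dict[tuple[str, int], bool] = {}

    def __contains__(self, token: str) -> bool:
        return token.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Lexicon({self.name!r}, {len(self.entries)} entries)"

    def possible_member(self, token: str, max_dist: int) -> bool:
        """True iff some entry is within ``max_dist`` edits of the token.

        Exact members trivially qualify at any ``max_dist``. Queries are
        case-insensitive and monotone in ``max_dist``.
        """
        if not 1 <= max_dist <= _MAX_FUZZY_DIST:
            raise ValueError(f"max_dist must be 1 or 2, got {max_dist}")
        t = token.lower()
        if t in self.entries:
            return True
        key = (t, max_dist)
        hit = self._fuzzy_cache.get(key)
        if hit is None:
            hit = self._possible_member_uncached(t, max_dist)
            self._fuzzy_cache[key] = hit
        return hit

    def _possible_member_uncached(self, t: str, max_dist: int) -> bool:
        seen: set[str] = set()
        for key in _deletions(t, max_dist):
            for cand in self._delete_index.get(key, ()):
                if cand not in seen:
                    seen.add(cand)
                    if _within_distance(t, cand, max_dist):
                        return True
        return False


_CAMEL_RE = re.compile(r"(?<=[a-z])(?=[A-Z])|(?<=[A-Za-z])(?=\d)")
_DELIM_RE = re.compile(r"[^0-9A-Za-z]+")
_DIGIT_RE = re.compile(r"\d+")


def _greedy_vocab_split(s: str, vocab: set[str]) -> list[str]:
    """Greedily cut ``s`` at boundaries of known words (longest match
    first), emitting both matched words and leftover runs."""
    parts: list[str] = []
    buf = ""
    i = 0
    n = len(s)
    while i < n:
        match = ""
        for j in range(n, i + MIN_VARIANT_LEN - 1, -1):
            if s[i:j] in vocab:
                match = s[i:j]
                break
        if match:
            if buf:
                parts.append(buf)
                buf = ""
            parts.append(match)
            i += len(match)
        else:
            buf += s[i]
            i += 1
    if buf:
        parts.append(buf)
    return parts


def username_variants(
    username: str,
    known_names: Lexicon | None = None,
    known_words: Lexicon | None = None,
) -> set[str]:
    """Derive the name fragments an author might be called by in posts.

    Emits the lower-cased username itself plus: the digits-stripped form,
    pieces split at non-alphanumeric delimiters, pieces split at
    camel-case boundaries, and pieces obtained by greedily cutting the
    digit-stripped form at boundaries of known names and words. Derived
    variants shorter than 3 characters are dropped (they carry almost no
    identifying power and would flood fuzzy matches).
    """
    base = username.lower()
    candidates: set[str] = set()

    stripped = _DIGIT_RE.sub("", base)
    candidates.add(stripped)

    for part in _DELIM_RE.split(base):
        candidates.add(part)
        candidates.add(_DIGIT_RE.sub("", part))

    for part in _CAMEL_RE.split(username):
        candidates.add(part.lower())
        candidates.add(_DIGIT_RE.sub("", part.lower()))

    vocab: set[str] = set()
    if known_names is not None:
        vocab |= known_names.entries
    if known_words is not None:
        vocab |= known_words.entries
    if vocab and stripped:
        for piece in _greedy_vocab_split(stripped, vocab):
            candidates.add(piece)

    out = {v for v in candidates if len(v) >= MIN_VARIANT_LEN}
    out.add(base)
    return out


def bundled_lexicon_dir() -> Path:
    """Directory of the small word lists shipped with the package.

    These are synthetic stand-in lists covering the same roles as the
    large gazetteers a production deployment would configure (name, common
    word, stop word, medical, drug and honorific lists); real lists are a
    drop-in replacement via :func:`load_lexicons` paths.
    """
    return Path(str(resources.files("mmbdeid").joinpath("data")))


def _read_wordlist(path: Path) -> list[str]:
    entries = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            entries.append(line.lower())
    return entries


def load_lexicons(
    paths: Mapping[str, str | Path] | None = None,
) -> dict[str, Lexicon]:
    """Load the six file-backed word lists.

    ``paths`` maps list names (see :data:`FILE_LEXICON_NAMES`) to
    plain-text files, one entry per line, ``#`` comments allowed; names
    not given fall back to the bundled lists. A missing or empty mandatory
    list raises ``ValueError`` naming it.
    """
    base = bundled_lexicon_dir()
    resolved: dict[str, Path] = {
        name: base / f"{name}s.txt" for name in FILE_LEXICON_NAMES
    }
    if paths:
        for name, p in paths.items():
            if name not in FILE_LEXICON_NAMES:
                raise ValueError(f"unknown lexicon name {name!r}")
            resolved[name] = Path(p)
    lexicons: dict[str, Lexicon] = {}
    for name, path in resolved.items():
        if not path.exists():
            raise ValueError(f"word list {name!r}: file not found: {path}")
        entries = _read_wordlist(path)
        if not entries:
            raise ValueError(f"word list {name!r} is empty: {path}")
        lexicons[name] = Lexicon(name, entries)
    return lexicons


def build_all_user_lexicon(authors: Iterable[str]) -> Lexicon:
    """Usernames of everyone who posted to the corpus, as a lexicon."""
    return Lexicon("all_user", authors)


def build_user_variant_lexicon(
    thread_authors: Iterable[str],
    known_names: Lexicon | None = None,
    known_words: Lexicon | None = None,
) -> Lexicon:
    """Variants of the usernames active in one thread."""
    variants: set[str] = set()
    for author in thread_authors:
        variants |= username_variants(author, known_names, known_words)
    return Lexicon("user_variant", variants)
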