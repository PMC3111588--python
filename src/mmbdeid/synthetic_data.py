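"""Labeled synthetic message-board corpora.

Real message-board data cannot be redistributed, so this module builds
corpora that reproduce the *structural* regularities the de-identifier's
features exploit: boards contain threads, threads contain messages by a
small set of board-local users; messages open by addressing another
participant by a fragment of their username, close with the author's
first name, and occasionally embed e-mail addresses, phone numbers and
URLs; planted names suffer occasional typos (one random character edit),
and filler text is drawn from a common-word pool with Zipf-like weights
so document-specific tokens (names) separate from corpus-wide filler in
tf-idf. Every planted name token is emitted in the gold annotation
stream, typos included.

Usernames are composed from name- and word-pool pieces plus optional
digits, so username-variant derivation can invert them; users are
board-local and usernames globally unique, so a board-level train/test
split guarantees the test boards' usernames were never seen in training
— the regime a deployed scrubber faces on a new board.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import AnnotatedToken, Corpus, Message
from .lexicon import bundled_lexicon_dir, username_variants
from .preprocess import preprocess_message

__all__ = ["GeneratorConfig", "generate_corpus", "split_corpus"]


@dataclass
class GeneratorConfig:
    """Shape and noise parameters of a generated corpus.

    Defaults give 5 boards x 10 threads x 20 messages = 1000 messages
    with 8 users per board; greetings and sign-offs are frequent but not
    universal, and one in ten planted names carries a typo — roughly the
    noise regime of real forum text.
    """

    n_boards: int = 5
    n_threads_per_board: int = 10
    n_messages_per_thread: int = 20
    n_users_per_board: int = 8
    name_pool: Path | None = None  #: default: bundled proper-name list
    word_pool: Path | None = None  #: default: bundled common-word list
    drug_pool: Path | None = None  #: default: bundled drug list
    p_greeting: float = 0.7
    p_signoff: float = 0.6
    p_typo: float = 0.1
    p_mention: float = 0.15
    p_drug: float = 0.2
    p_email: float = 0.05
    p_phone: float = 0.05
    p_url: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("p_greeting", "p_signoff", "p_typo", "p_mention", "p_drug",
                  "p_email", "p_phone", "p_url"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        for f in ("n_boards", "n_threads_per_board", "n_messages_per_thread",
                  "n_users_per_board"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


@dataclass
class _User:
    username: str
    first_name: str
    variants: list[str] = field(default_factory=list)


def _load_pool(path: Path | None, default_name: str) -> list[str]:
    p = path if path is not None else bundled_lexicon_dir() / default_name
    entries = [
        line.split("#", 1)[0].strip().lower()
        for line in Path(p).read_text(encoding="utf-8").splitlines()
    ]
    return sorted({e for e in entries if e})


def _zipf_weights(n: int) -> list[float]:
    return [1.0 / (i + 1) for i in range(n)]


def _typo(word: str, rng: random.Random) -> str:
    """One random character edit, staying alphabetic and non-empty."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    ops = ["insert", "substitute", "transpose"] + (["delete"] if len(word) > 2 else [])
    op = rng.choice(ops)
    i = rng.randrange(len(word))
    if op == "insert":
        return word[:i] + rng.choice(letters) + word[i:]
    if op == "delete":
        return word[:i] + word[i + 1 :]
    if op == "substitute":
        return word[:i] + rng.choice(letters.replace(word[i], "")) + word[i:][1:]
    if len(word) >= 2:  # transpose
        i = rng.randrange(len(word) - 1)
        if word[i] != word[i + 1]:
            return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word[: max(1, len(word) - 1)] + rng.choice(letters)


class _BodyBuilder:
    """Accumulates body text while recording planted-name spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.spans: list[tuple[int, int, str]] = []

    def add(self, text: str, label: str | None = None) -> None:
        if label is not None:
            self.spans.append((self.length, self.length + len(text), label))
        self.parts.append(text)
        self.length += len(text)

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _make_users(
    board_idx: int,
    config: GeneratorConfig,
    names: list[str],
    words: list[str],
    rng: random.Random,
    taken: set[str],
) -> list[_User]:
    if len(names) < 2 or len(words) < 2:
        raise ValueError("name/word pools too small to build users")
    users: list[_User] = []
    attempts = 0
    while len(users) < config.n_users_per_board:
        attempts += 1
        if attempts > 200 * config.n_users_per_board:
            raise ValueError(
                f"cannot build {config.n_users_per_board} unique users from "
                f"pools of {len(names)} names / {len(words)} words"
            )
        first = rng.choice(names)
        style = rng.randrange(5)
        if style == 0:
            username = f"{first}{rng.randrange(10, 100)}"
        elif style == 1:
            username = first + rng.choice(words)
        elif style == 2:
            username = first.capitalize() + rng.choice(names).capitalize()
        elif style == 3:
            username = f"{first}{rng.choice(words)}{rng.randrange(10, 100)}"
        else:
            username = f"{rng.choice(words)}{rng.choice(words)}{rng.randrange(10, 100)}"
        if username.lower() in taken:
            continue
        taken.add(username.lower())
        variants = sorted(v for v in username_variants(username) if v.isalnum())
        users.append(_User(username=username, first_name=first, variants=variants))
    return users


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, list[AnnotatedToken]]:
    """Build a corpus and its gold token annotations. Deterministic for a
    fixed config (including seed)."""
    rng = random.Random(config.seed)
    names = _load_pool(config.name_pool, "proper_names.txt")
    words = _load_pool(config.word_pool, "common_words.txt")
    drugs = _load_pool(config.drug_pool, "drug_words.txt")
    if not names or not words or not drugs:
        raise ValueError("generator pools must be non-empty")
    weights = _zipf_weights(len(words))
    word_set = set(words)

    corpus = Corpus()
    gold: list[AnnotatedToken] = []
    taken: set[str] = set()
    mid = 0

    for b in range(config.n_boards):
        board_id = f"board{b}"
        users = _make_users(b, config, names, words, rng, taken)
        for th in range(config.n_threads_per_board):
            thread_id = f"{board_id}-t{th}"
            k = rng.randint(2, min(5, len(users)))
            participants = rng.sample(users, k)
            # pre-draw the posting order; threads always have >= 2 voices
            # so greetings can address someone who actually posts here
            authors_seq = [
                rng.choice(participants)
                for _ in range(config.n_messages_per_thread)
            ]
            while (
                config.n_messages_per_thread >= 2
                and len({u.username for u in authors_seq}) < 2
            ):
                authors_seq[rng.randrange(len(authors_seq))] = rng.choice(participants)
            posters = {u.username for u in authors_seq}
            voices = [u for u in participants if u.username in posters]
            for author in authors_seq:
                mid += 1
                body, spans = _build_body(
                    author, voices, config, words, weights, word_set,
                    drugs, rng,
                )
                message = Message(
                    message_id=f"m{mid}",
                    board_id=board_id,
                    thread_id=thread_id,
                    author=author.username,
                    body=body,
                )
                corpus.add(message)
                gold.extend(_spans_to_gold(message, spans))
    return corpus, gold


def _pick_greeting_variant(target: _User, word_set: set[str], rng: random.Random) -> str:
    """A fragment of the target's username to address them by, preferring
    fragments that are not ordinary words (people go by the name part)."""
    nameish = [v for v in target.variants if v not in word_set]
    pool = nameish or target.variants or [target.username.lower()]
    return rng.choice(pool)


def _filler_sentence(
    builder: _BodyBuilder,
    words: list[str],
    weights: list[float],
    rng: random.Random,
    mention: str | None = None,
    mention_label: str | None = None,
) -> None:
    n = rng.randint(4, 9)
    chosen = rng.choices(words, weights=weights, k=n)
    slot = rng.randrange(1, n + 1) if mention else -1
    for i, w in enumerate(chosen):
        if i > 0:
            builder.add(" ")
        builder.add(w)
        if i + 1 == slot:
            builder.add(" ")
            builder.add(mention, mention_label)
    builder.add(" .")


def _build_body(
    author: _User,
    participants: list[_User],
    config: GeneratorConfig,
    words: list[str],
    weights: list[float],
    word_set: set[str],
    drugs: list[str],
    rng: random.Random,
) -> tuple[str, list[tuple[int, int, str]]]:
    b = _BodyBuilder()

    def plant_name(text: str, label: str) -> None:
        if rng.random() < config.p_typo:
            text = _typo(text, rng)
        b.add(text, label)

    others = [u for u in participants if u.username != author.username]
    if others and rng.random() < config.p_greeting:
        target = rng.choice(others)
        variant = _pick_greeting_variant(target, word_set, rng)
        if rng.random() < 0.5:
            variant = variant.capitalize()
        plant_name(variant, "USERNAME")
        b.add(" ,")
        if rng.random() < 0.5:
            b.add(" hi !")
        b.add("\n\n")

    n_paragraphs = rng.randint(1, 2)
    for p in range(n_paragraphs):
        for _ in range(rng.randint(1, 3)):
            mention = mention_label = None
            if others and rng.random() < config.p_mention:
                target = rng.choice(others)
                if rng.random() < 0.5:
                    mention, mention_label = target.first_name, "PROPER_NAME"
                else:
                    mention = _pick_greeting_variant(target, word_set, rng)
                    mention_label = "USERNAME"
            _filler_sentence(
                b, words, weights, rng,
                mention=mention, mention_label=mention_label,
            )
            b.add(" " if rng.random() < 0.5 else "\n")
        if rng.random() < config.p_drug:
            b.add(f"my doctor started me on {rng.choice(drugs)} today .\n")
        if rng.random() < config.p_email:
            user = author.first_name + str(rng.randrange(10, 1000))
            b.add(f"mail me at {user}@example.com any time .\n")
        if rng.random() < config.p_phone:
            d = [rng.randrange(10) for _ in range(10)]
            sep = rng.choice(["-", ".", " "])
            num = (
                f"{d[0]}{d[1]}{d[2]}{sep}{d[3]}{d[4]}{d[5]}{sep}"
                f"{d[6]}{d[7]}{d[8]}{d[9]}"
            )
            b.add(f"call me at {num} if you want to talk .\n")
        if rng.random() < config.p_url:
            b.add(
                f"i found www.{rng.choice(words)}{rng.choice(words)}.org/"
                f"{rng.choice(words)} helpful .\n"
            )
        if p + 1 < n_paragraphs:
            b.add("\n")

    if rng.random() < config.p_signoff:
        b.add("\n")
        if rng.random() < 0.4:
            b.add("hugs , ")
        name = author.first_name
        if rng.random() < 0.5:
            name = name.capitalize()
        plant_name(name, "PROPER_NAME")
        if rng.random() < 0.3:
            b.add(" !")
    return b.text, b.spans


def _spans_to_gold(
    message: Message, spans: list[tuple[int, int, str]]
) -> list[AnnotatedToken]:
    """Map planted character spans onto tokenizer output, one token each."""
    _, tokens = preprocess_message(message.body)
    by_span = {(t.start, t.end): t for t in tokens}
    out = []
    for start, end, label in spans:
        tok = by_span.get((start, end))
        if tok is None:
            raise RuntimeError(
                f"generator bug: planted span {(start, end)} in message "
                f"{message.message_id!r} is not a single token"
            )
        out.append(AnnotatedToken(message.message_id, tok.index, label))
    return out


def split_corpus(
    corpus: Corpus,
    gold: list[AnnotatedToken],
    fraction: float = 0.8,
    seed: int = 0,
) -> tuple[Corpus, list[AnnotatedToken], Corpus, list[AnnotatedToken]]:
    """Partition by board (never by message), so held-out boards carry
    entirely unseen usernames. Returns (train_corpus, train_gold,
    test_corpus, test_gold)."""
    boards = list(corpus.by_board)
    if len(boards) < 2:
        raise ValueError("board split requires at least 2 boards")
    rng = random.Random(seed)
    rng.shuffle(boards)
    n_train = min(max(int(round(fraction * len(boards))), 1), len(boards) - 1)
    train_boards = set(boards[:n_train])

    train, test = Corpus(), Corpus()
    for m in corpus:
        (train if m.board_id in train_boards else test).add(m)
    train_ids = set(train.by_id)
    train_gold = [a for a in gold if a.message_id in train_ids]
    test_gold = [a for a in gold if a.message_id not in train_ids]
    return train, train_gold, test, test_gold
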