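"""Independent reference implementations used only as test oracles.

Each oracle is written from the defining recurrence or formula, by a
different route than the library code it checks, and is deliberately
naive: correctness over speed.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def osa_distance(a: str, b: str) -> int:
    """Optimal-string-alignment distance by top-down recursion on
    prefixes: delete, insert, substitute, and transposition of the two
    final characters, each costing one edit."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    d = min(
        osa_distance(a[:-1], b) + 1,
        osa_distance(a, b[:-1]) + 1,
        osa_distance(a[:-1], b[:-1]) + (a[-1] != b[-1]),
    )
    if len(a) >= 2 and len(b) >= 2 and a[-1] == b[-2] and a[-2] == b[-1]:
        d = min(d, osa_distance(a[:-2], b[:-2]) + 1)
    return d


def naive_possible_member(token: str, entries, max_dist: int) -> bool:
    """Full scan of the lexicon with the recursive distance oracle."""
    t = token.lower()
    return any(osa_distance(t, e) <= max_dist for e in entries)


def naive_tfidf(documents: dict) -> dict:
    """Literal transcription of the tf-idf definition: score of token i
    in document j is count/sqrt(|j|) * ln(N/n_i)."""
    n_docs = len(documents)
    out = {}
    for key, stream in documents.items():
        scores = {}
        for tok in set(stream):
            tf = stream.count(tok) / math.sqrt(len(stream))
            n_i = sum(1 for other in documents.values() if tok in other)
            scores[tok] = tf * math.log(n_docs / n_i)
        out[key] = scores
    return out


def brute_force_marginals(scores, trans, start, end):
    """Token marginals by explicit enumeration of every label sequence.

    ``scores`` is (T, K) per-token label scores; the sequence score is
    the sum of token scores, consecutive-pair transition scores, and the
    start/end bonuses. Feasible only for tiny T and K.
    """
    scores = np.asarray(scores, dtype=float)
    T, K = scores.shape
    weights = {}
    for path in itertools.product(range(K), repeat=T):
        s = start[path[0]] + end[path[-1]] + sum(scores[t, k] for t, k in enumerate(path))
        s += sum(trans[path[t], path[t + 1]] for t in range(T - 1))
        weights[path] = math.exp(s)
    Z = sum(weights.values())
    marg = np.zeros((T, K))
    for path, w in weights.items():
        for t, k in enumerate(path):
            marg[t, k] += w
    return marg / Z
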