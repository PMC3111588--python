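"""Evaluation: confusion counts, the four headline metrics, lenient
re-coding, error taxonomy, and inter-coder agreement.

A predicted token counts as a name hit if it carries *either* name label
— removing identifying text matters more than which placeholder replaces
it — and punctuation tokens are excluded from all counts. Precision is
TP/(TP+FP), recall TP/(TP+FN), F the harmonic mean, and specificity
TN/(TN+FP): the proportion of true non-name tokens left untagged.
``tagging_error_rate`` (FP/(FP+TN)) is additionally reported, since
system comparisons sometimes call that quantity "precision" when scoring
over non-name tokens.

Lenient re-coding mirrors manual validation practice: a gold name that is
a short (≤ 3 character) substring of a much longer participant username,
or that a human flagged as an acronym or unrelated nickname, carries
negligible identifying power and is re-coded to OTHER before scoring.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_io import AnnotatedToken, NAME_LABELS
from .lexicon import Lexicon, damerau_levenshtein
from .preprocess import TokenSpan

__all__ = [
    "EvalReport",
    "labels_from_annotations",
    "score",
    "lenient_recode",
    "intercoder_agreement",
    "error_taxonomy",
]

#: Length cutoff for the automatic lenient rule: gold names this short
#: that are substrings of a long participant username get re-coded.
LENIENT_MAX_LEN = 3


@dataclass(frozen=True)
class EvalReport:
    """Token-level confusion counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_score: float
    specificity: float
    tagging_error_rate: float
    mode: str = "strict"
    #: metrics whose denominator was zero and were reported as 1.0
    zero_denominator: tuple[str, ...] = ()

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int, mode: str = "strict") -> "EvalReport":
        zero: list[str] = []

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                zero.append(name)
                return 1.0
            return num / den

        precision = ratio(tp, tp + fp, "precision")
        recall = ratio(tp, tp + fn, "recall")
        if precision + recall == 0:
            zero.append("f_score")
            f = 0.0
        else:
            f = 2 * precision * recall / (precision + recall)
        specificity = ratio(tn, tn + fp, "specificity")
        ter = 1.0 - specificity if (tn + fp) else 0.0
        return cls(
            tp=tp,
            fp=fp,
            fn=fn,
            tn=tn,
            precision=precision,
            recall=recall,
            f_score=f,
            specificity=specificity,
            tagging_error_rate=ter,
            mode=mode,
            zero_denominator=tuple(zero),
        )

    def summary(self) -> str:
        return (
            f"mode={self.mode} TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}\n"
            f"precision={self.precision:.4f} recall={self.recall:.4f} "
            f"f_score={self.f_score:.4f} specificity={self.specificity:.4f}\n"
            f"tagging_error_rate={self.tagging_error_rate:.4f}"
        )


def labels_from_annotations(
    annotations: Iterable[AnnotatedToken],
    tokens_by_message: Mapping[str, Sequence[TokenSpan]],
) -> dict[str, list[str]]:
    """Expand a sparse annotation stream into dense per-message label
    lists (unannotated tokens are OTHER)."""
    out = {mid: ["OTHER"] * len(toks) for mid, toks in tokens_by_message.items()}
    for a in annotations:
        if a.message_id not in out:
            raise ValueError(f"annotation for unknown message {a.message_id!r}")
        labs = out[a.message_id]
        if a.token_index >= len(labs):
            raise ValueError(
                f"message {a.message_id!r}: token index {a.token_index} out of "
                f"range ({len(labs)} tokens)"
            )
        labs[a.token_index] = a.label
    return out


def _is_name(label: str) -> bool:
    return label in NAME_LABELS


def score(
    gold: Mapping[str, Sequence[str]],
    predicted: Mapping[str, Sequence[str]],
    tokens: Mapping[str, Sequence[TokenSpan]],
    mode: str = "strict",
) -> EvalReport:
    """Score predictions against gold over all non-punctuation tokens.

    ``gold`` and ``predicted`` are dense per-message label lists aligned
    with ``tokens``; any length mismatch raises ``ValueError``.
    """
    tp = fp = fn = tn = 0
    for mid, toks in tokens.items():
        g = gold.get(mid)
        p = predicted.get(mid)
        if g is None or p is None:
            raise ValueError(f"message {mid!r}: missing gold or predicted labels")
        if len(g) != len(toks) or len(p) != len(toks):
            raise ValueError(f"message {mid!r}: label streams misaligned with tokens")
        for tok, gl, pl in zip(toks, g, p):
            if tok.is_punct:
                continue
            if _is_name(gl):
                if _is_name(pl):
                    tp += 1
                else:
                    fn += 1
            else:
                if _is_name(pl):
                    fp += 1
                else:
                    tn += 1
    return EvalReport.from_counts(tp, fp, fn, tn, mode=mode)


def lenient_recode(
    gold: Mapping[str, Sequence[str]],
    tokens: Mapping[str, Sequence[TokenSpan]],
    participants: Mapping[str, Sequence[str]],
    flagged: Iterable[tuple[str, int]] = (),
) -> dict[str, list[str]]:
    """Re-code gold names with negligible identifying power to OTHER.

    Automatic rule: a gold name token of length ≤ 3 that is a substring
    of some participant username strictly more than twice its length.
    ``flagged`` carries (message_id, token_index) pairs a human marked as
    acronyms or unrelated nicknames — judgments that cannot be automated.
    Never adds a name label, so lenient recall dominates strict recall
    whenever the re-coded tokens were predicted OTHER.
    """
    flagged = set(flagged)
    out: dict[str, list[str]] = {}
    for mid, labs in gold.items():
        toks = tokens[mid]
        users = participants.get(mid, ())
        new = list(labs)
        for i, (tok, lab) in enumerate(zip(toks, new)):
            if not _is_name(lab):
                continue
            if (mid, i) in flagged:
                new[i] = "OTHER"
                continue
            t = tok.text.lower()
            if len(t) <= LENIENT_MAX_LEN and any(
                t in u.lower() and len(u) > 2 * len(t) for u in users
            ):
                new[i] = "OTHER"
        out[mid] = new
    return out


def intercoder_agreement(
    a_tagged: int, b_tagged: int, both_tagged: int
) -> tuple[float, float]:
    """Percent agreement between two coders' name tags.

    Returns ``(100*both/a_tagged, 100*both/b_tagged)`` rounded to one
    decimal place; zero denominators are an error.
    """
    if both_tagged > min(a_tagged, b_tagged):
        raise ValueError("both_tagged cannot exceed either coder's count")
    if a_tagged == 0 or b_tagged == 0:
        raise ValueError("agreement undefined when a coder tagged nothing")
    return (
        round(100.0 * both_tagged / a_tagged, 1),
        round(100.0 * both_tagged / b_tagged, 1),
    )


def error_taxonomy(
    gold: Mapping[str, Sequence[str]],
    predicted: Mapping[str, Sequence[str]],
    tokens: Mapping[str, Sequence[TokenSpan]],
    lexicons: Mapping[str, Lexicon],
    participants: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict]:
    """Bucket false negatives and false positives by mechanical proxies.

    Missed names (FN): common-word member → ``ambiguous_common_word``;
    proper-name-list member → ``proper_name``; length ≤ 3 →
    ``abbreviation_acronym``; within 2 edits of a participant username →
    ``misspelled_username``; else ``other`` — checked in that order.
    Spurious names (FP): proper-name list → ``people``; location list (if
    one is supplied under the key ``location_word``) → ``places_institutions``;
    medical or drug list → ``medical``; else ``other``. Bucket counts sum
    to the FN / FP totals; percentages accompany the counts.
    """
    participants = participants or {}
    fn_buckets: Counter = Counter()
    fp_buckets: Counter = Counter()
    common = lexicons.get("common_word")
    proper = lexicons.get("proper_name")
    medical = lexicons.get("medical_word")
    drug = lexicons.get("drug_word")
    location = lexicons.get("location_word")

    for mid, toks in tokens.items():
        g, p = gold[mid], predicted[mid]
        users = participants.get(mid, ())
        for tok, gl, pl in zip(toks, g, p):
            if tok.is_punct:
                continue
            t = tok.text.lower()
            if _is_name(gl) and not _is_name(pl):
                if common is not None and t in common:
                    fn_buckets["ambiguous_common_word"] += 1
                elif proper is not None and t in proper:
                    fn_buckets["proper_name"] += 1
                elif len(t) <= 3:
                    fn_buckets["abbreviation_acronym"] += 1
                elif any(
                    damerau_levenshtein(t, u.lower()) <= 2 for u in users
                ):
                    fn_buckets["misspelled_username"] += 1
                else:
                    fn_buckets["other"] += 1
            elif not _is_name(gl) and _is_name(pl):
                if proper is not None and t in proper:
                    fp_buckets["people"] += 1
                elif location is not None and t in location:
                    fp_buckets["places_institutions"] += 1
                elif (medical is not None and t in medical) or (
                    drug is not None and t in drug
                ):
                    fp_buckets["medical"] += 1
                else:
                    fp_buckets["other"] += 1

    def table(buckets: Counter) -> dict:
        total = sum(buckets.values())
        return {
            "counts": dict(buckets),
            "total": total,
            "percentages": {
                k: round(100.0 * v / total, 1) for k, v in buckets.items()
            }
            if total
            else {},
        }

    return {
        "false_negatives": table(fn_buckets),
        "false_positives": table(fp_buckets),
    }
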