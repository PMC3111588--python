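"""Linear-chain conditional random field.

A discriminative sequence model: the probability of a label sequence y
for an observation sequence x is

    p(y | x) ∝ exp( Σ_t  w_state · f(x, t, y_t)  +  Σ_t w_trans[y_t, y_{t+1}]
                    + w_start[y_1] + w_end[y_T] )

with binary observation features f. Training maximizes the conditional
log-likelihood with an L2 penalty via L-BFGS; the partition function,
per-token marginals and pairwise expectations come from the
forward–backward recursions, run in log space and batched over all
sequences at once (sequences are padded to a common length, with padded
steps carrying the last valid value forward so the final forward vector
of each sequence is always in the last slot).

Only features seen in training enter the model; unseen feature strings
at prediction time are ignored. Training from a fixed dataset is fully
deterministic (zero initialization, no sampling).
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

__all__ = ["LinearChainCRF"]


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


class LinearChainCRF:
    """Log-linear sequence labeler over string-valued binary features.

    Parameters
    ----------
    c2:
        L2 regularization strength (penalty is ``c2 * ||w||^2``).
    max_iter:
        L-BFGS iteration cap.
    min_feature_count:
        Observation features seen fewer times than this in training are
        dropped from the model.
    """

    def __init__(self, c2: float = 0.1, max_iter: int = 120, min_feature_count: int = 1):
        self.c2 = float(c2)
        self.max_iter = int(max_iter)
        self.min_feature_count = int(min_feature_count)
        self.labels: tuple[str, ...] = ()
        self.vocab: dict[str, int] = {}
        self.w_state: np.ndarray | None = None  # (K, F)
        self.w_trans: np.ndarray | None = None  # (K, K)
        self.w_start: np.ndarray | None = None  # (K,)
        self.w_end: np.ndarray | None = None  # (K,)

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        X: Sequence[Sequence[Iterable[str]]],
        y: Sequence[Sequence[str]],
        labels: Sequence[str] | None = None,
    ) -> "LinearChainCRF":
        """Train on sequences of feature-string collections and labels."""
        if len(X) != len(y):
            raise ValueError("X and y must have the same number of sequences")
        seqs = [(xs, ys) for xs, ys in zip(X, y) if len(xs) > 0]
        for i, (xs, ys) in enumerate(seqs):
            if len(xs) != len(ys):
                raise ValueError(f"sequence {i}: {len(xs)} tokens vs {len(ys)} labels")
        if not seqs:
            raise ValueError("no non-empty training sequences")

        if labels is None:
            labels = sorted({lab for _, ys in seqs for lab in ys})
        self.labels = tuple(labels)
        lab_idx = {lab: k for k, lab in enumerate(self.labels)}
        K = len(self.labels)

        counts: dict[str, int] = {}
        for xs, _ in seqs:
            for feats in xs:
                for f in feats:
                    counts[f] = counts.get(f, 0) + 1
        self.vocab = {
            f: i
            for i, f in enumerate(
                f for f, c in counts.items() if c >= self.min_feature_count
            )
        }
        F = len(self.vocab)

        lengths = np.array([len(xs) for xs, _ in seqs], dtype=np.int64)
        B, L = len(seqs), int(lengths.max())
        T_total = int(lengths.sum())

        indptr = [0]
        indices: list[int] = []
        y_flat = np.empty(T_total, dtype=np.int64)
        pos = 0
        for xs, ys in seqs:
            for feats, lab in zip(xs, ys):
                try:
                    y_flat[pos] = lab_idx[lab]
                except KeyError:
                    raise ValueError(f"label {lab!r} not in label set {self.labels}")
                for f in feats:
                    j = self.vocab.get(f)
                    if j is not None:
                        indices.append(j)
                indptr.append(len(indices))
                pos += 1
        M = sp.csr_matrix(
            (
                np.ones(len(indices), dtype=np.float64),
                np.asarray(indices, dtype=np.int64),
                np.asarray(indptr, dtype=np.int64),
            ),
            shape=(T_total, F),
        )

        # flat-position <-> (sequence, step) maps for padding/unpadding
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        seq_of = np.repeat(np.arange(B), lengths)
        step_of = np.arange(T_total) - offsets[seq_of]
        valid = np.arange(L)[None, :] < lengths[:, None]  # (B, L)

        Y1 = np.zeros((T_total, K))
        Y1[np.arange(T_total), y_flat] = 1.0
        emp_state = np.asarray(M.T.dot(Y1)).T  # (K, F)
        emp_trans = np.zeros((K, K))
        emp_start = np.zeros(K)
        emp_end = np.zeros(K)
        for b in range(B):
            ys = y_flat[offsets[b] : offsets[b + 1]]
            np.add.at(emp_trans, (ys[:-1], ys[1:]), 1.0)
            emp_start[ys[0]] += 1.0
            emp_end[ys[-1]] += 1.0

        non_other = [k for k, lab in enumerate(self.labels) if lab != "OTHER"]
        if K > 1 and non_other and not np.isin(y_flat, non_other).any():
            warnings.warn(
                "training data contains no non-OTHER labels; "
                "name marginals may be degenerate",
                stacklevel=2,
            )

        MT = M.T.tocsc()
        n_state = K * F

        def unpack(w):
            Ws = w[:n_state].reshape(K, F)
            Wt = w[n_state : n_state + K * K].reshape(K, K)
            ws = w[n_state + K * K : n_state + K * K + K]
            we = w[n_state + K * K + K :]
            return Ws, Wt, ws, we

        def objective(w):
            Ws, Wt, ws, we = unpack(w)
            scores_flat = M.dot(Ws.T)  # (T, K)
            S = np.zeros((B, L, K))
            S[seq_of, step_of] = scores_flat

            alpha = np.empty((B, L, K))
            alpha[:, 0] = ws[None, :] + S[:, 0]
            for t in range(1, L):
                v = alpha[:, t - 1, :, None] + Wt[None, :, :]  # (B, K, K)
                new = S[:, t] + _logsumexp(v, axis=1)
                alpha[:, t] = np.where(valid[:, t, None], new, alpha[:, t - 1])
            logZ = _logsumexp(alpha[:, L - 1] + we[None, :], axis=1)  # (B,)

            # backward pass as a forward pass over reversed sequences
            S_rev = np.zeros_like(S)
            rev_idx = (lengths[seq_of] - 1 - step_of)
            S_rev[seq_of, rev_idx] = scores_flat
            gamma = np.empty((B, L, K))
            gamma[:, 0] = we[None, :]
            for u in range(1, L):
                v = (gamma[:, u - 1] + S_rev[:, u - 1])[:, None, :] + Wt[None, :, :]
                new = _logsumexp(v, axis=2)
                gamma[:, u] = np.where(valid[:, u, None], new, gamma[:, u - 1])
            beta = np.empty_like(gamma)
            beta[seq_of, step_of] = gamma[seq_of, rev_idx]

            logP = alpha + beta - logZ[:, None, None]
            P = np.where(valid[:, :, None], np.exp(logP), 0.0)  # (B, L, K)
            P_flat = P[seq_of, step_of]  # (T, K)

            exp_state = np.asarray(MT.dot(P_flat)).T  # (K, F)
            exp_trans = np.zeros((K, K))
            for t in range(L - 1):
                pair_valid = valid[:, t + 1]
                if not pair_valid.any():
                    break
                lp = (
                    alpha[:, t, :, None]
                    + Wt[None, :, :]
                    + (S[:, t + 1] + beta[:, t + 1])[:, None, :]
                    - logZ[:, None, None]
                )
                exp_trans += np.exp(lp[pair_valid]).sum(axis=0)
            exp_start = P[:, 0, :].sum(axis=0)
            exp_end = P[np.arange(B), lengths - 1, :].sum(axis=0)

            gold = (
                float((emp_state * Ws).sum())
                + float((emp_trans * Wt).sum())
                + float(emp_start @ ws)
                + float(emp_end @ we)
            )
            nll = float(logZ.sum()) - gold + self.c2 * float(w @ w)
            grad = np.concatenate(
                [
                    (exp_state - emp_state).ravel(),
                    (exp_trans - emp_trans).ravel(),
                    exp_start - emp_start,
                    exp_end - emp_end,
                ]
            ) + 2.0 * self.c2 * w
            return nll, grad

        w0 = np.zeros(n_state + K * K + 2 * K)
        res = minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxfun": 3 * self.max_iter},
        )
        Ws, Wt, ws, we = unpack(res.x)
        self.w_state, self.w_trans, self.w_start, self.w_end = Ws, Wt, ws, we
        return self

    # ------------------------------------------------------------ inference

    def _check_fitted(self) -> None:
        if self.w_state is None:
            raise RuntimeError("CRF is not fitted")

    def _score_sequence(self, xs: Sequence[Iterable[str]]) -> np.ndarray:
        assert self.w_state is not None
        T, K = len(xs), len(self.labels)
        s = np.zeros((T, K))
        for t, feats in enumerate(xs):
            idx = [self.vocab[f] for f in feats if f in self.vocab]
            if idx:
                s[t] = self.w_state[:, idx].sum(axis=1)
        return s

    def predict_marginals(self, xs: Sequence[Iterable[str]]) -> np.ndarray:
        """Per-token marginal label probabilities, shape (T, K).

        Rows sum to 1; the label order is ``self.labels``.
        """
        self._check_fitted()
        T, K = len(xs), len(self.labels)
        if T == 0:
            return np.zeros((0, K))
        s = self._score_sequence(xs)
        Wt, ws, we = self.w_trans, self.w_start, self.w_end
        alpha = np.empty((T, K))
        alpha[0] = ws + s[0]
        for t in range(1, T):
            alpha[t] = s[t] + _logsumexp(alpha[t - 1][:, None] + Wt, axis=0)
        beta = np.empty((T, K))
        beta[T - 1] = we
        for t in range(T - 2, -1, -1):
            beta[t] = _logsumexp(Wt + (s[t + 1] + beta[t + 1])[None, :], axis=1)
        logZ = _logsumexp(alpha[T - 1] + we, axis=0)
        P = np.exp(alpha + beta - logZ)
        return P / P.sum(axis=1, keepdims=True)

    # -------------------------------------------------------- serialization

    def save(self, path) -> None:
        self._check_fitted()
        meta = {
            "labels": list(self.labels),
            "c2": self.c2,
            "max_iter": self.max_iter,
            "min_feature_count": self.min_feature_count,
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            vocab=np.array(list(self.vocab.keys()), dtype=object),
            w_state=self.w_state,
            w_trans=self.w_trans,
            w_start=self.w_start,
            w_end=self.w_end,
        )

    @classmethod
    def load(cls, path) -> "LinearChainCRF":
        with np.load(path, allow_pickle=True) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            crf = cls(
                c2=meta["c2"],
                max_iter=meta["max_iter"],
                min_feature_count=meta["min_feature_count"],
            )
            crf.labels = tuple(meta["labels"])
            crf.vocab = {f: i for i, f in enumerate(z["vocab"].tolist())}
            crf.w_state = z["w_state"]
            crf.w_trans = z["w_trans"]
            crf.w_start = z["w_start"]
            crf.w_end = z["w_end"]
        return crf
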