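"""Linear-chain conditional random field: scoring, exact inference, loss.

A sequence ``Y = y_1..y_n`` over label set ``L`` is scored as

    score(Y) = sum_i E(i, y_i) + T(y_{i-1}, y_i)      with y_0 = START

where ``E`` are per-token emission scores and ``T`` is the transition
matrix, whose extra START row gives the initial-label scores (no explicit
STOP transitions by default). ``P(Y|X) = exp score(Y) / Z`` with the
partition function ``Z`` summed over all |L|^n sequences, computed exactly
by the forward recursion in log space (max-shifted log-sum-exp throughout).
Training minimizes the sentence-level negative log-likelihood; decoding is
exact Viterbi with ties broken toward the lowest label index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "CrfParams",
    "UnknownLabelError",
    "crf_gradients",
    "emission_scores",
    "log_partition",
    "nll_loss",
    "sequence_prob",
    "sequence_score",
    "viterbi_decode",
]


class UnknownLabelError(KeyError):
    """A label outside the CRF's label set."""


@dataclass
class CrfParams:
    """Label inventory, emission map and transition matrix.

    ``W`` maps fused features (width ``d_f``) linearly to per-label emission
    scores (Eq. uses a single affine map; no bias term). ``T`` has shape
    ``(|L|+1, |L|)``; its last row is the dedicated START symbol.
    """

    labels: list[str]
    W: np.ndarray  # (d_f, |L|)
    T: np.ndarray  # (|L|+1, |L|)

    def __post_init__(self):
        L = len(self.labels)
        if len(set(self.labels)) != L:
            raise ValueError("duplicate labels")
        if self.W.ndim != 2 or self.W.shape[1] != L:
            raise ValueError(f"W has shape {self.W.shape}, expected (d_f, {L})")
        if self.T.shape != (L + 1, L):
            raise ValueError(f"T has shape {self.T.shape}, expected {(L + 1, L)}")
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def start(self) -> int:
        return len(self.labels)

    def encode(self, labels: list[str]) -> np.ndarray:
        try:
            return np.array([self.index[lab] for lab in labels], dtype=np.int64)
        except KeyError as e:
            raise UnknownLabelError(e.args[0]) from None

    def decode(self, indices) -> list[str]:
        return [self.labels[i] for i in indices]

    @classmethod
    def init(
        cls, labels: list[str], d_f: int, seed: int | np.random.Generator = 0
    ) -> "CrfParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        L = len(labels)
        W = rng.normal(0.0, 1.0 / np.sqrt(d_f), size=(d_f, L))
        T = np.zeros((L + 1, L))
        return cls(labels=list(labels), W=W, T=T)


def emission_scores(F: np.ndarray, params: CrfParams) -> np.ndarray:
    """``E = F W`` (f in the emission term is the identity)."""
    return F @ params.W


def _check(E: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    if E.ndim != 2 or E.shape[0] < 1:
        raise ValueError("E must be (n, |L|) with n >= 1")
    n, L = E.shape
    if T.shape != (L + 1, L):
        raise ValueError(f"T has shape {T.shape}, expected {(L + 1, L)}")
    return E, T, n, L


def sequence_score(E: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """Unexponentiated score of one label-index sequence (START-prefixed)."""
    E, T, n, L = _check(E, T)
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (n,):
        raise ValueError(f"label sequence length {y.shape} != {n}")
    if np.any(y < 0) or np.any(y >= L):
        raise UnknownLabelError("label index out of range")
    prev = np.concatenate([[L], y[:-1]])  # START then shifted labels
    return float(E[np.arange(n), y].sum() + T[prev, y].sum())


def log_partition(E: np.ndarray, T: np.ndarray) -> float:
    """log sum over all |L|^n sequences of exp(score), by forward recursion."""
    E, T, n, L = _check(E, T)
    fwd = E[0] + T[L]
    for t in range(1, n):
        fwd = E[t] + logsumexp(fwd[:, None] + T[:L], axis=0)
    return float(logsumexp(fwd))


def sequence_prob(E: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """``P(Y|X)`` for one sequence; lies in (0, 1]."""
    return float(np.exp(sequence_score(E, T, y) - log_partition(E, T)))


def nll_loss(batch: list[tuple[np.ndarray, np.ndarray]], T: np.ndarray) -> float:
    """Sum over sentences of ``log Z - score(Y_gold)``; always >= 0."""
    if not batch:
        raise ValueError("empty batch")
    total = 0.0
    for E, y in batch:
        E = np.asarray(E, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if E.shape[0] != y.shape[0]:
            raise ValueError(f"emissions for {E.shape[0]} tokens but {y.shape[0]} labels")
        total += log_partition(E, T) - sequence_score(E, T, y)
    return float(total)


def crf_gradients(
    E: np.ndarray, T: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL of one sentence plus analytic gradients w.r.t. ``E`` and ``T``.

    Uses the forward-backward recursions: the gradient of ``log Z`` w.r.t.
    an emission is the posterior marginal of that (position, label), and
    w.r.t. a transition entry the expected transition count; the gold
    sequence contributes its observed counts with opposite sign.
    """
    E, T, n, L = _check(E, T)
    y = np.asarray(y, dtype=np.int64)
    if y.shape != (n,):
        raise ValueError("label length mismatch")

    fwd = np.empty((n, L))
    fwd[0] = E[0] + T[L]
    for t in range(1, n):
        fwd[t] = E[t] + logsumexp(fwd[t - 1][:, None] + T[:L], axis=0)
    logZ = float(logsumexp(fwd[-1]))

    bwd = np.zeros((n, L))
    for t in range(n - 2, -1, -1):
        bwd[t] = logsumexp(T[:L] + (E[t + 1] + bwd[t + 1])[None, :], axis=1)

    marg = np.exp(fwd + bwd - logZ)  # (n, L) posterior marginals
    dE = marg.copy()
    dE[np.arange(n), y] -= 1.0

    dT = np.zeros_like(T)
    dT[L] = marg[0]
    dT[L, y[0]] -= 1.0
    for t in range(n - 1):
        pair = np.exp(
            fwd[t][:, None] + T[:L] + (E[t + 1] + bwd[t + 1])[None, :] - logZ
        )
        dT[:L] += pair
        dT[y[t], y[t + 1]] -= 1.0

    nll = logZ - sequence_score(E, T, y)
    return float(nll), dE, dT


def viterbi_decode(E: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Exact argmax label-index sequence.

    Ties are broken toward the lowest label index at each backtracking step
    (``argmax`` keeps the first maximum).
    """
    E, T, n, L = _check(E, T)
    delta = E[0] + T[L]
    back = np.zeros((n, L), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + T[:L]  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)
        delta = E[t] + cand[back[t], np.arange(L)]
    y = np.empty(n, dtype=np.int64)
    y[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        y[t - 1] = back[t, y[t]]
    return y
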