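"""Pluggable token/node encoders.

The full-scale architecture embeds sentences and KG node surface forms with a
pre-trained biomedical transformer; here that sits behind a minimal contract
(a callable from a list of word strings to an ``n x d`` real matrix,
registered by name) so any contextual encoder can be plugged in. The shipped
reference encoder is a trainable word-lookup table: deterministic, fast, and
sufficient for desk-scale experiments where contextualization is supplied by
the knowledge pathway rather than the encoder.

Node surface forms are encoded by pooling their word vectors (mean pooling
for the lookup encoder; transformer plug-ins are expected to return a
summary vector for the boundary-marked word sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Sentence
from .kg import KnowledgeGraph, SentenceGraph

__all__ = [
    "ENCODER_REGISTRY",
    "EncoderConfig",
    "LookupEncoder",
    "WidthMismatchError",
    "encode_nodes",
    "encode_tokens",
    "make_encoder",
    "register_encoder",
]


class WidthMismatchError(ValueError):
    """An encoder returned vectors of the wrong width."""


@dataclass
class EncoderConfig:
    """Encoder settings.

    ``d`` defaults to 512, matching the hidden size used at full scale;
    desk-scale runs typically use 16-32. ``seed`` fixes the lookup-table
    initialization; ``lowercase`` controls vocabulary normalization.
    """

    kind: str = "lookup"
    d: int = 512
    lowercase: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("embedding width d must be >= 1")


ENCODER_REGISTRY: dict = {}


def register_encoder(name: str):
    """Register an encoder factory ``(cfg, vocabulary) -> encoder``."""

    def deco(factory):
        ENCODER_REGISTRY[name] = factory
        return factory

    return deco


def make_encoder(cfg: EncoderConfig, vocabulary=()):
    try:
        factory = ENCODER_REGISTRY[cfg.kind]
    except KeyError:
        raise KeyError(
            f"unknown encoder kind {cfg.kind!r}; registered: {sorted(ENCODER_REGISTRY)}"
        ) from None
    return factory(cfg, vocabulary)


@register_encoder("lookup")
class LookupEncoder:
    """Trainable per-word embedding table with a shared OOV vector.

    A pure function of (input words, table, seed): repeated calls are
    bitwise identical. Out-of-vocabulary words all map to the single OOV
    row, so whatever the training procedure learns for unseen words is
    shared across them.
    """

    def __init__(self, cfg: EncoderConfig, vocabulary=()):
        self.cfg = cfg
        self.vocab: dict[str, int] = {}
        for w in vocabulary:
            self.vocab.setdefault(self._norm(w), len(self.vocab))
        self.oov_index = len(self.vocab)
        rng = np.random.default_rng(cfg.seed)
        # small init keeps LeakyReLU pre-activations near the linear regime
        self.table = rng.normal(0.0, 0.1, size=(self.oov_index + 1, cfg.d))

    def _norm(self, word: str) -> str:
        return word.lower() if self.cfg.lowercase else word

    @property
    def d(self) -> int:
        return self.cfg.d

    def word_indices(self, words: list[str]) -> np.ndarray:
        return np.array(
            [self.vocab.get(self._norm(w), self.oov_index) for w in words], dtype=np.int64
        )

    def __call__(self, words: list[str]) -> np.ndarray:
        return self.table[self.word_indices(words)]


def encode_tokens(sentence: Sentence, encoder) -> np.ndarray:
    """Token embeddings ``S`` (one row per token)."""
    S = np.asarray(encoder(list(sentence.tokens)), dtype=float)
    d = getattr(encoder, "d", S.shape[1] if S.ndim == 2 else None)
    if S.ndim != 2 or S.shape != (len(sentence.tokens), d):
        raise WidthMismatchError(
            f"encoder returned shape {S.shape}, expected ({len(sentence.tokens)}, {d})"
        )
    if not np.all(np.isfinite(S)):
        raise ValueError("encoder produced non-finite values")
    return S


def encode_nodes(graph: SentenceGraph, kg: KnowledgeGraph, encoder) -> np.ndarray:
    """Node embeddings ``V'``: one pooled vector per sentence-graph node.

    Each node's surface form is split into words, encoded, and mean-pooled.
    Nodes with identical surface forms therefore get identical rows.
    """
    if graph.n_nodes == 0:
        return np.zeros((0, getattr(encoder, "d", 0)))
    rows = []
    for node_id in graph.node_ids:
        words = kg.surface_forms[node_id].split()
        M = np.asarray(encoder(words), dtype=float)
        if M.ndim != 2 or M.shape[0] != len(words):
            raise WidthMismatchError(f"encoder returned shape {M.shape} for {len(words)} words")
        rows.append(M.mean(axis=0))
    V = np.vstack(rows)
    if not np.all(np.isfinite(V)):
        raise ValueError("encoder produced non-finite values")
    return V
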