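"""Token-node alignment and linear fusion of the two embedding streams.

The GAT outputs one vector per sentence-graph node; tokens and nodes live on
different index sets. Alignment broadcasts each node vector across every
token of its matched span and fills unmatched tokens with zeros, after which
the two streams are projected into a common hidden space and added:

    F = S w1 + H~ w2

No nonlinearity follows the sum. Setting ``w2 = 0`` reduces the pipeline
exactly to the knowledge-free model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg import SentenceGraph

__all__ = ["FusionParams", "align_backward", "align_nodes_to_tokens", "fuse", "fuse_backward"]


class ShapeMismatchError(ValueError):
    """Operand shapes incompatible with the fusion maps."""


@dataclass
class FusionParams:
    """Trainable projections into the fused space (width ``d_f``)."""

    w1: np.ndarray  # (d, d_f): token stream
    w2: np.ndarray  # (K*d_h, d_f): knowledge stream

    def __post_init__(self):
        if self.w1.ndim != 2 or self.w2.ndim != 2 or self.w1.shape[1] != self.w2.shape[1]:
            raise ShapeMismatchError("w1 and w2 must be matrices mapping into the same d_f")

    @property
    def d_f(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def init(
        cls, d: int, knowledge_width: int, d_f: int, seed: int | np.random.Generator = 0
    ) -> "FusionParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        w1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, d_f))
        w2 = rng.normal(0.0, 1.0 / np.sqrt(knowledge_width), size=(knowledge_width, d_f))
        return cls(w1=w1, w2=w2)


def align_nodes_to_tokens(H: np.ndarray, graph: SentenceGraph, n: int) -> np.ndarray:
    """Broadcast node vectors to their matched tokens; zeros elsewhere."""
    width = H.shape[1] if H.ndim == 2 else 0
    out = np.zeros((n, width))
    for tok, local in graph.alignment.items():
        if tok < n:  # tokens beyond a truncation boundary are dropped
            out[tok] = H[local]
    return out


def align_backward(dHt: np.ndarray, graph: SentenceGraph, m: int) -> np.ndarray:
    """Adjoint of :func:`align_nodes_to_tokens`: sum token grads per node."""
    dH = np.zeros((m, dHt.shape[1]))
    for tok, local in graph.alignment.items():
        if tok < dHt.shape[0]:
            dH[local] += dHt[tok]
    return dH


def fuse(S: np.ndarray, Ht: np.ndarray, params: FusionParams) -> np.ndarray:
    """``F = S w1 + H~ w2`` - exactly linear in both arguments."""
    if S.shape[0] != Ht.shape[0]:
        raise ShapeMismatchError(f"row counts differ: S {S.shape} vs aligned nodes {Ht.shape}")
    if S.shape[1] != params.w1.shape[0] or Ht.shape[1] != params.w2.shape[0]:
        raise ShapeMismatchError(
            f"widths {S.shape[1]}/{Ht.shape[1]} do not fit maps {params.w1.shape}/{params.w2.shape}"
        )
    return S @ params.w1 + Ht @ params.w2


def fuse_backward(
    dF: np.ndarray, S: np.ndarray, Ht: np.ndarray, params: FusionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Returns ``(dS, dHt, dw1, dw2)``."""
    dS = dF @ params.w1.T
    dHt = dF @ params.w2.T
    dw1 = S.T @ dF
    dw2 = Ht.T @ dF
    return dS, dHt, dw1, dw2
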