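"""Multi-head graph attention over the sentence's knowledge subgraph.

Each node ``i`` attends over its first-order neighborhood ``N_i`` (read off
the adjacency matrix, which always includes the self-loop):

    alpha_ij^k = softmax_{j in N_i} LeakyReLU( a_k . [W_k v'_i || W_k v'_j] )
    g_i^k      = LeakyReLU( sum_{j in N_i} alpha_ij^k W_k v'_j + residual(v'_i) )
    h_i        = concat_k g_i^k

The residual adds the raw node vector when the input width equals the head
width; otherwise a learned per-head projection ``W_r`` maps it down. One
layer is used by default. Forward/backward are implemented directly in
NumPy; :func:`gat_backward` returns analytic gradients for every parameter
(checked against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttentionScores", "GatParams", "attention_scores", "gat_backward", "gat_forward"]


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _dleaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


@dataclass
class GatParams:
    """Learnable parameters and hyperparameters of one GAT layer.

    ``W``: (K, d, d_h) per-head projections; ``a``: (K, 2*d_h) per-head
    attention vectors; ``Wr``: (K, d, d_h) residual projections, present only
    when ``d != d_h`` (otherwise the residual is the raw input). The output
    width is ``K * d_h``.
    """

    K: int
    d: int
    d_h: int
    W: np.ndarray
    a: np.ndarray
    Wr: np.ndarray | None = None
    leaky_slope: float = 0.2
    dropout: float = 0.2

    def __post_init__(self):
        if self.K < 1 or self.d_h < 1:
            raise ValueError("K and d_h must be >= 1")
        if not (0 < self.leaky_slope < 1):
            raise ValueError("leaky_slope must lie in (0, 1)")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.W.shape != (self.K, self.d, self.d_h):
            raise ValueError(f"W has shape {self.W.shape}, expected {(self.K, self.d, self.d_h)}")
        if self.a.shape != (self.K, 2 * self.d_h):
            raise ValueError(f"a has shape {self.a.shape}, expected {(self.K, 2 * self.d_h)}")
        if self.d != self.d_h and self.Wr is None:
            raise ValueError("Wr required when d != d_h")

    @property
    def out_width(self) -> int:
        return self.K * self.d_h

    @classmethod
    def init(
        cls,
        d: int,
        d_h: int = 50,
        K: int = 4,
        seed: int | np.random.Generator = 0,
        leaky_slope: float = 0.2,
        dropout: float = 0.2,
    ) -> "GatParams":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(d)
        W = rng.normal(0.0, scale, size=(K, d, d_h))
        a = rng.normal(0.0, 0.1, size=(K, 2 * d_h))
        Wr = None if d == d_h else rng.normal(0.0, scale, size=(K, d, d_h))
        return cls(K=K, d=d, d_h=d_h, W=W, a=a, Wr=Wr, leaky_slope=leaky_slope, dropout=dropout)


@dataclass
class AttentionScores:
    """Per-head attention matrix; entries off the neighborhood support are 0."""

    alpha: np.ndarray
    head: int
    support: np.ndarray = field(repr=False, default=None)


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.diag(A) == 1):
        raise ValueError("adjacency diagonal must be all ones (self-loops)")
    return A > 0


def attention_scores(
    V: np.ndarray, adjacency: np.ndarray, params: GatParams, head: int
) -> AttentionScores:
    """Softmax-normalized neighborhood attention for one head (no dropout).

    Rows sum to 1 over exactly the neighborhood support; non-neighbors carry
    no mass. Isolated nodes cannot occur because the diagonal is 1.
    """
    support = _check_adjacency(adjacency)
    U = V @ params.W[head]
    s_src = U @ params.a[head, : params.d_h]
    s_dst = U @ params.a[head, params.d_h :]
    logits = leaky_relu(s_src[:, None] + s_dst[None, :], params.leaky_slope)
    masked = np.where(support, logits, -np.inf)
    masked -= masked.max(axis=1, keepdims=True)
    expd = np.exp(masked)
    alpha = expd / expd.sum(axis=1, keepdims=True)
    return AttentionScores(alpha=alpha, head=head, support=support)


def gat_forward(
    V: np.ndarray,
    adjacency: np.ndarray,
    params: GatParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """One GAT layer: returns updated node embeddings ``H`` (m x K*d_h).

    During training, inverted dropout is applied to the input embeddings and
    to the attention weights (the standard GAT recipe); at inference both
    are disabled. The returned cache holds everything
    :func:`gat_backward` needs.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] != params.d:
        raise ValueError(f"V has shape {V.shape}, expected (m, {params.d})")
    support = _check_adjacency(adjacency)
    m = V.shape[0]

    drop = params.dropout if training else 0.0
    if drop > 0 and rng is None:
        raise ValueError("training-mode dropout needs an rng")
    keep = 1.0 - drop
    in_mask = (
        (rng.random(V.shape) < keep).astype(float) / keep if drop > 0 else np.ones_like(V)
    )
    Vd = V * in_mask

    cache: dict = {
        "params": params,
        "Vd": Vd,
        "in_mask": in_mask,
        "support": support,
        "heads": [],
    }
    outs = []
    for k in range(params.K):
        U = Vd @ params.W[k]
        s_src = U @ params.a[k, : params.d_h]
        s_dst = U @ params.a[k, params.d_h :]
        raw = s_src[:, None] + s_dst[None, :]
        logits = leaky_relu(raw, params.leaky_slope)
        masked = np.where(support, logits, -np.inf)
        shifted = masked - masked.max(axis=1, keepdims=True)
        expd = np.exp(shifted)
        alpha = expd / expd.sum(axis=1, keepdims=True)
        att_mask = (
            (rng.random(alpha.shape) < keep).astype(float) / keep
            if drop > 0
            else np.ones_like(alpha)
        )
        alpha_d = alpha * att_mask
        M = alpha_d @ U
        if params.d == params.d_h:
            R = Vd
        else:
            R = Vd @ params.Wr[k]
        P = M + R
        G = leaky_relu(P, params.leaky_slope)
        outs.append(G)
        cache["heads"].append(
            {"U": U, "raw": raw, "alpha": alpha, "att_mask": att_mask, "alpha_d": alpha_d, "P": P}
        )
    H = np.concatenate(outs, axis=1) if m else np.zeros((0, params.out_width))
    return H, cache


def gat_backward(dH: np.ndarray, cache: dict) -> tuple[np.ndarray, dict]:
    """Backpropagate through :func:`gat_forward`.

    Returns ``(dV, grads)`` with ``grads`` holding ``W``, ``a`` and (when
    present) ``Wr`` arrays shaped like the parameters.
    """
    params: GatParams = cache["params"]
    Vd = cache["Vd"]
    support = cache["support"]
    slope = params.leaky_slope
    a1, a2 = params.a[:, : params.d_h], params.a[:, params.d_h :]

    dVd = np.zeros_like(Vd)
    gW = np.zeros_like(params.W)
    ga = np.zeros_like(params.a)
    gWr = np.zeros_like(params.Wr) if params.Wr is not None else None

    for k in range(params.K):
        hc = cache["heads"][k]
        U, raw, alpha, att_mask, alpha_d = (
            hc["U"],
            hc["raw"],
            hc["alpha"],
            hc["att_mask"],
            hc["alpha_d"],
        )
        dG = dH[:, k * params.d_h : (k + 1) * params.d_h]
        dP = dG * _dleaky(hc["P"], slope)
        # residual branch
        if params.d == params.d_h:
            dVd += dP
        else:
            gWr[k] = Vd.T @ dP
            dVd += dP @ params.Wr[k].T
        # message branch: M = alpha_d @ U
        dalpha_d = dP @ U.T
        dU = alpha_d.T @ dP
        dalpha = dalpha_d * att_mask
        # softmax rows over support
        rowdot = (dalpha * alpha).sum(axis=1, keepdims=True)
        dlogits = alpha * (dalpha - rowdot)
        dlogits = np.where(support, dlogits, 0.0)
        draw = dlogits * _dleaky(raw, slope)
        ds_src = draw.sum(axis=1)
        ds_dst = draw.sum(axis=0)
        dU += np.outer(ds_src, a1[k]) + np.outer(ds_dst, a2[k])
        ga[k, : params.d_h] = U.T @ ds_src
        ga[k, params.d_h :] = U.T @ ds_dst
        gW[k] = Vd.T @ dU
        dVd += dU @ params.W[k].T

    dV = dVd * cache["in_mask"]
    grads = {"W": gW, "a": ga}
    if gWr is not None:
        grads["Wr"] = gWr
    return dV, grads
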