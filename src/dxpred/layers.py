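"""Reusable computational blocks of the prediction models.

All functions operate on batched row-vector tensors: a "vector" argument of
the mathematical description becomes a (B, dim) tensor here. Weight matrices
use the (in_dim, out_dim) right-multiplication convention (the transpose of
the usual column-vector notation W v).

Blocks provided: affine (fully connected) layer, GRU step/sequence,
location-based attention, graph-based (ontology) attention, the two-level
reverse-time attention context used by RETAIN, visit embedding, and a
numerically stabilised softmax head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import CodeUniverse, OntologyDAG


def uniform_param(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
                  name: str = "") -> Tensor:
    bound = np.sqrt(1.0 / fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True,
                  name=name)


def zeros_param(shape, name: str = "") -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True, name=name)


def _rowvec(v: Tensor) -> tuple[Tensor, bool]:
    if v.ndim == 1:
        return ag.reshape(v, (1, v.shape[0])), True
    return v, False


# -- fully connected ----------------------------------------------------------


def fully_connected(v: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Affine map h = v W + b (no nonlinearity)."""
    v2, squeeze = _rowvec(v)
    if v2.shape[-1] != W.shape[0]:
        raise ValueError(f"shape mismatch: input dim {v2.shape[-1]} vs W {W.shape}")
    out = v2 @ W + b
    return ag.reshape(out, (W.shape[1],)) if squeeze else out


# -- GRU ----------------------------------------------------------------------


@dataclass
class GRUParams:
    """Gated recurrent unit parameters (update gate z, reset gate r).

    The recurrence, with logistic sigmoid gates:
        z_t = sigmoid(v_t W_z + h_{t-1} U_z + b_z)
        r_t = sigmoid(v_t W_r + h_{t-1} U_r + b_r)
        hcand = tanh(v_t W_h + r_t * (h_{t-1} U_h) + b_h)
        h_t = z_t * h_{t-1} + (1 - z_t) * hcand
    Note the convex combination places the *update* gate on the previous
    state, so zero parameters give h_t = 0.5 h_{t-1}.
    """

    W_z: Tensor
    W_r: Tensor
    W_h: Tensor
    U_z: Tensor
    U_r: Tensor
    U_h: Tensor
    b_z: Tensor
    b_r: Tensor
    b_h: Tensor

    @property
    def hidden_dim(self) -> int:
        return self.U_z.shape[0]

    def parameters(self, prefix: str = "gru") -> dict[str, Tensor]:
        return {f"{prefix}.{k}": getattr(self, k)
                for k in ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h",
                          "b_z", "b_r", "b_h")}


def init_gru(in_dim: int, g: int, rng: np.random.Generator,
             prefix: str = "gru") -> GRUParams:
    if g < 1:
        raise ValueError("hidden dim must be >= 1")
    return GRUParams(
        W_z=uniform_param(rng, (in_dim, g), in_dim, f"{prefix}.W_z"),
        W_r=uniform_param(rng, (in_dim, g), in_dim, f"{prefix}.W_r"),
        W_h=uniform_param(rng, (in_dim, g), in_dim, f"{prefix}.W_h"),
        U_z=uniform_param(rng, (g, g), g, f"{prefix}.U_z"),
        U_r=uniform_param(rng, (g, g), g, f"{prefix}.U_r"),
        U_h=uniform_param(rng, (g, g), g, f"{prefix}.U_h"),
        b_z=zeros_param(g, f"{prefix}.b_z"),
        b_r=zeros_param(g, f"{prefix}.b_r"),
        b_h=zeros_param(g, f"{prefix}.b_h"),
    )


def gru_step(v: Tensor, h_prev: Tensor, p: GRUParams) -> Tensor:
    v2, squeeze = _rowvec(v)
    h2, _ = _rowvec(h_prev)
    z = ag.sigmoid(v2 @ p.W_z + h2 @ p.U_z + p.b_z)
    r = ag.sigmoid(v2 @ p.W_r + h2 @ p.U_r + p.b_r)
    hcand = ag.tanh(v2 @ p.W_h + r * (h2 @ p.U_h) + p.b_h)
    h = z * h2 + (1.0 - z) * hcand
    return ag.reshape(h, (p.hidden_dim,)) if squeeze else h


def gru_sequence(inputs: list[Tensor], p: GRUParams,
                 h0: Tensor | None = None) -> list[Tensor]:
    """Fold gru_step over a non-empty input sequence, starting from zero."""
    if not inputs:
        raise ValueError("empty input sequence")
    first, squeeze = _rowvec(inputs[0])
    if h0 is None:
        h = Tensor(np.zeros((first.shape[0], p.hidden_dim)))
    else:
        h, _ = _rowvec(h0)
    states = []
    for v in inputs:
        v2, _ = _rowvec(v)
        h = gru_step(v2, h, p)
        states.append(h)
    if squeeze:
        states = [ag.reshape(s, (p.hidden_dim,)) for s in states]
    return states


# -- location-based attention -------------------------------------------------


@dataclass
class AttentionParams:
    """Scalar score per hidden state: alpha_i = h_i . W_alpha + b_alpha."""

    W_alpha: Tensor  # (g, 1)
    b_alpha: Tensor  # (1,)

    def parameters(self, prefix: str = "attn") -> dict[str, Tensor]:
        return {f"{prefix}.W_alpha": self.W_alpha, f"{prefix}.b_alpha": self.b_alpha}


def init_attention(g: int, rng: np.random.Generator,
                   prefix: str = "attn") -> AttentionParams:
    return AttentionParams(W_alpha=uniform_param(rng, (g, 1), g, f"{prefix}.W_alpha"),
                           b_alpha=zeros_param(1, f"{prefix}.b_alpha"))


def attention_scores(states: list[Tensor], p: AttentionParams) -> Tensor:
    """Raw (t, B) scores, one scalar per state per batch row."""
    scored = [ag.reshape(_rowvec(h)[0] @ p.W_alpha + p.b_alpha, (-1,))
              for h in states]
    return ag.stack(scored, axis=0)


def location_attention(states: list[Tensor],
                       p: AttentionParams) -> tuple[Tensor, Tensor]:
    """Softmax-normalised weights over states and the weighted-sum context.

    Returns (weights (t, B), context (B, g)); 1-d states are treated as B=1.
    """
    if not states:
        raise ValueError("attention needs at least one state")
    squeeze = states[0].ndim == 1
    states2 = [_rowvec(h)[0] for h in states]
    weights = ag.softmax(attention_scores(states2, p), axis=0)  # (t, B)
    stacked = ag.stack(states2, axis=0)                         # (t, B, g)
    t, b = weights.shape
    context = ag.tsum(ag.reshape(weights, (t, b, 1)) * stacked, axis=0)
    if squeeze:
        return ag.reshape(weights, (t,)), ag.reshape(context, (stacked.shape[2],))
    return weights, context


# -- graph-based (ontology) attention -----------------------------------------


@dataclass
class AncestorIndex:
    """Padded per-leaf ancestor sets A(i) over a fixed node ordering.

    Node ordering is: universe codes (leaves) first, in code order, then the
    internal nodes sorted by name. A(i) contains the leaf itself.
    """

    node_order: list[str]
    indices: np.ndarray  # (|C|, maxA) int, padded with 0
    mask: np.ndarray     # (|C|, maxA) bool, True where a real ancestor

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)


def ancestor_index(dag: OntologyDAG, universe: CodeUniverse) -> AncestorIndex:
    internal = sorted(set(dag.graph.nodes) - set(universe.codes))
    node_order = list(universe.codes) + internal
    pos = {n: i for i, n in enumerate(node_order)}
    anc_lists = []
    for code in universe.codes:
        anc = sorted(dag.ancestors(code), key=pos.__getitem__)
        anc_lists.append([pos[a] for a in anc])
    max_a = max(len(a) for a in anc_lists)
    idx = np.zeros((len(anc_lists), max_a), dtype=np.int64)
    mask = np.zeros((len(anc_lists), max_a), dtype=bool)
    for i, a in enumerate(anc_lists):
        idx[i, :len(a)] = a
        mask[i, :len(a)] = True
    return AncestorIndex(node_order, idx, mask)


@dataclass
class GraphAttentionParams:
    """Compatibility scorer theta(e_i, e_j) = u_a . tanh(W_a [e_i; e_j] + b_a)."""

    u_a: Tensor  # (l, 1)
    W_a: Tensor  # (2d, l)
    b_a: Tensor  # (l,)

    def parameters(self, prefix: str = "graph") -> dict[str, Tensor]:
        return {f"{prefix}.u_a": self.u_a, f"{prefix}.W_a": self.W_a,
                f"{prefix}.b_a": self.b_a}


def init_graph_attention(d: int, l: int, rng: np.random.Generator,
                         prefix: str = "graph") -> GraphAttentionParams:
    return GraphAttentionParams(
        u_a=uniform_param(rng, (l, 1), l, f"{prefix}.u_a"),
        W_a=uniform_param(rng, (2 * d, l), 2 * d, f"{prefix}.W_a"),
        b_a=zeros_param(l, f"{prefix}.b_a"))


def graph_attention_embed(anc: AncestorIndex, node_emb: Tensor,
                          p: GraphAttentionParams,
                          return_weights: bool = False):
    """Attention-weighted ancestor mixture g_i per leaf, as a (|C|, d) tensor.

    For each leaf i the weights alpha_ij are a softmax over j in A(i) of
    theta(e_i, e_j); g_i is the corresponding convex combination of the basic
    embeddings e_j, so rare leaves can borrow mass from their ancestors.
    """
    n_codes, max_a = anc.indices.shape
    d = node_emb.shape[1]
    e_anc = ag.take(node_emb, anc.indices, axis=0)            # (|C|, maxA, d)
    e_leaf = node_emb[np.arange(n_codes)]                     # (|C|, d)
    e_leaf_b = ag.reshape(e_leaf, (n_codes, 1, d)) + Tensor(np.zeros((n_codes, max_a, d)))
    pairs = ag.concatenate([e_leaf_b, e_anc], axis=2)         # (|C|, maxA, 2d)
    theta = ag.tanh(pairs @ p.W_a + p.b_a) @ p.u_a            # (|C|, maxA, 1)
    scores = ag.reshape(theta, (n_codes, max_a))
    scores = scores + Tensor(np.where(anc.mask, 0.0, -1e30))
    alpha = ag.softmax(scores, axis=1)                        # padded entries -> 0
    g = ag.tsum(ag.reshape(alpha, (n_codes, max_a, 1)) * e_anc, axis=1)
    if return_weights:
        return g, alpha
    return g


# -- RETAIN two-level context --------------------------------------------------


@dataclass
class RetainParams:
    """Code-level gate beta_t = tanh(h_t W_beta + b_beta), one gate per dim."""

    W_beta: Tensor  # (g, d)
    b_beta: Tensor  # (d,)

    def parameters(self, prefix: str = "retain") -> dict[str, Tensor]:
        return {f"{prefix}.W_beta": self.W_beta, f"{prefix}.b_beta": self.b_beta}


def init_retain(g: int, d: int, rng: np.random.Generator,
                prefix: str = "retain") -> RetainParams:
    return RetainParams(W_beta=uniform_param(rng, (g, d), g, f"{prefix}.W_beta"),
                        b_beta=zeros_param(d, f"{prefix}.b_beta"))


def retain_context(visit_embs: list[Tensor], alpha_states: list[Tensor],
                   beta_states: list[Tensor], attn: AttentionParams,
                   rp: RetainParams) -> Tensor:
    """Context c_t = sum_i alpha_i * (beta_i o v_i) over the visits so far.

    alpha is the softmax of scalar scores of ``alpha_states``; beta_i gates
    each embedding coordinate of visit i via ``beta_states``.
    """
    if not (len(visit_embs) == len(alpha_states) == len(beta_states)):
        raise ValueError("visit/alpha/beta sequences must have equal length")
    squeeze = visit_embs[0].ndim == 1
    vs = [_rowvec(v)[0] for v in visit_embs]
    a_states = [_rowvec(h)[0] for h in alpha_states]
    b_states = [_rowvec(h)[0] for h in beta_states]
    alpha = ag.softmax(attention_scores(a_states, attn), axis=0)  # (t, B)
    betas = [ag.tanh(h @ rp.W_beta + rp.b_beta) for h in b_states]
    t, b = alpha.shape
    gated = ag.stack([beta * v for beta, v in zip(betas, vs)], axis=0)  # (t,B,d)
    ctx = ag.tsum(ag.reshape(alpha, (t, b, 1)) * gated, axis=0)
    return ag.reshape(ctx, (ctx.shape[1],)) if squeeze else ctx


# -- visit embedding and softmax head ------------------------------------------


def visit_embedding(x: np.ndarray | Tensor, embedding: Tensor, b_v: Tensor) -> Tensor:
    """v = tanh(x @ embedding + b_v) for multi-hot rows x (non-empty visits).

    ``embedding`` is (|C|, d) — the transpose of the d x |C| matrix of the
    column-vector notation.
    """
    xd = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
    if xd.ndim == 1:
        xd = xd[None, :]
        squeeze = True
    else:
        squeeze = False
    if not np.all(np.isin(xd, (0.0, 1.0))):
        raise ValueError("visit vector must be binary")
    if np.any(xd.sum(axis=1) == 0):
        raise ValueError("empty visit (all-zero multi-hot row)")
    v = ag.tanh(Tensor(xd) @ embedding + b_v)
    return ag.reshape(v, (embedding.shape[1],)) if squeeze else v


def softmax_head(z: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Probabilities softmax(z W + b), stabilised by max-subtraction."""
    z2, squeeze = _rowvec(z)
    out = ag.softmax(z2 @ W + b, axis=-1)
    return ag.reshape(out, (W.shape[1],)) if squeeze else out
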