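"""Convolutional encoder over code descriptions.

Each diagnosis code's textual description is a short token sequence. Tokens
are mapped to pre-trained word vectors, stacked into an n-by-k matrix (zero
padded), and scanned by banks of convolution filters with several window
sizes. Each filter's feature map is ReLU-activated and max-pooled to a single
scalar; the pooled features, concatenated across filters and window sizes,
form the code's embedding e_i of dimension d = m*q (m filters per window,
q window sizes). Codes whose descriptions share words land near each other,
which is the whole point: rarely-observed codes inherit signal from textually
similar common ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import CodeUniverse, WordVectorTable


@dataclass
class ConvFilterBank:
    """Filters of the description CNN: m filters for each window size h.

    ``weights[h]`` has shape (m, h, k) and ``biases[h]`` shape (m,). The
    output embedding dimension is d = m * len(window_sizes).
    """

    window_sizes: tuple[int, ...]
    filters_per_window: int
    word_dim: int
    weights: dict[int, Tensor]
    biases: dict[int, Tensor]

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.window_sizes):
            raise ValueError("window sizes must be >= 1")
        self.window_sizes = tuple(sorted(self.window_sizes))
        for h in self.window_sizes:
            if self.weights[h].shape != (self.filters_per_window, h, self.word_dim):
                raise ValueError(f"filter weights for window {h} have wrong shape")
            if not np.all(np.isfinite(self.weights[h].data)):
                raise ValueError("non-finite filter weights")

    @property
    def out_dim(self) -> int:
        return self.filters_per_window * len(self.window_sizes)

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for h in self.window_sizes:
            out[f"cnn.W{h}"] = self.weights[h]
            out[f"cnn.b{h}"] = self.biases[h]
        return out


def init_filter_bank(window_sizes: tuple[int, ...], m: int, k: int,
                     rng: np.random.Generator) -> ConvFilterBank:
    """Seeded uniform init in +/- sqrt(1/(h*k)) per window size."""
    weights, biases = {}, {}
    for h in sorted(window_sizes):
        bound = np.sqrt(1.0 / (h * k))
        weights[h] = Tensor(rng.uniform(-bound, bound, size=(m, h, k)),
                            requires_grad=True, name=f"cnn.W{h}")
        biases[h] = Tensor(np.zeros(m), requires_grad=True, name=f"cnn.b{h}")
    return ConvFilterBank(tuple(sorted(window_sizes)), m, k, weights, biases)


@dataclass
class CodeEmbeddingMatrix:
    """The d x |C| code embedding matrix (column i embeds code i)."""

    matrix: np.ndarray
    source: str  # random | description_cnn | graph_attention

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_codes(self) -> int:
        return self.matrix.shape[1]


# -- reference (per-code) path ------------------------------------------------


def pad_and_stack(tokens: list[str], table: WordVectorTable, n: int,
                  truncate: bool = False) -> np.ndarray:
    """Stack the tokens' word vectors into an (n, k) matrix, zero padded.

    With ``truncate`` the first n tokens are kept when the description is
    longer than n; otherwise that is an error.
    """
    if len(tokens) > n:
        if not truncate:
            raise ValueError(f"description of length {len(tokens)} exceeds n={n}")
        tokens = tokens[:n]
    out = np.zeros((n, table.dim))
    for i, tok in enumerate(tokens):
        out[i] = table.lookup(tok)
    return out


def conv_feature_map(stacked: np.ndarray, filt: np.ndarray, bias: float) -> np.ndarray:
    """ReLU feature map of one h x k filter slid over the stacked description."""
    n, k = stacked.shape
    h = filt.shape[0]
    if n < h:
        raise ValueError(f"input length {n} shorter than window {h}")
    windows = np.stack([stacked[i:i + h].ravel() for i in range(n - h + 1)])
    return np.maximum(windows @ filt.ravel() + bias, 0.0)


def max_pool(feature_map: np.ndarray) -> float:
    if np.size(feature_map) == 0:
        raise ValueError("empty feature map")
    return float(np.max(feature_map))


def embed_code(tokens: list[str], bank: ConvFilterBank,
               table: WordVectorTable) -> np.ndarray:
    """Embed one description: pooled conv features, concatenated.

    Feature order is (window size ascending, filter index ascending).
    Descriptions shorter than the largest window are zero padded up to it so
    every window size yields at least one position.
    """
    if table.dim != bank.word_dim:
        raise ValueError("word-vector dim does not match filter bank")
    n = max(len(tokens), max(bank.window_sizes))
    stacked = pad_and_stack(tokens, table, n)
    feats = []
    for h in bank.window_sizes:
        W = bank.weights[h].data
        b = bank.biases[h].data
        for j in range(bank.filters_per_window):
            feats.append(max_pool(conv_feature_map(stacked, W[j], float(b[j]))))
    return np.asarray(feats)


# -- batched differentiable path ---------------------------------------------


def description_indices(universe: CodeUniverse, pad_to: int | None = None,
                        min_len: int = 1) -> np.ndarray:
    """(|C|, n) matrix of word indices; padding slots hold index n_words."""
    n = max(max(len(t) for t in universe.descriptions.values()), min_len)
    if pad_to is not None:
        n = max(n, pad_to)
    pad = universe.n_words
    out = np.full((universe.n_codes, n), pad, dtype=np.int64)
    for i, code in enumerate(universe.codes):
        toks = universe.descriptions[code]
        out[i, :len(toks)] = [universe.word_index[t] for t in toks]
    return out


def embed_all(universe: CodeUniverse, bank: ConvFilterBank, table: WordVectorTable,
              word_tensor: Tensor | None = None) -> Tensor:
    """Differentiable (|C|, d) embedding of every code description.

    ``word_tensor`` (an (n_words, k) parameter) switches the word vectors from
    frozen constants to trainable parameters; by default the pre-trained
    vectors are held fixed and only the filters learn.
    """
    idx = description_indices(universe, min_len=max(bank.window_sizes))
    n = idx.shape[1]
    lengths = np.array([len(universe.descriptions[c]) for c in universe.codes])
    if word_tensor is None:
        padded = np.vstack([table.vectors, np.zeros((1, table.dim))])
        emb = Tensor(padded[idx])  # constant (|C|, n, k)
    else:
        full = ag.concatenate([word_tensor, Tensor(np.zeros((1, table.dim)))], axis=0)
        emb = ag.take(full, idx, axis=0)
    per_window = []
    for h in bank.window_sizes:
        positions = n - h + 1
        windows = ag.stack([emb[:, i:i + h, :] for i in range(positions)], axis=1)
        flat = ag.reshape(windows, (universe.n_codes, positions, h * bank.word_dim))
        Wf = ag.reshape(bank.weights[h], (bank.filters_per_window, h * bank.word_dim))
        scores = ag.relu(flat @ ag.swapaxes(Wf, 0, 1) + bank.biases[h])
        # windows are only slid over each code's own padded description
        # (length max(len, largest window)), never over the extra padding
        # introduced by longer descriptions in the same batch — otherwise an
        # embedding would depend on batch composition
        n_valid = np.maximum(lengths, max(bank.window_sizes)) - h + 1  # (|C|,)
        valid = (np.arange(positions)[None, :] < n_valid[:, None])
        scores = scores * Tensor(valid[:, :, None].astype(float))
        per_window.append(ag.tmax(scores, axis=1))  # (|C|, m)
    return ag.concatenate(per_window, axis=1)  # (|C|, m*q)


def build_embedding_matrix(universe: CodeUniverse, bank: ConvFilterBank,
                           table: WordVectorTable) -> CodeEmbeddingMatrix:
    """The d x |C| matrix E with column i = embed_code(code i)."""
    emb = embed_all(universe, bank, table)
    return CodeEmbeddingMatrix(matrix=emb.data.T.copy(), source="description_cnn")
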