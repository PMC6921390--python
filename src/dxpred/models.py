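"""The six sequence predictors, each in base and enhanced form.

Every model maps a patient's visit sequence to a probability vector over
diagnosis-category labels at each timestep t (predicting the categories of
visit t+1 from visits 1..t):

    MLP     visit embedding -> affine -> softmax (no history)
    RNN     visit embedding -> GRU -> softmax
    RNN_a   GRU states 1..t -> location attention -> softmax
    DIPOLE  forward + backward GRU (over visits 1..t), concatenated 2g states
            -> location attention -> softmax
    RETAIN  two reverse-time GRUs -> visit-level (alpha) and code-level (beta)
            attention -> context over visit embeddings -> softmax
    GRAM    ontology graph attention produces the embedding matrix G,
            then as RNN

The *base* variant draws its code-embedding matrix at random (for GRAM: the
leaf basic embeddings); the *enhanced* variant computes it from the code
descriptions with the convolutional encoder, inside the computation graph, so
the filters train end-to-end with the predictor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import layers as L
from . import text_cnn as tc
from .autograd import Tensor
from .data import CodeUniverse, LabelSpace, OntologyDAG, PatientRecord, WordVectorTable

ARCHITECTURES = ("mlp", "rnn", "rnn_a", "dipole", "retain", "gram")
EMBEDDING_SOURCES = ("random", "description_cnn")


@dataclass
class ModelConfig:
    """Architecture and dimension choices for one predictor.

    ``d`` is the code-embedding dimension; with ``description_cnn`` it is
    derived as m*q from the filter bank and must not disagree. ``g`` is the
    GRU hidden dimension, ``l`` the graph-attention hidden dimension (GRAM
    only).
    """

    architecture: str
    embedding_source: str = "random"
    d: int = 24
    g: int = 32
    l: int = 16
    window_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_window: int = 8
    seed: int = 0
    freeze_word_vectors: bool = True

    def __post_init__(self) -> None:
        self.window_sizes = tuple(sorted(self.window_sizes))
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.embedding_source not in EMBEDDING_SOURCES:
            raise ValueError(f"unknown embedding source {self.embedding_source!r}")
        if self.embedding_source == "description_cnn":
            mq = self.filters_per_window * len(self.window_sizes)
            if self.d != mq:
                raise ValueError(
                    f"d={self.d} must equal m*q={mq} for description embeddings")


@dataclass
class PredictionBatch:
    """Per-patient, per-timestep label probabilities with a validity mask.

    ``probs`` is (T-1, B, n_labels): entry [t, b] predicts patient b's visit
    t+2 from visits 1..t+1 and is valid where ``mask[t, b]``.
    """

    probs: np.ndarray
    mask: np.ndarray
    patient_ids: list[str]

    def for_patient(self, b: int) -> np.ndarray:
        return self.probs[self.mask[:, b], b]


class SequenceModel:
    """A configured predictor: parameters plus the architecture wiring."""

    def __init__(self, config: ModelConfig, universe: CodeUniverse,
                 label_space: LabelSpace, dag: OntologyDAG | None = None,
                 word_table: WordVectorTable | None = None):
        if (config.architecture == "gram") != (dag is not None):
            raise ValueError("an ontology DAG is required iff architecture is gram")
        if (config.embedding_source == "description_cnn") != (word_table is not None):
            raise ValueError("a word-vector table is required iff the embedding "
                             "source is description_cnn")
        self.config = config
        self.universe = universe
        self.label_space = label_space
        self.dag = dag
        self.word_table = word_table
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(config.seed))

    # -- construction --------------------------------------------------------
    def _add(self, params: dict[str, Tensor]) -> None:
        for k, v in params.items():
            if k in self.params:
                raise ValueError(f"duplicate parameter {k}")
            self.params[k] = v

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        n_codes, n_labels = self.universe.n_codes, self.label_space.n_labels
        d, g = cfg.d, cfg.g

        self.bank: tc.ConvFilterBank | None = None
        self.word_tensor: Tensor | None = None
        if cfg.embedding_source == "description_cnn":
            self.bank = tc.init_filter_bank(cfg.window_sizes, cfg.filters_per_window,
                                            self.word_table.dim, rng)
            self._add(self.bank.parameters())
            if not cfg.freeze_word_vectors:
                self.word_tensor = Tensor(self.word_table.vectors.copy(),
                                          requires_grad=True, name="word_vectors")
                self._add({"word_vectors": self.word_tensor})
        elif cfg.architecture != "gram":
            self._add({"embedding": L.uniform_param(rng, (n_codes, d), n_codes,
                                                    "embedding")})

        if cfg.architecture == "gram":
            self.anc = L.ancestor_index(self.dag, self.universe)
            n_internal = self.anc.n_nodes - n_codes
            if cfg.embedding_source == "random":
                self._add({"leaf_embedding": L.uniform_param(
                    rng, (n_codes, d), n_codes, "leaf_embedding")})
            # internal ontology nodes always start from random basic embeddings
            self._add({"internal_embedding": L.uniform_param(
                rng, (n_internal, d), n_internal, "internal_embedding")})
            self.graph_attn = L.init_graph_attention(d, cfg.l, rng)
            self._add(self.graph_attn.parameters())

        self._add({"b_v": L.zeros_param(d, "b_v")})

        head_in = {"mlp": d, "rnn": g, "rnn_a": g, "dipole": 2 * g,
                   "retain": d, "gram": g}[cfg.architecture]
        self._add({"W_c": L.uniform_param(rng, (head_in, n_labels), head_in, "W_c"),
                   "b_c": L.zeros_param(n_labels, "b_c")})

        if cfg.architecture in ("rnn", "rnn_a", "gram"):
            self.gru = L.init_gru(d, g, rng)
            self._add(self.gru.parameters())
        if cfg.architecture == "dipole":
            self.gru_fwd = L.init_gru(d, g, rng, "gru_fwd")
            self.gru_bwd = L.init_gru(d, g, rng, "gru_bwd")
            self._add(self.gru_fwd.parameters("gru_fwd"))
            self._add(self.gru_bwd.parameters("gru_bwd"))
        if cfg.architecture == "retain":
            self.gru_alpha = L.init_gru(d, g, rng, "gru_alpha")
            self.gru_beta = L.init_gru(d, g, rng, "gru_beta")
            self._add(self.gru_alpha.parameters("gru_alpha"))
            self._add(self.gru_beta.parameters("gru_beta"))
            self.retain_params = L.init_retain(g, d, rng)
            self._add(self.retain_params.parameters())
        if cfg.architecture in ("rnn_a", "dipole"):
            attn_dim = 2 * g if cfg.architecture == "dipole" else g
            self.attn = L.init_attention(attn_dim, rng)
            self._add(self.attn.parameters())
        if cfg.architecture == "retain":
            self.attn = L.init_attention(g, rng)
            self._add(self.attn.parameters())

    # -- parameter access -----------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        return dict(self.params)

    def weight_matrices(self) -> dict[str, Tensor]:
        """Parameters subject to l2 regularisation (biases excluded)."""
        return {k: v for k, v in self.params.items() if v.ndim >= 2}

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter names do not match this model")
        for k, v in state.items():
            if self.params[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].data = np.asarray(v, dtype=np.float64)

    # -- embedding matrix ------------------------------------------------------
    def embedding_tensor(self) -> Tensor:
        """The (|C|, d) code-embedding matrix, inside the computation graph."""
        cfg = self.config
        if cfg.architecture == "gram":
            if cfg.embedding_source == "description_cnn":
                leaf = tc.embed_all(self.universe, self.bank, self.word_table,
                                    self.word_tensor)
            else:
                leaf = self.params["leaf_embedding"]
            node_emb = ag.concatenate([leaf, self.params["internal_embedding"]],
                                      axis=0)
            return L.graph_attention_embed(self.anc, node_emb, self.graph_attn)
        if cfg.embedding_source == "description_cnn":
            return tc.embed_all(self.universe, self.bank, self.word_table,
                                self.word_tensor)
        return self.params["embedding"]

    def embedding_matrix(self) -> tc.CodeEmbeddingMatrix:
        """The d x |C| embedding matrix as a plain array, with its source tag."""
        source = ("graph_attention" if self.config.architecture == "gram"
                  else self.config.embedding_source)
        return tc.CodeEmbeddingMatrix(matrix=self.embedding_tensor().data.T.copy(),
                                      source=source)

    # -- forward ---------------------------------------------------------------
    def _batch_arrays(self, records: list[PatientRecord]
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Multi-hot inputs (T, B, |C|) and visit-validity mask (T, B)."""
        n_codes = self.universe.n_codes
        T = max(r.n_visits for r in records)
        B = len(records)
        X = np.zeros((T, B, n_codes))
        valid = np.zeros((T, B), dtype=bool)
        for b, rec in enumerate(records):
            for t, visit in enumerate(rec.visits):
                X[t, b, list(visit)] = 1.0
                valid[t, b] = True
        return X, valid

    def forward_tensor(self, records: list[PatientRecord]
                       ) -> tuple[Tensor, np.ndarray]:
        """Probabilities (T-1, B, n_labels) as a graph tensor, plus the mask.

        The prediction at index t uses visits 1..t+1 only, so appending later
        visits never changes earlier predictions (causality).
        """
        for r in records:
            if r.n_visits < 2:
                raise ValueError(f"patient {r.patient_id} has fewer than two visits")
        X, valid = self._batch_arrays(records)
        T, B, _ = X.shape
        emb = self.embedding_tensor()
        b_v = self.params["b_v"]
        # padded visits are all-zero rows; their embeddings are computed but
        # every prediction that could see them is masked out of loss/metrics
        vs = [ag.tanh(Tensor(X[t]) @ emb + b_v) for t in range(T)]
        W_c, b_c = self.params["W_c"], self.params["b_c"]
        arch = self.config.architecture
        outputs: list[Tensor] = []
        if arch == "mlp":
            outputs = [L.softmax_head(vs[t], W_c, b_c) for t in range(T - 1)]
        elif arch in ("rnn", "gram"):
            states = L.gru_sequence(vs, self.gru)
            outputs = [L.softmax_head(states[t], W_c, b_c) for t in range(T - 1)]
        elif arch == "rnn_a":
            states = L.gru_sequence(vs, self.gru)
            for t in range(T - 1):
                _, ctx = L.location_attention(states[:t + 1], self.attn)
                outputs.append(L.softmax_head(ctx, W_c, b_c))
        elif arch == "dipole":
            fwd = L.gru_sequence(vs, self.gru_fwd)
            for t in range(T - 1):
                # backward GRU over the visits observed so far, reversed:
                # bwd[i] consumes v_{t+1}..v_{i+1}, keeping the model causal
                bwd_rev = L.gru_sequence(vs[:t + 1][::-1], self.gru_bwd)
                bwd = bwd_rev[::-1]
                h = [ag.concatenate([fwd[i], bwd[i]], axis=1) for i in range(t + 1)]
                _, ctx = L.location_attention(h, self.attn)
                outputs.append(L.softmax_head(ctx, W_c, b_c))
        elif arch == "retain":
            for t in range(T - 1):
                rev = vs[:t + 1][::-1]
                a_states = L.gru_sequence(rev, self.gru_alpha)[::-1]
                b_states = L.gru_sequence(rev, self.gru_beta)[::-1]
                ctx = L.retain_context(vs[:t + 1], a_states, b_states,
                                       self.attn, self.retain_params)
                outputs.append(L.softmax_head(ctx, W_c, b_c))
        probs = ag.stack(outputs, axis=0)  # (T-1, B, n_labels)
        mask = valid[1:, :]                # prediction t valid iff visit t+1 exists
        return probs, mask

    def forward(self, records: list[PatientRecord]) -> PredictionBatch:
        probs, mask = self.forward_tensor(records)
        return PredictionBatch(probs=probs.data.copy(), mask=mask,
                               patient_ids=[r.patient_id for r in records])


def build_model(config: ModelConfig, universe: CodeUniverse,
                label_space: LabelSpace, dag: OntologyDAG | None = None,
                word_table: WordVectorTable | None = None) -> SequenceModel:
    return SequenceModel(config, universe, label_space, dag, word_table)


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(model: SequenceModel, path: str | Path) -> None:
    """Single-file .npz archive: named parameter arrays + the JSON config."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    cfg = asdict(model.config)
    cfg["window_sizes"] = list(cfg["window_sizes"])
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, universe: CodeUniverse,
                    label_space: LabelSpace, dag: OntologyDAG | None = None,
                    word_table: WordVectorTable | None = None) -> SequenceModel:
    with np.load(path) as npz:
        cfg_dict = json.loads(bytes(npz["__config__"]).decode())
        cfg_dict["window_sizes"] = tuple(cfg_dict["window_sizes"])
        config = ModelConfig(**cfg_dict)
        model = SequenceModel(config, universe, label_space, dag, word_table)
        state = {k[len("param/"):]: npz[k] for k in npz.files
                 if k.startswith("param/")}
    model.load_state_dict(state)
    return model
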