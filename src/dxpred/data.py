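"""Domain types and file I/O for longitudinal diagnosis-code data.

The data model mirrors how claims/EHR extracts are usually prepared for
sequence modelling: a cohort of patients, each a time-ordered list of visits,
each visit an unordered set of diagnosis codes; a table of free-text code
descriptions; and a medical ontology (a rooted DAG whose leaves are the codes)
from which the category-label space — the prediction target — is derived.

File formats are deliberately plain text: visits as JSON Lines (one patient
per line), descriptions and ontology edges as two-column TSV, word vectors in
the word2vec text dialect.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

_TOKEN_CLEAN = re.compile(r"[^a-z0-9 ]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip non-alphanumeric characters, split on whitespace."""
    return _TOKEN_CLEAN.sub(" ", text.lower()).split()


@dataclass
class CodeUniverse:
    """The set of diagnosis codes with their tokenized descriptions.

    ``codes`` fixes the code indexing used everywhere else (multi-hot vectors,
    embedding-matrix columns); ``word_index`` is a bijection from the
    description vocabulary onto ``0..n_words-1``.
    """

    codes: list[str]
    descriptions: dict[str, list[str]]
    word_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.codes) != set(self.descriptions):
            missing = set(self.codes) - set(self.descriptions)
            extra = set(self.descriptions) - set(self.codes)
            raise ValueError(
                f"codes and descriptions disagree (missing={sorted(missing)[:5]}, "
                f"extra={sorted(extra)[:5]})")
        for code, toks in self.descriptions.items():
            if not toks:
                raise ValueError(f"code {code!r} has an empty description")
        if not self.word_index:
            words = sorted({w for toks in self.descriptions.values() for w in toks})
            self.word_index = {w: i for i, w in enumerate(words)}

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    @property
    def n_words(self) -> int:
        return len(self.word_index)

    def code_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codes)}

    def tokens_of(self, index: int) -> list[str]:
        return self.descriptions[self.codes[index]]


@dataclass
class PatientRecord:
    """One patient: a time-ordered sequence of visits (sets of code indices).

    Patients with fewer than two visits carry no prediction target (the model
    predicts visit t+1 from visits 1..t) and are rejected.
    """

    patient_id: str
    visits: list[frozenset[int]]

    def __post_init__(self) -> None:
        self.visits = [frozenset(v) for v in self.visits]
        if len(self.visits) < 2:
            raise ValueError(f"patient {self.patient_id!r} has fewer than two visits")
        for t, v in enumerate(self.visits):
            if not v:
                raise ValueError(f"patient {self.patient_id!r} visit {t} is empty")

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class OntologyDAG:
    """Rooted DAG over codes (leaves) and grouping nodes, edges child→parent."""

    graph: nx.DiGraph
    root: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def ancestors(self, node: str) -> set[str]:
        """The node itself plus everything reachable along child→parent edges."""
        return {node} | nx.descendants(self.graph, node)


@dataclass
class LabelSpace:
    """Category labels (children of the ontology root) and the code→label map."""

    labels: list[str]
    code_to_label: dict[int, int]

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def visit_labels(self, visit: Iterable[int]) -> frozenset[int]:
        return frozenset(self.code_to_label[c] for c in visit)


@dataclass
class DatasetSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int

    def subset(self, records: Sequence[PatientRecord], part: str) -> list[PatientRecord]:
        wanted = set(getattr(self, part))
        return [r for r in records if r.patient_id in wanted]


# -- loaders ------------------------------------------------------------------


def load_visits(path: str | Path, universe: CodeUniverse) -> list[PatientRecord]:
    """Read patient visit sequences from JSON Lines.

    Codes are interned against `universe`; patients with fewer than two visits
    are dropped (with a logged count), matching the usual cohort inclusion rule.
    """
    index = universe.code_index()
    records: list[PatientRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                pid = obj["patient_id"]
                visits_raw = obj["visits"]
            except (json.JSONDecodeError, KeyError, TypeError) as err:
                raise ValueError(f"{path}: malformed record on line {lineno}: {err}") from None
            visits: list[frozenset[int]] = []
            for visit in visits_raw:
                codes = set()
                for code in visit:
                    if code not in index:
                        raise ValueError(
                            f"{path}: unknown code {code!r} on line {lineno}")
                    codes.add(index[code])
                visits.append(frozenset(codes))
            if len(visits) < 2:
                dropped += 1
                continue
            records.append(PatientRecord(pid, visits))
    if dropped:
        logger.info("dropped %d patient(s) with fewer than two visits", dropped)
    if not records:
        logger.warning("no valid patients loaded from %s", path)
    return records


def write_visits(records: Iterable[PatientRecord], universe: CodeUniverse,
                 path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            visits = [sorted(universe.codes[i] for i in v) for v in rec.visits]
            fh.write(json.dumps({"patient_id": rec.patient_id, "visits": visits}) + "\n")


def load_descriptions(path: str | Path) -> CodeUniverse:
    """Read the two-column code→description TSV and build the code universe."""
    codes: list[str] = []
    descriptions: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                code, text = line.split("\t", 1)
            except ValueError:
                raise ValueError(f"{path}: line {lineno} is not two tab-separated "
                                 f"columns") from None
            if code in descriptions:
                raise ValueError(f"{path}: duplicate code {code!r} on line {lineno}")
            toks = tokenize(text)
            if not toks:
                raise ValueError(f"{path}: code {code!r} has an empty description "
                                 f"after tokenization (line {lineno})")
            codes.append(code)
            descriptions[code] = toks
    return CodeUniverse(codes=codes, descriptions=descriptions)


def write_descriptions(universe: CodeUniverse, path: str | Path) -> None:
    with open(path, "w") as fh:
        for code in universe.codes:
            fh.write(f"{code}\t{' '.join(universe.descriptions[code])}\n")


def load_ontology(path: str | Path) -> OntologyDAG:
    """Read child→parent TSV edges and validate the rooted DAG."""
    g = nx.DiGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno} is not two tab-separated "
                                 f"columns")
            child, parent = parts
            g.add_edge(child, parent)
    return build_ontology(g.edges())


def build_ontology(edges: Iterable[tuple[str, str]]) -> OntologyDAG:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"ontology must have exactly one root, found {sorted(roots)}")
    root = roots[0]
    for leaf in (n for n in g.nodes if g.in_degree(n) == 0):
        if not nx.has_path(g, leaf, root):  # pragma: no cover - unreachable in a DAG
            raise ValueError(f"leaf {leaf!r} does not reach the root")
    return OntologyDAG(graph=g, root=root)


def write_ontology(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w") as fh:
        for child, parent in sorted(dag.graph.edges):
            fh.write(f"{child}\t{parent}\n")


def derive_label_space(dag: OntologyDAG, universe: CodeUniverse) -> LabelSpace:
    """Category labels are the ontology nodes one level below the root.

    Every code (leaf) must sit under exactly one such node; that node is the
    code's prediction label.
    """
    labels = sorted(p for p in dag.graph.predecessors(dag.root))
    label_index = {lab: i for i, lab in enumerate(labels)}
    code_to_label: dict[int, int] = {}
    leaf_set = set(dag.leaves)
    for i, code in enumerate(universe.codes):
        if code not in leaf_set:
            raise ValueError(f"code {code!r} is not a leaf of the ontology")
        hits = [a for a in dag.ancestors(code) if a in label_index]
        if len(hits) != 1:
            raise ValueError(
                f"code {code!r} has {len(hits)} second-level ancestors; expected 1")
        code_to_label[i] = label_index[hits[0]]
    return LabelSpace(labels=labels, code_to_label=code_to_label)


def split_patients(records: Sequence[PatientRecord], seed: int) -> DatasetSplit:
    """Shuffle patients with `seed`, then partition 0.75 / 0.10 / 0.15.

    Train gets floor(0.75 N), validation floor(0.10 N), test the remainder.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 patients to split")
    ids = [r.patient_id for r in records]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(np.floor(0.75 * n))
    n_valid = int(np.floor(0.10 * n))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(train=shuffled[:n_train],
                        validation=shuffled[n_train:n_train + n_valid],
                        test=shuffled[n_train + n_valid:],
                        seed=seed)


# -- word vectors -------------------------------------------------------------


@dataclass
class WordVectorTable:
    """Per-word vectors aligned to a universe's word_index (row per word)."""

    vectors: np.ndarray  # (n_words, k)
    word_index: dict[str, int]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, word: str) -> np.ndarray:
        return self.vectors[self.word_index[word]]


def load_word_vectors(path: str | Path | None, universe: CodeUniverse, *,
                      dim: int | None = None, seed: int = 0) -> WordVectorTable:
    """Read word2vec-text vectors, restricted to the universe vocabulary.

    Words absent from the file (or the whole table, when no file is given) get
    seeded uniform random vectors in [-0.05, 0.05]^k, the usual small-init
    convention for untrained word embeddings.
    """
    table: dict[str, np.ndarray] = {}
    file_dim: int | None = None
    if path is not None:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: expected 'count dim' header")
            file_dim = int(header[1])
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split()
                if not parts:
                    continue
                word, vals = parts[0], parts[1:]
                if len(vals) != file_dim:
                    raise ValueError(
                        f"{path}: line {lineno} has {len(vals)} values, "
                        f"expected {file_dim}")
                if word in universe.word_index:
                    table[word] = np.asarray(vals, dtype=np.float64)
    k = file_dim if file_dim is not None else dim
    if k is None:
        raise ValueError("dim must be given when no vector file is supplied")
    rng = np.random.default_rng(seed)
    vectors = np.empty((universe.n_words, k))
    # one draw per word position, so a word's fallback vector depends only on
    # the seed and its index, not on which other words the file covered
    for word, idx in sorted(universe.word_index.items(), key=lambda kv: kv[1]):
        fallback = rng.uniform(-0.05, 0.05, size=k)
        vectors[idx] = table.get(word, fallback)
    return WordVectorTable(vectors=vectors, word_index=dict(universe.word_index))


def write_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(table.word_index)} {table.dim}\n")
        for word, idx in sorted(table.word_index.items(), key=lambda kv: kv[1]):
            vals = " ".join(f"{v:.6f}" for v in table.vectors[idx])
            fh.write(f"{word} {vals}\n")
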