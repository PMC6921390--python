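"""Synthetic EHR cohorts with the structure the framework assumes.

The generator emulates, at toy scale, the statistical features the prediction
framework exploits in real claims data:

* a three-level ICD-like ontology (root -> category nodes -> codes);
* code descriptions whose word overlap reflects relatedness: every category
  owns a private word pool and shares a common pool, so same-category codes
  share words the way "Chronic diastolic heart failure" and "Rheumatic heart
  failure (congestive)" share "heart failure";
* skewed code frequencies — a Zipf law within each category, with a
  configurable rare subset further down-weighted 10x;
* learnable visit-to-visit dynamics — each patient follows a first-order
  Markov chain over categories whose determinism is a knob: at 1.0 the next
  category is a fixed function of the current one, so the next-visit category
  is exactly predictable and a sequence model can be validated against a
  known ceiling.

Start categories are drawn from a Zipf law, so when there are more categories
than visits per patient the label frequencies themselves are skewed, giving
the rare-label (data-sufficiency) analysis something to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (CodeUniverse, OntologyDAG, PatientRecord, WordVectorTable,
                   build_ontology, write_descriptions, write_ontology,
                   write_visits, write_word_vectors)

ROOT = "ROOT"
# fixed generator constants (not knobs): share of the vocabulary common to all
# categories, probability a description word comes from the private pool, the
# within-category Zipf exponent, start-category skew, and rare-code penalty
SHARED_VOCAB_FRACTION = 0.25
PRIVATE_WORD_PROB = 0.7
ZIPF_EXPONENT = 1.0
START_ZIPF_EXPONENT = 1.2
RARE_DOWNWEIGHT = 0.1


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort; defaults are the standard test cohort."""

    n_codes: int = 50
    n_categories: int = 10
    n_patients: int = 500
    visit_length_mean: float = 4.0
    max_T: int = 10
    rare_fraction: float = 0.2
    transition_determinism: float = 1.0
    vocab_size: int = 150
    words_per_description: int = 6
    word_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codes < self.n_categories:
            raise ValueError("need at least one code per category")
        if not 0.0 <= self.transition_determinism <= 1.0:
            raise ValueError("transition_determinism must be in [0, 1]")
        if min(self.n_codes, self.n_categories, self.n_patients, self.max_T,
               self.vocab_size, self.words_per_description, self.word_dim) < 1:
            raise ValueError("all sizes must be positive")
        if self.max_T < 2 or self.visit_length_mean <= 0:
            raise ValueError("max_T must be >= 2 and visit_length_mean > 0")


def _category_of_codes(config: SynthConfig) -> list[list[int]]:
    """Code indices per category (codes dealt out contiguously)."""
    return [list(chunk) for chunk in
            np.array_split(np.arange(config.n_codes), config.n_categories)]


def category_name(j: int) -> str:
    return f"CAT{j:03d}"


def code_name(i: int) -> str:
    return f"C{i:04d}"


def generate_ontology_and_descriptions(config: SynthConfig
                                       ) -> tuple[OntologyDAG, CodeUniverse]:
    rng = np.random.default_rng(config.seed)
    per_cat = _category_of_codes(config)
    edges = []
    for j, members in enumerate(per_cat):
        edges.append((category_name(j), ROOT))
        for i in members:
            edges.append((code_name(i), category_name(j)))
    dag = build_ontology(edges)

    vocab = [f"w{v:04d}" for v in range(config.vocab_size)]
    n_shared = max(1, int(np.ceil(SHARED_VOCAB_FRACTION * config.vocab_size)))
    shared = vocab[:n_shared]
    private = [list(chunk) for chunk in
               np.array_split(np.asarray(vocab[n_shared:], dtype=object),
                              config.n_categories)]
    codes, descriptions = [], {}
    for j, members in enumerate(per_cat):
        pool = private[j] if len(private[j]) else shared
        for i in members:
            toks = []
            for _ in range(config.words_per_description):
                src = pool if rng.random() < PRIVATE_WORD_PROB else shared
                toks.append(str(src[rng.integers(len(src))]))
            codes.append(code_name(i))
            descriptions[code_name(i)] = toks
    return dag, CodeUniverse(codes=codes, descriptions=descriptions)


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def generate_cohort(config: SynthConfig, dag: OntologyDAG,
                    universe: CodeUniverse) -> list[PatientRecord]:
    """Markov-over-categories cohort with Zipf-skewed within-category codes."""
    rng = np.random.default_rng(config.seed + 1)
    per_cat = _category_of_codes(config)
    K = config.n_categories
    # within-category code weights: Zipf by rank, rare tail down-weighted 10x
    cat_weights = []
    for members in per_cat:
        w = _zipf_weights(len(members), ZIPF_EXPONENT)
        n_rare = int(np.ceil(config.rare_fraction * len(members)))
        if n_rare:
            w[len(members) - n_rare:] *= RARE_DOWNWEIGHT
        cat_weights.append(w / w.sum())
    start_w = _zipf_weights(K, START_ZIPF_EXPONENT)
    records = []
    for p in range(config.n_patients):
        T = int(rng.integers(2, config.max_T + 1))
        cat = int(rng.choice(K, p=start_w))
        visits = []
        for _ in range(T):
            members = per_cat[cat]
            size = int(min(len(members), max(1, rng.poisson(config.visit_length_mean))))
            chosen = rng.choice(members, size=size, replace=False,
                                p=cat_weights[cat])
            visits.append(frozenset(int(c) for c in chosen))
            if rng.random() < config.transition_determinism:
                cat = (cat + 1) % K
            else:
                cat = int(rng.integers(K))
        records.append(PatientRecord(patient_id=f"p{p:05d}", visits=visits))
    return records


def rare_code_set(config: SynthConfig) -> set[int]:
    """The down-weighted (rare) code indices, per category tail."""
    rare: set[int] = set()
    for members in _category_of_codes(config):
        n_rare = int(np.ceil(config.rare_fraction * len(members)))
        rare.update(int(c) for c in members[len(members) - n_rare:])
    return rare


def generate_word_vectors(config: SynthConfig,
                          universe: CodeUniverse) -> WordVectorTable:
    rng = np.random.default_rng(config.seed + 2)
    vectors = rng.normal(0.0, 0.3, size=(universe.n_words, config.word_dim))
    return WordVectorTable(vectors=vectors, word_index=dict(universe.word_index))


def generate(config: SynthConfig) -> tuple[OntologyDAG, CodeUniverse,
                                           list[PatientRecord], WordVectorTable]:
    """Everything in one call: ontology, universe, cohort, word vectors."""
    dag, universe = generate_ontology_and_descriptions(config)
    cohort = generate_cohort(config, dag, universe)
    table = generate_word_vectors(config, universe)
    return dag, universe, cohort, table


def write_fixtures(dag: OntologyDAG, universe: CodeUniverse,
                   cohort: list[PatientRecord], table: WordVectorTable,
                   outdir: str | Path) -> dict[str, Path]:
    """Emit the four files the loaders consume; loading them round-trips."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"visits": outdir / "visits.jsonl",
             "descriptions": outdir / "descriptions.tsv",
             "ontology": outdir / "ontology.tsv",
             "word_vectors": outdir / "word_vectors.txt"}
    write_visits(cohort, universe, paths["visits"])
    write_descriptions(universe, paths["descriptions"])
    write_ontology(dag, paths["ontology"])
    write_word_vectors(table, paths["word_vectors"])
    return paths
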