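"""Shared fixtures: a tiny hand-built universe/ontology and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from dxpred.data import (CodeUniverse, WordVectorTable, build_ontology,
                         derive_label_space, split_patients)
from dxpred.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def tiny_universe() -> CodeUniverse:
    """Four codes, two per category, with overlapping descriptions."""
    descriptions = {
        "428.32": ["chronic", "diastolic", "heart", "failure"],
        "398.91": ["rheumatic", "heart", "failure", "congestive"],
        "491.21": ["obstructive", "chronic", "bronchitis", "exacerbation"],
        "493.92": ["asthma", "unspecified", "exacerbation"],
    }
    return CodeUniverse(codes=list(descriptions), descriptions=descriptions)


@pytest.fixture(scope="session")
def tiny_dag(tiny_universe):
    return build_ontology([
        ("428.32", "390-459"), ("398.91", "390-459"),
        ("491.21", "460-519"), ("493.92", "460-519"),
        ("390-459", "ROOT"), ("460-519", "ROOT"),
    ])


@pytest.fixture(scope="session")
def tiny_labels(tiny_dag, tiny_universe):
    return derive_label_space(tiny_dag, tiny_universe)


@pytest.fixture(scope="session")
def tiny_table(tiny_universe) -> WordVectorTable:
    rng = np.random.default_rng(7)
    return WordVectorTable(
        vectors=rng.normal(0.0, 0.3, size=(tiny_universe.n_words, 5)),
        word_index=dict(tiny_universe.word_index))


@pytest.fixture(scope="session")
def small_cohort():
    """A small learnable cohort: 10 categories, 50 codes, 120 patients."""
    config = SynthConfig(n_patients=120, seed=11)
    dag, universe, cohort, table = generate(config)
    labels = derive_label_space(dag, universe)
    split = split_patients(cohort, seed=11)
    return {"config": config, "dag": dag, "universe": universe,
            "cohort": cohort, "table": table, "labels": labels, "split": split}
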