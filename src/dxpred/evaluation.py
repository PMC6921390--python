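"""Top-k evaluation of next-visit category prediction.

Two micro-averaged measures over all predicted timesteps of the test
patients, for k in {5, 10, 15, 20, 25, 30}:

* visit-level precision@k — per predicted visit, |top-k ∩ true labels| /
  min(k, number of true labels); coarse-grained.
* code-level accuracy@k — over all (visit, true-label) pairs, the fraction
  whose label appears in that visit's top-k; fine-grained, and monotone
  non-decreasing in k.

The data-sufficiency analysis buckets category labels into four quartile
groups by their training-set frequency (group "0-25" = rarest quarter) and
reports accuracy@k restricted to each group, which is where description-based
embeddings are expected to help most.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LabelSpace, PatientRecord
from .models import SequenceModel

DEFAULT_KS = (5, 10, 15, 20, 25, 30)
GROUP_NAMES = ("0-25", "25-50", "50-75", "75-100")


def top_k(yhat: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest-probability labels, ties to the lower index."""
    yhat = np.asarray(yhat)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > yhat.shape[-1]:
        raise ValueError(f"k={k} exceeds the number of labels {yhat.shape[-1]}")
    # stable sort on negated probabilities: equal values keep ascending index
    return np.argsort(-yhat, kind="stable")[:k]


def visit_precision_at_k(yhat: np.ndarray, y_true: Iterable[int], k: int) -> float:
    true = set(y_true)
    if not true:
        raise ValueError("empty true-label set")
    hits = len(set(top_k(yhat, k)) & true)
    return hits / min(k, len(true))


def code_accuracy_at_k(predictions: Sequence[tuple[np.ndarray, Iterable[int]]],
                       k: int) -> float:
    """Fraction of (visit, true-label) pairs whose label is in the top-k."""
    hits, total = 0, 0
    for yhat, y_true in predictions:
        top = set(top_k(yhat, k))
        for label in y_true:
            hits += label in top
            total += 1
    if total == 0:
        raise ValueError("no (visit, label) pairs to score")
    return hits / total


def frequency_groups(train_records: Sequence[PatientRecord],
                     label_space: LabelSpace) -> dict[int, str]:
    """Quartile group per label by training (visit, label) occurrence count.

    Labels are ranked by ascending frequency (ties broken by label index) and
    the ranked list is cut into four equal-cardinality bins; "0-25" holds the
    rarest quarter. With n_labels not divisible by 4, the earlier (rarer)
    bins receive the remainder.
    """
    if not train_records:
        raise ValueError("empty training set")
    counts = np.zeros(label_space.n_labels, dtype=np.int64)
    for rec in train_records:
        for visit in rec.visits:
            for lab in label_space.visit_labels(visit):
                counts[lab] += 1
    order = np.lexsort((np.arange(len(counts)), counts))  # freq asc, index asc
    groups: dict[int, str] = {}
    for name, chunk in zip(GROUP_NAMES, np.array_split(order, 4)):
        for lab in chunk:
            groups[int(lab)] = name
    return groups


@dataclass
class EvaluationReport:
    """Per-k overall metrics and per-frequency-group code accuracy."""

    visit_precision: dict[int, float]
    code_accuracy: dict[int, float]
    group_accuracy: dict[tuple[int, str], float | None] = field(default_factory=dict)
    model_name: str = ""
    embedding_source: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in sorted(self.visit_precision.items()):
            rows.append({"model": self.model_name,
                         "embedding_source": self.embedding_source,
                         "k": k, "metric": "visit_precision", "group": "",
                         "value": v})
        for k, v in sorted(self.code_accuracy.items()):
            rows.append({"model": self.model_name,
                         "embedding_source": self.embedding_source,
                         "k": k, "metric": "code_accuracy", "group": "",
                         "value": v})
        for (k, group), v in sorted(self.group_accuracy.items()):
            rows.append({"model": self.model_name,
                         "embedding_source": self.embedding_source,
                         "k": k, "metric": "code_accuracy", "group": group,
                         "value": np.nan if v is None else v})
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def collect_predictions(model: SequenceModel, records: Sequence[PatientRecord],
                        batch_size: int = 100
                        ) -> list[tuple[np.ndarray, frozenset[int]]]:
    """(probability vector, true label set) per predicted visit, in order."""
    label_space = model.label_space
    out: list[tuple[np.ndarray, frozenset[int]]] = []
    records = list(records)
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        batch = model.forward(chunk)
        for b, rec in enumerate(chunk):
            for t in range(rec.n_visits - 1):
                out.append((batch.probs[t, b],
                            label_space.visit_labels(rec.visits[t + 1])))
    return out


def evaluate(model: SequenceModel, test_records: Sequence[PatientRecord],
             groups: Mapping[int, str] | None = None,
             ks: Sequence[int] = DEFAULT_KS,
             model_name: str | None = None) -> EvaluationReport:
    """Score a trained model on test patients at every k (and per group)."""
    preds = collect_predictions(model, test_records)
    if not preds:
        raise ValueError("no predictions to evaluate")
    report = EvaluationReport(
        visit_precision={}, code_accuracy={},
        model_name=model_name or model.config.architecture,
        embedding_source=model.config.embedding_source)
    for k in ks:
        report.visit_precision[k] = float(np.mean(
            [visit_precision_at_k(yhat, true, k) for yhat, true in preds]))
        report.code_accuracy[k] = code_accuracy_at_k(preds, k)
    if groups is not None:
        for k in ks:
            for name in GROUP_NAMES:
                pairs = [(yhat, [lab for lab in true if groups[lab] == name])
                         for yhat, true in preds]
                pairs = [(yhat, labs) for yhat, labs in pairs if labs]
                report.group_accuracy[(k, name)] = (
                    code_accuracy_at_k(pairs, k) if pairs else None)
    return report
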