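"""Loss, Adadelta optimisation, batching and best-epoch model selection.

Training minimises a multi-label cross-entropy on the softmax output,

    loss = mean over predicted timesteps of -[ y . log yhat
                                              + (1-y) . log(1-yhat) ],

where y is the multi-hot of the next visit's category labels, plus an l2
penalty (coefficient 0.001) on all weight matrices. Patients are shuffled
each epoch into minibatches of 100, padded to the batch maximum sequence
length with masked timesteps that contribute exactly zero to loss and
gradients. After each epoch the validation loss is computed and the parameter
snapshot with the best validation loss over all epochs is returned.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data import LabelSpace, PatientRecord
from .models import PredictionBatch, SequenceModel

LOG_CLAMP = 1e-10


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 100
    l2_coeff: float = 0.001
    rho: float = 0.95        # Adadelta decay
    epsilon: float = 1e-6    # Adadelta conditioner
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.l2_coeff < 0:
            raise ValueError("invalid training configuration")


def make_targets(records: list[PatientRecord], label_space: LabelSpace,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Next-visit label multi-hots (T-1, B, L) and the prediction mask."""
    T = max(r.n_visits for r in records)
    B, n_labels = len(records), label_space.n_labels
    y = np.zeros((T - 1, B, n_labels))
    mask = np.zeros((T - 1, B), dtype=bool)
    for b, rec in enumerate(records):
        for t in range(1, rec.n_visits):
            y[t - 1, b, sorted(label_space.visit_labels(rec.visits[t]))] = 1.0
            mask[t - 1, b] = True
    return y, mask


def prediction_loss(batch: Tensor | PredictionBatch | np.ndarray,
                    targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean multi-label cross-entropy over unmasked timesteps (logs clamped)."""
    if isinstance(batch, PredictionBatch):
        probs, mask = Tensor(batch.probs), batch.mask
    elif isinstance(batch, Tensor):
        probs = batch
    else:
        probs = Tensor(np.asarray(batch, dtype=float))
    if mask is None:
        mask = np.ones(probs.shape[:-1], dtype=bool)
    y = Tensor(targets)
    log_p = ag.log(ag.clip(probs, LOG_CLAMP, 1.0))
    log_not_p = ag.log(ag.clip(1.0 - probs, LOG_CLAMP, 1.0))
    per_step = -ag.tsum(y * log_p + (1.0 - y) * log_not_p, axis=-1)  # (T-1, B)
    masked = per_step * Tensor(mask.astype(float))
    return ag.tsum(masked) * (1.0 / max(int(mask.sum()), 1))


def l2_penalty(model: SequenceModel, coeff: float = 0.001) -> Tensor:
    """coeff times the sum of squared weight-matrix entries (biases excluded)."""
    total: Tensor | float = 0.0
    for w in model.weight_matrices().values():
        total = ag.tsum(w * w) + total
    return total * coeff if isinstance(total, Tensor) else Tensor(0.0)


class Adadelta:
    """Adadelta with accumulated squared gradients and updates."""

    def __init__(self, params: dict[str, Tensor], rho: float = 0.95,
                 epsilon: float = 1e-6):
        self.params = params
        self.rho = rho
        self.epsilon = epsilon
        self.Eg2 = {k: np.zeros(p.shape) for k, p in params.items()}
        self.Edx2 = {k: np.zeros(p.shape) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.Eg2[k] = self.rho * self.Eg2[k] + (1 - self.rho) * g * g
            dx = -np.sqrt(self.Edx2[k] + self.epsilon) / \
                np.sqrt(self.Eg2[k] + self.epsilon) * g
            self.Edx2[k] = self.rho * self.Edx2[k] + (1 - self.rho) * dx * dx
            p.data = p.data + dx


@dataclass
class TrainResult:
    history: list[dict]                 # per epoch: losses and timing
    best_epoch: int                     # epoch whose snapshot was restored
    best_state: dict[str, np.ndarray]   # parameters at the best epoch

    @property
    def best_validation_loss(self) -> float:
        return self.history[self.best_epoch]["valid_loss"]


def _dataset_loss(model: SequenceModel, records: list[PatientRecord],
                  label_space: LabelSpace, batch_size: int) -> float:
    total, count = 0.0, 0
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        probs, mask = model.forward_tensor(chunk)
        y, _ = make_targets(chunk, label_space)
        n = int(mask.sum())
        total += float(prediction_loss(probs, y, mask).data) * n
        count += n
    return total / max(count, 1)


def train(model: SequenceModel, train_records: list[PatientRecord],
          valid_records: list[PatientRecord], config: TrainConfig) -> TrainResult:
    """Optimise the model, snapshotting the best-validation-loss parameters."""
    if not train_records:
        raise ValueError("empty training set")
    label_space = model.label_space
    opt = Adadelta(model.parameters(), config.rho, config.epsilon)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_state = model.state_dict()
    best_loss, best_epoch = np.inf, -1
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_records))
        epoch_loss, epoch_n = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_records[j] for j in order[i:i + config.batch_size]]
            probs, mask = model.forward_tensor(chunk)
            y, _ = make_targets(chunk, label_space)
            loss = prediction_loss(probs, y, mask) + l2_penalty(model,
                                                                config.l2_coeff)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch starting {i}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            n = int(mask.sum())
            epoch_loss += value * n
            epoch_n += n
        valid_loss = (_dataset_loss(model, valid_records, label_space,
                                    config.batch_size)
                      if valid_records else epoch_loss / max(epoch_n, 1))
        history.append({"epoch": epoch,
                        "train_loss": epoch_loss / max(epoch_n, 1),
                        "valid_loss": valid_loss,
                        "seconds": time.perf_counter() - t0})
        if valid_loss < best_loss:
            best_loss, best_epoch = valid_loss, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return TrainResult(history=history, best_epoch=best_epoch,
                       best_state=best_state)


def write_history(history: list[dict], path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss",
                                                "valid_loss", "seconds"])
        writer.writeheader()
        writer.writerows(history)
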