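"""Training loop, checkpointing, best-checkpoint selection, grid search.

Training is per-example stochastic gradient descent on the cross-entropy
(relative entropy against a one-hot target), with the training set
reshuffled every epoch from a seeded stream.  Every ``checkpoint_every``
epochs the model is scored on the validation set and a checkpoint (deep
parameter copy + validation accuracy + running training loss) is appended,
so ``total_epochs / checkpoint_every`` related-but-different models come
out of one run — 500 under the default 5000/10 schedule.  The best n
checkpoints by validation accuracy (ties to the earlier epoch) feed the
ensemble.

The validation selection metric is overall accuracy Q (fraction of correct
argmax calls).  Momentum, weight decay and minibatching are exposed but
inert by default; the learning rate is constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .n1nn_core import (N1NNConfig, N1NNParams, apply_gradients, backward,
                        forward, init_params, loss)
from .records import LocalizationClass

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "TrainingDivergedError",
    "evaluate_accuracy",
    "sgd_train",
    "select_best",
    "grid_search",
]

#: A training example: (N x D feature matrix, class label).
Example = Tuple[np.ndarray, LocalizationClass]


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule.

    ``learning_rate`` defaults to 0.015 (the middle of the 0.01-0.02 range
    that works well for this architecture family); ``total_epochs`` must be
    a multiple of ``checkpoint_every`` so the run yields exactly
    ``total_epochs / checkpoint_every`` checkpoints.
    """

    learning_rate: float = 0.015
    total_epochs: int = 5000
    checkpoint_every: int = 10
    seed: int = 0
    batch_size: int = 1
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.total_epochs < 1 or self.checkpoint_every < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.total_epochs % self.checkpoint_every != 0:
            raise ValueError(
                "checkpoint_every must divide total_epochs "
                f"({self.checkpoint_every} does not divide {self.total_epochs})"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def n_checkpoints(self) -> int:
        return self.total_epochs // self.checkpoint_every


@dataclass
class Checkpoint:
    """Model snapshot at a validation epoch."""

    epoch: int
    params: N1NNParams
    config: N1NNConfig
    validation_accuracy: float
    train_loss: float

    def fingerprint(self) -> int:
        """Cheap content hash used to reject duplicate ensemble members."""
        h = 0
        for a in self.params.arrays():
            h ^= hash(a.tobytes())
        return h ^ hash((self.epoch, round(self.validation_accuracy, 12)))


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, example_index: int):
        super().__init__(
            f"non-finite loss at epoch {epoch}, training example {example_index}"
        )
        self.epoch = epoch
        self.example_index = example_index


def evaluate_accuracy(params: N1NNParams, config: N1NNConfig,
                      examples: Sequence[Example]) -> float:
    """Overall accuracy Q: fraction of examples whose argmax matches the label."""
    if not examples:
        raise ValueError("cannot evaluate on an empty set")
    correct = 0
    for x, y in examples:
        trace = forward(params, x, config)
        if int(np.argmax(trace.probabilities)) == int(y):
            correct += 1
    return correct / len(examples)


def sgd_train(config: N1NNConfig, tconfig: TrainConfig,
              train: Sequence[Example], valid: Sequence[Example],
              log: Optional[list] = None) -> List[Checkpoint]:
    """Train by per-example SGD and return one checkpoint per validation point.

    Fully reproducible from ``tconfig.seed`` (parameter init and the
    per-epoch shuffles derive from it).  Raises
    :class:`TrainingDivergedError` on a non-finite loss.  If ``log`` is
    given, (epoch, mean train loss, validation accuracy) tuples are
    appended at every checkpoint.
    """
    if not train or not valid:
        raise ValueError("train and validation sets must be non-empty")
    init_seq, shuffle_seq = np.random.SeedSequence(tconfig.seed).spawn(2)
    params = init_params(config, seed=int(init_seq.generate_state(1)[0] % (2 ** 31)))
    rng = np.random.default_rng(shuffle_seq)

    velocity = None
    if tconfig.momentum:
        velocity = [np.zeros_like(a) for a in params.arrays()]

    checkpoints: List[Checkpoint] = []
    order = np.arange(len(train))
    for epoch in range(1, tconfig.total_epochs + 1):
        rng.shuffle(order)
        epoch_loss = 0.0
        pending = []  # minibatch gradient accumulator
        for j, idx in enumerate(order):
            x, y = train[idx]
            trace = forward(params, x, config)
            step_loss = loss(trace, y)
            if not np.isfinite(step_loss):
                raise TrainingDivergedError(epoch, int(idx))
            epoch_loss += step_loss
            grads = backward(params, trace, y)
            pending.append(grads)
            if len(pending) == tconfig.batch_size or j == len(order) - 1:
                _step(params, pending, tconfig, velocity)
                pending = []
        if epoch % tconfig.checkpoint_every == 0:
            acc = evaluate_accuracy(params, config, valid)
            mean_loss = epoch_loss / len(train)
            checkpoints.append(Checkpoint(
                epoch=epoch, params=params.copy(), config=config,
                validation_accuracy=acc, train_loss=mean_loss,
            ))
            if log is not None:
                log.append((epoch, mean_loss, acc))
    return checkpoints


def _step(params: N1NNParams, grads_list: List[N1NNParams],
          tconfig: TrainConfig, velocity: Optional[List[np.ndarray]]) -> None:
    summed = grads_list[0]
    for g in grads_list[1:]:
        for a, b in zip(summed.arrays(), g.arrays()):
            a += b
    scale = 1.0 / len(grads_list)
    if velocity is None:
        for a in summed.arrays():
            a *= scale
        apply_gradients(params, summed, tconfig.learning_rate,
                        tconfig.weight_decay)
    else:
        for v, g, w in zip(velocity, summed.arrays(), params.arrays()):
            v *= tconfig.momentum
            v += scale * (g + tconfig.weight_decay * w)
            w -= tconfig.learning_rate * v
        params.version += 1


def select_best(checkpoints: Sequence[Checkpoint], n: int = 6) -> List[Checkpoint]:
    """The n checkpoints with highest validation accuracy.

    Ties break toward the earlier epoch; the result is ordered by
    descending accuracy (then ascending epoch).
    """
    if n > len(checkpoints):
        raise ValueError(
            f"cannot select {n} checkpoints from {len(checkpoints)}"
        )
    ranked = sorted(checkpoints, key=lambda c: (-c.validation_accuracy, c.epoch))
    return list(ranked[:n])


@dataclass
class GridResult:
    config: N1NNConfig
    tconfig: TrainConfig
    best_accuracy: Optional[float]
    best_epoch: Optional[int]
    checkpoints: Optional[List[Checkpoint]]
    error: Optional[str] = None


def grid_search(grid: Sequence[Tuple[N1NNConfig, TrainConfig]],
                train: Sequence[Example], valid: Sequence[Example]
                ) -> List[GridResult]:
    """Train every (architecture, schedule) cell independently.

    A failing cell is recorded with its error message and the grid
    continues.  Each cell is seeded by its own TrainConfig, so the whole
    table is reproducible.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    results: List[GridResult] = []
    for config, tconfig in grid:
        try:
            cps = sgd_train(config, tconfig, train, valid)
            best = select_best(cps, 1)[0]
            results.append(GridResult(
                config=config, tconfig=tconfig,
                best_accuracy=best.validation_accuracy,
                best_epoch=best.epoch, checkpoints=cps,
            ))
        except Exception as exc:  # cell failure must not kill the grid
            results.append(GridResult(
                config=config, tconfig=tconfig,
                best_accuracy=None, best_epoch=None, checkpoints=None,
                error=str(exc),
            ))
    return results
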