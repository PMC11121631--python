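"""End-to-end driver routines composing the pipeline modules.

`learnability_experiment` is the package's canonical demonstration: it
builds a synthetic 4-class motif corpus, splits it 3:1:1, trains one small
network per input semi-context c in {2, 3, 4, 5} (minimal depth, k = 0),
keeps the 6 best checkpoints of each by validation accuracy, averages the
resulting 24 members, and scores the ensemble on the validation partition.
This mirrors the deployed predictor's construction — 6 best models from
each of 4 kernel sizes — at a scale that runs in well under a minute.

`cross_validation_folds` is a thin 5-fold driver over the interleaved
assignment, provided for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .dataset_pipeline import interleaved_split
from .encoding import encode_dataset
from .ensemble import EnsembleModel, build_ensemble, ensemble_predict
from .n1nn_core import N1NNConfig
from .records import ProteinRecord
from .synthetic_fixtures import GeneratorSpec, generate_dataset
from .training_selection import (Checkpoint, Example, TrainConfig, select_best,
                                 sgd_train)

__all__ = ["LearnabilityResult", "learnability_experiment", "cross_validation_folds"]

#: Input semi-contexts of the four ensembled configurations.
DEMO_SEMI_CONTEXTS = (2, 3, 4, 5)


@dataclass
class LearnabilityResult:
    ensemble: EnsembleModel
    validation_accuracy: float
    best_single_accuracies: List[float]
    n_train: int
    n_validation: int


def _encode_labeled(records: Sequence[ProteinRecord]) -> List[Example]:
    return [(pm.values, rec.label)
            for pm, rec in zip(encode_dataset(records), records)]


def learnability_experiment(
    seed: int,
    total_epochs: int = 200,
    n_best: int = 6,
    spec: GeneratorSpec | None = None,
) -> LearnabilityResult:
    """Train the 4-configuration, 24-member demo ensemble on synthetic data.

    The generator uses its defaults (4 classes, 50 sequences per class,
    noise-free disjoint motifs) with the given seed; training uses SGD with
    learning rate 0.1 and momentum 0.9 for ``total_epochs`` epochs,
    checkpointing every 10.
    """
    if spec is None:
        spec = GeneratorSpec(seed=seed)
    records = generate_dataset(spec)
    split = interleaved_split(records)
    train = _encode_labeled(split.train)
    valid = _encode_labeled(split.validation)

    groups: List[List[Checkpoint]] = []
    for i, c in enumerate(DEMO_SEMI_CONTEXTS):
        config = N1NNConfig(c=c, gamma=0, n_hidden_kernels=0, input_width=22,
                            kernel_hidden_units=16, state_units=16,
                            fc_hidden_units=16)
        tconfig = TrainConfig(learning_rate=0.1, momentum=0.9,
                              total_epochs=total_epochs, checkpoint_every=10,
                              seed=(seed + 1000 * (i + 1)) % (2 ** 31))
        checkpoints = sgd_train(config, tconfig, train, valid)
        groups.append(select_best(checkpoints, n_best))

    ensemble = build_ensemble(groups)
    correct = sum(
        int(ensemble_predict(ensemble, x)[1]) == int(y) for x, y in valid
    )
    return LearnabilityResult(
        ensemble=ensemble,
        validation_accuracy=correct / len(valid),
        best_single_accuracies=[g[0].validation_accuracy for g in groups],
        n_train=len(train),
        n_validation=len(valid),
    )


def cross_validation_folds(records: Sequence[ProteinRecord], n_folds: int = 5
                           ) -> List[Tuple[List[ProteinRecord], List[ProteinRecord]]]:
    """Assign record i to fold i mod n_folds; yield (train, held-out) per fold."""
    folds = [[] for _ in range(n_folds)]
    for i, rec in enumerate(records):
        folds[i % n_folds].append(rec)
    out = []
    for k in range(n_folds):
        held = folds[k]
        rest = [r for j, f in enumerate(folds) if j != k for r in f]
        out.append((rest, held))
    return out
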