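"""Ensembling of selected checkpoints into the final predictor.

The deployed predictor combines the best checkpoints of several
architectures (canonically the 6 best models from each of 4 kernel sizes,
24 in total) by unweighted averaging of their class-probability vectors;
majority voting over argmax calls is available as an option.  Members may
differ in depth and semi-context but must agree on the number of classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .n1nn_core import N1NNConfig, N1NNParams, forward
from .records import LocalizationClass
from .training_selection import Checkpoint

__all__ = ["EnsembleModel", "build_ensemble", "ensemble_predict"]


@dataclass
class EnsembleModel:
    """A bag of (config, params) members combined by probability averaging."""

    members: List[Tuple[N1NNConfig, N1NNParams]]
    rule: str = "mean"  # or "vote"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.rule not in ("mean", "vote"):
            raise ValueError(f"unknown combination rule {self.rule!r}")
        n_classes = {cfg.n_classes for cfg, _ in self.members}
        if len(n_classes) != 1:
            raise ValueError(f"members disagree on n_classes: {sorted(n_classes)}")

    @property
    def n_members(self) -> int:
        return len(self.members)


def build_ensemble(selected: Sequence[Sequence[Checkpoint]],
                   rule: str = "mean") -> EnsembleModel:
    """Flatten per-configuration checkpoint selections into one ensemble.

    Member count is the sum of the per-configuration selections (4 x 6 = 24
    in the canonical setup).  Duplicate checkpoints (identical parameters
    and epoch) are rejected by content fingerprint.
    """
    members: List[Tuple[N1NNConfig, N1NNParams]] = []
    seen = set()
    for group in selected:
        if not group:
            raise ValueError("every per-configuration checkpoint list must be non-empty")
        for cp in group:
            fp = cp.fingerprint()
            if fp in seen:
                raise ValueError(
                    f"duplicate checkpoint (epoch {cp.epoch}) passed to the ensemble"
                )
            seen.add(fp)
            members.append((cp.config, cp.params))
    return EnsembleModel(members=members, rule=rule)


def ensemble_predict(model: EnsembleModel, x: np.ndarray
                     ) -> Tuple[np.ndarray, LocalizationClass]:
    """Combine member outputs on one encoded sequence.

    Mean rule: unweighted element-wise average of member probability
    vectors.  Vote rule: each member casts its argmax; the tally is
    normalized to a probability vector.  Either way the predicted class is
    the argmax with lowest-index tie-break.
    """
    x = np.asarray(x, dtype=np.float64)
    for cfg, _ in model.members:
        if x.ndim != 2 or x.shape[1] != cfg.input_width:
            raise ValueError(
                f"input width {x.shape[1] if x.ndim == 2 else None} does not "
                f"match member input_width={cfg.input_width}"
            )
    n_classes = model.members[0][0].n_classes
    if model.rule == "mean":
        acc = np.zeros(n_classes)
        for cfg, params in model.members:
            acc += forward(params, x, cfg).probabilities
        probs = acc / model.n_members
    else:
        votes = np.zeros(n_classes)
        for cfg, params in model.members:
            votes[int(np.argmax(forward(params, x, cfg).probabilities))] += 1
        probs = votes / votes.sum()
    return probs, LocalizationClass(int(np.argmax(probs)))
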