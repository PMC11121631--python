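"""Sequence encodings consumed by the network.

Two modes:

* **one-hot** — each position is a 21-bit indicator over the residue
  alphabet (20 amino acids + 'X').
* **profile** — each position is a 22-vector of symbol frequencies computed
  over the rows of a multiple sequence alignment (21 residue columns plus a
  gap column), after which the column of the query's own residue is
  "clipped" to 1.  Profiles are indexed by query positions: alignment
  columns where the query itself is gapped (insertions in homologs) are
  dropped, so the matrix always has the query's length.

Non-query frequencies are left as computed after clipping (no
renormalization), so every entry stays in [0, 1] and the query signal is
always present at full strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .records import (ALPHABET, ALPHABET_INDEX, GAP, GAP_INDEX, AlignmentSet,
                      ProteinRecord)

__all__ = ["ProfileMatrix", "one_hot_encode", "build_profile", "encode_dataset"]

ONEHOT_WIDTH = len(ALPHABET)          # 21
PROFILE_WIDTH = len(ALPHABET) + 1     # 22, gap column last


@dataclass(frozen=True)
class ProfileMatrix:
    """An N x D per-position encoding of one protein.

    ``mode`` is ``"onehot"`` (D = 21, or 22 after harmonization with a zero
    gap column) or ``"profile"`` (D = 22).
    """

    record_id: str
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("profile values must be a 2-D matrix")
        if self.mode not in ("onehot", "profile"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("profile entries must lie in [0, 1]")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def one_hot_encode(record: ProteinRecord) -> ProfileMatrix:
    """Encode a sanitized sequence as an N x 21 one-hot matrix."""
    n = len(record.sequence)
    values = np.zeros((n, ONEHOT_WIDTH))
    for i, ch in enumerate(record.sequence):
        try:
            values[i, ALPHABET_INDEX[ch]] = 1.0
        except KeyError:
            raise ValueError(
                f"record {record.id!r}: character {ch!r} outside the alphabet"
            ) from None
    return ProfileMatrix(record_id=record.id, values=values, mode="onehot")


def build_profile(msa: AlignmentSet) -> ProfileMatrix:
    """Compute a clipped MSA frequency profile, indexed by query positions.

    For each column where the query (row 0) has a residue: columns 0-20 hold
    the frequency of each alphabet symbol among all rows, column 21 the gap
    frequency; the query-residue column is then set ("clipped") to 1.
    """
    query = msa.rows[0]
    rows = msa.rows
    n_rows = len(rows)
    keep = [j for j, ch in enumerate(query) if ch != GAP]
    values = np.zeros((len(keep), PROFILE_WIDTH))
    for i, j in enumerate(keep):
        for row in rows:
            ch = row[j]
            if ch == GAP:
                values[i, GAP_INDEX] += 1.0
            else:
                values[i, ALPHABET_INDEX[ch]] += 1.0
        values[i] /= n_rows
        values[i, ALPHABET_INDEX[query[j]]] = 1.0  # the clip
    return ProfileMatrix(msa.query_id, values, mode="profile")


def _harmonize_onehot(pm: ProfileMatrix) -> ProfileMatrix:
    """Pad a 21-wide one-hot matrix with a zero gap column to width 22."""
    padded = np.concatenate(
        [pm.values, np.zeros((pm.values.shape[0], 1))], axis=1
    )
    return ProfileMatrix(pm.record_id, padded, mode="onehot")


def encode_dataset(
    records: Sequence[ProteinRecord],
    msas: Optional[Dict[str, AlignmentSet]] = None,
    require_msa: bool = False,
) -> List[ProfileMatrix]:
    """Encode a record list; profile mode where an MSA exists, one-hot otherwise.

    All returned matrices share width 22 (one-hot matrices gain a zero gap
    column).  With ``require_msa=True`` every record must have an MSA.
    """
    msas = msas or {}
    if require_msa:
        missing = [r.id for r in records if r.id not in msas]
        if missing:
            raise ValueError(
                "profile mode requires an MSA for every record; missing: "
                + ", ".join(missing)
            )
    out: List[ProfileMatrix] = []
    for rec in records:
        if rec.id in msas:
            out.append(build_profile(msas[rec.id]))
        else:
            out.append(_harmonize_onehot(one_hot_encode(rec)))
    return out
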