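"""File I/O: FASTA, label tables, prediction tables, MSAs, model containers.

FASTA parsing goes through Biopython.  Models are stored in a numpy ``.npz``
container carrying a format-version tag, the JSON-encoded hyperparameter
configuration, every weight array bit-exactly, and optional checkpoint
metadata (epoch, validation score, running training loss).
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .n1nn_core import KernelParams, N1NNConfig, N1NNParams
from .records import (GAP, AlignmentSet, LocalizationClass, ProteinRecord,
                      sanitize_sequence)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "read_msa_fasta",
    "write_predictions",
    "read_predictions",
    "save_model",
    "load_model",
    "FastaParseError",
    "ModelFormatError",
]

MODEL_FORMAT_VERSION = "n1loc-model-1"
PREDICTIONS_VERSION = "n1loc-predictions-1"


class FastaParseError(ValueError):
    pass


class ModelFormatError(ValueError):
    pass


def read_fasta(path, labels: Optional[Dict[str, LocalizationClass]] = None
               ) -> List[ProteinRecord]:
    """Read a FASTA file into sanitized :class:`ProteinRecord` objects.

    Nonstandard residue letters collapse to 'X'; sequences are uppercased;
    file order is preserved.  Duplicate ids or empty sequences raise
    :class:`FastaParseError` naming the offending entry.  If ``labels`` is
    given, matching records get their label attached.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise FastaParseError(f"{path}: entry with empty header")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        raw = str(entry.seq)
        if not raw:
            raise FastaParseError(f"{path}: record {rid!r} has an empty sequence")
        try:
            seq = sanitize_sequence(raw)
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {rid!r}: {exc}") from None
        label = labels.get(rid) if labels else None
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_labels(path) -> Dict[str, LocalizationClass]:
    """Read a two-column (id TAB class) table; header row optional.

    Class tokens are matched case-insensitively with spaces and underscores
    interchangeable.  An unknown token raises, naming the token and line.
    """
    out: Dict[str, LocalizationClass] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            rid, token = parts[0].strip(), parts[1].strip()
            try:
                cls = LocalizationClass.parse(token)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(
                    f"{path}:{lineno}: unknown class token {token!r}"
                ) from None
            out[rid] = cls
    return out


def read_msa_fasta(path, query_id: Optional[str] = None) -> AlignmentSet:
    """Read one aligned-FASTA MSA; the first row is the query."""
    rows = []
    first_id = None
    for entry in SeqIO.parse(str(path), "fasta"):
        if first_id is None:
            first_id = entry.id
        raw = str(entry.seq).upper()
        cleaned = "".join(
            ch if ch == GAP else sanitize_sequence(ch) for ch in raw
        )
        rows.append(cleaned)
    if first_id is None:
        raise FastaParseError(f"{path}: empty MSA file")
    return AlignmentSet(query_id=query_id or first_id, rows=tuple(rows))


def write_predictions(records: Sequence[ProteinRecord],
                      probs: Sequence[np.ndarray], path) -> None:
    """Write a prediction TSV: id, predicted_class, 8 per-class probabilities.

    Probabilities appear in frozen class order at 6 decimal places; each
    vector must sum to 1 within 1e-6.  Ties in the argmax go to the lowest
    class index.
    """
    if len(records) != len(probs):
        raise ValueError(
            f"{len(records)} records but {len(probs)} probability vectors"
        )
    classes = list(LocalizationClass)
    with open(path, "w") as fh:
        fh.write("# " + PREDICTIONS_VERSION + "\n")
        fh.write("id\tpredicted_class\t" + "\t".join(c.name for c in classes) + "\n")
        for rec, p in zip(records, probs):
            p = np.asarray(p, dtype=float)
            if p.shape != (len(classes),):
                raise ValueError(f"record {rec.id!r}: probability vector has shape {p.shape}")
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"record {rec.id!r}: probabilities sum to {p.sum():.8f}, not 1"
                )
            pred = classes[int(np.argmax(p))]  # argmax returns lowest index on ties
            fh.write(rec.id + "\t" + pred.name + "\t"
                     + "\t".join(f"{v:.6f}" for v in p) + "\n")


def read_predictions(path) -> Tuple[List[str], List[LocalizationClass], np.ndarray]:
    """Read a prediction TSV back into (ids, predicted classes, probability matrix)."""
    ids: List[str] = []
    preds: List[LocalizationClass] = []
    rows: List[List[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            parts = line.split("\t")
            ids.append(parts[0])
            preds.append(LocalizationClass.parse(parts[1]))
            rows.append([float(v) for v in parts[2:]])
    return ids, preds, np.asarray(rows)


def _config_to_dict(config: N1NNConfig) -> dict:
    return {
        "c": config.c,
        "gamma": config.gamma,
        "n_hidden_kernels": config.n_hidden_kernels,
        "input_width": config.input_width,
        "kernel_hidden_units": config.kernel_hidden_units,
        "state_units": config.state_units,
        "fc_hidden_units": config.fc_hidden_units,
        "n_classes": config.n_classes,
    }


def save_model(params: N1NNParams, config: N1NNConfig, path,
               metadata: Optional[dict] = None) -> None:
    """Serialize a model (and optional checkpoint metadata) to an .npz container."""
    arrays = {}
    ik = params.input_kernel
    arrays["input_w1"], arrays["input_b1"] = ik.w1, ik.b1
    arrays["input_w2"], arrays["input_b2"] = ik.w2, ik.b2
    for i, kp in enumerate(params.hidden_kernels):
        arrays[f"hidden{i}_w1"], arrays[f"hidden{i}_b1"] = kp.w1, kp.b1
        arrays[f"hidden{i}_w2"], arrays[f"hidden{i}_b2"] = kp.w2, kp.b2
    arrays["fc_w1"], arrays["fc_b1"] = params.fc_w1, params.fc_b1
    arrays["fc_w2"], arrays["fc_b2"] = params.fc_w2, params.fc_b2
    np.savez(
        path,
        format_version=np.array(MODEL_FORMAT_VERSION),
        config_json=np.array(json.dumps(_config_to_dict(config))),
        metadata_json=np.array(json.dumps(metadata or {})),
        **arrays,
    )


def load_model(path) -> Tuple[N1NNParams, N1NNConfig, dict]:
    """Load a model saved by :func:`save_model`; bit-exact round trip.

    Raises :class:`ModelFormatError` on a version mismatch or a truncated /
    malformed file.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            if "format_version" not in data:
                raise ModelFormatError(f"{path}: missing format-version tag")
            version = str(data["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: unsupported model format {version!r}, "
                    f"expected {MODEL_FORMAT_VERSION!r}"
                )
            cfg = N1NNConfig(**json.loads(str(data["config_json"])))
            metadata = json.loads(str(data["metadata_json"]))
            ik = KernelParams(data["input_w1"], data["input_b1"],
                              data["input_w2"], data["input_b2"])
            hidden = [
                KernelParams(data[f"hidden{i}_w1"], data[f"hidden{i}_b1"],
                             data[f"hidden{i}_w2"], data[f"hidden{i}_b2"])
                for i in range(cfg.n_hidden_kernels)
            ]
            params = N1NNParams(
                input_kernel=ik,
                hidden_kernels=hidden,
                fc_w1=data["fc_w1"], fc_b1=data["fc_b1"],
                fc_w2=data["fc_w2"], fc_b2=data["fc_b2"],
            )
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"{path}: cannot read model file ({exc})") from exc
    return params, cfg, metadata
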