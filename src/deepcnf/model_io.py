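"""Model serialization and the prediction pipeline.

Models are stored as a single JSON document: format version, architecture,
alphabet orderings, flattened parameters with per-tensor shape records, and
training metadata.  JSON floats round-trip float64 exactly, so load(save(x))
reproduces the parameters bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import crf, dcnn
from .alphabets import AA_ALPHABET, SS3_ALPHABET, SS8_ALPHABET, ss8_string_to_ss3
from .features import build_features
from .io import ProfileMatrix
from .model import LayerSpec, ModelParams, ModelSpec

FORMAT_VERSION = 1


class ModelLoadError(ValueError):
    """Base class for model-file problems."""


class ModelVersionError(ModelLoadError):
    """The file's format_version is not supported."""


class ModelIntegrityError(ModelLoadError):
    """Truncated file or shape/parameter-count mismatch."""


def save_model(params: ModelParams, path, metadata: dict | None = None) -> None:
    spec = params.spec
    doc = {
        "format_version": FORMAT_VERSION,
        "spec": {
            "input_width": spec.input_width,
            "num_labels": spec.num_labels,
            "layers": [
                {"neurons": l.neurons, "half_window": l.half_window, "activation": l.activation}
                for l in spec.layers
            ],
        },
        "alphabets": {
            "ss8": SS8_ALPHABET,
            "ss3": SS3_ALPHABET,
            "amino_acids": AA_ALPHABET + "X",
        },
        "tensor_shapes": [list(w.shape) for w in params.W]
        + [list(params.U.shape), list(params.T.shape)],
        "parameters": params.to_vector().tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> tuple[ModelParams, dict]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelIntegrityError(f"{path}: not a complete JSON model file ({exc})") from None
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ModelIntegrityError(f"{path}: missing format_version")
    if doc["format_version"] != FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: format_version {doc['format_version']}, supported {FORMAT_VERSION}"
        )
    try:
        spec = ModelSpec(
            tuple(
                LayerSpec(l["neurons"], l["half_window"], l["activation"])
                for l in doc["spec"]["layers"]
            ),
            num_labels=doc["spec"]["num_labels"],
            input_width=doc["spec"]["input_width"],
        )
        vec = np.asarray(doc["parameters"], dtype=float)
        shapes = [tuple(s) for s in doc["tensor_shapes"]]
    except (KeyError, TypeError) as exc:
        raise ModelIntegrityError(f"{path}: malformed model document ({exc})") from None
    expected = sum(int(np.prod(s)) for s in shapes)
    if vec.size != expected:
        raise ModelIntegrityError(
            f"{path}: {vec.size} parameters, shape records expect {expected}"
        )
    try:
        params = ModelParams.from_vector(spec, vec)
    except ValueError as exc:
        raise ModelIntegrityError(f"{path}: {exc}") from None
    declared = [tuple(w.shape) for w in params.W] + [params.U.shape, params.T.shape]
    if declared != shapes:
        raise ModelIntegrityError(f"{path}: tensor shapes {shapes} do not match spec {declared}")
    return params, doc.get("metadata", {})


@dataclass
class PredictionRecord:
    """Per-sequence prediction: label strings plus the per-residue posteriors."""

    id: str
    sequence: str
    ss8: str
    ss3: str
    posterior: np.ndarray  # L x num_labels
    label_alphabet: str
    error: str | None = field(default=None)


def _label_alphabet(num_labels: int) -> str:
    if num_labels == 8:
        return SS8_ALPHABET
    if num_labels == 3:
        return SS3_ALPHABET
    raise ValueError(f"no label alphabet for {num_labels} labels")


# 3-state predictions rendered as 8-state strings use class representatives.
_SS3_TO_SS8 = {"H": "H", "E": "E", "C": "L"}


def predict_one(
    params: ModelParams, seq_id: str, residues: str, profile: ProfileMatrix, viterbi: bool = True
) -> PredictionRecord:
    """Features -> convolutional stack -> potentials -> decode + posteriors."""
    X = build_features(residues, profile)
    H = dcnn.forward(params, X)
    pot = crf.make_potentials(params.U, params.T, H[-1])
    post = crf.posteriors(pot)
    path = crf.decode_viterbi(pot) if viterbi else crf.decode_posterior(post)
    alphabet = _label_alphabet(params.spec.num_labels)
    pred = "".join(alphabet[i] for i in path)
    if params.spec.num_labels == 8:
        ss8, ss3 = pred, ss8_string_to_ss3(pred)
    else:
        ss8 = "".join(_SS3_TO_SS8[c] for c in pred)
        ss3 = pred
    return PredictionRecord(seq_id, residues, ss8, ss3, post.singleton, alphabet)


def predict(params: ModelParams, items, viterbi: bool = True, on_error=None) -> list[PredictionRecord]:
    """Predict a batch of (id, residues, ProfileMatrix) items.

    A failing item yields a record carrying its error message (and is reported
    through ``on_error``); the run continues.
    """
    records = []
    for seq_id, residues, profile in items:
        try:
            records.append(predict_one(params, seq_id, residues, profile, viterbi=viterbi))
        except Exception as exc:  # per-record isolation
            if on_error is not None:
                on_error(seq_id, exc)
            records.append(PredictionRecord(seq_id, residues, "", "", np.zeros((0, 0)), "", str(exc)))
    return records


def write_prediction_table(record: PredictionRecord, path) -> None:
    """Per-residue TSV: index, residue, SS8, SS3, one posterior column per label."""
    with open(path, "w") as fh:
        header = ["index", "residue", "ss8", "ss3"] + [f"p_{s}" for s in record.label_alphabet]
        fh.write("\t".join(header) + "\n")
        for i, aa in enumerate(record.sequence):
            row = [str(i + 1), aa, record.ss8[i], record.ss3[i]]
            row += [f"{p:.6f}" for p in record.posterior[i]]
            fh.write("\t".join(row) + "\n")


def write_prediction_fasta(records: list[PredictionRecord], path, three_state: bool = False) -> None:
    """Horizontal FASTA-like file of predicted SS strings."""
    with open(path, "w") as fh:
        for r in records:
            if r.error:
                continue
            fh.write(f">{r.id}\n{r.ss3 if three_state else r.ss8}\n")
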