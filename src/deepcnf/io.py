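"""File formats: FASTA, PSI-BLAST ASCII PSSM, label strings, dataset manifests.

The package consumes the outputs of PSI-BLAST (the 20-column log-odds block of
its ASCII position-specific scoring matrix) and of DSSP (per-residue 8-state
label strings); it never runs either program.  Sequences are read with
Biopython; the PSSM and label formats are parsed here.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .alphabets import SS8_INDEX, normalize_ss8


class PssmParseError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM; the message names the offending line."""


@dataclass
class ProfileMatrix:
    """The log-odds block of a PSI-BLAST PSSM.

    ``values`` is L x 20 in the column order of the source file
    (``residue_order``); ``residues`` is the query sequence as printed in the
    per-row residue column, kept for cross-checking against the FASTA record.
    """

    values: np.ndarray
    residue_order: str
    residues: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {self.values.shape}")
        if self.values.shape[0] != len(self.residues):
            raise ValueError("profile row count != residue string length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite entries")


@dataclass
class LabeledSequence:
    """One supervised unit: a residue string with its 8-state label string."""

    id: str
    residues: str
    labels: str

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.labels):
            raise ValueError(
                f"{self.id}: residue length {len(self.residues)} != label length {len(self.labels)}"
            )
        bad = set(self.labels) - set(SS8_INDEX)
        if bad:
            raise ValueError(f"{self.id}: labels outside 8-state alphabet: {sorted(bad)}")


def _as_stream(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    if isinstance(source, str):
        return _stdio.StringIO(source)
    return source


def parse_pssm(source) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM, returning its first 20-column block.

    Accepts a path or an open text stream.  The file layout is: free-form
    header lines, a column-header line listing the 20 residue letters (once
    for the log-odds block, usually again for the frequency block), one row
    per query residue (index, residue letter, 20 log-odds integers, optional
    trailing columns), then trailing statistics which are ignored.
    """
    stream = _as_stream(source)
    close = isinstance(source, (str, Path))
    try:
        return _parse_pssm_lines(stream)
    finally:
        if close:
            stream.close()


def parse_pssm_text(text: str) -> ProfileMatrix:
    """Parse a PSSM held in a string."""
    return _parse_pssm_lines(_stdio.StringIO(text))


def _parse_pssm_lines(stream: TextIO) -> ProfileMatrix:
    residue_order: str | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if residue_order is None:
            # The column header is the first line of >= 20 single-letter tokens.
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                residue_order = "".join(tokens[:20])
            continue
        # Data rows start with the 1-based residue index.
        if not tokens[0].isdigit():
            break  # trailing statistics block
        if len(tokens) < 22:
            raise PssmParseError(f"line {lineno}: expected index, residue and 20 scores")
        idx = int(tokens[0])
        if idx != len(rows) + 1:
            raise PssmParseError(f"line {lineno}: residue index {idx}, expected {len(rows) + 1}")
        if len(tokens[1]) != 1 or not tokens[1].isalpha():
            raise PssmParseError(f"line {lineno}: bad residue column {tokens[1]!r}")
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise PssmParseError(f"line {lineno}: non-numeric score ({exc})") from None
        residues.append(tokens[1])
    if residue_order is None:
        raise PssmParseError("no PSSM column header found (empty or truncated file)")
    if not rows:
        raise PssmParseError("PSSM has a header but no residue rows")
    return ProfileMatrix(np.array(rows), residue_order, "".join(residues))


def write_pssm(profile: ProfileMatrix, path) -> None:
    """Write a profile back out in PSI-BLAST's ASCII layout.

    Scores are printed as integers when they are integral (PSI-BLAST's own
    dialect), else with full float precision so parse/write round-trips.
    """
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        letters = "  ".join(profile.residue_order)
        fh.write(f"            {letters}\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.values), start=1):
            cells = " ".join(
                f"{int(v):3d}" if float(v).is_integer() else repr(float(v)) for v in row
            )
            fh.write(f"{i:5d} {res}  {cells}\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3179\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record) FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_labels(path) -> list[tuple[str, str]]:
    """Read a label file of two-line records: '>id' then the 8-state string.

    DSSP coil dialects (blank, '-', 'C') are normalized to 'L'.
    """
    records: list[tuple[str, str]] = []
    rid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records.append((rid, normalize_ss8("".join(chunks))))
                rid = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            elif line.strip():
                chunks.append(line.strip())
    if rid is not None:
        records.append((rid, normalize_ss8("".join(chunks))))
    return records


def write_labels(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, labels in records:
            fh.write(f">{rid}\n{labels}\n")


@dataclass
class ManifestEntry:
    id: str
    fasta: Path
    pssm: Path
    labels: Path | None


def read_manifest(path) -> list[ManifestEntry]:
    """Read a tab-separated dataset manifest: id, fasta, pssm[, labels].

    Relative paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected id<TAB>fasta<TAB>pssm[<TAB>labels]")
            rid, fasta, pssm = parts[:3]
            labels = parts[3] if len(parts) > 3 and parts[3] else None
            entries.append(
                ManifestEntry(
                    rid,
                    base / fasta,
                    base / pssm,
                    base / labels if labels else None,
                )
            )
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path) -> None:
    base = Path(path).parent
    with open(path, "w") as fh:
        for e in entries:
            cols = [e.id, str(Path(e.fasta).relative_to(base)), str(Path(e.pssm).relative_to(base))]
            if e.labels is not None:
                cols.append(str(Path(e.labels).relative_to(base)))
            fh.write("\t".join(cols) + "\n")


def load_dataset(manifest_path):
    """Load a manifest into (LabeledSequence, ProfileMatrix) pairs.

    Entries without a label column get an all-'L' placeholder label string so
    prediction-only datasets flow through the same container.
    """
    out = []
    for entry in read_manifest(manifest_path):
        seqs = read_fasta(entry.fasta)
        if len(seqs) != 1:
            raise ValueError(f"{entry.fasta}: expected exactly one FASTA record")
        rid, seq = seqs[0]
        profile = parse_pssm(entry.pssm)
        if profile.values.shape[0] != len(seq):
            raise ValueError(
                f"{entry.id}: PSSM has {profile.values.shape[0]} rows, sequence length {len(seq)}"
            )
        if entry.labels is not None:
            labrecs = dict(read_labels(entry.labels))
            labels = labrecs.get(entry.id) or labrecs.get(rid)
            if labels is None:
                raise ValueError(f"{entry.id}: no matching record in {entry.labels}")
        else:
            labels = "L" * len(seq)
        out.append((LabeledSequence(entry.id, seq, labels), profile))
    return out
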