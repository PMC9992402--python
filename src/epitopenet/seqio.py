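"""Peptide sequence I/O and integer encoding.

Linear B-cell epitope candidates are short peptides (typically 11-25
residues) over the 20-letter amino-acid alphabet.  Before they can be fed
to an embedding layer they are mapped to fixed-length integer vectors:
each residue gets a code in 1..20 (alphabetical order, A=1 ... Y=20) and
the padding symbol 'X' gets code 0.  Sequences shorter than the
standardized length L are padded at the tail with code 0; sequences longer
than L are truncated to their first L residues (with a logged warning).

Labels never live inside FASTA headers: they arrive either as a per-file
label (paired positive/negative FASTA files) or as a two-column
``id<TAB>label`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("epitopenet")

#: Valid input residues, in code order (code = index + 1).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol; its code 0 never appears in valid *input* sequences.
PAD_CHAR = "X"
PAD_CODE = 0

#: residue -> integer code (A=1, C=2, ..., Y=20; X=0 reserved for padding).
AA_TO_CODE = {PAD_CHAR: PAD_CODE, **{aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}}
CODE_TO_AA = {code: aa for aa, code in AA_TO_CODE.items()}

DEFAULT_LENGTH = 25


class SequenceValidationError(ValueError):
    """An input sequence violates the 20-letter alphabet or is empty."""


class FastaParseError(ValueError):
    """A file could not be parsed as FASTA."""


@dataclass
class EpitopeRecord:
    """One identified peptide with an optional binary epitope label.

    label is 1 for a linear B-cell epitope (BCE), 0 for a non-BCE, or
    ``None`` when unknown (e.g. prediction input).
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        validate_sequence(self.sequence, record_id=self.id)
        if self.label is not None and self.label not in (0, 1):
            raise SequenceValidationError(
                f"record {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )


def validate_sequence(seq: str, record_id: str = "<sequence>") -> None:
    """Raise :class:`SequenceValidationError` unless *seq* is a non-empty
    string over the 20-letter amino-acid alphabet (B, J, O, U, Z and the
    padding symbol X are rejected in input)."""
    if not seq:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise SequenceValidationError(
                f"Format Error: record {record_id!r} contains illegal character "
                f"{ch!r}; sequences must consist of characters in "
                f"{AMINO_ACIDS!r}"
            )


@dataclass
class EncodedBatch:
    """Fixed-length integer encoding of a batch of peptides.

    ``codes`` is an n x L integer matrix with entries in [0, 20]; code 0
    only ever appears as a contiguous suffix of a row (tail padding).
    """

    codes: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("row count must equal id count")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > 20:
            raise ValueError("codes must lie in [0, 20]")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]


def read_fasta(path: str | Path, label: Optional[int] = None) -> list[EpitopeRecord]:
    """Read peptides from a FASTA file, optionally attaching one label to all.

    Multi-line sequences are allowed; the description after the first
    whitespace of a header is ignored.  Duplicate ids, empty sequences and
    characters outside the 20-letter alphabet raise errors naming the
    offending record.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not a FASTA file (no '>' header)")
    records: list[EpitopeRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise FastaParseError(f"{path}: FASTA entry with empty header")
        if rid in seen:
            raise SequenceValidationError(
                f"duplicate record id {rid!r} in {path}"
            )
        seen.add(rid)
        records.append(EpitopeRecord(id=rid, sequence=str(entry.seq), label=label))
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def write_fasta(records: Iterable[EpitopeRecord], path: str | Path) -> None:
    """Write records as plain two-line FASTA entries."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` table (no header)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
        rid, lab = parts[0].strip(), parts[1].strip()
        if lab not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
        if rid in labels:
            raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
        labels[rid] = int(lab)
    return labels


def attach_labels(records: Sequence[EpitopeRecord], labels: dict[str, int]) -> list[EpitopeRecord]:
    """Return records with labels looked up by id (all ids must be present)."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise KeyError(f"no label for record {rec.id!r}")
        out.append(EpitopeRecord(id=rec.id, sequence=rec.sequence, label=labels[rec.id]))
    return out


def encode_sequence(seq: str, L: int = DEFAULT_LENGTH) -> np.ndarray:
    """Integer-encode one peptide to a fixed-length vector.

    Position i holds the code of residue i; positions past the sequence
    end hold the padding code 0.  Sequences longer than L keep only their
    first L residues (a warning is logged: the benchmark data this length
    standardization was designed for never exceeds 25 residues).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    seq = seq.upper()
    validate_sequence(seq)
    if len(seq) > L:
        logger.warning(
            "sequence of length %d truncated to first %d residues", len(seq), L
        )
        seq = seq[:L]
    vec = np.zeros(L, dtype=np.int64)
    for i, ch in enumerate(seq):
        vec[i] = AA_TO_CODE[ch]
    return vec


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` on the unpadded prefix."""
    out = []
    for code in np.asarray(codes).ravel():
        if code == PAD_CODE:
            break
        out.append(CODE_TO_AA[int(code)])
    return "".join(out)


def encode_batch(
    records: Sequence[EpitopeRecord], L: int = DEFAULT_LENGTH
) -> tuple[EncodedBatch, Optional[np.ndarray]]:
    """Encode records to an :class:`EncodedBatch` plus an aligned label vector.

    The label vector is returned only when every record carries a label;
    row order always equals input record order.
    """
    if not records:
        raise ValueError("records must be non-empty")
    codes = np.stack([encode_sequence(rec.sequence, L) for rec in records])
    batch = EncodedBatch(codes=codes, ids=[rec.id for rec in records])
    if all(rec.label is not None for rec in records):
        labels = np.array([rec.label for rec in records], dtype=np.int64)
    else:
        labels = None
    return batch, labels


def write_predictions(
    records: Sequence[EpitopeRecord],
    probabilities: Sequence[float],
    threshold: float,
    path: str | Path,
) -> None:
    """Write a tab-separated prediction table: id, sequence, probability, call.

    A peptide is called "BCE" when its probability is >= threshold (ties at
    the threshold go positive); row order preserves input order.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if len(probabilities) != len(records):
        raise ValueError(
            f"{len(records)} records but {len(probabilities)} probabilities"
        )
    if len(probabilities) and (probabilities.min() < 0 or probabilities.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with Path(path).open("w") as fh:
        fh.write("id\tsequence\tprobability\tcall\n")
        for rec, p in zip(records, probabilities):
            call = "BCE" if p >= threshold else "non-BCE"
            fh.write(f"{rec.id}\t{rec.sequence}\t{p:.6f}\t{call}\n")
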