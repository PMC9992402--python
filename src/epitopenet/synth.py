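"""Synthetic labelled peptide datasets with a plantable class signal.

The generator emulates the shape of curated linear-epitope benchmarks:
balanced positive/negative peptide sets with lengths distributed in
[11, 25] over a uniform residue background.  Class signal is injected by
overwriting a window of the background sequence with a fixed motif in a
controllable fraction of positives ("penetrance") and negatives
("contamination"); overwriting rather than inserting keeps the length
distribution exact.  Exact motif counts are enforced by choosing which
records carry the motif (round-half-up of penetrance*n), not by
per-record coin flips, so substring counts are deterministic for every
seed.

This is NOT a biophysically realistic epitope simulator — there is no
antigen context and no structural signal; it exists so that every stage of
the pipeline is exercisable and learnable without external downloads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    EpitopeRecord,
    validate_sequence,
    write_fasta,
)

logger = logging.getLogger("epitopenet")

DEFAULT_MOTIF = "CWKHY"


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset."""

    n_pos: int = 400
    n_neg: int = 400
    length_range: tuple[int, int] = (11, 25)
    motif: str = DEFAULT_MOTIF
    penetrance: float = 1.0
    contamination: float = 0.0
    background: Optional[Sequence[float]] = None  # default: uniform over 20 AAs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        validate_sequence(self.motif.upper(), record_id="<motif>")
        self.motif = self.motif.upper()
        if len(self.motif) > lo:
            raise ValueError("motif must fit within the shortest sequence")
        if not (0 <= self.contamination <= self.penetrance <= 1):
            raise ValueError("require 0 <= contamination <= penetrance <= 1")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or bg.min() < 0 or not math.isclose(bg.sum(), 1.0):
                raise ValueError("background must be a probability vector over 20 residues")
            self.background = tuple(bg)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _background_seq(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=bg)
    return "".join(AMINO_ACIDS[c] for c in codes)


def generate(spec: SynthSpec) -> list[EpitopeRecord]:
    """Generate labelled records; deterministic given ``spec.seed``.

    Exactly round(penetrance * n_pos) positives and
    round(contamination * n_neg) negatives contain the motif as a
    substring (planted at a uniformly random valid offset); all other
    records are guaranteed motif-free (background draws that contain the
    motif by chance are redrawn).
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(
        spec.background if spec.background is not None else np.full(20, 1 / 20)
    )
    lo, hi = spec.length_range

    def make_group(n: int, n_carriers: int, label: int, prefix: str) -> list[EpitopeRecord]:
        carriers = np.zeros(n, dtype=bool)
        if n:
            carriers[rng.choice(n, size=n_carriers, replace=False)] = True
        records = []
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            seq = _background_seq(rng, length, bg)
            if carriers[i]:
                offset = int(rng.integers(0, length - len(spec.motif) + 1))
                seq = seq[:offset] + spec.motif + seq[offset + len(spec.motif):]
            else:
                while spec.motif in seq:  # keep non-carriers exactly motif-free
                    seq = _background_seq(rng, length, bg)
            records.append(
                EpitopeRecord(id=f"{prefix}{i + 1}", sequence=seq, label=label)
            )
        return records

    positives = make_group(
        spec.n_pos, _round_half_up(spec.penetrance * spec.n_pos), 1, "pos"
    )
    negatives = make_group(
        spec.n_neg, _round_half_up(spec.contamination * spec.n_neg), 0, "neg"
    )
    return positives + negatives


def generate_length_stats(records: Sequence[EpitopeRecord]) -> tuple[int, float, int]:
    """(min, mean, max) of the sequence lengths of non-empty *records*."""
    if not records:
        raise ValueError("records must be non-empty")
    lengths = [len(rec.sequence) for rec in records]
    return min(lengths), float(np.mean(lengths)), max(lengths)


def write_dataset(records: Sequence[EpitopeRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write paired positive/negative FASTA files plus an id->label TSV.

    These are exactly the formats the sequence-I/O layer consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    paths = {
        "positives": out_dir / "positives.fasta",
        "negatives": out_dir / "negatives.fasta",
        "labels": out_dir / "labels.tsv",
    }
    write_fasta(pos, paths["positives"])
    write_fasta(neg, paths["negatives"])
    with paths["labels"].open("w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")
    return paths
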