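"""Reading, validation and assembly of labelled fixed-length RNA sequence windows.

The predictors in this package operate on fixed-length windows (41 nt by
default) centred on a candidate modification site.  Benchmark collections for
m6A/m5C site prediction ship as paired FASTA files — one file of windows
around experimentally verified sites (positives) and one of windows around
unmodified sites of the same nucleotide (negatives).  This module reads such
files, normalizes the alphabet (DNA-style ``T`` to ``U``, lowercase to
uppercase) and assembles a :class:`LabelledDataset` with +1/−1 labels.

Positions are reported 1-based inclusive in all user-facing output (so the
central adenosine of a 41-nt window sits at position 21); internally Python's
0-based indexing is used throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
_ALLOWED = frozenset(RNA_ALPHABET)


class FastaFormatError(ValueError):
    """Raised when a file cannot be parsed as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when sequences violate the dataset contract (length/alphabet)."""


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA window: identifier plus residues over {A, C, G, U}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class LabelledDataset:
    """Fixed-length sequence windows with binary site labels (+1 modified, −1 not)."""

    sequences: list[RnaSequence]
    labels: np.ndarray  # int array of +1 / −1, parallel to `sequences`
    window_length: int
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise SequenceValidationError(
                f"{self.name}: {len(self.sequences)} sequences but "
                f"{len(self.labels)} labels"
            )
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise SequenceValidationError(f"{self.name}: labels must be ±1, got {bad}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.labels == -1))

    def subset(self, indices: Iterable[int], name: str | None = None) -> "LabelledDataset":
        idx = list(indices)
        return LabelledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            window_length=self.window_length,
            name=name or self.name,
        )


def normalize_residues(raw: str) -> str:
    """Uppercase and map DNA-style T to U.  Does not validate the alphabet."""
    return raw.upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file into normalized :class:`RnaSequence` records.

    ``T`` is accepted and mapped to ``U`` (public benchmarks are distributed in
    the DNA alphabet); lowercase is uppercased.  Record order is preserved.

    Raises
    ------
    FastaFormatError
        If the file is empty or text precedes the first header line (the
        offending line number is named).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    stripped_lines = text.splitlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(stripped_lines, start=1) if ln.strip()), None
    )
    if first_content is None:
        raise FastaFormatError(f"{path}: empty FASTA file")
    line_no, line = first_content
    if not line.lstrip().startswith(">"):
        raise FastaFormatError(
            f"{path}: line {line_no} is not a FASTA header (expected '>'): {line[:40]!r}"
        )
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(RnaSequence(id=rec.id, residues=normalize_residues(str(rec.seq))))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Sequence[RnaSequence], path: str | Path) -> None:
    """Write records as single-line FASTA (deterministic byte layout)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def validate_sequences(
    sequences: Sequence[RnaSequence], window_length: int, source: str = "input"
) -> None:
    """Check length and alphabet of every record; report all offenders at once.

    Ambiguity codes (N, Y, R, ...) are rejected rather than silently encoded:
    the propensity encoder has no slot for ambiguous k-mers and curated
    benchmark windows contain none.
    """
    wrong_length = [s.id for s in sequences if s.length != window_length]
    bad_alphabet = [s.id for s in sequences if not _ALLOWED.issuperset(s.residues)]
    problems = []
    if wrong_length:
        problems.append(
            f"wrong length (expected {window_length} nt): {', '.join(wrong_length[:10])}"
            + (" ..." if len(wrong_length) > 10 else "")
        )
    if bad_alphabet:
        problems.append(
            "non-ACGU characters after normalization: "
            + ", ".join(bad_alphabet[:10])
            + (" ..." if len(bad_alphabet) > 10 else "")
        )
    if problems:
        raise SequenceValidationError(f"{source}: " + "; ".join(problems))


def load_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    window_length: int,
    name: str = "dataset",
) -> LabelledDataset:
    """Assemble a labelled dataset from paired positive/negative FASTA files.

    Positives are labelled +1, negatives −1; every sequence is validated
    against ``window_length`` and the {A,C,G,U} alphabet.
    """
    positives = read_fasta(pos_path)
    negatives = read_fasta(neg_path)
    validate_sequences(positives, window_length, source=str(pos_path))
    validate_sequences(negatives, window_length, source=str(neg_path))
    sequences = positives + negatives
    labels = np.concatenate(
        [np.ones(len(positives), dtype=int), -np.ones(len(negatives), dtype=int)]
    )
    return LabelledDataset(
        sequences=sequences, labels=labels, window_length=window_length, name=name
    )
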