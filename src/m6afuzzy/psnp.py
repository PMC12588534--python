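"""Position-specific k-mer propensity (PSNP / PSTNP) encoding.

An L-nt window contains L − k + 1 overlapping k-mers, one starting at each
position.  From a labelled training split we tabulate, separately for the
positive and the negative class, the relative frequency F±(m, j) of k-mer m
starting at position j.  The propensity score of a k-mer at a position is the
difference of the two class frequencies,

    score(m, j) = F⁺(m, j) − F⁻(m, j),

and a sequence is encoded by looking up the propensity of each of its own
k-mers at its own position, giving a (L − k + 1)-dimensional feature vector —
37 features for the canonical 41-nt window with k = 5.  A positives-only
variant (score = F⁺ alone) is available via ``mode="positive"``.

The table is a pure function of the training split; encoding is a pure
lookup.  Per position, each class's frequency column sums to 1, so each
difference column sums to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .sequence_io import LabelledDataset, RnaSequence

_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

PROPENSITY_MODES = ("difference", "positive")


def kmer_to_row(kmer: str) -> int:
    """Lexicographic (A<C<G<U) row index of a k-mer, i.e. its base-4 value."""
    idx = 0
    for ch in kmer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def row_to_kmer(row: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[row % 4])
        row //= 4
    return "".join(reversed(out))


def _residue_codes(sequences: list[RnaSequence]) -> np.ndarray:
    """(N, L) integer codes; assumes validated ACGU sequences of equal length."""
    lookup = np.full(128, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lookup[ord(b)] = i
    arr = np.frombuffer(
        "".join(s.residues for s in sequences).encode("ascii"), dtype=np.uint8
    )
    codes = lookup[arr]
    if np.any(codes < 0):
        bad = sorted({chr(c) for c in arr[codes < 0]})
        raise ValueError(f"non-ACGU residues in input: {bad}")
    return codes.reshape(len(sequences), -1)


def _kmer_ids(codes: np.ndarray, k: int) -> np.ndarray:
    """(N, L−k+1) base-4 k-mer ids from per-residue codes."""
    powers = 4 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
    return windows @ powers


@dataclass
class PropensityTable:
    """Per-position k-mer propensity lookup of shape (4^k, L − k + 1)."""

    k: int
    window_length: int
    scores: np.ndarray
    mode: str = "difference"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        expected = (4**self.k, self.window_length - self.k + 1)
        if self.scores.shape != expected:
            raise ValueError(
                f"propensity table shape {self.scores.shape}, expected {expected}"
            )

    @property
    def n_features(self) -> int:
        return self.window_length - self.k + 1

    def kmer_index(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        return kmer_to_row(kmer)

    def score(self, kmer: str, position: int) -> float:
        """Propensity of `kmer` starting at 1-based window position `position`."""
        return float(self.scores[self.kmer_index(kmer), position - 1])


@dataclass
class FeatureMatrix:
    """Encoded dataset: N × d real matrix with parallel sequence ids."""

    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match matrix rows")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def class_frequencies(
    sequences: list[RnaSequence], k: int, window_length: int, pseudocount: float = 0.0
) -> np.ndarray:
    """(4^k, L−k+1) per-position relative k-mer frequencies within one class.

    With additive pseudocount α the column normaliser becomes n + α·4^k, so
    every column still sums to exactly 1.
    """
    d = window_length - k + 1
    counts = np.zeros((4**k, d), dtype=float)
    if sequences:
        ids = _kmer_ids(_residue_codes(sequences), k)
        for j in range(d):
            np.add.at(counts[:, j], ids[:, j], 1.0)
    n = len(sequences)
    return (counts + pseudocount) / (n + pseudocount * 4**k)


def build_propensity(
    train: LabelledDataset,
    k: int = 5,
    mode: str = "difference",
    pseudocount: float = 0.0,
) -> PropensityTable:
    """Build the propensity table from a *training* split only.

    Raises if either class is empty or ``k`` exceeds the window length.  An
    unseen k-mer at a position scores 0 by default (no pseudocount), so two
    classes with identical sequence multisets produce an all-zero table.
    """
    if mode not in PROPENSITY_MODES:
        raise ValueError(f"mode must be one of {PROPENSITY_MODES}, got {mode!r}")
    if k > train.window_length:
        raise ValueError(
            f"k={k} exceeds window length {train.window_length}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    pos = [s for s, y in zip(train.sequences, train.labels) if y == 1]
    neg = [s for s, y in zip(train.sequences, train.labels) if y == -1]
    if not pos or not neg:
        raise ValueError(
            f"{train.name}: both classes must be non-empty to build a propensity "
            f"table (got {len(pos)} positive, {len(neg)} negative)"
        )
    f_pos = class_frequencies(pos, k, train.window_length, pseudocount)
    if mode == "difference":
        f_neg = class_frequencies(neg, k, train.window_length, pseudocount)
        scores = f_pos - f_neg
    else:
        scores = f_pos
    return PropensityTable(
        k=k, window_length=train.window_length, scores=scores, mode=mode
    )


def encode(seq: RnaSequence, table: PropensityTable) -> np.ndarray:
    """Encode one window as its per-position propensity vector (length L−k+1)."""
    if seq.length != table.window_length:
        raise ValueError(
            f"sequence {seq.id!r} has length {seq.length}, "
            f"table expects {table.window_length}"
        )
    ids = _kmer_ids(_residue_codes([seq]), table.k)[0]
    return table.scores[ids, np.arange(table.n_features)]


def encode_dataset(ds: LabelledDataset, table: PropensityTable) -> FeatureMatrix:
    """Row-wise :func:`encode` of a whole dataset; row order preserved."""
    if not ds.sequences:
        return FeatureMatrix(
            values=np.zeros((0, table.n_features)), row_ids=[]
        )
    for s in ds.sequences:
        if s.length != table.window_length:
            raise ValueError(
                f"sequence {s.id!r} has length {s.length}, "
                f"table expects {table.window_length}"
            )
    ids = _kmer_ids(_residue_codes(ds.sequences), table.k)
    values = table.scores[ids, np.arange(table.n_features)[None, :]]
    return FeatureMatrix(values=values, row_ids=[s.id for s in ds.sequences])


def table_to_tsv(table: PropensityTable, path: str | Path) -> None:
    """Serialize a table as TSV: rows = k-mers lexicographic, columns = positions."""
    d = table.n_features
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("kmer\t" + "\t".join(str(j) for j in range(1, d + 1)) + "\n")
        for row, kmer in enumerate("".join(t) for t in product(_BASES, repeat=table.k)):
            fh.write(
                kmer + "\t" + "\t".join(repr(float(v)) for v in table.scores[row]) + "\n"
            )


def table_from_tsv(
    path: str | Path, window_length: int | None = None, mode: str = "difference"
) -> PropensityTable:
    """Inverse of :func:`table_to_tsv` (bit-exact via repr round-trip)."""
    with open(Path(path), "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        d = len(header) - 1
        rows = []
        k = None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if k is None:
                k = len(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if k is None:
        raise ValueError(f"{path}: empty propensity table")
    scores = np.asarray(rows, dtype=float)
    L = window_length if window_length is not None else d + k - 1
    return PropensityTable(k=k, window_length=L, scores=scores, mode=mode)
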