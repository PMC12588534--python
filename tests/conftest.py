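"""Shared fixtures: tiny deterministic datasets and FASTA writers."""

from __future__ import annotations

import numpy as np
import pytest

from m6afuzzy import (
    LabelledDataset,
    MotifDatasetSpec,
    RnaSequence,
    gen_motif_dataset,
)


def make_dataset(pos_seqs, neg_seqs, window_length, name="toy"):
    sequences = [
        RnaSequence(id=f"pos{i}", residues=s) for i, s in enumerate(pos_seqs)
    ] + [RnaSequence(id=f"neg{i}", residues=s) for i, s in enumerate(neg_seqs)]
    labels = np.concatenate(
        [np.ones(len(pos_seqs), dtype=int), -np.ones(len(neg_seqs), dtype=int)]
    )
    return LabelledDataset(
        sequences=sequences, labels=labels, window_length=window_length, name=name
    )


@pytest.fixture
def toy_dataset():
    """L=7 two-sequence dataset from which k=3 propensities are hand-countable."""
    return make_dataset(["GGACAUU"], ["AAUAAAA"], window_length=7)


@pytest.fixture
def small_motif_dataset():
    """A compact motif dataset for pipeline-level tests."""
    spec = MotifDatasetSpec(n_pos=60, n_neg=60, seed=7, motif_fidelity=1.0)
    return gen_motif_dataset(spec)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
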