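"""Amino-acid k-mer frequency features for protein sequences.

Each protein sequence is summarised as a vector of sliding-window k-mer
counts over the 20-letter standard amino-acid alphabet, normalised by the
full sequence length.  With the default ``k = 3`` this yields exactly
20**3 = 8000 features per protein, which is the representation the rest of
the pipeline (per-term classification, bagging, ensembling) consumes.

The canonical in-memory container for a feature matrix is a
:class:`pandas.DataFrame` whose index holds the protein identifiers and
whose columns are all length-k strings over the alphabet in lexicographic
order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered.
STANDARD_AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residue letters that occur in real sequence databases but are not part of
#: the standard 20-letter alphabet (ambiguity codes and rare residues).
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BJOUXZ*")

NONSTANDARD_POLICIES = ("drop-kmer", "map-to-X-and-drop", "error")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with a unique identifier and its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class FeaturizerConfig:
    """Configuration of the k-mer featurizer.

    Parameters
    ----------
    k
        k-mer length (window size).  Default 3.
    alphabet
        Ordered residue alphabet; defaults to the 20 standard amino acids.
    nonstandard_policy
        How to treat sliding windows containing a letter outside the
        alphabet: ``"drop-kmer"`` (default) silently skips those windows so
        the feature space stays exactly ``len(alphabet)**k``;
        ``"map-to-X-and-drop"`` first maps known nonstandard residues to X
        and then drops windows containing X; ``"error"`` raises on the
        first nonstandard letter.
    normalize_by_full_length
        When True (default) k-mer counts are divided by the full sequence
        length L; when False by the number of windows L - k + 1.
    """

    k: int = 3
    alphabet: tuple[str, ...] = STANDARD_AMINO_ACIDS
    nonstandard_policy: str = "drop-kmer"
    normalize_by_full_length: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate letters")
        if any(len(a) != 1 for a in self.alphabet):
            raise ValueError("alphabet entries must be single letters")
        if self.nonstandard_policy not in NONSTANDARD_POLICIES:
            raise ValueError(
                f"nonstandard_policy must be one of {NONSTANDARD_POLICIES}, "
                f"got {self.nonstandard_policy!r}"
            )


def enumerate_kmers(config: FeaturizerConfig = FeaturizerConfig()) -> list[str]:
    """Return every length-k string over the alphabet, lexicographically.

    The order is deterministic and is the frozen column order used by all
    feature matrices downstream.
    """
    alphabet = sorted(config.alphabet)
    return ["".join(p) for p in itertools.product(alphabet, repeat=config.k)]


def _standardize(sequence: str, config: FeaturizerConfig) -> str:
    seq = sequence.upper()
    if config.nonstandard_policy == "map-to-X-and-drop":
        table = str.maketrans({c: "X" for c in NONSTANDARD_RESIDUES if c != "X"})
        seq = seq.translate(table)
    return seq


def count_kmers(record: ProteinRecord, config: FeaturizerConfig = FeaturizerConfig()) -> dict[str, int]:
    """Count sliding-window k-mers of ``record.sequence``.

    Returns a sparse mapping (absent k-mers have count zero).  Windows
    containing a letter outside the alphabet are handled according to
    ``config.nonstandard_policy``.  A sequence shorter than k yields no
    windows; a warning is logged and all counts are zero.
    """
    seq = _standardize(record.sequence, config)
    k = config.k
    alpha = set(config.alphabet)
    if len(seq) < k:
        logger.warning(
            "sequence %s shorter than k=%d (length %d); all k-mer counts zero",
            record.id, k, len(seq),
        )
        return {}
    if config.nonstandard_policy == "error":
        for pos, letter in enumerate(seq):
            if letter not in alpha:
                raise ValueError(
                    f"protein {record.id!r}: nonstandard letter {letter!r} "
                    f"at position {pos + 1}"
                )
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if all(c in alpha for c in window):
            counts[window] = counts.get(window, 0) + 1
    return counts


def featurize(
    records: Sequence[ProteinRecord],
    config: FeaturizerConfig = FeaturizerConfig(),
) -> pd.DataFrame:
    """Build the proteins x k-mers normalized frequency matrix.

    Each row is the k-mer count vector of one protein divided by its full
    sequence length L (the window count L - k + 1 is available via
    ``normalize_by_full_length=False``).  Row order follows the input
    order; column order is the frozen lexicographic k-mer order.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate protein ids: {dups}")
    kmers = enumerate_kmers(config)
    col_index = {kmer: j for j, kmer in enumerate(kmers)}
    values = np.zeros((len(records), len(kmers)), dtype=float)
    for i, record in enumerate(records):
        counts = count_kmers(record, config)
        if config.normalize_by_full_length:
            denom = len(record.sequence)
        else:
            denom = max(len(record.sequence) - config.k + 1, 1)
        for kmer, count in counts.items():
            values[i, col_index[kmer]] = count / denom
    return pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=kmers)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    The token before the first whitespace in each header is the protein id.
    """
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def write_feature_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialize a feature matrix as TSV (first column ``protein_id``)."""
    matrix.to_csv(path, sep="\t", index_label="protein_id")


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix TSV written by :func:`write_feature_tsv`."""
    return pd.read_csv(path, sep="\t", index_col="protein_id")
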