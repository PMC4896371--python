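"""Core domain types shared across the toolkit.

Coordinates are 1-based inclusive everywhere user-facing, matching EMBL
feature tables and Artemis. Internal numpy arrays are 0-based; the offset
never leaks across module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequencedRead:
    """A single sequencing read with Phred (integer) base qualities."""

    read_id: str
    bases: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Replicon:
    """One independently replicating reference element (chromosome or plasmid)."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.name!r}: empty sequence")


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature (CDS/tRNA/rRNA), 1-based inclusive coordinates."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: Optional[str] = None
    feature_type: str = "CDS"
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.gene_id!r}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AlignmentRecord:
    """Outcome of mapping one read: one record per input read, mapped or not."""

    read_id: str
    replicon: str = "*"
    pos: int = 0  # 1-based leftmost mapped coordinate
    strand: str = "+"
    aligned_length: int = 0
    mapq: int = 0
    is_unique: bool = False
    is_mapped: bool = False


@dataclass
class InsertionPlot:
    """Per-base insertion read counts for one replicon (forward and reverse).

    ``forward[i]`` / ``reverse[i]`` hold the count at 1-based position i+1.
    """

    replicon: str
    forward: np.ndarray
    reverse: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.int64)
        self.reverse = np.asarray(self.reverse, dtype=np.int64)
        if self.forward.shape != self.reverse.shape or self.forward.ndim != 1:
            raise ValueError("forward/reverse arrays must be 1-D and equally long")
        if (self.forward < 0).any() or (self.reverse < 0).any():
            raise ValueError("insertion counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.forward.shape[0])

    @classmethod
    def zeros(cls, replicon: str, length: int) -> "InsertionPlot":
        return cls(replicon, np.zeros(length, dtype=np.int64), np.zeros(length, dtype=np.int64))

    def combined(self) -> np.ndarray:
        return self.forward + self.reverse


@dataclass(frozen=True)
class InsertionSiteSummary:
    """Genome-wide insertion summary for one replicon."""

    replicon: str
    n_sites: int
    total_reads: int


@dataclass
class GeneInsertionStats:
    """Per-gene insertion statistics, the row of the gene-stats table."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    read_count: int
    insertion_count: int
    gene_length: int
    gene_name: Optional[str] = None
    feature_type: str = "CDS"
    product: Optional[str] = None

    @property
    def insertion_index(self) -> float:
        return self.insertion_count / self.gene_length
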