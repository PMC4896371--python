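"""Read mapping under the toolkit's mapping contract.

The built-in mapper is a deterministic seed-and-extend, ungapped aligner:
sampled k-mer seeds from the read locate candidate positions in a full
k-mer index of the reference; each candidate placement is scored by
ungapped identity over the whole read on both strands. TraDIS insertion
calling needs only the junction coordinate, so indel-free alignment is
sufficient at desk scale and keeps the exhaustive-scan oracle exact.

A read maps iff its best placement reaches ``min_identity``; it is unique
iff the best identity strictly beats the second best. Ties are resolved to
the lexicographically smallest (replicon name, position, strand) and
flagged non-unique. The built-in mapper synthesizes MAPQ 60 for unique
placements and 0 otherwise.

An adapter hook lets users substitute an external short-read mapper; when
the executable is missing the pipeline degrades gracefully to the built-in
mapper.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core import AlignmentRecord, Replicon, SequencedRead, revcomp

logger = logging.getLogger(__name__)

MIN_MAPPABLE_READ_LENGTH = 20


@dataclass(frozen=True)
class MappingParams:
    """Seed length, seed stride, identity cutoff and uniqueness MAPQ gate."""

    kmer: int
    step: int
    min_identity: float = 0.96
    mapq_unique_threshold: int = 30

    def __post_init__(self) -> None:
        if not 1 <= self.step <= self.kmer:
            raise ValueError("require 1 <= step <= kmer")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


def default_params(read_length: int) -> MappingParams:
    """Length-banded default mapping parameters.

    <70 nt: kmer 13 step 2; 70-99 nt: kmer 13 step 4; >=100 nt: kmer 20
    step 4; identity 0.96 throughout. With these bands a read carrying no
    more mismatches than the identity cutoff allows always retains at least
    one clean seed, so the seeded search is exact (see docs/methods.md).
    """
    if read_length < MIN_MAPPABLE_READ_LENGTH:
        raise ValueError(
            f"read length {read_length} < {MIN_MAPPABLE_READ_LENGTH}: too short to map reliably"
        )
    if read_length < 70:
        return MappingParams(kmer=13, step=2)
    if read_length < 100:
        return MappingParams(kmer=13, step=4)
    return MappingParams(kmer=20, step=4)


class GenomeIndex:
    """Exhaustive forward-strand k-mer index over a multi-replicon genome."""

    def __init__(self, replicons: Sequence[Replicon], kmer: int):
        if not replicons:
            raise ValueError("genome is empty")
        self.replicons = list(replicons)
        self.kmer = kmer
        self.by_name: Dict[str, Replicon] = {r.name: r for r in replicons}
        self._index: Dict[str, List[Tuple[int, int]]] = {}
        for ri, rep in enumerate(self.replicons):
            seq = rep.sequence
            for p in range(rep.length - kmer + 1):
                self._index.setdefault(seq[p : p + kmer], []).append((ri, p))

    def candidates(self, kmer_seq: str) -> List[Tuple[int, int]]:
        return self._index.get(kmer_seq, ())


def _seed_offsets(read_len: int, kmer: int, step: int) -> List[int]:
    offsets = list(range(0, read_len - kmer + 1, step))
    last = read_len - kmer
    if offsets and offsets[-1] != last:
        offsets.append(last)
    return offsets


def _identity(query: str, target: str) -> float:
    # 'N' never matches an ACGT reference base.
    return sum(a == b for a, b in zip(query, target)) / len(query)


def map_read(read: SequencedRead, index: GenomeIndex, params: MappingParams) -> AlignmentRecord:
    """Map a single trimmed read; always returns exactly one record."""
    L = len(read.bases)
    if L < params.kmer:
        return AlignmentRecord(read_id=read.read_id, is_mapped=False)

    queries = {"+": read.bases, "-": revcomp(read.bases)}
    # candidate placements keyed by (replicon_idx, start0, strand)
    candidates = set()
    for strand, query in queries.items():
        for off in _seed_offsets(L, params.kmer, params.step):
            for ri, p in index.candidates(query[off : off + params.kmer]):
                start = p - off
                if start >= 0 and start + L <= index.replicons[ri].length:
                    candidates.add((ri, start, strand))

    best_ident = -1.0
    best: List[Tuple[str, int, str]] = []  # (replicon name, pos0, strand), ident-tied
    for ri, start, strand in candidates:
        ident = _identity(queries[strand], index.replicons[ri].sequence[start : start + L])
        if ident > best_ident:
            best_ident = ident
            best = [(index.replicons[ri].name, start, strand)]
        elif ident == best_ident:
            best.append((index.replicons[ri].name, start, strand))

    if best_ident < params.min_identity:
        return AlignmentRecord(read_id=read.read_id, is_mapped=False)
    unique = len(best) == 1
    name, start, strand = min(best)
    return AlignmentRecord(
        read_id=read.read_id,
        replicon=name,
        pos=start + 1,
        strand=strand,
        aligned_length=L,
        mapq=60 if unique else 0,
        is_unique=unique,
        is_mapped=True,
    )


def map_reads(
    reads: Iterable[SequencedRead],
    genome: Sequence[Replicon],
    params: Optional[MappingParams] = None,
    index: Optional[GenomeIndex] = None,
) -> Iterator[AlignmentRecord]:
    """Map trimmed reads against the reference; one record per read.

    ``params`` defaults to the length band of the first read encountered.
    """
    reads = iter(reads)
    try:
        first = next(reads)
    except StopIteration:
        return
    if params is None:
        params = default_params(len(first.bases))
    if index is None:
        index = GenomeIndex(genome, params.kmer)
    yield map_read(first, index, params)
    for read in reads:
        yield map_read(read, index, params)


def retained(records: Iterable[AlignmentRecord], params: MappingParams) -> Iterator[AlignmentRecord]:
    """The alignments that proceed to insertion plotting: mapped, unique,
    and at or above the uniqueness MAPQ gate."""
    for rec in records:
        if rec.is_mapped and rec.is_unique and rec.mapq >= params.mapq_unique_threshold:
            yield rec


# ---------------------------------------------------------------------------
# Brute-force reference scan (oracle for validating the seeded mapper)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def exhaustive_map_read(
    read: SequencedRead, genome: Sequence[Replicon], params: MappingParams
) -> AlignmentRecord:
    """Exhaustive all-positions, both-strands ungapped identity scan.

    Independent reference implementation of the mapping contract: every
    placement of the read inside every replicon is scored by Hamming
    identity, with the same acceptance, uniqueness and tie-break rules as
    the seeded mapper. Quadratic — for validation at desk scale only.
    """
    L = len(read.bases)
    if L < params.kmer:
        return AlignmentRecord(read_id=read.read_id, is_mapped=False)
    queries = {"+": _encode(read.bases), "-": _encode(revcomp(read.bases))}
    best_ident = -1.0
    best: List[Tuple[str, int, str]] = []
    for rep in genome:
        if rep.length < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(_encode(rep.sequence), L)
        for strand, q in queries.items():
            matches = (windows == q).sum(axis=1)
            ident_row = matches / L
            m = float(ident_row.max())
            if m > best_ident:
                best_ident = m
                best = []
            if m == best_ident:
                for start in np.nonzero(ident_row == m)[0]:
                    best.append((rep.name, int(start), strand))
    if best_ident < params.min_identity:
        return AlignmentRecord(read_id=read.read_id, is_mapped=False)
    unique = len(best) == 1
    name, start, strand = min(best)
    return AlignmentRecord(
        read_id=read.read_id,
        replicon=name,
        pos=start + 1,
        strand=strand,
        aligned_length=L,
        mapq=60 if unique else 0,
        is_unique=unique,
        is_mapped=True,
    )


# ---------------------------------------------------------------------------
# External mapper adapter


def external_mapper_adapter(
    reads_path: str,
    genome_path: str,
    out_sam_path: str,
    params: MappingParams,
    command_template: Optional[Sequence[str]] = None,
    executable: str = "smalt",
) -> Optional[str]:
    """Run an external short-read mapper, producing SAM readable by this
    toolkit.

    ``command_template`` is a list of argv items in which ``{ref}``,
    ``{reads}`` and ``{out}`` are substituted. Returns the SAM path, or
    ``None`` when the executable is absent (callers then fall back to the
    built-in mapper). A nonzero exit is a hard error carrying the tool's
    stderr.
    """
    if command_template is None:
        command_template = [executable, "map", "-f", "sam", "-o", "{out}", "{ref}", "{reads}"]
    prog = command_template[0]
    if shutil.which(prog) is None:
        logger.info("external mapper %r not found; using built-in mapper", prog)
        return None
    argv = [
        item.format(ref=genome_path, reads=reads_path, out=out_sam_path)
        for item in command_template
    ]
    proc = subprocess.run(argv, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"external mapper failed (exit {proc.returncode}): {proc.stderr.strip()}"
        )
    return out_sam_path
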