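"""Transposon-tag detection, filtering and trimming.

TraDIS sequencing begins inside the transposon, so every genuine
transposon–chromosome junction read starts with a short (typically 8-12 nt)
transposon tag. Reads are kept only if their 5' prefix matches the expected
tag within a Hamming-distance tolerance, and the tag is stripped before
mapping. Matching is anchored at position 0 — no scanning into the read —
and base qualities play no role in acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, List, Tuple

from .core import SequencedRead

_VALID_TAG_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TagSpec:
    """The transposon tag to detect/strip and the matching tolerance."""

    tag: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.tag) <= 20:
            raise ValueError("tag length must be in 1..20")
        if not set(self.tag) <= _VALID_TAG_BASES:
            raise ValueError(f"tag contains non-ACGT characters: {self.tag!r}")
        if not 0 <= self.max_mismatches < len(self.tag):
            raise ValueError("max_mismatches must be >= 0 and < tag length")


@dataclass
class TagFilterReport:
    """Exact tallies from one pass of tag filtering."""

    total_reads: int = 0
    reads_with_tag: int = 0
    reads_without_tag: int = 0

    @property
    def fraction_with_tag(self) -> float:
        return self.reads_with_tag / self.total_reads if self.total_reads else 0.0


def match_tag(read: SequencedRead, spec: TagSpec) -> bool:
    """True iff the read's 5' prefix matches the tag within tolerance.

    'N' in the read counts as a mismatch; reads shorter than the tag never
    match.
    """
    tag = spec.tag
    if len(read.bases) < len(tag):
        return False
    prefix = read.bases[: len(tag)]
    mismatches = sum(a != b for a, b in zip(prefix, tag))
    return mismatches <= spec.max_mismatches


def filter_and_trim(
    reads: Iterable[SequencedRead], spec: TagSpec
) -> Tuple[List[SequencedRead], TagFilterReport]:
    """Keep tagged reads, strip the tag, report exact tallies.

    Output reads are the matching inputs with the first ``len(tag)`` bases
    and qualities removed, input order preserved. A read that would trim to
    length zero cannot be mapped; it is dropped and counted as without-tag.
    """
    report = TagFilterReport()
    out: List[SequencedRead] = []
    k = len(spec.tag)
    for read in reads:
        report.total_reads += 1
        if match_tag(read, spec) and len(read.bases) > k:
            report.reads_with_tag += 1
            out.append(
                SequencedRead(
                    read_id=read.read_id,
                    bases=read.bases[k:],
                    qualities=list(read.qualities[k:]),
                )
            )
        else:
            report.reads_without_tag += 1
    return out, report


def iter_filter_and_trim(
    reads: Iterable[SequencedRead], spec: TagSpec, report: TagFilterReport
) -> Iterator[SequencedRead]:
    """Streaming variant of :func:`filter_and_trim`; tallies accumulate into
    the caller's report as the stream is consumed."""
    k = len(spec.tag)
    for read in reads:
        report.total_reads += 1
        if match_tag(read, spec) and len(read.bases) > k:
            report.reads_with_tag += 1
            yield SequencedRead(read.read_id, read.bases[k:], list(read.qualities[k:]))
        else:
            report.reads_without_tag += 1


def write_report(report: TagFilterReport, path: str) -> None:
    """Two-column TSV of the report fields."""
    with open(path, "wt") as fh:
        fh.write(f"total_reads\t{report.total_reads}\n")
        fh.write(f"reads_with_tag\t{report.reads_with_tag}\n")
        fh.write(f"reads_without_tag\t{report.reads_without_tag}\n")
        fh.write(f"fraction_with_tag\t{report.fraction_with_tag!r}\n")
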