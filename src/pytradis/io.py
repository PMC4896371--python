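"""Readers and writers for every on-disk format the toolkit touches.

FASTQ (Phred+33, optionally gzipped), FASTA references, EMBL / GFF3 gene
annotation, SAM alignments, Artemis userplot insertion-plot files and the
tab-delimited gene-statistics table. All coordinates exposed here are
1-based inclusive. Readers and writers are mutually inverse on valid
inputs; tests assert the round trips.
"""

from __future__ import annotations

import gzip
import io as _stdio
import logging
import os
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO

import numpy as np
import pysam
from Bio import SeqIO

from .core import AlignmentRecord, GeneFeature, GeneInsertionStats, InsertionPlot, Replicon

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_KEYS = ("CDS", "tRNA", "rRNA")

#: Fixed column order of the gene-statistics table.
GENE_STATS_COLUMNS = (
    "locus_tag",
    "gene_name",
    "ncrna",
    "start",
    "end",
    "strand",
    "read_count",
    "ins_index",
    "gene_length",
    "ins_count",
    "fcn",
)


def _is_gzipped(path: str) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def _open_text_read(path: str) -> TextIO:
    if _is_gzipped(path):
        return _stdio.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _open_text_write(path: str) -> TextIO:
    if str(path).endswith(".gz"):
        return _stdio.TextIOWrapper(gzip.open(path, "wb"))
    return open(path, "wt")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str) -> Iterator["SequencedRead"]:
    """Stream reads from a plain or gzipped 4-line FASTQ file (Phred+33).

    Malformed records (missing '@'/'+' markers, sequence/quality length
    mismatch) raise ``ValueError`` naming the offending line number.
    """
    from .core import SequencedRead

    with _open_text_read(path) as fh:
        line_no = 0
        while True:
            header = fh.readline()
            if not header:
                return
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}: line {line_no}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"{path}: line {line_no}: truncated FASTQ record")
            line_no += 3
            if not plus.startswith("+"):
                raise ValueError(f"{path}: line {line_no - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: line {line_no}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            if not seq:
                raise ValueError(f"{path}: line {line_no - 2}: empty sequence")
            yield SequencedRead(
                read_id=header[1:].split()[0],
                bases=seq,
                qualities=[ord(c) - 33 for c in qual],
            )


def write_fastq(reads: Iterable["SequencedRead"], path: str) -> int:
    """Write reads as 4-line FASTQ (Phred+33; gzip when path ends '.gz').

    Returns the number of records written. ``read_fastq`` reproduces the
    input exactly.
    """
    n = 0
    with _open_text_write(path) as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA reference


def read_fasta(path: str) -> List[Replicon]:
    """Load a (multi-)FASTA reference; one Replicon per record."""
    with _open_text_read(path) as fh:
        replicons = [Replicon(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
    names = [r.name for r in replicons]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate replicon names")
    return replicons


def write_fasta(replicons: Sequence[Replicon], path: str, width: int = 70) -> None:
    with _open_text_write(path) as fh:
        for rep in replicons:
            fh.write(f">{rep.name}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation (EMBL feature table / GFF3)


def _envelope(feature) -> tuple[int, int]:
    # Compound/join locations are reduced to their min-start..max-end
    # envelope: bacterial gene-level counting does not need exon structure.
    start = int(feature.location.start) + 1  # Biopython is 0-based half-open
    end = int(feature.location.end)
    return start, end


def _check_bounds(
    gene_id: str,
    start: int,
    end: int,
    replicon: str,
    replicon_lengths: Optional[Dict[str, int]],
    out_of_bounds: str,
) -> Optional[tuple[int, int]]:
    if replicon_lengths is None or replicon not in replicon_lengths:
        return start, end
    length = replicon_lengths[replicon]
    if end <= length and start >= 1:
        return start, end
    if out_of_bounds == "skip":
        logger.warning("feature %s extends past replicon end; skipped", gene_id)
        return None
    logger.warning("feature %s extends past replicon end; clamped", gene_id)
    return max(start, 1), min(end, length)


def read_annotation(
    path: str,
    dialect: str = "embl",
    feature_keys: Sequence[str] = DEFAULT_FEATURE_KEYS,
    replicon_lengths: Optional[Dict[str, int]] = None,
    out_of_bounds: str = "clamp",
) -> List[GeneFeature]:
    """Parse gene features from an EMBL feature table or a GFF3 file.

    Only features whose key/type is in ``feature_keys`` (default CDS, tRNA,
    rRNA) are kept. Coordinates are returned 1-based inclusive regardless of
    dialect; compound (join/complement) locations are reduced to their
    envelope. Features running past a known replicon end are clamped or
    skipped per ``out_of_bounds``.
    """
    if dialect == "embl":
        return _read_embl(path, feature_keys, replicon_lengths, out_of_bounds)
    if dialect == "gff3":
        return _read_gff3(path, feature_keys, replicon_lengths, out_of_bounds)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _first(qualifiers, key) -> Optional[str]:
    vals = qualifiers.get(key)
    return vals[0] if vals else None


def _read_embl(path, feature_keys, replicon_lengths, out_of_bounds) -> List[GeneFeature]:
    features: List[GeneFeature] = []
    keys = set(feature_keys)
    with _open_text_read(path) as fh:
        for rec in SeqIO.parse(fh, "embl"):
            for feat in rec.features:
                if feat.type not in keys:
                    continue
                start, end = _envelope(feat)
                gene_id = (
                    _first(feat.qualifiers, "locus_tag")
                    or _first(feat.qualifiers, "gene")
                    or f"{rec.id}_{start}_{end}"
                )
                bounds = _check_bounds(gene_id, start, end, rec.id, replicon_lengths, out_of_bounds)
                if bounds is None:
                    continue
                features.append(
                    GeneFeature(
                        gene_id=gene_id,
                        replicon=rec.id,
                        start=bounds[0],
                        end=bounds[1],
                        strand="-" if feat.location.strand == -1 else "+",
                        product=_first(feat.qualifiers, "product"),
                        feature_type=feat.type,
                        gene_name=_first(feat.qualifiers, "gene"),
                    )
                )
    _require_unique_ids(features, path)
    return features


def _parse_gff_attributes(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path, feature_keys, replicon_lengths, out_of_bounds) -> List[GeneFeature]:
    # Flat column parse: bacterial annotations have no exon hierarchy worth
    # a feature database.
    features: List[GeneFeature] = []
    keys = set(feature_keys)
    with _open_text_read(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: line {line_no}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            if ftype not in keys:
                continue
            attrs = _parse_gff_attributes(attrs_s)
            start, end = int(start_s), int(end_s)
            gene_id = attrs.get("locus_tag") or attrs.get("ID") or f"{seqid}_{start}_{end}"
            bounds = _check_bounds(gene_id, start, end, seqid, replicon_lengths, out_of_bounds)
            if bounds is None:
                continue
            features.append(
                GeneFeature(
                    gene_id=gene_id,
                    replicon=seqid,
                    start=bounds[0],
                    end=bounds[1],
                    strand="-" if strand == "-" else "+",
                    product=attrs.get("product"),
                    feature_type=ftype,
                    gene_name=attrs.get("gene") or attrs.get("Name"),
                )
            )
    _require_unique_ids(features, path)
    return features


def _require_unique_ids(features: Sequence[GeneFeature], path: str) -> None:
    seen = set()
    for f in features:
        if f.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {f.gene_id!r}")
        seen.add(f.gene_id)


def write_gff3(features: Sequence[GeneFeature], path: str, replicons: Optional[Sequence[Replicon]] = None) -> None:
    """Write features as GFF3 (inverse of ``read_annotation(..., 'gff3')``)."""
    with _open_text_write(path) as fh:
        fh.write("##gff-version 3\n")
        if replicons:
            for rep in replicons:
                fh.write(f"##sequence-region {rep.name} 1 {rep.length}\n")
        for f in features:
            attrs = [f"ID={f.gene_id}", f"locus_tag={f.gene_id}"]
            if f.gene_name:
                attrs.append(f"gene={f.gene_name}")
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.replicon,
                        "pytradis",
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Artemis userplot insertion-plot files


def read_plot(path: str, replicon: str = "", expected_length: Optional[int] = None) -> InsertionPlot:
    """Read a two-column Artemis userplot file (forward, reverse counts).

    One whitespace-separated line per reference base. When
    ``expected_length`` is given, a differing line count is a hard error.
    """
    with _open_text_read(path) as fh:
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {data.shape[1]}")
    if expected_length is not None and data.shape[0] != expected_length:
        raise ValueError(
            f"{path}: {data.shape[0]} lines but replicon length is {expected_length}"
        )
    if (data < 0).any():
        raise ValueError(f"{path}: negative insertion counts")
    return InsertionPlot(replicon=replicon, forward=data[:, 0].copy(), reverse=data[:, 1].copy())


def write_plot(plot: InsertionPlot, path: str) -> None:
    """Write an InsertionPlot as an Artemis userplot file (gzip on '.gz')."""
    with _open_text_write(path) as fh:
        for f, r in zip(plot.forward.tolist(), plot.reverse.tolist()):
            fh.write(f"{f} {r}\n")


def plot_path(prefix: str, replicon: str, gzipped: bool = False) -> str:
    suffix = ".gz" if gzipped else ""
    return f"{prefix}.{replicon}.insert_site_plot{suffix}"


# ---------------------------------------------------------------------------
# SAM alignments

_UNIQUE_MAPQ_DEFAULT = 30


def write_sam(
    records: Iterable[AlignmentRecord],
    replicons: Sequence[Replicon],
    path: str,
) -> int:
    """Write alignment records as SAM with one @SQ line per replicon.

    Only the fields carried by :class:`AlignmentRecord` are emitted; read
    sequence and qualities are not retained ('*'). Mapped-reverse records
    get flag 16, unmapped records flag 4.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.name, "LN": r.length} for r in replicons],
    }
    n = 0
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            if rec.is_mapped:
                a.reference_name = rec.replicon
                a.reference_start = rec.pos - 1
                a.mapping_quality = rec.mapq
                a.cigarstring = f"{rec.aligned_length}M"
                a.flag = 16 if rec.strand == "-" else 0
            else:
                a.flag = 4
                a.mapping_quality = 0
            out.write(a)
            n += 1
    return n


def read_sam(path: str, mapq_unique_threshold: int = _UNIQUE_MAPQ_DEFAULT) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM (or BAM) file.

    ``is_unique`` is inferred as mapq >= ``mapq_unique_threshold`` — the SAM
    convention the built-in mapper writes (60 unique, 0 repeat). Secondary
    and supplementary alignments are skipped.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            if a.is_unmapped:
                yield AlignmentRecord(read_id=a.query_name, is_mapped=False)
                continue
            aligned_length = a.reference_end - a.reference_start
            yield AlignmentRecord(
                read_id=a.query_name,
                replicon=a.reference_name,
                pos=a.reference_start + 1,
                strand="-" if a.is_reverse else "+",
                aligned_length=aligned_length,
                mapq=a.mapping_quality,
                is_unique=a.mapping_quality >= mapq_unique_threshold,
                is_mapped=True,
            )


# ---------------------------------------------------------------------------
# Gene-statistics table


def write_gene_stats(stats: Sequence[GeneInsertionStats], path: str) -> None:
    """Write the per-gene statistics table as TSV with a single header line.

    Column order is fixed (:data:`GENE_STATS_COLUMNS`); ``ncrna`` flags
    non-CDS features; ``ins_index`` is serialized with full precision but is
    recomputed from the integer columns on read, so round trips are exact.
    """
    with _open_text_write(path) as fh:
        fh.write("\t".join(GENE_STATS_COLUMNS) + "\n")
        for s in stats:
            fh.write(
                "\t".join(
                    [
                        s.gene_id,
                        s.gene_name or "-",
                        "0" if s.feature_type == "CDS" else "1",
                        str(s.start),
                        str(s.end),
                        s.strand,
                        str(s.read_count),
                        repr(s.insertion_index),
                        str(s.gene_length),
                        str(s.insertion_count),
                        s.product or "-",
                    ]
                )
                + "\n"
            )


def read_gene_stats(path: str, replicon: str = "") -> List[GeneInsertionStats]:
    """Read a gene-statistics TSV written by :func:`write_gene_stats`."""
    out: List[GeneInsertionStats] = []
    with _open_text_read(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_STATS_COLUMNS:
            raise ValueError(f"{path}: unexpected gene-stats header {header!r}")
        for line_no, line in enumerate(fh, 2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(GENE_STATS_COLUMNS):
                raise ValueError(f"{path}: line {line_no}: wrong column count")
            out.append(
                GeneInsertionStats(
                    gene_id=cols[0],
                    replicon=replicon,
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[5],
                    read_count=int(cols[6]),
                    insertion_count=int(cols[9]),
                    gene_length=int(cols[8]),
                    gene_name=None if cols[1] == "-" else cols[1],
                    feature_type="CDS" if cols[2] == "0" else "ncRNA",
                    product=None if cols[10] == "-" else cols[10],
                )
            )
    return out
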