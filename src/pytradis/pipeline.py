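"""Full-run orchestration: filter → map → plot → gene statistics.

``run_pipeline`` produces exactly the files the stage commands would
produce when run in sequence with the same parameters — stage equivalence
is bit-exact and tested. A machine-readable RunReport captures per-stage
read tallies (the headline statistic being the fraction of reads that both
carry an intact tag and map uniquely), the parameters used and per-stage
wall time, so any run is reproducible from its report.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import io as tio
from .core import AlignmentRecord, GeneInsertionStats, InsertionPlot, Replicon
from .genestats import gene_stats
from .mapping import GenomeIndex, MappingParams, default_params, map_read, retained
from .plots import build_plots
from .tags import TagFilterReport, TagSpec, iter_filter_and_trim

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-stage read tallies and run metadata."""

    total_reads: int = 0
    tagged_reads: int = 0
    mapped_reads: int = 0
    uniquely_mapped_reads: int = 0
    retained_reads: int = 0
    parameters: Dict[str, object] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)

    @property
    def fraction_tagged_and_unique(self) -> float:
        return self.retained_reads / self.total_reads if self.total_reads else 0.0

    def validate(self) -> None:
        seq = [
            self.total_reads,
            self.tagged_reads,
            self.mapped_reads,
            self.uniquely_mapped_reads,
            self.retained_reads,
        ]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"pipeline tallies increased along the pipeline: {seq}")


def write_report(report: RunReport, tsv_path: str, text_path: Optional[str] = None) -> None:
    rows = [
        ("total_reads", report.total_reads),
        ("tagged_reads", report.tagged_reads),
        ("mapped_reads", report.mapped_reads),
        ("uniquely_mapped_reads", report.uniquely_mapped_reads),
        ("retained_reads", report.retained_reads),
        ("fraction_tagged_and_unique", repr(report.fraction_tagged_and_unique)),
    ]
    with open(tsv_path, "wt") as fh:
        for key, val in rows:
            fh.write(f"{key}\t{val}\n")
    if text_path:
        with open(text_path, "wt") as fh:
            fh.write("== tradis run report ==\n")
            for key, val in rows:
                fh.write(f"{key:30s} {val}\n")
            fh.write("-- parameters --\n")
            for key, val in sorted(report.parameters.items()):
                fh.write(f"{key:30s} {val}\n")
            fh.write("-- wall time (s) --\n")
            for key, val in report.stage_seconds.items():
                fh.write(f"{key:30s} {val:.3f}\n")


@dataclass
class PipelineResult:
    plots: Dict[str, InsertionPlot]
    stats: List[GeneInsertionStats]
    report: RunReport
    outdir: str


def _sniff_dialect(path: str) -> str:
    from .io import _open_text_read

    with _open_text_read(path) as fh:
        first = fh.readline()
    return "gff3" if first.startswith("##gff") else "embl"


def run_pipeline(
    fastq_path: str,
    reference_path: str,
    tag_spec: TagSpec,
    outdir: str,
    annotation_path: Optional[str] = None,
    params: Optional[MappingParams] = None,
    trim5: float = 0.0,
    trim3: float = 0.0,
    junction_end: str = "5prime",
    gzip_outputs: bool = False,
    prefix: str = "tradis",
) -> PipelineResult:
    """Run filter → map → plot → genestats, writing all stage outputs.

    Outputs in ``outdir``: ``<prefix>.filtered.fastq``, ``<prefix>.sam``,
    one ``<prefix>.<replicon>.insert_site_plot`` per replicon,
    ``<prefix>.gene_stats.tsv`` (when annotation given),
    ``<prefix>.filter_report.tsv`` and ``<prefix>.run_report.{tsv,txt}``.
    """
    os.makedirs(outdir, exist_ok=True)
    report = RunReport()
    genome = tio.read_fasta(reference_path)

    # -- filter ------------------------------------------------------------
    t0 = time.perf_counter()
    tag_report = TagFilterReport()
    filtered_path = os.path.join(outdir, f"{prefix}.filtered.fastq" + (".gz" if gzip_outputs else ""))
    trimmed = list(iter_filter_and_trim(tio.read_fastq(fastq_path), tag_spec, tag_report))
    tio.write_fastq(trimmed, filtered_path)
    report.total_reads = tag_report.total_reads
    report.tagged_reads = tag_report.reads_with_tag
    report.stage_seconds["filter"] = time.perf_counter() - t0
    from .tags import write_report as write_tag_report

    write_tag_report(tag_report, os.path.join(outdir, f"{prefix}.filter_report.tsv"))
    logger.info("filter: %d/%d reads tagged", tag_report.reads_with_tag, tag_report.total_reads)

    # -- map ---------------------------------------------------------------
    t0 = time.perf_counter()
    if params is None and trimmed:
        params = default_params(len(trimmed[0].bases))
    elif params is None:
        params = MappingParams(kmer=13, step=2)  # nothing to map; placeholder
    records: List[AlignmentRecord] = []
    if trimmed:
        index = GenomeIndex(genome, params.kmer)
        records = [map_read(r, index, params) for r in trimmed]
    sam_path = os.path.join(outdir, f"{prefix}.sam")
    tio.write_sam(records, genome, sam_path)
    report.mapped_reads = sum(r.is_mapped for r in records)
    report.uniquely_mapped_reads = sum(r.is_mapped and r.is_unique for r in records)
    report.retained_reads = sum(1 for _ in retained(records, params))
    report.stage_seconds["map"] = time.perf_counter() - t0
    logger.info("map: %d mapped, %d unique", report.mapped_reads, report.uniquely_mapped_reads)

    # -- plot --------------------------------------------------------------
    t0 = time.perf_counter()
    plots = build_plots(records, genome, params, junction_end=junction_end)
    for name, plot in plots.items():
        tio.write_plot(plot, os.path.join(outdir, tio.plot_path(prefix, name, gzip_outputs)))
    report.stage_seconds["plot"] = time.perf_counter() - t0

    # -- gene statistics ---------------------------------------------------
    stats: List[GeneInsertionStats] = []
    if annotation_path is not None:
        t0 = time.perf_counter()
        genes = tio.read_annotation(
            annotation_path,
            dialect=_sniff_dialect(annotation_path),
            replicon_lengths={r.name: r.length for r in genome},
        )
        stats = gene_stats(plots, genes, trim5=trim5, trim3=trim3)
        tio.write_gene_stats(stats, os.path.join(outdir, f"{prefix}.gene_stats.tsv"))
        report.stage_seconds["genestats"] = time.perf_counter() - t0

    report.parameters = {
        "tag": tag_spec.tag,
        "max_mismatches": tag_spec.max_mismatches,
        "kmer": params.kmer,
        "step": params.step,
        "min_identity": params.min_identity,
        "mapq_unique_threshold": params.mapq_unique_threshold,
        "trim5": trim5,
        "trim3": trim3,
        "junction_end": junction_end,
        "reference": os.path.basename(reference_path),
        "fastq": os.path.basename(fastq_path),
    }
    report.validate()
    write_report(
        report,
        os.path.join(outdir, f"{prefix}.run_report.tsv"),
        os.path.join(outdir, f"{prefix}.run_report.txt"),
    )
    return PipelineResult(plots=plots, stats=stats, report=report, outdir=outdir)
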