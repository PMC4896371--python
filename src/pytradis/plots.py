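"""Per-base insertion-site counting from uniquely mapped reads.

Each retained alignment increments exactly one base: the read base adjacent
to the transposon junction. The tag sits at the read's 5' end, so that end
abuts the transposon — for a forward alignment this is the leftmost mapped
coordinate, for a reverse alignment the rightmost. Both strands therefore
report the same insertion event at (near-)identical reference coordinates.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence

from .core import AlignmentRecord, InsertionPlot, InsertionSiteSummary, Replicon
from .mapping import MappingParams, retained


def junction_position(rec: AlignmentRecord, junction_end: str = "5prime") -> int:
    """1-based reference coordinate of the transposon-junction-proximal base.

    ``junction_end='3prime'`` flips the convention (counts the far end of
    the read instead), for comparison with tools that do so.
    """
    five_prime = rec.pos if rec.strand == "+" else rec.pos + rec.aligned_length - 1
    if junction_end == "5prime":
        return five_prime
    return rec.pos + rec.aligned_length - 1 if rec.strand == "+" else rec.pos


def build_plots(
    alignments: Iterable[AlignmentRecord],
    genome: Sequence[Replicon],
    params: MappingParams,
    junction_end: str = "5prime",
) -> Dict[str, InsertionPlot]:
    """Tally retained alignments into one InsertionPlot per replicon.

    Retained = mapped, unique and MAPQ at or above the uniqueness gate;
    everything else contributes nothing. Alignments naming an unknown
    replicon are a hard error.
    """
    plots = {rep.name: InsertionPlot.zeros(rep.name, rep.length) for rep in genome}
    for rec in retained(alignments, params):
        if rec.replicon not in plots:
            raise ValueError(f"alignment to unknown replicon {rec.replicon!r}")
        plot = plots[rec.replicon]
        site = junction_position(rec, junction_end)
        if rec.strand == "+":
            plot.forward[site - 1] += 1
        else:
            plot.reverse[site - 1] += 1
    return plots


def summarize_plot(plot: InsertionPlot) -> InsertionSiteSummary:
    """Count distinct insertion sites and total supporting reads."""
    combined = plot.combined()
    return InsertionSiteSummary(
        replicon=plot.replicon,
        n_sites=int((combined > 0).sum()),
        total_reads=int(combined.sum()),
    )
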