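"""Synthetic transposon-library generator with full ground truth.

Emulates the read structure of transposon-junction sequencing: each
genuine read is the transposon tag followed by ``read_length`` bases of
chromosomal sequence starting at the insertion site, read in the
insertion's orientation. The generator plants a set of essential genes
that receive zero insertions, scatters the remaining insertions uniformly,
draws a geometric number of reads per insertion (a simple model of PCR and
abundance dispersion), optionally injects i.i.d. substitution errors into
the chromosomal part, and mixes in untagged contaminant fragments.

Every quantity the downstream pipeline computes — per-base insertion
counts, per-gene statistics, the essential-gene set — is available as an
exact truth table, so end-to-end assertions can demand bit-exact recovery.

What this does not emulate: realistic base-quality profiles, indel errors,
target-site duplication, GC insertion bias (available but off by default),
or multi-round selection dynamics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import GeneFeature, GeneInsertionStats, InsertionPlot, Replicon, SequencedRead, revcomp
from .tags import TagSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_READ_QUALITY = 40  # constant Phred quality; quality modeling is out of scope


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated TraDIS experiment.

    Defaults describe a desk-scale dense library: a 45 kb chromosome plus a
    5 kb plasmid, 40 genes of 300-1500 nt (bacteria-like coding density),
    20% essential, 2500 distinct
    insertion sites (≈0.05 per base, hence a mean insertion index near
    0.05), a geometric mean of 2 reads per insertion, a 10 nt Tn5
    mosaic-end-like tag, 50 nt reads after the tag, 10% untagged
    contaminants and no sequencing error (error injection is opt-in so the
    truth tables stay exact by default).
    """

    seed: int = 0
    n_replicons: int = 2
    replicon_lengths: Tuple[int, ...] = (45_000, 5_000)
    n_genes: int = 40
    gene_length_range: Tuple[int, int] = (300, 1500)
    frac_essential: float = 0.2
    n_insertions: int = 2_500
    reads_per_insertion: float = 2.0
    tag: str = "TAAGAGACAG"
    read_length: int = 50
    frac_untagged: float = 0.1
    base_error_rate: float = 0.0
    gc_bias: float = 0.0  # log-weight added to G/C target bases; 0 = uniform
    intergenic_gap_range: Tuple[int, int] = (50, 300)

    def __post_init__(self) -> None:
        if len(self.replicon_lengths) != self.n_replicons:
            raise ValueError("replicon_lengths must have n_replicons entries")
        for frac in (self.frac_essential, self.frac_untagged, self.base_error_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.reads_per_insertion < 1:
            raise ValueError("reads_per_insertion (geometric mean) must be >= 1")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("bad gene_length_range")
        TagSpec(self.tag)  # validates alphabet/length

    @property
    def tag_spec(self) -> TagSpec:
        return TagSpec(self.tag)


@dataclass
class SimulatedLibrary:
    """A simulated experiment plus exact truth tables."""

    config: SimulationConfig
    genome: List[Replicon]
    genes: List[GeneFeature]
    essential_ids: set
    insertions: List[Tuple[str, int, str]]  # (replicon, 1-based junction pos, strand)
    reads_per_site: List[int]
    reads: List[SequencedRead]
    truth_plots: Dict[str, InsertionPlot]
    truth_stats: List[GeneInsertionStats]
    reads_truth: Dict[str, Tuple[str, int, str]]  # tagged read id -> junction

    @property
    def n_tagged_reads(self) -> int:
        return sum(self.reads_per_site)


def _random_genome(rng: np.random.Generator, config: SimulationConfig) -> List[Replicon]:
    reps = []
    for i, length in enumerate(config.replicon_lengths):
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        reps.append(Replicon(name=f"replicon{i + 1}", sequence=seq))
    return reps


def _pack_genes(rng: np.random.Generator, config: SimulationConfig,
                genome: Sequence[Replicon]) -> List[GeneFeature]:
    lo, hi = config.gene_length_range
    gap_lo, gap_hi = config.intergenic_gap_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    genes: List[GeneFeature] = []
    rep_iter = iter(genome)
    rep = next(rep_iter)
    cursor = 1
    for g in range(config.n_genes):
        length = int(lengths[g])
        while True:
            gap = int(rng.integers(gap_lo, gap_hi + 1))
            start = cursor + gap
            if start + length - 1 <= rep.length:
                break
            rep_next = next(rep_iter, None)
            if rep_next is None:
                raise ValueError(
                    f"infeasible gene packing: only {g} of {config.n_genes} genes fit"
                )
            rep, cursor = rep_next, 1
        genes.append(
            GeneFeature(
                gene_id=f"SIM_{g + 1:04d}",
                replicon=rep.name,
                start=start,
                end=start + length - 1,
                strand=str(strands[g]),
                product=f"simulated protein {g + 1}",
            )
        )
        cursor = start + length
    return genes


def _essential_masks(
    genome: Sequence[Replicon], genes: Sequence[GeneFeature], essential_ids: set
) -> Dict[str, np.ndarray]:
    masks = {rep.name: np.zeros(rep.length, dtype=bool) for rep in genome}
    for gene in genes:
        if gene.gene_id in essential_ids:
            masks[gene.replicon][gene.start - 1 : gene.end] = True
    return masks


def _draw_insertions(
    rng: np.random.Generator,
    config: SimulationConfig,
    genome: Sequence[Replicon],
    essential_mask: Dict[str, np.ndarray],
) -> List[Tuple[str, int, str]]:
    """Distinct (replicon, junction position, strand) triples, uniform over
    every placement where the read fits and the site is outside essential
    genes."""
    L = config.read_length
    cand_rep: List[np.ndarray] = []
    cand_pos: List[np.ndarray] = []
    cand_strand: List[np.ndarray] = []
    for ri, rep in enumerate(genome):
        ok = ~essential_mask[rep.name]
        pos = np.arange(1, rep.length + 1)
        fwd = ok & (pos + L - 1 <= rep.length)
        rev = ok & (pos >= L)
        for strand_code, mask in ((0, fwd), (1, rev)):
            p = pos[mask]
            cand_rep.append(np.full(p.size, ri))
            cand_pos.append(p)
            cand_strand.append(np.full(p.size, strand_code))
    rep_all = np.concatenate(cand_rep)
    pos_all = np.concatenate(cand_pos)
    strand_all = np.concatenate(cand_strand)
    if config.n_insertions > rep_all.size:
        raise ValueError("n_insertions exceeds the number of admissible sites")
    if config.gc_bias == 0.0:
        pick = rng.choice(rep_all.size, size=config.n_insertions, replace=False)
    else:
        # mild Tn5-style target bias: log-weight gc_bias at G/C bases.
        # Weighted sampling without replacement via Gumbel top-k.
        is_gc = np.empty(rep_all.size, dtype=bool)
        for ri, rep in enumerate(genome):
            m = rep_all == ri
            bases = np.frombuffer(rep.sequence.encode(), dtype=np.uint8)[pos_all[m] - 1]
            is_gc[m] = (bases == ord("G")) | (bases == ord("C"))
        logw = config.gc_bias * is_gc.astype(float)
        keys = logw + rng.gumbel(size=rep_all.size)
        pick = np.argpartition(-keys, config.n_insertions - 1)[: config.n_insertions]
    pick.sort()
    return [
        (genome[rep_all[i]].name, int(pos_all[i]), "+" if strand_all[i] == 0 else "-")
        for i in pick
    ]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate(config: SimulationConfig) -> SimulatedLibrary:
    """Generate a complete simulated experiment; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    genome = _random_genome(rng, config)
    by_name = {rep.name: rep for rep in genome}
    genes = _pack_genes(rng, config, genome)
    n_essential = round(config.frac_essential * config.n_genes)
    essential_idx = rng.choice(config.n_genes, size=n_essential, replace=False)
    essential_ids = {genes[i].gene_id for i in essential_idx}
    masks = _essential_masks(genome, genes, essential_ids)
    insertions = _draw_insertions(rng, config, genome, masks)

    mean = config.reads_per_insertion
    reads_per_site = (
        [1] * len(insertions)
        if mean == 1
        else [int(k) for k in rng.geometric(1.0 / mean, size=len(insertions))]
    )

    L = config.read_length
    tag = config.tag
    reads: List[SequencedRead] = []
    reads_truth: Dict[str, Tuple[str, int, str]] = {}
    qual = [_READ_QUALITY] * (L + len(tag))
    for i, ((rep_name, pos, strand), k) in enumerate(zip(insertions, reads_per_site)):
        seq = by_name[rep_name].sequence
        if strand == "+":
            genomic = seq[pos - 1 : pos - 1 + L]
        else:
            genomic = revcomp(seq[pos - L : pos])
        for j in range(k):
            rid = f"ins{i:06d}_r{j}"
            reads.append(
                SequencedRead(rid, tag + _apply_errors(rng, genomic, config.base_error_rate), list(qual))
            )
            reads_truth[rid] = (rep_name, pos, strand)

    n_tagged = len(reads)
    n_untagged = round(n_tagged * config.frac_untagged / (1.0 - config.frac_untagged)) \
        if config.frac_untagged < 1 else 0
    frag_len = L + len(tag)
    rep_weights = np.array([r.length for r in genome], dtype=float)
    rep_weights /= rep_weights.sum()
    for u in range(n_untagged):
        while True:
            rep = genome[rng.choice(len(genome), p=rep_weights)]
            start = int(rng.integers(1, rep.length - frag_len + 2))
            frag = rep.sequence[start - 1 : start - 1 + frag_len]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            # guarantee the contaminant cannot pass tag filtering, even at
            # a 1-mismatch tolerance
            if sum(a != b for a, b in zip(frag[: len(tag)], tag)) > 1:
                break
        reads.append(SequencedRead(f"untagged{u:06d}", frag, list(qual)))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    truth_plots = {rep.name: InsertionPlot.zeros(rep.name, rep.length) for rep in genome}
    for (rep_name, pos, strand), k in zip(insertions, reads_per_site):
        if strand == "+":
            truth_plots[rep_name].forward[pos - 1] += k
        else:
            truth_plots[rep_name].reverse[pos - 1] += k

    truth_stats = []
    for gene in genes:
        span = truth_plots[gene.replicon].combined()[gene.start - 1 : gene.end]
        truth_stats.append(
            GeneInsertionStats(
                gene_id=gene.gene_id,
                replicon=gene.replicon,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                read_count=int(span.sum()),
                insertion_count=int((span > 0).sum()),
                gene_length=gene.length,
                gene_name=gene.gene_name,
                feature_type=gene.feature_type,
                product=gene.product,
            )
        )

    return SimulatedLibrary(
        config=config,
        genome=genome,
        genes=genes,
        essential_ids=essential_ids,
        insertions=insertions,
        reads_per_site=reads_per_site,
        reads=reads,
        truth_plots=truth_plots,
        truth_stats=truth_stats,
        reads_truth=reads_truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing / manifest round trip

_MANIFEST_NAME = "manifest.txt"


def write_manifest(config: SimulationConfig, path: str) -> None:
    """Flat key=value manifest from which the library regenerates exactly."""
    with open(path, "wt") as fh:
        fh.write(f"seed={config.seed}\n")
        fh.write(f"n_replicons={config.n_replicons}\n")
        fh.write("replicon_lengths=" + ",".join(map(str, config.replicon_lengths)) + "\n")
        fh.write(f"n_genes={config.n_genes}\n")
        fh.write(f"gene_length_range={config.gene_length_range[0]},{config.gene_length_range[1]}\n")
        fh.write(f"frac_essential={config.frac_essential!r}\n")
        fh.write(f"n_insertions={config.n_insertions}\n")
        fh.write(f"reads_per_insertion={config.reads_per_insertion!r}\n")
        fh.write(f"tag={config.tag}\n")
        fh.write(f"read_length={config.read_length}\n")
        fh.write(f"frac_untagged={config.frac_untagged!r}\n")
        fh.write(f"base_error_rate={config.base_error_rate!r}\n")
        fh.write(f"gc_bias={config.gc_bias!r}\n")
        fh.write(f"intergenic_gap_range={config.intergenic_gap_range[0]},{config.intergenic_gap_range[1]}\n")


def read_manifest(path: str) -> SimulationConfig:
    kv: Dict[str, str] = {}
    with open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key] = value
    pair = lambda s: tuple(int(x) for x in s.split(","))
    return SimulationConfig(
        seed=int(kv["seed"]),
        n_replicons=int(kv["n_replicons"]),
        replicon_lengths=pair(kv["replicon_lengths"]),
        n_genes=int(kv["n_genes"]),
        gene_length_range=pair(kv["gene_length_range"]),
        frac_essential=float(kv["frac_essential"]),
        n_insertions=int(kv["n_insertions"]),
        reads_per_insertion=float(kv["reads_per_insertion"]),
        tag=kv["tag"],
        read_length=int(kv["read_length"]),
        frac_untagged=float(kv["frac_untagged"]),
        base_error_rate=float(kv["base_error_rate"]),
        gc_bias=float(kv.get("gc_bias", 0.0)),
        intergenic_gap_range=pair(kv["intergenic_gap_range"]),
    )


def write_fixture(lib: SimulatedLibrary, directory: str, force: bool = False) -> str:
    """Write the full fixture (FASTA, GFF3, EMBL, FASTQ, truth tables) plus
    the manifest; returns the manifest path. Refuses a non-empty directory
    unless ``force``."""
    from . import io as tio

    os.makedirs(directory, exist_ok=True)
    if os.listdir(directory) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True to overwrite)")
    tio.write_fasta(lib.genome, os.path.join(directory, "genome.fasta"))
    tio.write_gff3(lib.genes, os.path.join(directory, "annotation.gff3"), lib.genome)
    _write_embl(lib, os.path.join(directory, "annotation.embl"))
    tio.write_fastq(lib.reads, os.path.join(directory, "reads.fastq"))
    for name, plot in lib.truth_plots.items():
        tio.write_plot(plot, os.path.join(directory, tio.plot_path("truth", name)))
    tio.write_gene_stats(lib.truth_stats, os.path.join(directory, "truth_gene_stats.tsv"))
    with open(os.path.join(directory, "essential_ids.txt"), "wt") as fh:
        for gid in sorted(lib.essential_ids):
            fh.write(gid + "\n")
    manifest = os.path.join(directory, _MANIFEST_NAME)
    write_manifest(lib.config, manifest)
    return manifest


def load_fixture(manifest_path: str) -> SimulatedLibrary:
    """Regenerate the library bit-identically from its manifest."""
    return simulate(read_manifest(manifest_path))


def _write_embl(lib: SimulatedLibrary, path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    records = []
    for rep in lib.genome:
        rec = SeqRecord(Seq(rep.sequence), id=rep.name, name=rep.name,
                        description="simulated replicon",
                        annotations={"molecule_type": "genomic DNA"})
        for gene in lib.genes:
            if gene.replicon != rep.name:
                continue
            feat = SeqFeature(
                FeatureLocation(gene.start - 1, gene.end, strand=1 if gene.strand == "+" else -1),
                type=gene.feature_type,
            )
            feat.qualifiers["locus_tag"] = [gene.gene_id]
            if gene.product:
                feat.qualifiers["product"] = [gene.product]
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, path, "embl")
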