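# Methods

This note records the models, conventions and numerical choices behind
pytradis, in the order data flows through the pipeline.

## Read model and tag filtering

A TraDIS junction read is modelled as `tag + flank`: the transposon tag
(default 10 nt) followed by chromosomal sequence that starts at the base
adjacent to the transposon and runs in the insertion's orientation. Tag
matching is anchored at read position 0 with a Hamming tolerance
(default 0 mismatches): sequencing begins inside the transposon, so
scanning for the tag deeper in the read would invent junctions and is
deliberately not offered. `N` counts as a mismatch; base qualities play no
role in acceptance (tag bases come from early, high-accuracy cycles).
Indel tolerance would require alignment and is not supported. Reads that
would trim to length zero are dropped and counted as untagged, keeping the
tally conservation exact: `reads_with_tag + reads_without_tag =
total_reads`, and every tagged read is emitted.

## Mapping

The built-in mapper is seed-and-extend and **ungapped**: sampled k-mers
from the read (stride `step`, plus a final seed flush with the read end)
are looked up in an exhaustive k-mer index of the forward reference;
every candidate placement in which the full read fits is scored by
Hamming identity on both strands. A read maps iff the best identity
reaches `min_identity`, is unique iff the best strictly beats the second
best, and ties report the lexicographically smallest
(replicon, position, strand) with `is_unique = False`. MAPQ is
synthesized: 60 for unique placements, 0 otherwise; only unique
placements at MAPQ ≥ 30 reach the insertion plots.

Length-banded defaults: read < 70 nt → k=13, step=2; 70–99 → k=13,
step=4; ≥ 100 → k=20, step=4; identity 0.96 in all bands. These are this
package's documented choices (config-overridable), selected so the seeded
search is provably exact: at identity 0.96 a read of length L carries at
most ⌊0.04·L⌋ mismatches, and each mismatch can invalidate at most
⌈k/step⌉ seed offsets — fewer, in every band, than the seeds available —
so any acceptable placement retains at least one clean seed. The
exhaustive all-positions scan (`exhaustive_map_read`) is therefore an
oracle the seeded mapper must equal, and the test suite and acceptance
script assert that equality. Gapped alignment is out of scope: insertion
calling needs only the junction coordinate, and indel-free scoring keeps
the oracle exact.

An adapter can invoke an external mapper via an argv template; a missing
executable logs a notice and falls back to the built-in mapper, a nonzero
exit is a hard error carrying the tool's stderr.

## Insertion plots

Each retained alignment increments exactly one base: the
junction-proximal read end — reference `pos` for forward alignments,
`pos + aligned_length − 1` for reverse ones. Both strands of the same
insertion thus report (near-)identical coordinates. The convention is
flippable (`junction_end='3prime'`) for comparison with tools that count
the far end. No site merging is done across strands or within windows;
the per-gene unique-site count tolerates the small positional jitter of
target-site duplication. Plot files are Artemis userplot format: one
whitespace-separated line per reference base, two columns (forward,
reverse), optionally gzipped; the line count must equal the replicon
length.

## Gene statistics

Coordinates are 1-based inclusive everywhere user-facing (EMBL/Artemis
convention). Compound `join(...)` locations are reduced to their
min–max envelope — bacterial gene-level counting does not need exon
structure; this is a documented limitation for the rare spliced feature.
Per gene, forward + reverse counts are summed over the gene span; both
strands count regardless of gene strand because an insertion disrupts the
gene either way; overlapping genes each count shared bases fully.
Optional `trim5`/`trim3` fractions (default 0) shave the span
strand-awarely, reflecting that terminal insertions often do not disrupt
function; the reported `gene_length` stays the full annotated length so
the insertion index remains comparable across trim settings. CDS, tRNA
and rRNA features are kept by default, with non-CDS rows flagged in the
`ncrna` column.

## Essentiality

**Model.** In a dense library, per-gene insertion indices are bimodal:
a zero-adjacent mode (essential genes, whose mutants are lost) and a
broad positive mode. We model the index distribution as a two-component
gamma mixture and classify by the per-gene log-odds
`L(x) = log2( Γ(x; a_ess, b_ess) / Γ(x; a_non, b_non) )` with threshold 2
(4:1 odds, the conventional choice; CLI-overridable). Changepoints are
the two index values where |L| crosses the threshold, found by Brent root
finding on the first sign change of a geometric grid (tolerance 1e-12);
for well-separated components (a_ess < a_non, b_ess > b_non) L is
strictly decreasing so each crossing is unique, and the label rule is
equivalent to the interval rule [changepoint_lo, changepoint_hi].

**Zeros.** A gamma likelihood is undefined at 0, so zero indices are
replaced by half the smallest positive index — for valley finding,
fitting and evaluation alike. The classifier asserts that the density
ratio at this pseudo-value clears the essential threshold, so a
zero-index gene is always called essential.

**Valley (pivot).** A Gaussian KDE with Silverman bandwidth is evaluated
on log10 of the (pseudo-replaced) indices; the pivot is the density
argmin between the two largest local maxima. The log scale is used
because the modes are separated multiplicatively (~10^-3 vs ~5·10^-2);
on the raw scale the zero-adjacent spike is inside one bandwidth of the
origin and the valley is poorly resolved. Unimodal densities raise a hard
error advising that the library is not dense enough. At least 100 gene
indices are required; genes shorter than 100 nt are excluded from valley
finding and fitting (their indices are too granular) but are still
classified.

**Fitting.** Each component is first fit by gamma maximum likelihood to
its side of the pivot (solving log a − ψ(a) = log x̄ − avg(log x)). The
hard split truncates both components and misassigns observations in the
overlap region, which biases the recovered parameters far beyond what a
downstream user should accept (in simulation, rate errors of 30–60 %), so
an EM pass over the full two-gamma mixture refines the split fit: E-step
responsibilities from the current weighted densities, M-step weighted
gamma MLEs, until the mixture log-likelihood changes by < 1e-9 relative
(max 300 iterations). Safeguards keep the split fit when EM collapses
onto a degenerate component (shape > 10³, or a mixing weight < 10⁻³) —
exactly what happens when every essential gene sits on the same
pseudo-value, in which case the continuous model has no proper ML
solution. For such (near-)constant or atom-dominated sides the component
fit itself falls back to the exponential sub-family (shape 1,
rate 1/mean), the ML solution with the shape pinned; the resulting
component decays fast enough that the zero region remains decisively
essential. This is a likelihood-ratio classification, not hypothesis
testing: no multiple-testing correction applies, and none is offered.

## Comparative analysis

Counts are gene-level read counts by default (`ins_count` selectable).
The computation is self-contained:

* **TMM.** M/A values against a reference column (the sample whose 75th
  count percentile over library size is closest to the mean), trimming
  30 % of M and 5 % of A from each tail, precision-weighted trimmed mean;
  factors are rescaled to geometric mean 1. The test suite cross-checks
  the factors to 1e-6 against an independent reference implementation.
* **Common dispersion.** Counts are scaled to the geometric-mean
  effective library size (a documented approximation to quantile
  adjustment), and a single φ maximizes the exact NB conditional
  log-likelihood of each gene's replicate counts given their group sum,
  optimized on log φ over [10⁻⁶, 10] (bounded Brent). Estimates at the
  lower bound report φ = 0, the Poisson limit. At least one condition
  must have ≥ 2 replicates; otherwise the caller must supply φ.
* **Exact test.** With equal (scaled) library sizes the null conditional
  law of one condition's summed count given the gene total `z` has
  weights `w(k) ∝ Γ(k + r₁)/k! · Γ(z − k + r₂)/(z − k)!` with
  `rᵢ = nᵢ/φ`, reducing to Binomial(z, n₁/(n₁+n₂)) as φ → 0. The
  two-sided p-value sums the weights of all outcomes no more probable
  than the observed one (so identical counts give p = 1 exactly, and the
  φ = 0 case matches the standard two-sided conditional binomial test).
  Group sums are rounded per group, which makes the test exactly
  symmetric under condition swap. Fold changes use a half-count prior per
  group mean. Genes with zero counts in both conditions are excluded and
  reported with empty p/q; Benjamini–Hochberg runs over the tested genes.
  Only the common-dispersion two-group design is supported — tagwise or
  trended dispersion shrinkage and GLM designs with covariates are out of
  scope.

## Simulator

The simulator defines the study conditions all validation runs under.
Defaults: a 45 kb chromosome plus 5 kb plasmid (multi-replicon handling
is exercised by default), 40 genes of 300–1500 nt packed with 50–300 nt
intergenic gaps (bacteria-like coding density), 20 % essential genes
receiving zero insertions by construction, 2500 distinct insertion sites
drawn uniformly over all placements where a read fits outside essential
genes (≈ 0.05 sites per base, hence non-essential insertion indices
around 0.05 — a dense library), geometric reads-per-insertion with
mean 2 (a minimal model of PCR/abundance dispersion), a 10 nt
Tn5-mosaic-end-like tag `TAAGAGACAG`, 50 nt of chromosomal sequence per
read, 10 % untagged contaminant reads (matching the >90 % tagged-and-
unique figure routinely achieved by the protocol), and no substitution
error by default so every truth table is exact; error injection
(`base_error_rate`) applies i.i.d. substitutions to the chromosomal part
only, leaving the tag intact. Contaminant fragments are resampled until
their prefix is at least 2 mismatches from the tag, so planted untagged
fractions are recovered *exactly* even at a 1-mismatch filter tolerance.
Reads per insertion, strand (½ each), positions and read order are all
drawn from one seeded generator: the same manifest regenerates the
fixture byte-identically.

What the simulator does **not** emulate — and what passing tests on it
therefore cannot show: realistic base-quality profiles (qualities are
constant Q40), indel sequencing errors, Tn5 target-site duplication and
insertion-site sequence bias (a GC-bias option is deliberately off by
default to keep truth tables analytic), chromosomal repeats (random
genomes are essentially repeat-free, so real-genome multi-mapping rates
will be higher), and multi-round selection dynamics. Scenario sizes used
in the validation suite (10 000-read filter runs, 20 kb oracle genomes,
600 kb/500-gene essentiality libraries over 10 seeds, 100 gamma-recovery
replicates, 2000-gene 3v3 count tests) were chosen as the smallest scales
at which the measured properties are stable.

## Determinism

Everything outside the simulator is deterministic: mapping ties break
lexicographically, the KDE/EM/root-finding pipeline has no random
element, and re-running any stage on identical inputs rewrites identical
bytes. The only randomness is the simulator seed.
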