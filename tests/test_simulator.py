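"""Library simulator: determinism, ground-truth bookkeeping, fixtures."""

import numpy as np
import pytest

from pytradis import io as tio
from pytradis.simulate import (
    SimulationConfig,
    load_fixture,
    read_manifest,
    simulate,
    write_fixture,
    write_manifest,
)
from pytradis.tags import filter_and_trim


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_replicons=2, replicon_lengths=(1000,))
    with pytest.raises(ValueError):
        SimulationConfig(frac_untagged=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(reads_per_insertion=0.5)


def test_same_seed_is_byte_identical(tmp_path):
    a = simulate(SimulationConfig(seed=7))
    b = simulate(SimulationConfig(seed=7))
    pa, pb = tmp_path / "a.fastq", tmp_path / "b.fastq"
    tio.write_fastq(a.reads, str(pa))
    tio.write_fastq(b.reads, str(pb))
    assert pa.read_bytes() == pb.read_bytes()
    assert a.genome[0].sequence == b.genome[0].sequence


def test_different_seed_differs():
    a = simulate(SimulationConfig(seed=7))
    b = simulate(SimulationConfig(seed=8))
    assert a.genome[0].sequence != b.genome[0].sequence


def test_exact_essential_gene_count():
    lib = simulate(
        SimulationConfig(seed=1, n_replicons=1, replicon_lengths=(600_000,),
                         n_genes=500, n_insertions=20_000, frac_essential=0.2)
    )
    assert len(lib.essential_ids) == 100
    by_id = {s.gene_id: s for s in lib.truth_stats}
    assert all(by_id[g].insertion_count == 0 for g in lib.essential_ids)


def test_no_insertion_inside_essential_genes(small_lib):
    spans = {
        (g.replicon, p)
        for g in small_lib.genes
        if g.gene_id in small_lib.essential_ids
        for p in range(g.start, g.end + 1)
    }
    assert all((rep, pos) not in spans for rep, pos, _ in small_lib.insertions)


def test_truth_conservation(small_lib):
    total = sum(int(p.combined().sum()) for p in small_lib.truth_plots.values())
    assert total == small_lib.n_tagged_reads == sum(small_lib.reads_per_site)


def test_insertions_are_distinct(small_lib):
    assert len(set(small_lib.insertions)) == len(small_lib.insertions)


def test_reads_follow_the_read_model(clean_lib):
    """Tagged read = tag + genomic flank starting at the junction, read in
    the insertion orientation."""
    from pytradis.core import revcomp

    by_name = {r.name: r for r in clean_lib.genome}
    tag = clean_lib.config.tag
    L = clean_lib.config.read_length
    checked = 0
    for read in clean_lib.reads[:100]:
        rep, pos, strand = clean_lib.reads_truth[read.read_id]
        seq = by_name[rep].sequence
        expect = seq[pos - 1 : pos - 1 + L] if strand == "+" else revcomp(seq[pos - L : pos])
        assert read.bases == tag + expect
        checked += 1
    assert checked == 100


def test_untagged_fraction_and_tag_immunity():
    cfg = SimulationConfig(seed=9, n_insertions=1800, reads_per_insertion=1.0, frac_untagged=0.1)
    lib = simulate(cfg)
    assert len(lib.reads) == 2000
    _, report = filter_and_trim(lib.reads, cfg.tag_spec)
    assert report.fraction_with_tag == 0.9
    # contaminants survive even a 1-mismatch tolerance
    from pytradis.tags import TagSpec

    _, tolerant = filter_and_trim(lib.reads, TagSpec(cfg.tag, max_mismatches=1))
    assert tolerant.fraction_with_tag == 0.9


def test_base_errors_hit_genomic_part_only():
    cfg = SimulationConfig(seed=3, base_error_rate=0.05, frac_untagged=0.0)
    lib = simulate(cfg)
    tag = cfg.tag
    assert all(r.bases.startswith(tag) for r in lib.reads)
    _, report = filter_and_trim(lib.reads, cfg.tag_spec)
    assert report.fraction_with_tag == 1.0


def test_gc_bias_shifts_insertion_sites_toward_gc():
    def gc_fraction(lib):
        by_name = {r.name: r for r in lib.genome}
        hits = sum(by_name[rep].sequence[pos - 1] in "GC" for rep, pos, _ in lib.insertions)
        return hits / len(lib.insertions)

    uniform = simulate(SimulationConfig(seed=17, gc_bias=0.0))
    biased = simulate(SimulationConfig(seed=17, gc_bias=1.0))
    assert abs(gc_fraction(uniform) - 0.5) < 0.03
    assert gc_fraction(biased) > gc_fraction(uniform) + 0.1


def test_manifest_round_trip(tmp_path):
    cfg = SimulationConfig(seed=13, base_error_rate=0.001, frac_untagged=0.07, gc_bias=0.3)
    path = tmp_path / "manifest.txt"
    write_manifest(cfg, str(path))
    assert read_manifest(str(path)) == cfg


def test_fixture_regenerates_bit_identically(small_lib, fixture_dir, tmp_path):
    lib2 = load_fixture(str(fixture_dir / "manifest.txt"))
    p1 = tmp_path / "regen.fastq"
    tio.write_fastq(lib2.reads, str(p1))
    assert p1.read_bytes() == (fixture_dir / "reads.fastq").read_bytes()


def test_fixture_refuses_nonempty_dir(small_lib, tmp_path):
    d = tmp_path / "occupied"
    d.mkdir()
    (d / "something.txt").write_text("x")
    with pytest.raises(FileExistsError):
        write_fixture(small_lib, str(d))


def test_truth_table_matches_gene_statistics_module(small_lib):
    from pytradis.genestats import gene_stats

    stats = gene_stats(small_lib.truth_plots, small_lib.genes)
    assert [(s.gene_id, s.read_count, s.insertion_count) for s in stats] == [
        (s.gene_id, s.read_count, s.insertion_count) for s in small_lib.truth_stats
    ]


def test_insertion_index_separation_across_seeds():
    """Default-density libraries show the bimodal structure essentiality
    needs: essentials at zero, non-essential indices well away from it."""
    for seed in (1, 2, 3):
        lib = simulate(SimulationConfig(seed=seed))
        idx = np.array([s.insertion_index for s in lib.truth_stats])
        ess = np.array([s.gene_id in lib.essential_ids for s in lib.truth_stats])
        assert (idx[ess] == 0).all()
        assert np.median(idx[~ess]) > 0.02
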