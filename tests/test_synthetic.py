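"""Simulator tests: every expected value is either trivially known or computed
by an independent oracle (plain substring scans, binomial/Poisson bounds)."""

import warnings
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from temob import synthetic as syn
from temob.core import revcomp


def scan_genome(genome, seq):
    """Test-local exhaustive substring oracle (independent of the package's)."""
    hits = []
    for contig, ref in genome.contigs.items():
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            i = ref.find(query)
            while i != -1:
                hits.append((contig, i, strand))
                i = ref.find(query, i + 1)
    return hits


# ---------------------------------------------------------------------------
# build_toy_genome
# ---------------------------------------------------------------------------


def test_zero_divergence_identity(toy_genome):
    for copy in toy_genome.te_copies:
        embedded = toy_genome.contigs[copy.contig][copy.start:copy.end]
        consensus = toy_genome.te_library[copy.family]
        expected = consensus if copy.strand == "+" else revcomp(consensus)
        assert embedded == expected


def test_determinism_byte_identical():
    cfg = syn.GenomeConfig()
    a = syn.build_toy_genome(cfg, 1)
    b = syn.build_toy_genome(cfg, 1)
    assert a.contigs == b.contigs
    assert a.te_library == b.te_library
    assert a.te_copies == b.te_copies
    assert a.clusters == b.clusters
    assert a.features == b.features


def test_different_seed_differs():
    cfg = syn.GenomeConfig()
    assert syn.build_toy_genome(cfg, 1).contigs != syn.build_toy_genome(cfg, 2).contigs


def test_divergence_rate_recovered():
    cfg = syn.GenomeConfig(divergence=0.02)
    genome = syn.build_toy_genome(cfg, 3)
    fractions = []
    for copy in genome.te_copies:
        embedded = genome.contigs[copy.contig][copy.start:copy.end]
        consensus = genome.te_library[copy.family]
        expected = consensus if copy.strand == "+" else revcomp(consensus)
        mismatches = sum(1 for a, b in zip(embedded, expected) if a != b)
        fractions.append(mismatches / len(expected))
    # substitutions hit a random base including resampling-to-different, so
    # the observed mismatch fraction tracks the nominal rate directly
    assert abs(np.mean(fractions) - 0.02) < 0.005


def test_sizing_error_on_tiny_contigs():
    cfg = syn.GenomeConfig(contigs={"c1": 3_000, "c2": 3_000})
    with pytest.raises(syn.SizingError):
        syn.build_toy_genome(cfg, 1)


def test_config_validation():
    with pytest.raises(ValueError):
        syn.GenomeConfig(contigs={"only": 100_000}).validate()
    with pytest.raises(ValueError):
        syn.GenomeConfig(families={"A": 1000, "B": 1000}).validate()


def test_cluster1_exists_and_genome_valid(toy_genome):
    toy_genome.validate()
    ids = [c.cluster_id for c in toy_genome.clusters]
    assert "cluster1" in ids
    assert [c.klass for c in toy_genome.clusters if c.cluster_id == "cluster1"] == ["piRNA"]


# ---------------------------------------------------------------------------
# small-RNA simulator
# ---------------------------------------------------------------------------


def test_single_source_library(toy_genome):
    truth = syn.TruthTable(smallrna_profile={("ZAMx", 25, "antisense"): 200})
    reads, records = syn.simulate_smallrna_library(toy_genome, truth, seed=5)
    assert len(reads) == 200
    zam_copies = toy_genome.copies_of("ZAMx")
    for name, seq in reads:
        assert len(seq) == 25
        hits = scan_genome(toy_genome, seq)
        assert hits, "read must realign to the genome"
        for contig, pos, strand in hits:
            inside = [c for c in zam_copies if c.contig == contig
                      and c.start <= pos and pos + 25 <= c.end]
            assert inside, "read must come from a ZAMx copy"
            assert all(strand != c.strand for c in inside), "antisense to the copy"


def test_first_nt_composition_controlled(toy_genome):
    truth = syn.TruthTable(smallrna_profile={("ZAMx", 21, "sense"): 800})
    reads, _ = syn.simulate_smallrna_library(toy_genome, truth, seed=11, first_nt_a={21: 0.6})
    n_a = sum(1 for _, seq in reads if seq[0] == "A")
    lo, hi = stats.binom.interval(0.99, 800, 0.6)
    assert lo <= n_a <= hi


def test_two_identical_copies_give_two_best_alignments(toy_genome):
    # default genome embeds 2 identical copies per family at divergence 0
    truth = syn.TruthTable(smallrna_profile={("GTWx", 24, "sense"): 100})
    reads, records = syn.simulate_smallrna_library(toy_genome, truth, seed=13)
    per_read = Counter(r.qname for r in records)
    for name, seq in reads:
        assert per_read[name] == len(scan_genome(toy_genome, seq))
        assert per_read[name] == 2


def test_unknown_family_error(toy_genome):
    truth = syn.TruthTable(smallrna_profile={("NOPE", 25, "sense"): 10})
    with pytest.raises(syn.UnknownFamilyError):
        syn.simulate_smallrna_library(toy_genome, truth, seed=1)


def test_smallrna_determinism(toy_genome):
    truth = syn.TruthTable(smallrna_profile={("ZAMx", 25, "sense"): 50})
    a = syn.simulate_smallrna_library(toy_genome, truth, seed=3)
    b = syn.simulate_smallrna_library(toy_genome, truth, seed=3)
    assert a[0] == b[0]


def test_label_recovery_oracle(smallrna_setup):
    """Every emitted read's truth label is recoverable by exhaustive realignment."""
    genome, truth, reads, records = smallrna_setup
    copy_info = [(c.family, c.contig, c.start, c.end) for c in genome.te_copies]
    cluster_info = [(c.cluster_id, c.contig, c.start, c.end) for c in genome.clusters]
    truth_by_name = {}
    for rec in records:
        truth_by_name[rec.qname] = rec.tags["ZF"]
    rng = np.random.default_rng(0)
    sample = rng.choice(len(reads), size=200, replace=False)
    for i in sample:
        name, seq = reads[i]
        sources = set()
        for contig, pos, strand in scan_genome(genome, seq):
            for fam, c, s, e in copy_info:
                if c == contig and s <= pos and pos + len(seq) <= e:
                    sources.add(fam)
            for cid, c, s, e in cluster_info:
                if c == contig and s <= pos and pos + len(seq) <= e:
                    sources.add(cid)
        assert truth_by_name[name] in sources


# ---------------------------------------------------------------------------
# WGS simulator
# ---------------------------------------------------------------------------


def test_wgs_no_artifacts_all_junctions_real(planted_wgs):
    genome, truth, records = planted_wgs
    kinds = {r.tags["ZT"] for r in records}
    assert "artefact" not in kinds
    junction = [r for r in records if r.tags["ZT"] == "real_junction"]
    assert junction, "planted insertions must generate junction fragments"


def test_wgs_null_library_has_no_te_evidence(small_genome):
    truth = syn.TruthTable()  # no insertions, no chimeras
    records = syn.simulate_wgs_library(small_genome, truth, coverage=10, seed=8)
    assert all(r.tags["ZT"] == "background" for r in records)
    assert all(not r.is_unmapped for r in records)
    assert all(r.left_clip == 0 and r.right_clip == 0 for r in records)


def test_wgs_geometry_error(small_genome):
    with pytest.raises(syn.GeometryError):
        syn.simulate_wgs_library(small_genome, syn.TruthTable(), coverage=1,
                                 read_len=100, insert_mean=150)


def test_wgs_softclip_tail_is_te_sequence(planted_wgs):
    genome, truth, records = planted_wgs
    planted_at = {(p.contig, p.pos): p.family for p in truth.planted_insertions}
    checked = 0
    for rec in records:
        if rec.tags["ZT"] != "real_junction" or rec.is_unmapped:
            continue
        if rec.right_clip >= 20:
            clip_coord = rec.ref_end
            fam = planted_at.get((rec.ref, clip_coord))
            if fam is None:
                continue
            tail = rec.clipped_seq("right")
            consensus = genome.te_library[fam]
            assert tail in consensus or revcomp(tail) in consensus
            checked += 1
    assert checked >= 10


def test_wgs_coverage_scales_records(small_genome):
    truth = syn.TruthTable()
    low = syn.simulate_wgs_library(small_genome, truth, coverage=4, seed=1)
    high = syn.simulate_wgs_library(small_genome, truth, coverage=8, seed=1)
    assert abs(len(high) / len(low) - 2) < 0.01


def test_chimera_count_tracks_copy_number():
    """Families with 10x the copies get ~10x the chimeric fragments."""
    cfg = syn.GenomeConfig(
        contigs={"chr1": 120_000, "chr2": 120_000},
        families={"BIG": 1_500, "SMALL": 1_500, "OTHER": 1_500},
        copies={"BIG": 10, "SMALL": 1, "OTHER": 1},
        cluster_length=2_000,
    )
    genome = syn.build_toy_genome(cfg, 21)
    truth = syn.TruthTable(chimera_rate=0.4)
    records = syn.simulate_wgs_library(genome, truth, coverage=20, seed=22)
    frags = {}
    for rec in records:
        if rec.tags["ZT"] == "artefact":
            frags.setdefault(rec.qname, rec.tags["ZF"])
    counts = Counter(frags.values())
    n_big, n_small = counts["BIG"], counts["SMALL"]
    # independent Poisson oracle: BIG ~ Binomial(n_big + n_small, 10/11)
    assert stats.binomtest(n_big, n_big + n_small, 10 / 11).pvalue > 1e-3
    assert n_big + n_small > 50


def test_chimera_te_junctions_uniform_along_consensus():
    cfg = syn.GenomeConfig(contigs={"chr1": 80_000, "chr2": 80_000},
                           families={"A": 2_000, "B": 2_000, "C": 2_000}, copies=3)
    genome = syn.build_toy_genome(cfg, 31)
    truth = syn.TruthTable(chimera_rate=2.0)
    records = syn.simulate_wgs_library(genome, truth, coverage=20, seed=32)
    # clipped chimeric tails should match TE interiors, not only ends:
    # recover junction offsets by locating clip tails in the consensus
    offsets = []
    for rec in records:
        if rec.tags["ZT"] != "artefact" or rec.is_unmapped:
            continue
        for side in ("left", "right"):
            tail = rec.clipped_seq(side)
            if len(tail) < 25:
                continue
            cons = genome.te_library[rec.tags["ZF"]]
            pos = cons.find(tail)
            if pos == -1:
                pos = cons.find(revcomp(tail))
            if pos != -1:
                offsets.append(pos / len(cons))
    assert len(offsets) > 30
    assert stats.kstest(offsets, "uniform").pvalue > 1e-4


# ---------------------------------------------------------------------------
# mobilome simulator
# ---------------------------------------------------------------------------


def test_mobilome_absent_circle_zero_reads(small_genome):
    truth = syn.TruthTable(planted_circles={"ZAMx": 100, "GTWx": 0})
    records = syn.simulate_mobilome_library(small_genome, truth, n_reads=400, seed=5)
    by_family = Counter(r.tags.get("ZF") for r in records if r.tags["ZT"] == "circle")
    assert by_family["GTWx"] == 0
    assert by_family["ZAMx"] == 400


def test_mobilome_depth_doubling(small_genome):
    truth = syn.TruthTable(planted_circles={"ZAMx": 300, "GTWx": 100})
    low = syn.simulate_mobilome_library(small_genome, truth, n_reads=1000, seed=6)
    high = syn.simulate_mobilome_library(small_genome, truth, n_reads=2000, seed=7)

    def circle_counts(records):
        return Counter(r.tags["ZF"] for r in records if r.tags["ZT"] == "circle")

    c_low, c_high = circle_counts(low), circle_counts(high)
    for fam in ("ZAMx", "GTWx"):
        assert abs(c_high[fam] / c_low[fam] - 2) < 0.35  # sampling error band
    # normalized composition is depth-invariant
    assert abs(c_high["ZAMx"] / c_high["GTWx"] - c_low["ZAMx"] / c_low["GTWx"]) < 0.6


def test_mobilome_mt_normalization_arithmetic(small_genome):
    from temob import mobilome as mb

    truth = syn.TruthTable(planted_circles={"ZAMx": 1})
    records = syn.simulate_mobilome_library(small_genome, truth, n_reads=500, seed=8,
                                            mt_background=1000)
    te_reads, _ = mb.assign_te_reads(records, small_genome)
    remapped = mb.remap_canonical(te_reads, small_genome.te_library)
    counts, _ = mb.family_counts(remapped)
    mt = mb.count_mt_reads(records, small_genome.mt_contig)
    assert mt == 1000
    normalized = mb.normalize_mt(counts, mt)
    assert normalized["ZAMx"] == pytest.approx(500.0, abs=1.0)


def test_mobilome_zero_mt_warns(small_genome):
    truth = syn.TruthTable(planted_circles={"ZAMx": 10})
    with pytest.warns(syn.NormalizationImpossibleWarning):
        syn.simulate_mobilome_library(small_genome, truth, n_reads=10, seed=9, mt_background=0)


def test_truth_table_rejects_breakpoint_in_same_family_copy(small_genome):
    copy = small_genome.copies_of("ZAMx")[0]
    bad = syn.TruthTable(planted_insertions=[
        syn.PlantedInsertion("ZAMx", copy.contig, copy.start + 100)])
    with pytest.raises(ValueError):
        bad.validate(small_genome)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def test_genome_write_load_roundtrip(tmp_path, small_genome):
    syn.write_genome(small_genome, tmp_path)
    back = syn.load_genome(tmp_path)
    assert back.contigs == small_genome.contigs
    assert back.te_library == small_genome.te_library
    assert back.te_copies == small_genome.te_copies
    assert back.clusters == small_genome.clusters
    assert back.features == small_genome.features
    assert back.mt_contig == small_genome.mt_contig


def test_truth_writer(tmp_path, small_genome):
    planted = syn.plant_insertions(small_genome, ["ZAMx"], seed=1)
    truth = syn.TruthTable(planted_insertions=planted,
                           planted_circles={"GTWx": 5},
                           smallrna_profile={("ZAMx", 25, "sense"): 10})
    syn.write_truth(truth, tmp_path)
    assert (tmp_path / "planted_insertions.tsv").exists()
    assert (tmp_path / "planted_circles.tsv").exists()
    assert (tmp_path / "smallrna_profile.tsv").exists()
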