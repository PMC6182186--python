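"""Toy-genome and read-library simulators with known ground truth.

Generates a small reference genome with embedded TE copies, piRNA/siRNA
clusters and gene features, plus three library types mirroring the inputs of
the downstream analyses:

* small-RNA libraries (18-30 nt reads with family/size/strand structure and
  controllable 5'-nucleotide composition),
* whole-genome paired-end libraries carrying planted TE insertions and,
  optionally, artefactual TE-genome chimeric fragments,
* mobilome libraries sampled from circular TE DNA plus a mitochondrial
  background used for normalization.

No external aligner is involved: alignment records are emitted directly with
correct clip/mate/score fields, and every emitted read carries truth tags
(``ZT`` truth kind, ``ZF`` family, ``ZO`` orientation) so downstream stages
can be validated exactly.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, IntervalIndex, random_seq, revcomp, write_bed, write_fasta

SENSE = "sense"
ANTISENSE = "antisense"


class SizingError(ValueError):
    """A contig is too short to host the requested features."""


class UnknownFamilyError(KeyError):
    """A requested family is absent from the TE library / genome."""


class GeometryError(ValueError):
    """Impossible fragment geometry (e.g. insert shorter than two reads)."""


class NormalizationImpossibleWarning(UserWarning):
    """Raised when a library is simulated without any normalizer reads."""


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TECopy:
    family: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ClusterAnnot:
    cluster_id: str
    contig: str
    start: int
    end: int
    klass: str  # "piRNA" | "siRNA"


@dataclass(frozen=True)
class FeatureAnnot:
    klass: str  # rRNA | miRNA | 3UTR | gene
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class GenomeConfig:
    """Generator settings for :func:`build_toy_genome`."""

    contigs: dict[str, int] = field(default_factory=lambda: {"chr1": 100_000, "chr2": 100_000})
    mt_name: str = "chrM"
    mt_length: int = 16_000
    families: dict[str, int] = field(
        default_factory=lambda: {"ZAMx": 2_000, "GTWx": 2_000, "CTRLx": 2_000}
    )
    copies: int | dict[str, int] = 2
    pirna_clusters: int = 1
    sirna_clusters: int = 1
    cluster_length: int = 4_000
    # feature class -> (count, length)
    features: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"rRNA": (2, 500), "miRNA": (2, 100), "3UTR": (3, 300), "gene": (3, 1_000)}
    )
    divergence: float = 0.0
    min_gap: int = 300

    def copies_for(self, family: str) -> int:
        if isinstance(self.copies, int):
            return self.copies
        return self.copies.get(family, 0)

    def validate(self) -> None:
        if len(self.contigs) < 2:
            raise ValueError("need at least 2 contigs")
        if len(self.families) < 3:
            raise ValueError("need at least 3 TE families")
        if self.pirna_clusters < 1 or self.sirna_clusters < 1:
            raise ValueError("need at least one piRNA and one siRNA cluster")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class ToyGenome:
    contigs: dict[str, str]  # includes the mitochondrial contig
    te_library: dict[str, str]  # family -> consensus sequence
    te_copies: list[TECopy]
    clusters: list[ClusterAnnot]
    features: list[FeatureAnnot]
    mt_contig: str

    def te_copy_index(self) -> IntervalIndex:
        return IntervalIndex((c.contig, c.start, c.end, c) for c in self.te_copies)

    def cluster_index(self) -> IntervalIndex:
        return IntervalIndex((c.contig, c.start, c.end, c) for c in self.clusters)

    def feature_index(self) -> IntervalIndex:
        return IntervalIndex((f.contig, f.start, f.end, f) for f in self.features)

    def nuclear_contigs(self) -> dict[str, str]:
        return {name: seq for name, seq in self.contigs.items() if name != self.mt_contig}

    def copies_of(self, family: str) -> list[TECopy]:
        return [c for c in self.te_copies if c.family == family]

    def validate(self) -> None:
        for c in self.te_copies:
            if c.family not in self.te_library:
                raise UnknownFamilyError(c.family)
        for iv in [*self.te_copies, *self.clusters, *self.features]:
            contig = iv.contig
            if not (0 <= iv.start < iv.end <= len(self.contigs[contig])):
                raise ValueError(f"interval out of contig bounds: {iv}")
        if self.mt_contig not in self.contigs:
            raise ValueError("mt contig missing")
        if not any(c.cluster_id == "cluster1" for c in self.clusters):
            raise ValueError("cluster1 (normalizer) missing")


def _place(rng: np.random.Generator, contig_lengths: dict[str, int],
           occupied: dict[str, list[tuple[int, int]]], length: int, min_gap: int,
           max_tries: int = 400) -> tuple[str, int]:
    """Choose a random non-overlapping placement; raise SizingError if impossible."""
    names = list(contig_lengths)
    for _ in range(max_tries):
        contig = names[rng.integers(len(names))]
        clen = contig_lengths[contig]
        if clen <= length + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap, clen - length - min_gap))
        end = start + length
        if all(end + min_gap <= s or start >= e + min_gap for s, e in occupied[contig]):
            occupied[contig].append((start, end))
            return contig, start
    raise SizingError(f"could not place a feature of length {length}; contigs too short/crowded")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def build_toy_genome(config: GenomeConfig, seed: int) -> ToyGenome:
    """Deterministically build a toy genome per ``config``.

    TE copies are embedded verbatim (with optional point-mutation divergence),
    clusters and features annotate unique background sequence.  The first
    piRNA cluster gets the id ``cluster1`` and serves as the small-RNA
    normalizer downstream.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E0]))

    te_library = {fam: random_seq(rng, length) for fam, length in config.families.items()}
    contig_seqs = {name: random_seq(rng, length) for name, length in config.contigs.items()}
    contig_seqs[config.mt_name] = random_seq(rng, config.mt_length)

    nuclear = dict(config.contigs)
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in nuclear}

    te_copies: list[TECopy] = []
    replacements: dict[str, list[tuple[int, str]]] = {name: [] for name in nuclear}
    for fam, consensus in te_library.items():
        for _ in range(config.copies_for(fam)):
            contig, start = _place(rng, nuclear, occupied, len(consensus), config.min_gap)
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = consensus if strand == "+" else revcomp(consensus)
            embedded = _mutate(rng, embedded, config.divergence)
            replacements[contig].append((start, embedded))
            te_copies.append(TECopy(fam, contig, start, start + len(consensus), strand))

    clusters: list[ClusterAnnot] = []
    cid = 0
    for klass, n in (("piRNA", config.pirna_clusters), ("siRNA", config.sirna_clusters)):
        for _ in range(n):
            cid += 1
            contig, start = _place(rng, nuclear, occupied, config.cluster_length, config.min_gap)
            clusters.append(ClusterAnnot(f"cluster{cid}", contig, start, start + config.cluster_length, klass))

    features: list[FeatureAnnot] = []
    for klass, (count, length) in config.features.items():
        for _ in range(count):
            contig, start = _place(rng, nuclear, occupied, length, config.min_gap)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(FeatureAnnot(klass, contig, start, start + length, strand))

    for contig, repls in replacements.items():
        if not repls:
            continue
        seq = contig_seqs[contig]
        pieces, cursor = [], 0
        for start, embedded in sorted(repls):
            pieces.append(seq[cursor:start])
            pieces.append(embedded)
            cursor = start + len(embedded)
        pieces.append(seq[cursor:])
        contig_seqs[contig] = "".join(pieces)

    genome = ToyGenome(contig_seqs, te_library, te_copies, clusters, features, config.mt_name)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedInsertion:
    family: str
    contig: str
    pos: int  # breakpoint, reference coordinates
    strand: str = "+"


@dataclass
class TruthTable:
    """Ground truth for a simulation round."""

    planted_insertions: list[PlantedInsertion] = field(default_factory=list)
    planted_circles: dict[str, int] = field(default_factory=dict)
    # (family-or-cluster-id, size, sense|antisense) -> read count
    smallrna_profile: dict[tuple[str, int, str], int] = field(default_factory=dict)
    chimera_rate: float = 0.0

    def validate(self, genome: ToyGenome) -> None:
        for (fam, size, strand), count in self.smallrna_profile.items():
            if count < 0:
                raise ValueError("negative profile count")
            if strand not in (SENSE, ANTISENSE):
                raise ValueError(f"bad strand {strand!r}")
        for fam, count in self.planted_circles.items():
            if fam not in genome.te_library:
                raise UnknownFamilyError(fam)
            if count < 0:
                raise ValueError("negative circle count")
        same_family = IntervalIndex(
            (c.contig, c.start, c.end, c.family) for c in genome.te_copies
        )
        for ins in self.planted_insertions:
            hits = same_family.overlapping(ins.contig, ins.pos, ins.pos + 1)
            if any(payload == ins.family for _, _, payload in hits):
                raise ValueError("planted breakpoint inside a pre-existing copy of the same family")


def plant_insertions(genome: ToyGenome, families: Sequence[str], seed: int,
                     min_separation: int = 5_000, margin: int = 600) -> list[PlantedInsertion]:
    """Choose breakpoints in unique background sequence, pairwise well separated."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A5]))
    occupied = IntervalIndex(
        [(c.contig, c.start, c.end, "te") for c in genome.te_copies]
        + [(c.contig, c.start, c.end, "cluster") for c in genome.clusters]
        + [(f.contig, f.start, f.end, "feature") for f in genome.features]
    )
    nuclear = genome.nuclear_contigs()
    names = list(nuclear)
    chosen: list[PlantedInsertion] = []
    for fam in families:
        if fam not in genome.te_library:
            raise UnknownFamilyError(fam)
        for _ in range(500):
            contig = names[rng.integers(len(names))]
            pos = int(rng.integers(margin, len(nuclear[contig]) - margin))
            if occupied.overlapping(contig, pos - margin, pos + margin):
                continue
            if any(p.contig == contig and abs(p.pos - pos) < min_separation for p in chosen):
                continue
            chosen.append(PlantedInsertion(fam, contig, pos, "+"))
            break
        else:
            raise SizingError("could not place planted insertion; genome too crowded")
    return chosen


# ---------------------------------------------------------------------------
# Small-RNA library
# ---------------------------------------------------------------------------


def exhaustive_align(genome: ToyGenome, seq: str) -> list[tuple[str, int, str]]:
    """All exact occurrences of ``seq`` in the genome, both strands.

    This doubles as the label-recovery oracle: it is a plain substring scan,
    independent of any indexing used elsewhere.
    """
    hits = []
    rc = revcomp(seq)
    for contig, ref in genome.contigs.items():
        for query, strand in ((seq, "+"), (rc, "-")):
            start = ref.find(query)
            while start != -1:
                hits.append((contig, start, strand))
                start = ref.find(query, start + 1)
    return hits


def _source_intervals(genome: ToyGenome, name: str) -> list[tuple[str, int, int, str]]:
    """Genomic intervals a profile entry draws reads from (TE copies or a cluster)."""
    if name in genome.te_library:
        copies = genome.copies_of(name)
        if not copies:
            raise UnknownFamilyError(f"family {name} has no genomic copies")
        return [(c.contig, c.start, c.end, c.strand) for c in copies]
    for cluster in genome.clusters:
        if cluster.cluster_id == name:
            return [(cluster.contig, cluster.start, cluster.end, "+")]
    raise UnknownFamilyError(name)


def simulate_smallrna_library(
    genome: ToyGenome,
    truth: TruthTable,
    n_reads: int | None = None,
    seed: int = 0,
    first_nt_a: Mapping[int, float] | None = None,
) -> tuple[list[tuple[str, str]], list[AlignedRead]]:
    """Simulate a small-RNA library from ``truth.smallrna_profile``.

    Returns ``(reads, records)`` where ``reads`` are (name, sequence) pairs
    and ``records`` contain one alignment per exact genomic occurrence (the
    first occurrence is primary, the rest secondary), giving multi-mapper
    structure for free whenever copies share sequence.

    ``n_reads`` resamples the profile to that total (multinomially);
    ``None`` uses profile counts literally.  ``first_nt_a`` maps a read size
    to the desired fraction of reads starting with 5'-A at that size.
    """
    truth.validate(genome)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5124]))

    keys = sorted(truth.smallrna_profile)
    counts = np.array([truth.smallrna_profile[k] for k in keys], dtype=float)
    if n_reads is not None:
        if counts.sum() <= 0:
            raise ValueError("profile is empty")
        counts = rng.multinomial(n_reads, counts / counts.sum())
    counts = counts.astype(int)

    reads: list[tuple[str, str]] = []
    records: list[AlignedRead] = []
    serial = 0
    for (name, size, strand), count in zip(keys, counts):
        if count == 0:
            continue
        if not 18 <= size <= 30:
            raise ValueError(f"profile size {size} outside 18-30")
        sources = _source_intervals(genome, name)
        want_a_frac = None if first_nt_a is None else first_nt_a.get(size)
        for _ in range(count):
            want_a = None if want_a_frac is None else bool(rng.random() < want_a_frac)
            seq = None
            for _ in range(200):
                contig, s0, e0, src_strand = sources[rng.integers(len(sources))]
                if e0 - s0 < size:
                    continue
                off = int(rng.integers(s0, e0 - size + 1))
                sub = genome.contigs[contig][off:off + size]
                oriented = sub if src_strand == "+" else revcomp(sub)
                candidate = oriented if strand == SENSE else revcomp(oriented)
                if want_a is None or (candidate[0] == "A") == want_a:
                    seq = candidate
                    break
            if seq is None:
                seq = candidate  # composition target unreachable; take last draw
            serial += 1
            qname = f"sr{serial}"
            reads.append((qname, seq))
            hits = exhaustive_align(genome, seq)
            for i, (hc, hp, hs) in enumerate(hits):
                stored = seq if hs == "+" else revcomp(seq)
                records.append(AlignedRead(
                    qname=qname, seq=stored, ref=hc, pos=hp, strand=hs,
                    cigar=f"{size}M", score=0, is_secondary=(i > 0),
                    tags={"ZF": name, "ZO": strand, "ZT": "smallrna"},
                ))
    return reads, records


# ---------------------------------------------------------------------------
# WGS library (planted insertions + chimeric artefacts)
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    start: int   # fragment/donor coordinate
    end: int
    kind: str    # "genome" | "te"
    ref: str | None      # contig for genome segments
    ref_pos: int         # reference coordinate of segment start (genome segments)
    family: str | None = None


class _SegmentMap:
    """Maps donor/fragment coordinates back to reference alignments."""

    def __init__(self, segments: list[_Segment], seq: str):
        self.segments = segments
        self.seq = seq
        self._starts = [s.start for s in segments]

    def _segment_at(self, pos: int) -> _Segment:
        return self.segments[bisect_right(self._starts, pos) - 1]

    def classify(self, a: int, b: int, min_anchor: int) -> tuple[str | None, int, str, str | None]:
        """Classify read interval [a, b) of the donor.

        Returns (ref, pos, cigar, te_family_touched).  ``ref is None`` means
        unmapped.  A read overlaps at most one genome/TE junction by
        construction (TE inserts are longer than a read).
        """
        length = b - a
        first = self._segment_at(a)
        last = self._segment_at(b - 1)
        if first is last:
            if first.kind == "genome":
                return first.ref, first.ref_pos + (a - first.start), f"{length}M", None
            return None, -1, "", first.family
        # junction read: one genome side, one TE side
        if first.kind == "genome":
            g = first.end - a
            fam = last.family
            if g < min_anchor:
                return None, -1, "", fam
            return first.ref, first.ref_pos + (a - first.start), f"{g}M{length - g}S", fam
        g = b - last.start
        fam = first.family
        if g < min_anchor:
            return None, -1, "", fam
        return last.ref, last.ref_pos, f"{length - g}S{g}M", fam


def _donor_for_contig(genome: ToyGenome, contig: str,
                      insertions: list[PlantedInsertion]) -> _SegmentMap:
    ref = genome.contigs[contig]
    segments: list[_Segment] = []
    pieces: list[str] = []
    cursor_ref = 0
    cursor_donor = 0
    for ins in sorted(insertions, key=lambda i: i.pos):
        glen = ins.pos - cursor_ref
        segments.append(_Segment(cursor_donor, cursor_donor + glen, "genome", contig, cursor_ref))
        pieces.append(ref[cursor_ref:ins.pos])
        cursor_donor += glen
        te_seq = genome.te_library[ins.family]
        if ins.strand == "-":
            te_seq = revcomp(te_seq)
        segments.append(_Segment(cursor_donor, cursor_donor + len(te_seq), "te", None, -1, ins.family))
        pieces.append(te_seq)
        cursor_donor += len(te_seq)
        cursor_ref = ins.pos
    segments.append(_Segment(cursor_donor, cursor_donor + len(ref) - cursor_ref, "genome", contig, cursor_ref))
    pieces.append(ref[cursor_ref:])
    return _SegmentMap(segments, "".join(pieces))


def _emit_pair(records: list[AlignedRead], qname: str, smap: _SegmentMap,
               s: int, f: int, read_len: int, min_anchor: int, truth_tag: str,
               fam_hint: str | None) -> None:
    """Emit the two mates of fragment [s, s+f) against ``smap``."""
    intervals = [(s, s + read_len, "+"), (s + f - read_len, s + f, "-")]
    sides = []
    for a, b, strand in intervals:
        ref, pos, cigar, fam = smap.classify(a, b, min_anchor)
        sides.append((ref, pos, cigar, fam, strand, smap.seq[a:b]))
    for i, (ref, pos, cigar, fam, strand, seq) in enumerate(sides):
        oref, opos, _, ofam, ostrand, _ = sides[1 - i]
        tag_fam = fam or ofam or fam_hint
        tags = {"ZT": truth_tag if (fam or ofam) else "background"}
        if tag_fam:
            tags["ZF"] = tag_fam
        mate_unmapped = oref is None
        record = AlignedRead(
            qname=qname, seq=seq, ref=ref, pos=pos, strand=strand, cigar=cigar,
            score=0, is_paired=True, is_read1=(i == 0),
            mate_ref=oref if not mate_unmapped else ref,
            mate_pos=opos if not mate_unmapped else pos,
            mate_unmapped=mate_unmapped, mate_strand=ostrand, tags=tags,
        )
        if ref is None:
            record.mate_ref = oref
            record.mate_pos = opos
            record.cigar = ""
            record.pos = -1
        records.append(record)


def simulate_wgs_library(
    genome: ToyGenome,
    truth: TruthTable,
    coverage: float,
    read_len: int = 100,
    insert_mean: int = 500,
    insert_sd: int = 50,
    seed: int = 0,
    min_anchor: int = 20,
) -> list[AlignedRead]:
    """Simulate a paired-end genomic library as alignment records.

    Fragments spanning a planted breakpoint yield soft-clipped alignments
    (clipped tail = TE sequence, clip coordinate = breakpoint) and OEA pairs
    (TE-interior mate unmapped).  Artefactual TE-genome chimeras are added at
    ``truth.chimera_rate`` expected fragments per genomic TE copy per fold of
    coverage, with the TE-side junction uniform along the consensus (no
    preference for TE ends).  Truth tags: ``ZT`` in {background,
    real_junction, artefact}, ``ZF`` family.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if insert_mean < 2 * read_len:
        raise GeometryError("insert_mean must be at least twice the read length")
    truth.validate(genome)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3965]))

    nuclear = genome.nuclear_contigs()
    by_contig: dict[str, list[PlantedInsertion]] = {name: [] for name in nuclear}
    for ins in truth.planted_insertions:
        by_contig[ins.contig].append(ins)
    donors = {name: _donor_for_contig(genome, name, inss) for name, inss in by_contig.items()}

    records: list[AlignedRead] = []
    names = list(donors)
    lengths = np.array([len(donors[n].seq) for n in names], dtype=float)
    total = lengths.sum()
    n_frag = int(round(coverage * total / (2 * read_len)))
    contig_choice = rng.choice(len(names), size=n_frag, p=lengths / total)
    frag_lens = np.maximum(2 * read_len + 10, np.round(rng.normal(insert_mean, insert_sd, n_frag)).astype(int))
    for i in range(n_frag):
        smap = donors[names[contig_choice[i]]]
        f = int(min(frag_lens[i], len(smap.seq) - 1))
        s = int(rng.integers(0, len(smap.seq) - f))
        _emit_pair(records, f"wg{i}", smap, s, f, read_len, min_anchor, "real_junction", None)

    # artefactual chimeras, one synthetic 2-segment fragment each
    serial = 0
    for copy in genome.te_copies:
        n_chim = rng.poisson(truth.chimera_rate * coverage)
        consensus = genome.te_library[copy.family]
        for _ in range(n_chim):
            serial += 1
            f = max(2 * read_len + 10, int(round(rng.normal(insert_mean, insert_sd))))
            contig = names[rng.integers(len(names))]
            ref = nuclear[contig]
            u = int(rng.integers(read_len // 2, f - read_len // 2))  # junction offset in fragment
            j = int(rng.integers(0, len(consensus)))                # TE-side junction, uniform
            te_strand = "+" if rng.random() < 0.5 else "-"
            cons = consensus if te_strand == "+" else revcomp(consensus)
            genome_left = rng.random() < 0.5
            if genome_left:
                g, t = u, f - u
                te_part = cons[j:j + t]
                gpos = int(rng.integers(g, len(ref) - 1))
                gpart = ref[gpos - g:gpos]
                seq = gpart + te_part
                segments = [
                    _Segment(0, g, "genome", contig, gpos - g),
                    _Segment(g, len(seq), "te", None, -1, copy.family),
                ]
            else:
                g, t = f - u, u
                te_part = cons[max(0, j - t):j]
                t = len(te_part)
                gpos = int(rng.integers(0, len(ref) - g))
                gpart = ref[gpos:gpos + g]
                seq = te_part + gpart
                segments = [
                    _Segment(0, t, "te", None, -1, copy.family),
                    _Segment(t, len(seq), "genome", contig, gpos),
                ]
            smap = _SegmentMap(segments, seq)
            f_eff = len(seq)
            if f_eff < 2 * read_len:
                continue
            _emit_pair(records, f"chim{serial}", smap, 0, f_eff, read_len, min_anchor,
                       "artefact", copy.family)
    return records


# ---------------------------------------------------------------------------
# Mobilome library
# ---------------------------------------------------------------------------


def simulate_mobilome_library(
    genome: ToyGenome,
    truth: TruthTable,
    n_reads: int,
    seed: int = 0,
    mt_background: int = 1_000,
    background_genomic: int = 0,
    read_len: int = 250,
    circle_wrap: bool = True,
) -> list[AlignedRead]:
    """Simulate a mobilome (eccDNA) library as alignment records.

    ``n_reads`` TE-circle reads are distributed across families in proportion
    to ``truth.planted_circles`` copy counts and aligned to the canonical TE
    contigs (reads crossing the circle junction are soft-clipped when
    ``circle_wrap``; with ``circle_wrap=False`` circles are sampled as if
    linearized, a stand-in for junction structures that do not recreate a
    contiguous consensus ring).  ``mt_background`` reads come from the
    mitochondrial contig and ``background_genomic`` reads from random nuclear
    positions.  Mates are emitted as independent single-end records.
    """
    truth.validate(genome)
    if mt_background == 0:
        warnings.warn("no mtDNA background requested; normalization will be impossible",
                      NormalizationImpossibleWarning, stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xECC]))

    records: list[AlignedRead] = []
    fams = sorted(truth.planted_circles)
    weights = np.array([truth.planted_circles[f] for f in fams], dtype=float)
    serial = 0
    if weights.sum() > 0 and n_reads > 0:
        alloc = rng.multinomial(n_reads, weights / weights.sum())
        for fam, count in zip(fams, alloc):
            consensus = genome.te_library[fam]
            L = len(consensus)
            doubled = consensus + consensus
            for _ in range(count):
                serial += 1
                if circle_wrap:
                    start = int(rng.integers(0, L))
                    seq = doubled[start:start + read_len]
                    m = min(read_len, L - start)
                    cigar = f"{m}M" if m == read_len else f"{m}M{read_len - m}S"
                else:
                    start = int(rng.integers(0, max(1, L - read_len)))
                    seq = consensus[start:start + read_len]
                    cigar = f"{len(seq)}M"
                strand = "+" if rng.random() < 0.5 else "-"
                records.append(AlignedRead(
                    qname=f"mb{serial}", seq=seq, ref=fam, pos=start, strand=strand,
                    cigar=cigar, score=0, tags={"ZT": "circle", "ZF": fam},
                ))
    mt_seq = genome.contigs[genome.mt_contig]
    for _ in range(mt_background):
        serial += 1
        start = int(rng.integers(0, len(mt_seq) - read_len))
        records.append(AlignedRead(
            qname=f"mb{serial}", seq=mt_seq[start:start + read_len],
            ref=genome.mt_contig, pos=start, strand="+", cigar=f"{read_len}M",
            score=0, tags={"ZT": "mt"},
        ))
    nuclear = genome.nuclear_contigs()
    names = list(nuclear)
    for _ in range(background_genomic):
        serial += 1
        contig = names[rng.integers(len(names))]
        ref = nuclear[contig]
        start = int(rng.integers(0, len(ref) - read_len))
        records.append(AlignedRead(
            qname=f"mb{serial}", seq=ref[start:start + read_len], ref=contig,
            pos=start, strand="+", cigar=f"{read_len}M", score=0,
            tags={"ZT": "background"},
        ))
    return records


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def reference_lengths(genome: ToyGenome, include_canonical: bool = False) -> dict[str, int]:
    lengths = {name: len(seq) for name, seq in genome.contigs.items()}
    if include_canonical:
        lengths.update({fam: len(seq) for fam, seq in genome.te_library.items()})
    return lengths


def write_genome(genome: ToyGenome, outdir: str | Path) -> None:
    """Write the toy genome as FASTA + BED6 annotation files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "genome.fa", genome.contigs)
    write_fasta(outdir / "te_library.fa", genome.te_library)
    write_bed(outdir / "te_copies.bed",
              [(c.contig, c.start, c.end, c.family, 0, c.strand) for c in genome.te_copies])
    write_bed(outdir / "clusters.bed",
              [(c.contig, c.start, c.end, f"{c.cluster_id}|{c.klass}", 0, "+") for c in genome.clusters])
    write_bed(outdir / "features.bed",
              [(f.contig, f.start, f.end, f.klass, 0, f.strand) for f in genome.features])
    with open(outdir / "mt_contig.txt", "w") as fh:
        fh.write(genome.mt_contig + "\n")


def load_genome(outdir: str | Path) -> ToyGenome:
    """Load a genome previously written by :func:`write_genome`."""
    from .core import read_bed, read_fasta

    outdir = Path(outdir)
    contigs = read_fasta(outdir / "genome.fa")
    te_library = read_fasta(outdir / "te_library.fa")
    te_copies = [TECopy(name, contig, start, end, strand)
                 for contig, start, end, name, _, strand in read_bed(outdir / "te_copies.bed")]
    clusters = []
    for contig, start, end, name, _, _ in read_bed(outdir / "clusters.bed"):
        cid, klass = name.split("|")
        clusters.append(ClusterAnnot(cid, contig, start, end, klass))
    features = [FeatureAnnot(name, contig, start, end, strand)
                for contig, start, end, name, _, strand in read_bed(outdir / "features.bed")]
    mt_contig = (outdir / "mt_contig.txt").read_text().strip()
    return ToyGenome(contigs, te_library, te_copies, clusters, features, mt_contig)


def write_truth(truth: TruthTable, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(i.family, i.contig, i.pos, i.strand) for i in truth.planted_insertions],
        columns=["family", "contig", "pos", "strand"],
    ).to_csv(outdir / "planted_insertions.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.planted_circles.items()), columns=["family", "copies"]) \
        .to_csv(outdir / "planted_circles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(f, s, o, c) for (f, s, o), c in sorted(truth.smallrna_profile.items())],
        columns=["family", "size", "strand", "count"],
    ).to_csv(outdir / "smallrna_profile.tsv", sep="\t", index=False)
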