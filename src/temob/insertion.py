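"""De novo TE insertion calling from paired-end genomic alignments.

Evidence comes from two read classes: soft-clipped alignments (the clipped
tail may span a TE-genome junction) and one-end-anchored (OEA) pairs (the
unmapped mate may derive from inserted TE sequence).  Evidence is clustered
by anchor position (single linkage), each cluster's query sequences are
locally aligned against a library of TE terminal segments, and a second
clustering step over the assigned clusters defines the insertion breakpoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .core import AlignedRead, group_by_qname, revcomp


@dataclass(frozen=True)
class Evidence:
    kind: str            # "soft_clip" | "oea"
    contig: str
    anchor_pos: int      # clip coordinate (soft_clip) or inner anchor edge (oea)
    anchor_strand: str
    query_seq: str       # clipped tail or unmapped mate, reference-forward
    qname: str
    clip_side: str | None = None  # "left" | "right" for soft_clip


@dataclass
class TEEndLibrary:
    """Terminal segments of canonical TE sequences used for junction matching.

    Entries are built from the first/last ``end_len`` bases of each
    consensus, then truncated to ``effective_len_cap`` (an insert-size
    restriction that keeps matches near the true TE ends and disfavors
    interior chimeric junctions).
    """

    entries: list[tuple[str, str, str]]  # (family, "5p"|"3p", sequence)
    end_len: int = 600
    effective_len_cap: int = 500

    @classmethod
    def from_consensus(cls, te_library: Mapping[str, str],
                       end_len: int = 600, effective_len_cap: int = 500) -> "TEEndLibrary":
        entries = []
        for family, seq in te_library.items():
            five = seq[:end_len][:effective_len_cap]
            three = seq[-end_len:][-effective_len_cap:]
            entries.append((family, "5p", five))
            entries.append((family, "3p", three))
        return cls(entries, end_len, effective_len_cap)


@dataclass
class CallerConfig:
    min_clip: int = 20
    min_query: int = 20
    cluster_window: int = 1_000     # ~2x insert size
    second_window: int = 50
    min_support: int = 2
    identity_threshold: float = 0.9
    min_hit_len: int = 20
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    max_queries_per_cluster: int = 40  # cap on sequences aligned per cluster
    end_len: int = 600
    effective_len_cap: int = 500


@dataclass
class EvidenceCluster:
    contig: str
    evidence: list[Evidence]
    # filled by match_te_ends:
    family: str | None = None
    te_end: str | None = None
    ambiguous: bool = False
    family_scores: dict[str, float] = field(default_factory=dict)
    mean_identity: float = 0.0

    @property
    def start(self) -> int:
        return min(e.anchor_pos for e in self.evidence)

    @property
    def end(self) -> int:
        return max(e.anchor_pos for e in self.evidence)

    @property
    def support(self) -> int:
        return len(self.evidence)


@dataclass
class InsertionCall:
    family: str
    contig: str
    breakpoint: int
    te_end: str | None
    support_sc: int
    support_oea: int
    mean_match_score: float

    @property
    def support(self) -> int:
        return self.support_sc + self.support_oea


def extract_evidence(alignments: Iterable[AlignedRead],
                     cfg: CallerConfig | None = None) -> list[Evidence]:
    """Soft-clip and OEA evidence from primary paired-end alignments.

    Soft clips of at least ``min_clip`` on either side of a primary mapped
    record become soft_clip evidence anchored at the clip coordinate.  Pairs
    with exactly one mapped mate contribute OEA evidence anchored at the
    mapped mate's inner edge, with the unmapped mate as query.  Query
    sequences shorter than ``min_query`` are discarded.
    """
    cfg = cfg or CallerConfig()
    evidence: list[Evidence] = []
    paired_seen = False
    for qname, records in group_by_qname(alignments):
        primaries = [r for r in records if not r.is_secondary]
        paired_seen = paired_seen or any(r.is_paired for r in primaries)
        for rec in primaries:
            if rec.is_unmapped:
                continue
            if rec.left_clip >= cfg.min_clip and rec.left_clip >= cfg.min_query:
                evidence.append(Evidence(
                    "soft_clip", rec.ref, rec.pos, rec.strand,
                    rec.clipped_seq("left"), qname, clip_side="left"))
            if rec.right_clip >= cfg.min_clip and rec.right_clip >= cfg.min_query:
                evidence.append(Evidence(
                    "soft_clip", rec.ref, rec.ref_end, rec.strand,
                    rec.clipped_seq("right"), qname, clip_side="right"))
        mapped = [r for r in primaries if not r.is_unmapped]
        unmapped = [r for r in primaries if r.is_unmapped]
        if len(primaries) == 2 and len(mapped) == 1 and len(unmapped) == 1:
            anchor, mate = mapped[0], unmapped[0]
            if len(mate.seq) >= cfg.min_query:
                anchor_pos = anchor.ref_end if anchor.strand == "+" else anchor.pos
                evidence.append(Evidence(
                    "oea", anchor.ref, anchor_pos, anchor.strand, mate.seq, qname))
    if not paired_seen:
        import warnings

        warnings.warn("input looks single-end; OEA evidence cannot be extracted", stacklevel=2)
    return evidence


def cluster_evidence(evidence: Sequence[Evidence], cluster_window: int,
                     min_support: int = 1) -> list[EvidenceCluster]:
    """Single-linkage positional clustering of evidence anchors.

    Consecutive anchors on the same contig at most ``cluster_window`` apart
    join the same cluster; clusters with support below ``min_support`` are
    dropped.
    """
    ordered = sorted(evidence, key=lambda e: (e.contig, e.anchor_pos))
    clusters: list[EvidenceCluster] = []
    current: list[Evidence] = []
    for ev in ordered:
        if current and (ev.contig != current[-1].contig
                        or ev.anchor_pos - current[-1].anchor_pos > cluster_window):
            clusters.append(EvidenceCluster(current[0].contig, current))
            current = []
        current.append(ev)
    if current:
        clusters.append(EvidenceCluster(current[0].contig, current))
    return [c for c in clusters if c.support >= min_support]


def _make_aligner(cfg: CallerConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap
    aligner.extend_gap_score = cfg.gap
    return aligner


def _best_local(aligner: Align.PairwiseAligner, query: str, target: str) -> tuple[float, float, int]:
    """(score, identity, aligned-length) of the best local alignment, trying both strands."""
    best = (float("-inf"), 0.0, 0)
    for q in (query, revcomp(query)):
        alignments = aligner.align(q, target)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        aligned = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / aligned if aligned else 0.0
        if aln.score > best[0]:
            best = (float(aln.score), identity, counts.identities + counts.mismatches)
    return best


def match_te_ends(cluster: EvidenceCluster, lib: TEEndLibrary,
                  cfg: CallerConfig | None = None) -> EvidenceCluster:
    """Assign a cluster to a TE family by local alignment of its queries.

    Each query is aligned against every library entry (local alignment,
    default scoring +1/-1/-2 as a BLAT stand-in).  Hits must reach
    ``identity_threshold`` over at least ``min_hit_len`` aligned bases.  The
    cluster is assigned to the family with the highest total hit score;
    exact ties leave the cluster flagged ambiguous.
    """
    cfg = cfg or CallerConfig()
    if not lib.entries:
        raise ValueError("empty TE end library")
    aligner = _make_aligner(cfg)
    family_scores: Counter = Counter()
    end_scores: Counter = Counter()
    identities: list[float] = []
    queries = cluster.evidence
    if len(queries) > cfg.max_queries_per_cluster:
        # deterministic even subsample; soft clips first (they carry the junction)
        ranked = sorted(queries, key=lambda e: (e.kind != "soft_clip", e.qname))
        queries = ranked[: cfg.max_queries_per_cluster]
    for ev in queries:
        if not ev.query_seq:
            continue
        # per-family best hit for this query; every passing family is credited
        per_family: dict[str, tuple[float, str, float]] = {}
        for family, end, entry_seq in lib.entries:
            score, identity, hit_len = _best_local(aligner, ev.query_seq, entry_seq)
            if identity >= cfg.identity_threshold and hit_len >= cfg.min_hit_len:
                if family not in per_family or score > per_family[family][0]:
                    per_family[family] = (score, end, identity)
        for family, (score, end, identity) in per_family.items():
            family_scores[family] += score
            end_scores[(family, end)] += score
            identities.append(identity)
    cluster.family_scores = dict(family_scores)
    cluster.mean_identity = sum(identities) / len(identities) if identities else 0.0
    if not family_scores:
        cluster.family, cluster.ambiguous = None, False
        return cluster
    ranked = family_scores.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        cluster.family, cluster.ambiguous = None, True
        return cluster
    family = ranked[0][0]
    cluster.family = family
    cluster.ambiguous = False
    ends = [(score, end) for (fam, end), score in end_scores.items() if fam == family]
    cluster.te_end = max(ends)[1] if ends else None
    return cluster


def _breakpoint_of(evidence: Sequence[Evidence]) -> int:
    """Modal soft-clip coordinate; OEA-only clusters use the inner anchor edges."""
    clips = [e.anchor_pos for e in evidence if e.kind == "soft_clip"]
    if clips:
        counts = Counter(clips)
        top = max(counts.values())
        return min(pos for pos, n in counts.items() if n == top)
    fw = [e.anchor_pos for e in evidence if e.anchor_strand == "+"]
    rv = [e.anchor_pos for e in evidence if e.anchor_strand == "-"]
    if fw and rv:
        return (max(fw) + min(rv)) // 2
    return max(fw) if fw else min(rv)


def call_breakpoints(clusters: Iterable[EvidenceCluster],
                     cfg: CallerConfig | None = None) -> list[InsertionCall]:
    """Second clustering step: merge same-family clusters and define breakpoints."""
    cfg = cfg or CallerConfig()
    assigned = [c for c in clusters if c.family and not c.ambiguous]
    assigned.sort(key=lambda c: (c.family, c.contig, _breakpoint_of(c.evidence)))
    calls: list[InsertionCall] = []
    group: list[EvidenceCluster] = []

    def flush(group: list[EvidenceCluster]) -> None:
        evidence = [e for c in group for e in c.evidence]
        bp = _breakpoint_of(evidence)
        sc = sum(1 for e in evidence if e.kind == "soft_clip")
        oea = len(evidence) - sc
        score_total = sum(sum(c.family_scores.values()) for c in group)
        te_end = Counter(c.te_end for c in group if c.te_end).most_common(1)
        calls.append(InsertionCall(
            family=group[0].family, contig=group[0].contig, breakpoint=bp,
            te_end=te_end[0][0] if te_end else None,
            support_sc=sc, support_oea=oea,
            mean_match_score=score_total / len(evidence) if evidence else 0.0,
        ))

    prev_bp = None
    for cluster in assigned:
        bp = _breakpoint_of(cluster.evidence)
        if group and (cluster.family != group[-1].family or cluster.contig != group[-1].contig
                      or bp - prev_bp > cfg.second_window):
            flush(group)
            group = []
        group.append(cluster)
        prev_bp = bp
    if group:
        flush(group)
    return calls


def call_insertions(alignments: Iterable[AlignedRead], te_library: Mapping[str, str],
                    cfg: CallerConfig | None = None) -> list[InsertionCall]:
    """Full pipeline: evidence -> clusters -> TE-end matching -> breakpoint calls."""
    cfg = cfg or CallerConfig()
    lib = TEEndLibrary.from_consensus(te_library, cfg.end_len, cfg.effective_len_cap)
    evidence = extract_evidence(alignments, cfg)
    clusters = cluster_evidence(evidence, cfg.cluster_window, cfg.min_support)
    matched = [match_te_ends(c, lib, cfg) for c in clusters]
    return call_breakpoints(matched, cfg)
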