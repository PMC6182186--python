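"""eccDNA (mobilome) read quantification.

Reads whose best-score alignment lands in a genomic TE copy or a canonical
TE contig are retained as TE reads, re-aligned against the canonical TE
sequences only, filtered by a score floor (alignments scoring strictly below
the floor are discarded), down-weighted 1/k over ex-aequo best assignments
and finally normalized per thousand mitochondrial reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .core import AlignedRead, group_by_qname, revcomp
from .synthetic import ToyGenome


class FormatError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


def uniform_weights(alignments: list[AlignedRead]) -> dict[str, float]:
    """Default ex-aequo strategy: each of the k tied locations gets 1/k."""
    weights: Counter = Counter()
    for aln in alignments:
        weights[aln.ref] += 1.0 / len(alignments)
    return dict(weights)


@dataclass
class MobilomeConfig:
    score_floor: int = -10           # alignments scoring strictly lower are discarded
    norm_unit: float = 1_000.0       # reads per thousand mtDNA reads
    max_alignments_considered: int = 10
    weight_strategy: Callable[[list[AlignedRead]], dict[str, float]] = uniform_weights

    def __post_init__(self):
        if self.score_floor > 0:
            raise ValueError("score floor must be <= 0 under the 0-is-perfect convention")


def assign_te_reads(
    alignments: Iterable[AlignedRead],
    genome: ToyGenome,
) -> tuple[list[AlignedRead], int]:
    """Keep reads with >=1 best-score alignment in a TE copy or canonical TE.

    Input alignments are against the combined genome + canonical-TE universe.
    Returns (records of retained reads, number of rejected reads).
    """
    te_index = genome.te_copy_index()
    canonical = set(genome.te_library)
    retained: list[AlignedRead] = []
    rejected = 0
    for qname, records in group_by_qname(alignments):
        mapped = [r for r in records if not r.is_unmapped]
        if not mapped:
            rejected += 1
            continue
        if any("no_AS" in r.tags for r in mapped):
            raise FormatError(f"read {qname} lacks an alignment score (AS tag)")
        best = max(r.score for r in mapped)
        best_alns = [r for r in mapped if r.score == best]
        is_te = any(
            aln.ref in canonical or te_index.overlapping(aln.ref, aln.pos, aln.ref_end)
            for aln in best_alns
        )
        if is_te:
            retained.extend(records)
        else:
            rejected += 1
    return retained, rejected


def remap_canonical(
    reads: Iterable[AlignedRead],
    te_library: Mapping[str, str],
    circular: bool = True,
) -> list[AlignedRead]:
    """Second-pass alignment of reads against canonical TE sequences only.

    Exact substring search on both strands; with ``circular`` the consensus
    is doubled so reads spanning a circle junction still match.  One record
    per hit family (a family is hit at most once per read).
    """
    seen: dict[str, str] = {}
    for rec in reads:
        if rec.qname not in seen:
            seen[rec.qname] = rec.seq if rec.strand == "+" else revcomp(rec.seq)
    out: list[AlignedRead] = []
    for qname, seq in seen.items():
        first = True
        for family, consensus in te_library.items():
            target = consensus + consensus if circular else consensus
            hit_pos, hit_strand = None, None
            for query, strand in ((seq, "+"), (revcomp(seq), "-")):
                pos = target.find(query)
                if pos != -1 and pos < len(consensus):
                    hit_pos, hit_strand = pos, strand
                    break
            if hit_pos is not None:
                out.append(AlignedRead(
                    qname=qname, seq=seq, ref=family, pos=hit_pos, strand=hit_strand,
                    cigar=f"{len(seq)}M", score=0, is_secondary=not first,
                ))
                first = False
    return out


def family_counts(
    te_alignments: Iterable[AlignedRead],
    cfg: MobilomeConfig | None = None,
) -> tuple[pd.Series, int]:
    """Weighted per-family counts from canonical-TE alignments.

    Alignments scoring strictly below ``cfg.score_floor`` are discarded; a
    read with k surviving ex-aequo best-score alignments contributes 1/k to
    each family (default strategy), so weights sum to the number of retained
    reads.  Returns (weights, dropped-read count).
    """
    cfg = cfg or MobilomeConfig()
    weights: Counter = Counter()
    dropped = 0
    for qname, records in group_by_qname(te_alignments):
        surviving = [r for r in records if not r.is_unmapped and r.score >= cfg.score_floor]
        surviving.sort(key=lambda r: -r.score)
        surviving = surviving[: cfg.max_alignments_considered]
        if not surviving:
            dropped += 1
            continue
        best = surviving[0].score
        best_alns = [r for r in surviving if r.score == best]
        for family, weight in cfg.weight_strategy(best_alns).items():
            weights[family] += weight
    series = pd.Series(dict(weights), dtype=float).sort_index()
    series.name = "weighted_count"
    return series, dropped


def count_mt_reads(alignments: Iterable[AlignedRead], mt_contig: str) -> int:
    """Reads whose best-score alignment is on the mitochondrial contig."""
    n = 0
    for _, records in group_by_qname(alignments):
        mapped = [r for r in records if not r.is_unmapped]
        if not mapped:
            continue
        best = max(r.score for r in mapped)
        if any(r.ref == mt_contig for r in mapped if r.score == best):
            n += 1
    return n


def normalize_mt(counts: pd.Series, mt_read_count: int, norm_unit: float = 1_000.0) -> pd.Series:
    """Counts per ``norm_unit`` (default: per thousand) mitochondrial reads."""
    if mt_read_count <= 0:
        raise NormalizationError("mtDNA read count must be > 0 for normalization")
    out = counts * norm_unit / mt_read_count
    out.name = "normalized_count"
    return out


def compare_conditions(
    norm_a: pd.Series,
    norm_b: pd.Series,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-family (norm_a, norm_b, fold) table; high-fold families flagged.

    Families absent from both conditions appear with zeros, an undefined
    (NaN) fold, and are never flagged.
    """
    families = sorted(set(norm_a.index) | set(norm_b.index))
    a = norm_a.reindex(families).fillna(0.0)
    b = norm_b.reindex(families).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where((a == 0) & (b == 0), np.nan, a / b)
    table = pd.DataFrame({"norm_a": a, "norm_b": b, "fold": fold})
    table["flagged"] = (table["fold"] >= fold_threshold) | ((b == 0) & (a > 0))
    table.index.name = "family"
    return table
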