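"""Small-RNA (piRNA/siRNA) classification, counting and normalization.

Pipeline stages, mirroring a standard ovary small-RNA analysis:

1. :func:`trim_and_select` — 3' linker removal and 18-30 nt size selection;
2. :func:`annotate` — genomic annotation of best-score alignments
   (rRNA/miRNA exclusion, non-exclusive cluster/TE/3'UTR labels,
   unique-mapper flagging);
3. :func:`assign_families` / :func:`classify` — re-assignment of candidates
   against canonical TE sequences, then partition into piRNA candidates
   (23-30 nt) and siRNA candidates (21 nt);
4. :func:`count_and_normalize` — fractional (1/k) per-family counting
   normalized to the unique mappers of the germline normalizer cluster
   ("cluster1");
5. :func:`size_distribution`, :func:`first_nt_bias`, :func:`fold_change` —
   the derived summary statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignedRead, group_by_qname, revcomp
from .synthetic import ANTISENSE, SENSE, ToyGenome


class NormalizationError(ValueError):
    """Normalizer count is zero or missing; refusing to divide silently."""


@dataclass
class ClassifierConfig:
    trim_min: int = 18
    trim_max: int = 30
    pirna_min: int = 23
    pirna_max: int = 30
    sirna_len: int = 21
    excluded_classes: frozenset[str] = frozenset({"rRNA", "miRNA"})
    max_mismatches: int = 0  # mismatch tolerance of the canonical re-assignment
    scale: float = 1e6

    def __post_init__(self):
        if not (self.trim_min <= self.pirna_min <= self.pirna_max <= self.trim_max):
            raise ValueError("piRNA size range must nest inside the trim range")
        if not self.trim_min <= self.sirna_len <= self.trim_max:
            raise ValueError("siRNA length must lie inside the trim range")


def trim_and_select(
    reads: Iterable[tuple[str, str]],
    cfg: ClassifierConfig | None = None,
    linker: str | None = None,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Strip a 3' linker (if given) and keep reads of length 18-30.

    Returns the retained (name, seq) pairs and a log of discarded reads by
    reason (``too_short`` / ``too_long``).
    """
    cfg = cfg or ClassifierConfig()
    retained: list[tuple[str, str]] = []
    log = {"too_short": 0, "too_long": 0, "no_linker": 0, "retained": 0}
    empty = True
    for name, seq in reads:
        empty = False
        if linker:
            idx = seq.find(linker)
            if idx != -1:
                seq = seq[:idx]
            else:
                log["no_linker"] += 1
        if len(seq) < cfg.trim_min:
            log["too_short"] += 1
        elif len(seq) > cfg.trim_max:
            log["too_long"] += 1
        else:
            retained.append((name, seq))
            log["retained"] += 1
    if empty:
        import warnings

        warnings.warn("trim_and_select received no reads", stacklevel=2)
    return retained, log


@dataclass
class AnnotatedRead:
    qname: str
    seq: str
    unique: bool
    # non-exclusive labels: (category, name, orientation)
    labels: list[tuple[str, str, str]] = field(default_factory=list)
    excluded: bool = False

    @property
    def size(self) -> int:
        return len(self.seq)


def annotate(
    alignments: Iterable[AlignedRead],
    genome: ToyGenome,
    cfg: ClassifierConfig | None = None,
) -> list[AnnotatedRead]:
    """Annotate each read from its best-score genomic alignments.

    Reads whose best-score alignments touch an excluded feature class
    (rRNA/miRNA by default) are marked ``excluded``.  Remaining reads carry
    every category they overlap — cluster, TE family, 3'UTR — with the
    orientation recorded relative to the annotated feature's strand.  A read
    is a unique mapper iff exactly one best-score alignment exists.
    """
    cfg = cfg or ClassifierConfig()
    te_index = genome.te_copy_index()
    cluster_index = genome.cluster_index()
    feature_index = genome.feature_index()
    contig_names = set(genome.contigs)

    annotated: list[AnnotatedRead] = []
    for qname, records in group_by_qname(alignments):
        for rec in records:
            if not rec.is_unmapped and rec.ref not in contig_names:
                raise ValueError(f"alignment reference {rec.ref!r} not in genome")
        mapped = [r for r in records if not r.is_unmapped]
        if not mapped:
            continue
        best = max(r.score for r in mapped)
        best_alns = [r for r in mapped if r.score == best]
        primary = best_alns[0]
        read_seq = primary.seq if primary.strand == "+" else revcomp(primary.seq)

        labels: list[tuple[str, str, str]] = []
        excluded = False
        for aln in best_alns:
            start, end = aln.pos, aln.ref_end
            for _, _, feat in feature_index.overlapping(aln.ref, start, end):
                if feat.klass in cfg.excluded_classes:
                    excluded = True
                elif feat.klass == "3UTR":
                    orient = SENSE if aln.strand == feat.strand else ANTISENSE
                    labels.append(("3UTR", feat.klass, orient))
            for _, _, clu in cluster_index.overlapping(aln.ref, start, end):
                orient = SENSE if aln.strand == "+" else ANTISENSE
                labels.append(("cluster", clu.cluster_id, orient))
            for _, _, copy in te_index.overlapping(aln.ref, start, end):
                orient = SENSE if aln.strand == copy.strand else ANTISENSE
                labels.append(("TE", copy.family, orient))
        annotated.append(AnnotatedRead(
            qname=qname, seq=read_seq, unique=(len(best_alns) == 1),
            labels=sorted(set(labels)), excluded=excluded,
        ))
    return annotated


def cluster_unique_count(annotated: Iterable[AnnotatedRead], cluster_id: str = "cluster1") -> int:
    """Unique-mapper reads overlapping the normalizer cluster."""
    return sum(
        1 for r in annotated
        if r.unique and not r.excluded and any(cat == "cluster" and name == cluster_id
                                               for cat, name, _ in r.labels)
    )


@dataclass
class Candidate:
    """A classified small-RNA read with its canonical family assignments."""

    qname: str
    seq: str
    unique: bool
    families: list[tuple[str, str]]  # (family, orientation); len == k for 1/k counting

    @property
    def size(self) -> int:
        return len(self.seq)


def _scan_with_mismatches(query: str, target: str, max_mm: int) -> bool:
    n, m = len(query), len(target)
    if n > m:
        return False
    if max_mm <= 0:
        return query in target
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    for off in range(m - n + 1):
        if int((t[off:off + n] != q).sum()) <= max_mm:
            return True
    return False


def assign_families(
    annotated: Iterable[AnnotatedRead],
    te_library: Mapping[str, str],
    cfg: ClassifierConfig | None = None,
) -> list[Candidate]:
    """Re-assign annotated reads to families against canonical TE sequences.

    Per-family counting downstream uses this canonical assignment, not the
    genomic copy a read happened to align to.  Reads matching no canonical
    sequence (e.g. pure cluster reads) are dropped here.
    """
    cfg = cfg or ClassifierConfig()
    candidates = []
    for read in annotated:
        if read.excluded or not read.labels:
            continue
        assignments: list[tuple[str, str]] = []
        for family, consensus in te_library.items():
            if _scan_with_mismatches(read.seq, consensus, cfg.max_mismatches):
                assignments.append((family, SENSE))
            elif _scan_with_mismatches(revcomp(read.seq), consensus, cfg.max_mismatches):
                assignments.append((family, ANTISENSE))
        if assignments:
            candidates.append(Candidate(read.qname, read.seq, read.unique, assignments))
    return candidates


def classify(
    candidates: Iterable[Candidate],
    cfg: ClassifierConfig | None = None,
) -> tuple[list[Candidate], list[Candidate]]:
    """Partition candidates into (piRNA candidates, siRNA candidates).

    piRNA candidates have sizes in [pirna_min, pirna_max]; siRNA candidates
    are exactly ``sirna_len`` long.  The sets are disjoint.
    """
    cfg = cfg or ClassifierConfig()
    pirna = [c for c in candidates if cfg.pirna_min <= c.size <= cfg.pirna_max]
    sirna = [c for c in candidates if c.size == cfg.sirna_len]
    return pirna, sirna


def count_and_normalize(
    candidates: Sequence[Candidate],
    cluster1_unique_count: int,
    scale: float = 1e6,
    by_size: bool = False,
) -> pd.DataFrame:
    """Fractional per-(family, orientation[, size]) counts, normalized.

    A candidate with k ex-aequo family assignments contributes 1/k to each,
    so the table's raw column sums to the number of candidate reads.
    ``normalized = raw * scale / cluster1_unique_count``.
    """
    if cluster1_unique_count <= 0:
        raise NormalizationError("cluster1 unique-mapper count must be > 0")
    acc: Counter = Counter()
    for cand in candidates:
        k = len(cand.families)
        for family, orientation in cand.families:
            key = (family, orientation, cand.size) if by_size else (family, orientation)
            acc[key] += 1.0 / k
    if by_size:
        rows = [(f, o, s, raw) for (f, o, s), raw in sorted(acc.items())]
        table = pd.DataFrame(rows, columns=["family", "orientation", "size", "raw"])
    else:
        rows = [(f, o, raw) for (f, o), raw in sorted(acc.items())]
        table = pd.DataFrame(rows, columns=["family", "orientation", "raw"])
    table["normalized"] = table["raw"] * scale / cluster1_unique_count
    table.attrs["cluster1_unique_count"] = cluster1_unique_count
    table.attrs["scale"] = scale
    return table


def size_distribution(
    candidates: Iterable[Candidate],
    family: str,
    size_range: tuple[int, int] = (18, 30),
) -> pd.DataFrame:
    """13-bin (18-30 nt) x 2-strand table of fractional counts for a family."""
    lo, hi = size_range
    sizes = range(lo, hi + 1)
    table = pd.DataFrame(0.0, index=list(sizes), columns=[SENSE, ANTISENSE])
    table.index.name = "size"
    seen = False
    for cand in candidates:
        matches = [(f, o) for f, o in cand.families if f == family]
        if not matches:
            continue
        seen = True
        if not lo <= cand.size <= hi:
            continue
        k = len(cand.families)
        for _, orientation in matches:
            table.loc[cand.size, orientation] += 1.0 / k
    if not seen:
        raise KeyError(f"no candidates assigned to family {family!r}")
    return table


def first_nt_bias(candidates: Sequence[Candidate], cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """5' nucleotide fractions, reported per class (siRNA-sized vs piRNA-sized).

    Each class column sums to 1 (only classes with members are reported).
    """
    cfg = cfg or ClassifierConfig()
    if not candidates:
        raise ValueError("first_nt_bias of an empty candidate set is undefined")
    counts: dict[str, Counter] = {}
    for cand in candidates:
        if cand.size == cfg.sirna_len:
            klass = f"{cfg.sirna_len}nt"
        elif cfg.pirna_min <= cand.size <= cfg.pirna_max:
            klass = f"{cfg.pirna_min}-{cfg.pirna_max}nt"
        else:
            continue
        counts.setdefault(klass, Counter())[cand.seq[0]] += 1
    if not counts:
        raise ValueError("no candidates in the siRNA or piRNA size classes")
    table = pd.DataFrame(
        {klass: [cnt.get(nt, 0) for nt in "ACGT"] for klass, cnt in sorted(counts.items())},
        index=list("ACGT"),
    ).astype(float)
    return table / table.sum(axis=0)


def fold_change(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    pseudocount: float = 1.0,
    orientation: str | None = None,
) -> pd.DataFrame:
    """Per-family log2 fold changes of normalized counts (A over B).

    ``pseudocount`` is added to both normalized values before the ratio, so
    zero-count families yield finite fold changes; families present in only
    one table are treated as zero on the other side and flagged.
    """
    def collapse(table: pd.DataFrame) -> pd.Series:
        sub = table
        if orientation is not None:
            sub = sub[sub["orientation"] == orientation]
        return sub.groupby("family")["normalized"].sum()

    a, b = collapse(table_a), collapse(table_b)
    families = sorted(set(a.index) | set(b.index))
    na = a.reindex(families).fillna(0.0)
    nb = b.reindex(families).fillna(0.0)
    fc = (na + pseudocount) / (nb + pseudocount)
    out = pd.DataFrame({
        "norm_a": na,
        "norm_b": nb,
        "fc": fc,
        "log2_fc": np.log2(fc),
        "one_sided": [(f not in a.index) or (f not in b.index) for f in families],
    })
    out.index.name = "family"
    return out


def spearman_fc(fc_x: Sequence[float], fc_y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation between two fold-change vectors."""
    rho, p = stats.spearmanr(fc_x, fc_y)
    return float(rho), float(p)
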