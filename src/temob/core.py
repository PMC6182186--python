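"""Shared primitives: alignment records, interval lookup, sequence helpers, SAM/BED/FASTA I/O.

Conventions used throughout the package:

* coordinates are 0-based half-open internally; BED output is 0-based
  half-open, SAM output 1-based (handled by pysam);
* alignment scores follow an end-to-end convention where 0 is a perfect
  alignment and penalties are negative, so score floors such as ``-10``
  can be applied with a plain comparison.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: CIGAR operations that consume reference bases.
_REF_OPS = frozenset("MDN=X")
#: CIGAR operations that consume query bases.
_QUERY_OPS = frozenset("MIS=X")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, n: int) -> str:
    """Uniform random ACGT string of length ``n``."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytes(alphabet[rng.integers(0, 4, n)]).decode("ascii")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class AlignedRead:
    """One alignment record (a thin, format-agnostic stand-in for a SAM line).

    ``pos`` is the 0-based leftmost reference coordinate.  Unmapped reads
    have ``ref is None``.  ``seq`` is stored in reference-forward
    orientation for mapped reads (SAM convention); ``strand`` records the
    original read orientation.
    """

    qname: str
    seq: str
    ref: str | None = None
    pos: int = -1
    strand: str = "+"
    cigar: str = ""
    score: int = 0
    mapq: int = 60
    is_paired: bool = False
    is_read1: bool = True
    mate_ref: str | None = None
    mate_pos: int = -1
    mate_unmapped: bool = False
    mate_strand: str = "+"
    is_secondary: bool = False
    tags: dict = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return self.ref is None

    @property
    def ref_length(self) -> int:
        """Number of reference bases consumed by the alignment."""
        return sum(n for n, op in parse_cigar(self.cigar) if op in _REF_OPS)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.pos + self.ref_length

    @property
    def left_clip(self) -> int:
        ops = parse_cigar(self.cigar)
        return ops[0][0] if ops and ops[0][1] == "S" else 0

    @property
    def right_clip(self) -> int:
        ops = parse_cigar(self.cigar)
        return ops[-1][0] if ops and ops[-1][1] == "S" else 0

    def clipped_seq(self, side: str) -> str:
        """Return the soft-clipped tail on ``side`` ('left' or 'right')."""
        if side == "left":
            return self.seq[: self.left_clip]
        if side == "right":
            n = self.right_clip
            return self.seq[-n:] if n else ""
        raise ValueError(f"unknown side {side!r}")


class IntervalIndex:
    """Static interval lookup (per-contig sorted starts + running max end).

    Intervals are (contig, start, end, payload) with 0-based half-open
    coordinates.  Query cost is O(log n + hits) in the common case.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, object]]):
        per_contig: dict[str, list[tuple[int, int, object]]] = {}
        for contig, start, end, payload in intervals:
            per_contig.setdefault(contig, []).append((start, end, payload))
        self._index: dict[str, tuple[list[int], list[tuple[int, int, object]], list[int]]] = {}
        for contig, ivs in per_contig.items():
            ivs.sort(key=lambda iv: iv[0])
            starts = [iv[0] for iv in ivs]
            maxend = []
            running = -1
            for _, end, _ in ivs:
                running = max(running, end)
                maxend.append(running)
            self._index[contig] = (starts, ivs, maxend)

    def overlapping(self, contig: str, start: int, end: int) -> list[tuple[int, int, object]]:
        """All intervals on ``contig`` overlapping [start, end)."""
        if contig not in self._index:
            return []
        starts, ivs, maxend = self._index[contig]
        hi = bisect_right(starts, end - 1)
        hits = []
        i = hi - 1
        while i >= 0 and maxend[i] > start:
            if ivs[i][1] > start:
                hits.append(ivs[i])
            i -= 1
        hits.reverse()
        return hits


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path: str | Path, rows: Iterable[Sequence]) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]),
                         f[3] if len(f) > 3 else ".",
                         f[4] if len(f) > 4 else "0",
                         f[5] if len(f) > 5 else "+"))
    return rows


def _flag(read: AlignedRead) -> int:
    flag = 0
    if read.is_paired:
        flag |= 0x1
        flag |= 0x40 if read.is_read1 else 0x80
        if read.mate_unmapped:
            flag |= 0x8
        if read.mate_strand == "-":
            flag |= 0x20
    if read.is_unmapped:
        flag |= 0x4
    if read.strand == "-":
        flag |= 0x10
    if read.is_secondary:
        flag |= 0x100
    return flag


def write_sam(path: str | Path, reads: Iterable[AlignedRead], ref_lengths: Mapping[str, int]) -> None:
    """Write records as plain-text SAM with an @SQ line per reference."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.qname
            seg.query_sequence = read.seq
            seg.query_qualities = None
            seg.flag = _flag(read)
            if read.is_unmapped:
                seg.reference_id = tid.get(read.mate_ref, -1) if read.mate_ref else -1
                seg.reference_start = read.mate_pos if read.mate_pos >= 0 else -1
                seg.mapping_quality = 0
            else:
                seg.reference_id = tid[read.ref]
                seg.reference_start = read.pos
                seg.cigarstring = read.cigar
                seg.mapping_quality = read.mapq
            if read.is_paired:
                seg.next_reference_id = tid.get(read.mate_ref, -1) if read.mate_ref else -1
                seg.next_reference_start = read.mate_pos if read.mate_pos >= 0 else -1
            seg.set_tag("AS", int(read.score))
            for key, value in read.tags.items():
                seg.set_tag(key, value)
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Read a SAM file back into :class:`AlignedRead` records."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            tags = dict(seg.get_tags())
            if "AS" in tags:
                score = tags.pop("AS")
            else:
                score = 0
                if not seg.is_unmapped:
                    tags["no_AS"] = 1  # flag for stages that require scores
            reads.append(AlignedRead(
                qname=seg.query_name,
                seq=seg.query_sequence or "",
                ref=None if seg.is_unmapped else seg.reference_name,
                pos=-1 if seg.is_unmapped else seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                cigar="" if seg.is_unmapped else (seg.cigarstring or ""),
                score=int(score),
                mapq=seg.mapping_quality,
                is_paired=seg.is_paired,
                is_read1=(not seg.is_paired) or seg.is_read1,
                mate_ref=seg.next_reference_name if seg.is_paired and seg.next_reference_id >= 0 else None,
                mate_pos=seg.next_reference_start if seg.is_paired else -1,
                mate_unmapped=seg.mate_is_unmapped if seg.is_paired else False,
                mate_strand="-" if (seg.is_paired and seg.mate_is_reverse) else "+",
                is_secondary=seg.is_secondary,
                tags=tags,
            ))
    return reads


def group_by_qname(reads: Iterable[AlignedRead]) -> Iterator[tuple[str, list[AlignedRead]]]:
    groups: dict[str, list[AlignedRead]] = {}
    for read in reads:
        groups.setdefault(read.qname, []).append(read)
    yield from groups.items()
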