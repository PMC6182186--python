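"""Windowed comparison of insertion call sets, de novo ratios and
coverage-matched subsampling.

Matching is family-aware throughout: a call in one set matches a call in
another only if both family and position (within +/- ``window``) agree.
Per-family "de novo insertion ratios" between two conditions separate
genuine insertions (present in one condition only) from artefactual
chimera-driven calls (equally abundant in both at matched coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, group_by_qname
from .insertion import CallerConfig, InsertionCall, call_insertions


@dataclass
class CompareConfig:
    window: int = 20          # calls within +/- window are "the same insertion"
    n_subsamples: int = 44
    subsample_seed: int = 0

    def __post_init__(self):
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.n_subsamples < 1:
            raise ValueError("need at least one subsample")


def _matches(a: InsertionCall, b: InsertionCall, window: int) -> bool:
    return (a.family == b.family and a.contig == b.contig
            and abs(a.breakpoint - b.breakpoint) <= window)


def library_specific(
    calls_a: Sequence[InsertionCall],
    calls_b: Sequence[InsertionCall],
    cfg: CompareConfig | None = None,
) -> tuple[list[InsertionCall], list[InsertionCall], list[InsertionCall]]:
    """Split two call sets into (unique_to_a, unique_to_b, shared).

    A call in A is shared iff a same-family call in B lies within the
    window of its breakpoint (and symmetrically); ``shared`` lists the
    A-side representatives.
    """
    cfg = cfg or CompareConfig()
    unique_a, shared = [], []
    for a in calls_a:
        (shared if any(_matches(a, b, cfg.window) for b in calls_b) else unique_a).append(a)
    unique_b = [b for b in calls_b
                if not any(_matches(a, b, cfg.window) for a in calls_a)]
    return unique_a, unique_b, shared


def multi_intersect(
    call_sets: Sequence[Sequence[InsertionCall]],
    cfg: CompareConfig | None = None,
    set_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Presence/absence matrix of merged loci across >= 2 call sets.

    Loci are merged per (family, contig) by single linkage with the window;
    a locus present in exactly one set is a candidate de novo insertion of
    that library.  Column sums equal per-set call counts after merging.
    """
    cfg = cfg or CompareConfig()
    if len(call_sets) < 2:
        raise ValueError("multi_intersect needs at least two call sets")
    names = list(set_names) if set_names is not None else [f"set{i}" for i in range(len(call_sets))]
    tagged = [(call, i) for i, calls in enumerate(call_sets) for call in calls]
    tagged.sort(key=lambda t: (t[0].family, t[0].contig, t[0].breakpoint))
    rows = []
    group: list[tuple[InsertionCall, int]] = []

    def flush(group):
        calls = [c for c, _ in group]
        members = {i for _, i in group}
        rows.append({
            "family": calls[0].family,
            "contig": calls[0].contig,
            "start": min(c.breakpoint for c in calls),
            "end": max(c.breakpoint for c in calls),
            **{name: (i in members) for i, name in enumerate(names)},
        })

    for item in tagged:
        call, _ = item
        if group and (call.family != group[-1][0].family
                      or call.contig != group[-1][0].contig
                      or call.breakpoint - group[-1][0].breakpoint > cfg.window):
            flush(group)
            group = []
        group.append(item)
    if group:
        flush(group)
    table = pd.DataFrame(rows, columns=["family", "contig", "start", "end", *names])
    table["n_sets"] = table[names].sum(axis=1)
    return table


def unique_counts_by_family(unique_calls: Iterable[InsertionCall],
                            families: Sequence[str] | None = None) -> pd.Series:
    counts: dict[str, int] = {f: 0 for f in (families or [])}
    for call in unique_calls:
        counts[call.family] = counts.get(call.family, 0) + 1
    series = pd.Series(counts, dtype=float).sort_index()
    series.name = "unique_count"
    return series


def denovo_ratio(
    unique_counts_a: Mapping[str, float] | pd.Series,
    unique_counts_b: Mapping[str, float] | pd.Series,
    pseudocount: float = 0.0,
    flag_threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-family ratio of library-specific insertion counts (A over B).

    With the default ``pseudocount=0``: a zero denominator with a nonzero
    numerator yields ``inf`` (insertions seen in A only) and both-zero
    families yield ``NaN`` (undefined, not 1).  A positive pseudocount gives
    the regularized ratio ``(a + eps) / (b + eps)``.
    """
    a = pd.Series(dict(unique_counts_a), dtype=float)
    b = pd.Series(dict(unique_counts_b), dtype=float)
    families = sorted(set(a.index) | set(b.index))
    na = a.reindex(families).fillna(0.0) + pseudocount
    nb = b.reindex(families).fillna(0.0) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((na == 0) & (nb == 0), np.nan, na / nb)
    table = pd.DataFrame({
        "unique_a": na - pseudocount,
        "unique_b": nb - pseudocount,
        "ratio": ratio,
    }, index=pd.Index(families, name="family"))
    table["flagged"] = table["ratio"] > flag_threshold
    return table


def subsample_pairs(alignments: Sequence[AlignedRead], target_mapped: int,
                    rng: np.random.Generator) -> list[AlignedRead]:
    """Draw read pairs without replacement until ``target_mapped`` primary
    mapped reads are included (read-pair granularity preserves OEA
    semantics)."""
    pairs = list(group_by_qname(alignments))
    mapped_per_pair = np.array([
        sum(1 for r in records if not r.is_unmapped and not r.is_secondary)
        for _, records in pairs
    ])
    total = int(mapped_per_pair.sum())
    if target_mapped > total:
        raise ValueError(f"target {target_mapped} exceeds {total} mapped reads available")
    order = rng.permutation(len(pairs))
    if target_mapped == total:
        chosen = order  # fraction 1.0: every pair, identical to the full analysis
    else:
        cumulative = np.cumsum(mapped_per_pair[order])
        cut = int(np.searchsorted(cumulative, target_mapped, side="left")) + 1
        chosen = order[:cut]
    out: list[AlignedRead] = []
    for i in sorted(chosen):
        out.extend(pairs[i][1])
    return out


def count_mapped(alignments: Iterable[AlignedRead]) -> int:
    return sum(1 for r in alignments if not r.is_unmapped and not r.is_secondary)


def subsample_matched(
    alignments_a: Sequence[AlignedRead],
    calls_b: Sequence[InsertionCall],
    target_mapped: int,
    te_library: Mapping[str, str],
    caller_cfg: CallerConfig | None = None,
    cfg: CompareConfig | None = None,
    families: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Coverage-matched subsampling of library A against fixed calls B.

    Library A is subsampled ``cfg.n_subsamples`` times to ``target_mapped``
    mapped reads (read-pair granularity, independent derived seeds); the
    full caller plus the library-specific comparison is rerun per subsample
    and the per-family mean and SD of unique-to-A counts are returned, along
    with every replicate column.
    """
    caller_cfg = caller_cfg or CallerConfig()
    cfg = cfg or CompareConfig()
    seeds = np.random.SeedSequence([int(cfg.subsample_seed), 0x5AB5]).spawn(cfg.n_subsamples)
    replicates = []
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        subset = subsample_pairs(alignments_a, target_mapped, rng)
        calls_a = call_insertions(subset, te_library, caller_cfg)
        unique_a, _, _ = library_specific(calls_a, calls_b, cfg)
        counts = unique_counts_by_family(unique_a, families)
        counts.name = f"rep{i}"
        replicates.append(counts)
    table = pd.concat(replicates, axis=1).fillna(0.0)
    result = pd.DataFrame({
        "mean_unique": table.mean(axis=1),
        "sd_unique": table.std(axis=1, ddof=0),
    })
    result.index.name = "family"
    return pd.concat([result, table], axis=1)
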