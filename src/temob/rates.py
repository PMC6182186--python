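"""Transposition-rate arithmetic, Poisson insertion probabilities and
TE-load fold-change statistics.

The per-genome event rate over one generation is treated as Poisson; with
``g`` independent generations and ``n`` independent individuals the number
of events is Poisson with mean ``g * n * lambda``, giving

* ``p_zero(lam, g)      = exp(-g * lam)``
* ``p_at_least_one_among(lam, g, n) = 1 - exp(-g * n * lam)``

``lam`` here is the per-genome rate: the per-copy rate times the number of
active copies (keep the two scales distinct — see :func:`per_genome_rate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RateParams:
    lam: float                 # per-copy per-generation transposition rate
    generations: int = 1
    individuals: int = 1
    active_copies: int = 1
    denovo_count: int = 0
    preexisting_count: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("rate must be >= 0")
        if self.generations < 1 or self.individuals < 1:
            raise ValueError("generations and individuals must be >= 1")
        if self.denovo_count < 0 or self.preexisting_count < 0:
            raise ValueError("counts must be >= 0")

    @property
    def genome_rate(self) -> float:
        return per_genome_rate(self.lam, self.active_copies)


def per_genome_rate(per_copy_rate: float, active_copies: int) -> float:
    """Per-genome event rate = per-copy rate x number of active copies."""
    return per_copy_rate * active_copies


def transposition_rate(denovo_count: int, preexisting_count: int, generations: int = 1) -> float:
    """New insertions per pre-existing copy per generation.

    Computed as ``denovo / (preexisting * generations)``.  The alternative
    literal reading ``denovo / preexisting * generations`` (multiplying by
    the generation count) coincides with this one at ``generations == 1``,
    the case used for single-generation sequencing estimates, but diverges
    otherwise; the division reading is the one consistent with a
    "per copy and generation" rate and is what this function returns.
    """
    if preexisting_count <= 0:
        raise ValueError("preexisting_count must be > 0")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return denovo_count / (preexisting_count * generations)


def p_zero(lambda_total: float, generations: int = 1) -> float:
    """Probability of zero events after ``generations`` (Poisson, k=0)."""
    if lambda_total < 0:
        raise ValueError("rate must be >= 0")
    return math.exp(-generations * lambda_total)


def p_at_least_one_among(lambda_total: float, generations: int, individuals: int) -> float:
    """Probability that at least one of ``individuals`` independent genomes
    shows at least one event after ``generations``: 1 - exp(-g*n*lambda)."""
    if lambda_total < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-generations * individuals * lambda_total)


def load_growth(initial_copies: float, rate: float, generations: int) -> float:
    """Copy number after compounding ``copies *= (1 + rate)`` per generation."""
    return initial_copies * (1.0 + rate) ** generations


def min_rate_for_fold(fold: float, generations: int) -> float:
    """Smallest per-generation rate r with (1+r)**generations >= fold."""
    return fold ** (1.0 / generations) - 1.0


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def te_load_foldchange(
    measurements: pd.DataFrame,
    baseline: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-family TE-load fold changes versus a baseline condition.

    ``measurements`` needs columns (family, condition, value) with >= 3
    replicate values per (family, condition).  For every non-baseline
    condition the fold is ``mean(condition) / mean(baseline)``; a Shapiro
    normality p-value (on pooled residuals) and a two-tailed t-test p-value
    with significance stars are reported.
    """
    required = {"family", "condition", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    rows = []
    for family, sub in measurements.groupby("family"):
        base = sub.loc[sub["condition"] == baseline, "value"].to_numpy(float)
        if len(base) < 3:
            raise ValueError(f"need >=3 baseline replicates for {family}")
        for condition, cond_sub in sub.groupby("condition"):
            if condition == baseline:
                continue
            vals = cond_sub["value"].to_numpy(float)
            if len(vals) < 3:
                raise ValueError(f"need >=3 replicates for {family}/{condition}")
            fold = vals.mean() / base.mean()
            residuals = np.concatenate([vals - vals.mean(), base - base.mean()])
            shapiro_p = float(stats.shapiro(residuals).pvalue)
            t_p = float(stats.ttest_ind(vals, base, equal_var=equal_var).pvalue)
            rows.append({
                "family": family, "condition": condition, "fold": fold,
                "shapiro_p": shapiro_p, "t_p": t_p, "stars": _stars(t_p),
            })
    return pd.DataFrame(rows, columns=["family", "condition", "fold", "shapiro_p", "t_p", "stars"])


def qpcr_relative_quantity(ct_target: Sequence[float], ct_reference: Sequence[float],
                           efficiency: float = 2.0) -> np.ndarray:
    """Efficiency-based relative quantification of qPCR Ct values.

    Returns ``efficiency ** (ct_reference - ct_target)`` per replicate — the
    copy number of the target relative to a single-copy reference, assuming
    a common amplification efficiency (default: perfect doubling).
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    return efficiency ** (ct_r - ct_t)
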