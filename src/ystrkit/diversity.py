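"""Haplotype diversity and repeat-number variance on minimal haplotypes.

Haplotype diversity is Nei's unbiased gene diversity,

    h = n/(n-1) * (1 - sum_i p_i^2),

the probability that two chromosomes sampled without replacement carry
different haplotypes.  Repeat variance V is the unweighted mean over loci of
the per-locus sample variance (n-1 denominator) of repeat counts; under the
stepwise mutation model it grows linearly with time, so V and h together
separate old diverse lineages from recent expansions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .profiles import MinHt


@dataclass(frozen=True)
class DiversitySummary:
    """Per-group summary: n samples, k distinct, h, mean variance, shared."""

    n: int
    k: int
    h: float
    V: float
    shared: int


def haplotype_diversity(haplotypes: Sequence[tuple]) -> float:
    """Unbiased gene diversity h = n/(n-1) (1 - sum p_i^2); needs n >= 2."""
    n = len(haplotypes)
    if n < 2:
        raise ValueError(f"haplotype diversity needs n >= 2, got {n}")
    counts = np.array(list(Counter(map(tuple, haplotypes)).values()), dtype=float)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def repeat_variance(
    haplotypes: Sequence[tuple], loci: Sequence[str] | None = None
) -> tuple[dict[str, float], float]:
    """Per-locus sample variance of repeat counts and their unweighted mean.

    `loci` names the positions (defaults to ``L1..Lk``); all haplotypes must
    share one length.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError(f"repeat variance needs n >= 2, got {n}")
    arr = np.asarray([tuple(h) for h in haplotypes], dtype=float)
    if loci is None:
        loci = [f"L{i + 1}" for i in range(arr.shape[1])]
    if len(loci) != arr.shape[1]:
        raise ValueError("loci names do not match haplotype length")
    var = arr.var(axis=0, ddof=1)
    per_locus = {name: float(v) for name, v in zip(loci, var)}
    return per_locus, float(var.mean())


def shared_haplotype_count(haplotypes: Sequence[tuple]) -> int:
    """Number of distinct haplotypes observed at least twice."""
    return sum(1 for c in Counter(map(tuple, haplotypes)).values() if c >= 2)


def summarize(
    haplotypes: Sequence[MinHt], loci: Sequence[str] | None = None
) -> DiversitySummary:
    n = len(haplotypes)
    _, V = repeat_variance(haplotypes, loci)
    return DiversitySummary(
        n=n,
        k=len(set(map(tuple, haplotypes))),
        h=haplotype_diversity(haplotypes),
        V=V,
        shared=shared_haplotype_count(haplotypes),
    )
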