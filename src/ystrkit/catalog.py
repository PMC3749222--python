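"""Locus catalogs: which Y-STR loci exist, which are multi-copy, and the
minimal-haplotype subset.

The *minimal haplotype* (minHt) is the classical forensic seven-locus set
DYS19, DYS389I, DYS389B, DYS390, DYS391, DYS392, DYS393 (DYS385a/b belongs
to the historical definition but, being a duplicated locus whose two alleles
cannot be phased, is disregarded in all analyses here).  DYS389B is a
derived quantity: DYS389II is amplified as a fragment containing DYS389I,
so DYS389B = DYS389II - DYS389I.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: Minimal-haplotype loci, in canonical order.
MINHT_LOCI: tuple[str, ...] = (
    "DYS19",
    "DYS389I",
    "DYS389B",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
)

#: STR systems present in two copies on the Y chromosome; their two alleles
#: cannot be assigned to a physical copy and are stored unordered.
DEFAULT_MULTI_COPY: frozenset[str] = frozenset(
    {"YCAIIa/b", "DYS385a/b", "DYS459", "DYS464"}
)


@dataclass(frozen=True)
class LocusCatalog:
    """Ordered set of locus names with copy-number annotations.

    Parameters
    ----------
    loci
        Ordered locus names as they appear in input tables.
    multi_copy
        Subset of `loci` that are duplicated systems (two alleles expected).
    minht_loci
        Ordered minimal-haplotype loci; must all be single-copy.
    """

    loci: tuple[str, ...]
    multi_copy: frozenset[str] = DEFAULT_MULTI_COPY
    minht_loci: tuple[str, ...] = MINHT_LOCI

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names in catalog")
        bad = set(self.minht_loci) & set(self.multi_copy)
        if bad:
            raise ValueError(f"minHt loci must be single-copy, got {sorted(bad)}")

    def is_multi_copy(self, locus: str) -> bool:
        return locus in self.multi_copy

    @property
    def single_copy(self) -> tuple[str, ...]:
        return tuple(l for l in self.loci if l not in self.multi_copy)


def default_catalog(extra_loci: Sequence[str] = ()) -> LocusCatalog:
    """Catalog covering the minHt loci plus any additional loci supplied."""
    loci = list(MINHT_LOCI)
    for l in extra_loci:
        if l not in loci:
            loci.append(l)
    return LocusCatalog(loci=tuple(loci))
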