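"""STR profiles, the minimal haplotype, and the atypical-allele filters.

A :class:`StrProfile` holds one male's multi-locus Y-STR genotype together
with population/region labels.  Allele values are repeat counts stored as
exact :class:`decimal.Decimal` so that partial-repeat micro-variants such as
``13.2`` (13 full repeats plus a 2-bp partial motif) survive round trips
without floating-point noise.

Downstream statistics assume one integer allele per single-copy locus, so
samples carrying *atypical* alleles — a micro-variant, or a duplication of a
normally single-copy locus — are filtered out (and reported) before
diversity, network or dating computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, InvalidOperation
from typing import Iterable, Mapping, Sequence

from .catalog import LocusCatalog

Allele = Decimal


def parse_allele(text: str) -> Allele:
    """Parse one allele repeat count, e.g. ``"13"`` or ``"13.2"``.

    Raises ValueError for non-numeric or non-positive values.
    """
    try:
        value = Decimal(text.strip())
    except InvalidOperation as exc:
        raise ValueError(f"unparseable allele value {text!r}") from exc
    if value <= 0:
        raise ValueError(f"allele value must be positive, got {text!r}")
    return value


def format_allele(value: Allele) -> str:
    """Render an allele, dropping a spurious fractional part (13 not 13.0)."""
    if value == value.to_integral_value():
        return str(int(value))
    return str(value.normalize())


def is_microvariant(value: Allele) -> bool:
    return value != value.to_integral_value()


class MinHt(tuple):
    """Ordered tuple of integer repeat counts on the minimal-haplotype loci.

    Behaves as a plain tuple (hashable, comparable); construction validates
    that every value is a positive integer — profiles carrying fractional
    micro-variant alleles must be excluded before building a MinHt.
    """

    def __new__(cls, values: Iterable[int]) -> "MinHt":
        vals = tuple(values)
        for v in vals:
            if int(v) != v or v <= 0:
                raise ValueError(f"MinHt values must be positive integers, got {v!r}")
        return super().__new__(cls, (int(v) for v in vals))


@dataclass
class StrProfile:
    """One sample's Y-STR genotype with provenance labels.

    ``alleles`` maps locus name to the list of allele values observed at
    that locus: length one for a typical single-copy locus, length two for
    duplicated systems (DYS385a/b etc.) or for a sample carrying an
    anomalous duplication of a single-copy locus.
    """

    sample_id: str
    population: str
    region: str
    alleles: dict[str, tuple[Allele, ...]]
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        clean: dict[str, tuple[Allele, ...]] = {}
        for locus, values in self.alleles.items():
            vals = tuple(Decimal(str(v)) if not isinstance(v, Decimal) else v
                         for v in values)
            if not vals:
                raise ValueError(f"{self.sample_id}: empty allele list at {locus}")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{self.sample_id}: non-positive allele at {locus}")
            clean[locus] = vals
        self.alleles = clean

    # ------------------------------------------------------------------
    def has_locus(self, locus: str) -> bool:
        return locus in self.alleles

    def single_allele(self, locus: str) -> Allele:
        vals = self.alleles[locus]
        if len(vals) != 1:
            raise ValueError(
                f"{self.sample_id}: expected one allele at {locus}, got {len(vals)}"
            )
        return vals[0]

    def microvariant_loci(self, loci: Sequence[str] | None = None) -> list[str]:
        """Loci (restricted to `loci` if given) carrying a fractional allele."""
        names = self.alleles.keys() if loci is None else loci
        return [
            l for l in names
            if l in self.alleles and any(is_microvariant(v) for v in self.alleles[l])
        ]

    def duplicated_loci(
        self, catalog: LocusCatalog, loci: Sequence[str] | None = None
    ) -> list[str]:
        """Single-copy loci (restricted to `loci` if given) with >1 allele."""
        names = self.alleles.keys() if loci is None else loci
        return [
            l for l in names
            if l in self.alleles
            and not catalog.is_multi_copy(l)
            and len(self.alleles[l]) > 1
        ]

    @property
    def is_microvariant(self) -> bool:
        return bool(self.microvariant_loci())


@dataclass(frozen=True)
class Exclusion:
    """Record of one profile removed by a filter, with the reason."""

    sample_id: str
    reason: str


def filter_atypical(
    profiles: Sequence[StrProfile],
    loci: Sequence[str],
    catalog: LocusCatalog,
) -> tuple[list[StrProfile], list[Exclusion]]:
    """Partition profiles into (kept, excluded) on the given loci.

    A profile is excluded if, at any of `loci`, it carries a fractional
    micro-variant allele or a duplication of a single-copy locus.  Order is
    preserved; kept + excluded partition the input.
    """
    known = set(catalog.loci)
    unknown = [l for l in loci if l not in known]
    if unknown:
        raise ValueError(f"unknown loci: {unknown}")

    kept: list[StrProfile] = []
    excluded: list[Exclusion] = []
    for p in profiles:
        dup = p.duplicated_loci(catalog, loci)
        micro = p.microvariant_loci(loci)
        if dup:
            excluded.append(
                Exclusion(p.sample_id, f"duplicated locus: {','.join(dup)}")
            )
        elif micro:
            excluded.append(
                Exclusion(p.sample_id, f"micro-variant allele: {','.join(micro)}")
            )
        else:
            kept.append(p)
    return kept, excluded


def require_complete(
    profiles: Sequence[StrProfile], loci: Sequence[str]
) -> tuple[list[StrProfile], list[Exclusion]]:
    """Drop (and report) profiles missing any of the required loci."""
    kept: list[StrProfile] = []
    excluded: list[Exclusion] = []
    for p in profiles:
        missing = [l for l in loci if not p.has_locus(l)]
        if missing:
            excluded.append(Exclusion(p.sample_id, f"missing loci: {','.join(missing)}"))
        else:
            kept.append(p)
    return kept, excluded


def to_minht(profile: StrProfile, catalog: LocusCatalog) -> MinHt:
    """Project a profile onto the ordered minimal-haplotype tuple.

    The profile must carry exactly one integer allele at each minHt locus;
    loci outside the minHt set are ignored.
    """
    values = []
    for locus in catalog.minht_loci:
        if not profile.has_locus(locus):
            raise ValueError(f"{profile.sample_id}: missing minHt locus {locus}")
        v = profile.single_allele(locus)
        if is_microvariant(v):
            raise ValueError(
                f"{profile.sample_id}: micro-variant allele at {locus}; "
                "filter atypical profiles first"
            )
        values.append(int(v))
    return MinHt(values)


def minhts(
    profiles: Sequence[StrProfile], catalog: LocusCatalog
) -> list[MinHt]:
    return [to_minht(p, catalog) for p in profiles]
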