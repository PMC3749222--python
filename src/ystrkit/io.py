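"""Tab-delimited readers/writers for STR haplotype tables.

Dialect: UTF-8, tab-separated, header row.  Metadata columns ``sample_id``,
``population``, ``region`` (plus optional ``haplogroup``) precede one column
per locus.  Duplicated systems may arrive either as one comma-joined column
(``DYS385a/b`` = ``"13,17"``) or as a suffixed column pair (``DYS385a``,
``DYS385b``); on write they are always serialized comma-joined.  A
single-copy column containing a comma records an anomalous duplication.

DYS389B is accepted directly or derived as DYS389II - DYS389I when only the
raw fragment counts are present.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .catalog import LocusCatalog
from .profiles import (
    Allele,
    Exclusion,
    StrProfile,
    format_allele,
    parse_allele,
)

META_COLUMNS = ("sample_id", "population", "region")


def sniff_catalog(path: str | Path) -> LocusCatalog:
    """Build a catalog from a table header: every non-metadata column is a
    locus; a/b column pairs collapse to one duplicated system; DYS389I+II
    imply the derived DYS389B."""
    from .catalog import DEFAULT_MULTI_COPY, MINHT_LOCI

    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    skip = set(META_COLUMNS) | {"haplogroup"}
    loci: list[str] = []
    cols = [c for c in header if c not in skip]
    colset = set(cols)
    for col in cols:
        if col[:-1] + "a/b" in DEFAULT_MULTI_COPY and col.endswith(("a", "b")):
            system = col[:-1] + "a/b"
            if system not in loci:
                loci.append(system)
        elif col not in loci:
            loci.append(col)
    if "DYS389B" not in colset and {"DYS389I", "DYS389II"} <= colset:
        loci.append("DYS389B")
    minht = tuple(l for l in MINHT_LOCI if l in loci)
    return LocusCatalog(loci=tuple(loci), minht_loci=minht)


@dataclass(frozen=True)
class RowError:
    """A cell that could not be parsed; the row is dropped."""

    row: int          # 1-based data-row number
    column: str
    message: str


def _pair_columns(locus: str) -> tuple[str, str] | None:
    """Suffixed column pair for an a/b system, e.g. DYS385a/b -> (DYS385a, DYS385b)."""
    if locus.endswith("a/b"):
        stem = locus[: -len("a/b")]
        return stem + "a", stem + "b"
    return None


def read_str_table(
    path: str | Path, catalog: LocusCatalog
) -> tuple[list[StrProfile], list[RowError]]:
    """Read a haplotype table; returns (profiles, row-level error records).

    Every locus in the catalog must be resolvable from the header (directly,
    via an a/b column pair, or — for DYS389B — via DYS389I+DYS389II);
    otherwise a ValueError is raised.  Unparseable or non-positive alleles
    produce a :class:`RowError` and drop the row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise ValueError(f"{path}: empty file, no header")
        missing_meta = [c for c in META_COLUMNS if c not in header]
        if missing_meta:
            raise ValueError(f"{path}: missing required columns {missing_meta}")

        # Resolve each catalog locus to its source columns.
        plans: dict[str, tuple[str, ...]] = {}
        for locus in catalog.loci:
            if locus in header:
                plans[locus] = (locus,)
                continue
            pair = _pair_columns(locus)
            if pair and pair[0] in header and pair[1] in header:
                plans[locus] = pair
                continue
            if locus == "DYS389B" and "DYS389I" in header and "DYS389II" in header:
                plans[locus] = ("DYS389I", "DYS389II")  # derived by subtraction
                continue
            raise ValueError(f"{path}: missing required locus column {locus}")

        profiles: list[StrProfile] = []
        errors: list[RowError] = []
        for i, row in enumerate(reader, start=1):
            try:
                profiles.append(_parse_row(i, row, catalog, plans, errors))
            except _RowFailed:
                pass
    return profiles, errors


class _RowFailed(Exception):
    pass


def _parse_row(
    rownum: int,
    row: dict[str, str],
    catalog: LocusCatalog,
    plans: dict[str, tuple[str, ...]],
    errors: list[RowError],
) -> StrProfile:
    def cell(col: str) -> str:
        return (row.get(col) or "").strip()

    def parse_cell(col: str) -> tuple[Allele, ...]:
        text = cell(col)
        if not text:
            return ()
        try:
            return tuple(parse_allele(part) for part in text.split(","))
        except ValueError as exc:
            errors.append(RowError(rownum, col, str(exc)))
            raise _RowFailed from exc

    alleles: dict[str, tuple[Allele, ...]] = {}
    for locus, cols in plans.items():
        if locus == "DYS389B" and cols == ("DYS389I", "DYS389II"):
            v1, v2 = parse_cell("DYS389I"), parse_cell("DYS389II")
            if not v1 or not v2:
                continue  # incomplete; recorded as missing locus downstream
            if len(v1) == 1 and len(v2) == 1:
                b = v2[0] - v1[0]
                if b <= 0:
                    errors.append(
                        RowError(rownum, "DYS389II",
                                 f"DYS389II ({v2[0]}) must exceed DYS389I ({v1[0]})")
                    )
                    raise _RowFailed
                alleles[locus] = (b,)
            else:
                # duplicated DYS389 system: keep raw alleles, flag via count
                alleles[locus] = tuple(b - v1[0] for b in v2)
            continue
        if len(cols) == 2:  # a/b column pair
            va, vb = parse_cell(cols[0]), parse_cell(cols[1])
            vals = va + vb
        else:
            vals = parse_cell(cols[0])
        if vals:
            alleles[locus] = vals

    # carry along any extra locus columns present in the file
    known_cols = {c for cols in plans.values() for c in cols} | set(META_COLUMNS) | {
        "haplogroup"
    }
    for col, text in row.items():
        if col in known_cols or col is None:
            continue
        if (text or "").strip():
            try:
                alleles[col] = tuple(
                    parse_allele(part) for part in text.strip().split(",")
                )
            except ValueError as exc:
                errors.append(RowError(rownum, col, str(exc)))
                raise _RowFailed from exc

    return StrProfile(
        sample_id=cell("sample_id"),
        population=cell("population"),
        region=cell("region"),
        alleles=alleles,
        haplogroup=cell("haplogroup") or None,
    )


def write_str_table(
    path: str | Path,
    profiles: Sequence[StrProfile],
    loci: Sequence[str] | None = None,
) -> None:
    """Write profiles tab-delimited; multi-allele loci are comma-joined.

    `loci` fixes the column order; by default the union of observed loci in
    first-seen order is used.
    """
    if loci is None:
        seen: dict[str, None] = {}
        for p in profiles:
            for l in p.alleles:
                seen.setdefault(l)
        loci = list(seen)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow([*META_COLUMNS, "haplogroup", *loci])
        for p in profiles:
            row = [p.sample_id, p.population, p.region, p.haplogroup or ""]
            for l in loci:
                vals = p.alleles.get(l, ())
                row.append(",".join(format_allele(v) for v in vals))
            writer.writerow(row)


def write_exclusions(path: str | Path, exclusions: Iterable[Exclusion]) -> None:
    """Exclusion report: one line per removed sample with the reason."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "reason"])
        for e in exclusions:
            writer.writerow([e.sample_id, e.reason])
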