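"""Bundled example dataset: haplogroup composition of a 463-chromosome
haplogroup-Q survey spanning Mexico to South America plus Mongolia and
Kamchatka.

The table records, per population, the direct haplogroup counts together
with per-sample anomaly annotations (one anomalous DYS390 duplication, two
partial-repeat micro-variant carriers).  Expanding it yields one labeled
record per chromosome, which exercises the frequency, clade-aggregation and
exclusion machinery end to end without any genotype download.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .classify import FrequencyTable, HaplogroupTree, frequency_table

ASIAN_MACRO_AREA = "Asia"


@dataclass(frozen=True)
class SurveySample:
    sample_id: str
    macro_area: str
    population: str
    label: str
    anomaly: str | None  # "duplicated:<locus>" or "microvariant:<locus>=<allele>"

    @property
    def is_native_american(self) -> bool:
        return self.macro_area != ASIAN_MACRO_AREA

    @property
    def has_duplicated_locus(self) -> bool:
        return self.anomaly is not None and self.anomaly.startswith("duplicated")

    @property
    def has_microvariant(self) -> bool:
        return self.anomaly is not None and self.anomaly.startswith("microvariant")


def load_survey_counts() -> pd.DataFrame:
    """The raw count table (macro_area, population, label, count, anomaly)."""
    source = resources.files("ystrkit.data").joinpath("survey_counts.tsv")
    with resources.as_file(source) as path:
        df = pd.read_csv(path, sep="\t", dtype={"count": int})
    df["anomaly"] = df["anomaly"].where(df["anomaly"].notna(), None)
    return df


def expand_survey_samples() -> list[SurveySample]:
    """One record per chromosome, with deterministic sample ids."""
    df = load_survey_counts()
    samples: list[SurveySample] = []
    counters: dict[str, int] = {}
    for row in df.itertuples(index=False):
        for _ in range(row.count):
            counters[row.population] = counters.get(row.population, 0) + 1
            sid = f"{row.population.replace(' ', '')}-{counters[row.population]:03d}"
            samples.append(
                SurveySample(
                    sample_id=sid,
                    macro_area=row.macro_area,
                    population=row.population,
                    label=row.label,
                    anomaly=row.anomaly,
                )
            )
    return samples


def survey_frequency_table(by: str = "population") -> FrequencyTable:
    """Direct-count frequency table of the survey, by population or macro-area."""
    samples = expand_survey_samples()
    key = {
        "population": lambda s: s.population,
        "macro_area": lambda s: s.macro_area,
    }[by]
    return frequency_table([(key(s), s.label) for s in samples])


def native_american_samples() -> list[SurveySample]:
    return [s for s in expand_survey_samples() if s.is_native_american]


def ordination_input_samples(tree: HaplogroupTree) -> list[SurveySample]:
    """Samples entering the 33-locus ordination: Native American chromosomes
    inside the main continental clade (out-of-tree arrivals such as Q1b are
    dropped), minus any sample with a duplicated single-copy locus.
    Micro-variant carriers are retained (their fractional alleles are valid
    numerically)."""
    keep: list[SurveySample] = []
    for s in native_american_samples():
        node = tree.node_of_label(s.label)
        if node is None or tree.is_descendant(node, "Q1b"):
            continue
        if s.has_duplicated_locus:
            continue
        keep.append(s)
    return keep


def dating_input_samples(
    tree: HaplogroupTree,
    clade: str,
    exclude_clades: tuple[str, ...] = (),
) -> list[SurveySample]:
    """Samples entering ASD dating for `clade`: Native American members of
    the clade with neither duplicated loci nor micro-variants.  Q1b samples
    (recent out-of-continent arrivals) are always dropped; `exclude_clades`
    removes nested subclades, e.g. dating L54(xM3)."""
    keep: list[SurveySample] = []
    for s in native_american_samples():
        node = tree.node_of_label(s.label)
        if node is None or not tree.is_descendant(node, clade):
            continue
        if tree.is_descendant(node, "Q1b"):
            continue
        if any(tree.is_descendant(node, ex) for ex in exclude_clades):
            continue
        if s.anomaly is not None:
            continue
        keep.append(s)
    return keep
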