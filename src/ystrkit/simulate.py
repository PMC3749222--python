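"""Synthetic Y-STR/SNP datasets with the statistical structure the analyses
assume.

Haplotypes evolve from a founder under the unconstrained symmetric stepwise
mutation model (SMM): each mutation shifts a locus by +-1 repeat with equal
probability.  Two genealogy shapes are supported:

* ``star`` — every sample descends independently from the founder for T_g
  generations (the limiting shape of a rapid demographic expansion); each
  locus mutates with per-generation probability mu, so E[ASD about the
  founder] = mu * T_g exactly.
* ``coalescent`` — a Kingman n-coalescent genealogy (drawn with msprime)
  with effective size ``ne`` scaled so that E[pairwise TMRCA] = 2*ne
  generations; mutation counts are Poisson(mu * branch length) per locus.

Multi-population structure is obtained by evolving one founder per
population from the root founder for ``divergence_gens`` generations (or by
specifying founders directly).  Biallelic SNP markers can be layered on
branches — the root, a population stem, or a random internal clade of a
coalescent tree — defining true haplogroup assignments for classifier
recovery tests.  Anomalies (partial-repeat micro-variants, duplications of
single-copy loci) are injected at configurable rates to exercise the
atypical-allele filters.

All randomness flows from one master seed through named substreams, so
adding a new stochastic operation never perturbs existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from decimal import Decimal
from typing import Mapping, Sequence

import numpy as np

from .catalog import MINHT_LOCI, LocusCatalog, default_catalog
from .classify import ANCESTRAL, DERIVED, HaplogroupTree, SnpCalls
from .profiles import StrProfile

DEFAULT_FOUNDER: tuple[int, ...] = (13, 13, 16, 24, 10, 14, 13)  # modal minHt


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: optional explicit founder and true
    haplogroup node (tree node name) for its samples."""

    name: str
    founder: tuple[int, ...] | None = None
    haplogroup: str | None = None


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic dataset."""

    genealogy: str = "star"                      # "star" | "coalescent"
    n: int = 100                                 # samples per population
    loci: tuple[str, ...] = MINHT_LOCI
    founder: tuple[int, ...] = DEFAULT_FOUNDER
    mu: float = 6.9e-4                           # per locus per generation
    t_g: int = 1000                              # star depth, generations
    ne: float = 1000.0                           # coalescent: E[T2] = 2*ne
    populations: tuple[PopulationSpec, ...] = (PopulationSpec("pop1"),)
    divergence_gens: int = 0
    snp_markers: Mapping[str, str] = field(default_factory=dict)
    microvariant_rate: float = 0.0
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        for rate in (self.microvariant_rate, self.duplication_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("anomaly rates must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.founder) != len(self.loci):
            raise ValueError("founder length must match loci")
        for p in self.populations:
            if p.founder is not None and len(p.founder) != len(self.loci):
                raise ValueError(f"{p.name}: founder length must match loci")


@dataclass
class SimTruth:
    """Generating values: founders, depth, per-sample branch/haplogroup and
    the derived-sample set of every placed SNP marker."""

    founders: dict[str, tuple[int, ...]]
    t_g: int
    population_of: dict[str, str]
    haplogroup_of: dict[str, str | None]
    snp_derived: dict[str, frozenset[str]]


@dataclass
class SimResult:
    profiles: list[StrProfile]
    truth: SimTruth
    config: SimConfig


# ----------------------------------------------------------------------
def _smm_displacement(
    rng: np.random.Generator, n_mutations: np.ndarray
) -> np.ndarray:
    """Net repeat displacement after the given numbers of +-1 steps."""
    up = rng.binomial(n_mutations, 0.5)
    return 2 * up - n_mutations


def _population_founders(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    root = np.asarray(config.founder, dtype=int)
    founders = {}
    for pop in config.populations:
        if pop.founder is not None:
            founders[pop.name] = np.asarray(pop.founder, dtype=int)
        elif config.divergence_gens > 0:
            k = rng.binomial(config.divergence_gens, config.mu, size=root.shape)
            founders[pop.name] = root + _smm_displacement(rng, k)
        else:
            founders[pop.name] = root.copy()
    return founders


def _profiles_from_matrix(
    pop: PopulationSpec,
    values: np.ndarray,
    config: SimConfig,
) -> list[StrProfile]:
    profiles = []
    for i, row in enumerate(values):
        alleles = {
            locus: (Decimal(int(v)),) for locus, v in zip(config.loci, row)
        }
        profiles.append(
            StrProfile(
                sample_id=f"{pop.name}-{i:04d}",
                population=pop.name,
                region="simulated",
                alleles=alleles,
                haplogroup=pop.haplogroup,
            )
        )
    return profiles


def _resolve_snps(
    config: SimConfig,
    clade_leaves: dict[str, dict[int, list[str]]],
    sample_ids: dict[str, list[str]],
    rng: np.random.Generator,
) -> dict[str, frozenset[str]]:
    """Translate snp_markers placements into derived-sample sets.

    Placements: ``"root"`` (everyone), a population name (that population's
    stem branch), or ``"clade:<pop>"`` (a random internal clade of that
    population's coalescent tree).
    """
    all_ids = [s for ids in sample_ids.values() for s in ids]
    derived: dict[str, frozenset[str]] = {}
    for marker, where in config.snp_markers.items():
        if where == "root":
            derived[marker] = frozenset(all_ids)
        elif where in sample_ids:
            derived[marker] = frozenset(sample_ids[where])
        elif where.startswith("clade:"):
            pop = where.split(":", 1)[1]
            if pop not in clade_leaves or not clade_leaves[pop]:
                raise ValueError(
                    f"marker {marker}: no internal clades available in {pop!r}"
                )
            node = rng.choice(sorted(clade_leaves[pop]))
            derived[marker] = frozenset(clade_leaves[pop][node])
        else:
            raise ValueError(f"marker {marker}: unknown placement {where!r}")
    return derived


def simulate_star(config: SimConfig) -> SimResult:
    """Star-genealogy SMM simulation; deterministic given config.seed."""
    if config.genealogy != "star":
        raise ValueError("config.genealogy must be 'star'")
    founders = _population_founders(config, substream(config.seed, "founders"))
    rng = substream(config.seed, "star")
    profiles: list[StrProfile] = []
    sample_ids: dict[str, list[str]] = {}
    for pop in config.populations:
        k = rng.binomial(
            config.t_g, config.mu, size=(config.n, len(config.loci))
        )
        values = founders[pop.name][None, :] + _smm_displacement(rng, k)
        batch = _profiles_from_matrix(pop, values, config)
        profiles.extend(batch)
        sample_ids[pop.name] = [p.sample_id for p in batch]

    snp_derived = _resolve_snps(
        config, {}, sample_ids, substream(config.seed, "snps")
    )
    truth = SimTruth(
        founders={k: tuple(int(x) for x in v) for k, v in founders.items()},
        t_g=config.t_g,
        population_of={p.sample_id: p.population for p in profiles},
        haplogroup_of={p.sample_id: p.haplogroup for p in profiles},
        snp_derived=snp_derived,
    )
    return SimResult(profiles=profiles, truth=truth, config=config)


def simulate_coalescent(config: SimConfig) -> SimResult:
    """Kingman-coalescent SMM simulation (one genealogy per population)."""
    if config.genealogy != "coalescent":
        raise ValueError("config.genealogy must be 'coalescent'")
    import msprime

    founders = _population_founders(config, substream(config.seed, "founders"))
    rng = substream(config.seed, "coalescent")
    profiles: list[StrProfile] = []
    sample_ids: dict[str, list[str]] = {}
    clade_leaves: dict[str, dict[int, list[str]]] = {}

    for pop in config.populations:
        msp_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=config.n,
            ploidy=1,
            population_size=2.0 * config.ne,
            random_seed=msp_seed,
        )
        tree = ts.first()
        L = len(config.loci)
        values: dict[int, np.ndarray] = {tree.root: founders[pop.name].copy()}
        order = list(tree.nodes(order="preorder"))
        for u in order:
            if u == tree.root:
                continue
            t = tree.branch_length(u)
            k = rng.poisson(config.mu * t, size=L)
            values[u] = values[tree.parent(u)] + _smm_displacement(rng, k)
        leaf_values = np.vstack([values[i] for i in range(config.n)])
        batch = _profiles_from_matrix(pop, leaf_values, config)
        profiles.extend(batch)
        ids = [p.sample_id for p in batch]
        sample_ids[pop.name] = ids

        clades = {}
        for u in order:
            leaves = [ids[l] for l in tree.leaves(u)]
            if u != tree.root and 2 <= len(leaves) < config.n:
                clades[int(u)] = leaves
        clade_leaves[pop.name] = clades

    snp_derived = _resolve_snps(
        config, clade_leaves, sample_ids, substream(config.seed, "snps")
    )
    truth = SimTruth(
        founders={k: tuple(int(x) for x in v) for k, v in founders.items()},
        t_g=config.t_g,
        population_of={p.sample_id: p.population for p in profiles},
        haplogroup_of={p.sample_id: p.haplogroup for p in profiles},
        snp_derived=snp_derived,
    )
    return SimResult(profiles=profiles, truth=truth, config=config)


def simulate(config: SimConfig) -> SimResult:
    if config.genealogy == "star":
        return simulate_star(config)
    return simulate_coalescent(config)


# ----------------------------------------------------------------------
def inject_anomalies(
    profiles: Sequence[StrProfile],
    microvariant_rate: float,
    duplication_rate: float,
    seed: int,
    catalog: LocusCatalog | None = None,
) -> tuple[list[StrProfile], int]:
    """Randomly give samples a +0.2 partial-repeat allele and/or a second
    allele at a single-copy locus.  Returns (new profiles, count injected).
    """
    for rate in (microvariant_rate, duplication_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("anomaly rates must lie in [0, 1]")
    rng = substream(seed, "anomalies")
    out: list[StrProfile] = []
    injected = 0
    for p in profiles:
        if catalog is None:
            loci = sorted(p.alleles)
        else:
            loci = [l for l in sorted(p.alleles) if not catalog.is_multi_copy(l)]
        hit_micro = rng.random() < microvariant_rate
        hit_dup = rng.random() < duplication_rate
        if not (hit_micro and loci) and not (hit_dup and loci):
            out.append(p)
            continue
        alleles = dict(p.alleles)
        if hit_micro and loci:
            locus = loci[rng.integers(len(loci))]
            vals = alleles[locus]
            alleles[locus] = (vals[0] + Decimal("0.2"),) + vals[1:]
        if hit_dup and loci:
            locus = loci[rng.integers(len(loci))]
            vals = alleles[locus]
            alleles[locus] = vals + (vals[0] + 1,)
        injected += 1
        out.append(replace(p, alleles=alleles))
    return out, injected


def truth_snp_calls(
    result: SimResult, tree: HaplogroupTree
) -> dict[str, SnpCalls]:
    """Complete SNP call sets implied by the simulation truth.

    A sample is derived at every marker of every node on the root path of
    its true haplogroup (plus any explicitly placed marker covering it) and
    ancestral at every other tree marker.
    """
    calls: dict[str, SnpCalls] = {}
    for p in result.profiles:
        sid = p.sample_id
        node = result.truth.haplogroup_of.get(sid)
        derived_markers: set[str] = set()
        if node is not None:
            for n in tree.path_from_root(node):
                derived_markers.update(tree.nodes[n].markers)
        for marker, samples in result.truth.snp_derived.items():
            if sid in samples and marker in tree.marker_node:
                derived_markers.add(marker)
        states = {
            m: (DERIVED if m in derived_markers else ANCESTRAL)
            for m in tree.marker_node
        }
        calls[sid] = SnpCalls(states)
    return calls
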