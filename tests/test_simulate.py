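"""Stepwise-mutation-model simulator: determinism, expectations, anomalies,
SNP layering."""

import numpy as np
import pytest

from ystrkit.catalog import MINHT_LOCI, default_catalog
from ystrkit.classify import classify
from ystrkit.profiles import filter_atypical, to_minht
from ystrkit.simulate import (
    PopulationSpec,
    SimConfig,
    inject_anomalies,
    simulate_coalescent,
    simulate_star,
    truth_snp_calls,
)


@pytest.fixture(scope="module")
def cat():
    return default_catalog()


class TestSimConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mu=1.5)
        with pytest.raises(ValueError):
            SimConfig(microvariant_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(genealogy="ladder")

    def test_founder_length_must_match_loci(self):
        with pytest.raises(ValueError):
            SimConfig(founder=(13, 13))


class TestStar:
    def test_mu_zero_all_founder(self, cat):
        res = simulate_star(SimConfig(n=10, mu=0.0, seed=1))
        for p in res.profiles:
            assert to_minht(p, cat) == res.truth.founders["pop1"]

    def test_same_seed_identical_output(self, cat):
        cfg = SimConfig(n=25, t_g=500, seed=77)
        a, b = simulate_star(cfg), simulate_star(cfg)
        assert [p.alleles for p in a.profiles] == [p.alleles for p in b.profiles]

    def test_different_seed_differs(self):
        a = simulate_star(SimConfig(n=50, t_g=2000, seed=1))
        b = simulate_star(SimConfig(n=50, t_g=2000, seed=2))
        assert [p.alleles for p in a.profiles] != [p.alleles for p in b.profiles]

    def test_asd_expectation_matches_mu_t(self, cat):
        """Analytic check: E[ASD about the founder] = mu * T_g."""
        from ystrkit.dating import asd

        cfg = SimConfig(n=2000, t_g=1000, mu=6.9e-4, seed=42)
        res = simulate_star(cfg)
        haps = [to_minht(p, cat) for p in res.profiles]
        per, mean = asd(haps, res.truth.founders["pop1"])
        expected = cfg.mu * cfg.t_g
        # Monte-Carlo SE of the mean over n*L displacement draws
        draws = np.asarray([tuple(h) for h in haps], float) - np.asarray(
            res.truth.founders["pop1"], float
        )
        se = (draws**2).std(ddof=1) / np.sqrt(draws.size)
        assert abs(mean - expected) < 3 * se

    def test_population_divergence_shifts_founders(self):
        cfg = SimConfig(
            n=5, t_g=10, mu=0.0, seed=3, divergence_gens=500,
            populations=(PopulationSpec("A"), PopulationSpec("B")),
        )
        res = simulate_star(cfg)
        assert set(res.truth.founders) == {"A", "B"}


class TestCoalescent:
    def test_pairwise_asd_expectation(self, cat):
        """n=2: E[ASD] = 2 mu E[TMRCA] = 4 ne mu (heavy-tailed, 400 reps)."""
        ne, mu = 500.0, 6.9e-4
        vals = []
        for rep in range(400):
            res = simulate_coalescent(
                SimConfig(genealogy="coalescent", n=2, ne=ne, mu=mu,
                          seed=9000 + rep)
            )
            a, b = (np.array(to_minht(p, cat)) for p in res.profiles)
            vals.append(((a - b) ** 2).mean())
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 4 * ne * mu) < 3 * se

    def test_tiny_ne_near_founder(self, cat):
        res = simulate_coalescent(
            SimConfig(genealogy="coalescent", n=2, ne=1.0, mu=6.9e-4, seed=5)
        )
        founder = np.array(res.truth.founders["pop1"])
        for p in res.profiles:
            assert np.abs(np.array(to_minht(p, cat)) - founder).sum() <= 2

    def test_clade_snp_marks_exactly_that_clade(self):
        res = simulate_coalescent(
            SimConfig(genealogy="coalescent", n=12, ne=200.0, seed=8,
                      snp_markers={"M3": "clade:pop1"})
        )
        derived = res.truth.snp_derived["M3"]
        assert 2 <= len(derived) < 12
        all_ids = {p.sample_id for p in res.profiles}
        assert derived < all_ids

    def test_deterministic(self):
        cfg = SimConfig(genealogy="coalescent", n=10, ne=300.0, seed=21)
        a, b = simulate_coalescent(cfg), simulate_coalescent(cfg)
        assert [p.alleles for p in a.profiles] == [p.alleles for p in b.profiles]


class TestAnomalies:
    def test_zero_rates_identity(self):
        res = simulate_star(SimConfig(n=10, seed=2))
        out, k = inject_anomalies(res.profiles, 0.0, 0.0, seed=4)
        assert k == 0
        assert [p.alleles for p in out] == [p.alleles for p in res.profiles]

    def test_rate_one_microvariant_excludes_everyone(self, cat):
        res = simulate_star(SimConfig(n=20, seed=2))
        out, k = inject_anomalies(res.profiles, 1.0, 0.0, seed=4)
        assert k == 20
        kept, excluded = filter_atypical(out, MINHT_LOCI, cat)
        assert kept == [] and len(excluded) == 20

    def test_reproducible_binomial_count(self):
        res = simulate_star(SimConfig(n=500, seed=6))
        out1, k1 = inject_anomalies(res.profiles, 0.1, 0.0, seed=99)
        out2, k2 = inject_anomalies(res.profiles, 0.1, 0.0, seed=99)
        assert k1 == k2
        assert [p.alleles for p in out1] == [p.alleles for p in out2]
        # plausible Binomial(500, ~0.1) draw
        assert 20 <= k1 <= 85

    def test_duplication_is_second_allele_at_single_copy_locus(self, cat):
        res = simulate_star(SimConfig(n=10, seed=2))
        out, k = inject_anomalies(res.profiles, 0.0, 1.0, seed=4)
        assert k == 10
        for p in out:
            assert len(p.duplicated_loci(cat)) == 1


class TestSnpTruth:
    def test_branch_snps_define_clades(self, tree):
        cfg = SimConfig(
            n=8, t_g=100, seed=13,
            populations=(PopulationSpec("andes", haplogroup="Q1a3a1a"),
                         PopulationSpec("mexico", haplogroup="Q1a3a1")),
            snp_markers={"M242": "root"},
        )
        res = simulate_star(cfg)
        assert len(res.truth.snp_derived["M242"]) == 16

    def test_classifier_recovers_generating_branch(self, tree):
        """Complete simulated SNP calls classify every sample back to its
        generating node."""
        cfg = SimConfig(
            n=15, t_g=100, seed=17,
            populations=(
                PopulationSpec("a", haplogroup="Q1a3a1a"),
                PopulationSpec("b", haplogroup="Q1a3a1"),
                PopulationSpec("c", haplogroup="Q1a"),
                PopulationSpec("d", haplogroup="Q1b"),
            ),
        )
        res = simulate_star(cfg)
        calls = truth_snp_calls(res, tree)
        for p in res.profiles:
            label = classify(calls[p.sample_id], tree)
            assert tree.node_of_label(label) == res.truth.haplogroup_of[p.sample_id]
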