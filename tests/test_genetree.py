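"""Coalescent gene-tree simulation under MSC, MSC-I and MSC-M."""

import numpy as np
import pytest
from scipy import stats

from readcoal import (
    IntrogressionEvent,
    MigrationBand,
    SpeciesNetwork,
    simulate_gene_tree,
)

THETA = 0.01
FIVE_TAU = {k: v * THETA for k, v in dict(r=5, s=4, t=3, u=4.5).items()}
FIVE_TOPO = "(((A,B)t,C)s,(D,E)u)r;"


def _five_species(**kwargs):
    return SpeciesNetwork(FIVE_TOPO, tau=FIVE_TAU, theta=THETA, **kwargs)


class TestSinglePopulation:
    def test_pair_tmrca_is_exponential(self, rng):
        """Two alleles in one population coalesce at rate 2/theta: the TMRCA
        is Exponential with mean theta/2."""
        net = SpeciesNetwork("(A,B)r;", tau={"r": 0.5}, theta=THETA)
        times = np.array([
            simulate_gene_tree(net, {"A": 2}, rng).root_time for _ in range(20000)
        ])
        assert times.mean() == pytest.approx(THETA / 2, rel=0.03)
        p = stats.kstest(times, stats.expon(scale=THETA / 2).cdf).pvalue
        assert p > 0.01

    def test_ancestral_entry_shifts_tmrca(self, rng):
        """One allele from each of two species: TMRCA - tau is Exponential
        with mean theta/2 in the ancestral population."""
        tau = 0.02
        net = SpeciesNetwork("(A,B)r;", tau={"r": tau}, theta=THETA)
        times = np.array([
            simulate_gene_tree(net, {"A": 1, "B": 1}, rng).root_time
            for _ in range(10000)
        ])
        assert times.min() >= tau
        p = stats.kstest(times - tau, stats.expon(scale=THETA / 2).cdf).pvalue
        assert p > 0.01


class TestTreeStructure:
    def test_tip_count_and_labels(self, tree_b, rng):
        tree = simulate_gene_tree(tree_b, {s: 4 for s in tree_b.species}, rng)
        tips = tree.tips()
        assert len(tips) == 20
        assert tips[0].label == "A_1_1"
        assert {(t.species, t.individual, t.allele) for t in tips} == {
            (sp, ind, al)
            for sp in "ABCDE" for ind in (1, 2) for al in (1, 2)
        }

    def test_times_weakly_increase_toward_root(self, tree_b, rng):
        tree = simulate_gene_tree(tree_b, {s: 2 for s in tree_b.species}, rng)

        def check(node):
            for child in node.children:
                assert child.time <= node.time
                check(child)

        check(tree.root)

    def test_one_allele_per_species_coalesces_above_shallowest_split(self, tree_b, rng):
        """With one allele per species no within-population pair exists below
        the shallowest ancestral divergence."""
        shallowest = min(tree_b.tau(n) for n in "stu")
        for _ in range(50):
            tree = simulate_gene_tree(tree_b, {s: 1 for s in tree_b.species}, rng)
            assert min(tree.coalescent_times()) >= shallowest

    def test_newick_round_trips_through_dendropy(self, tree_b, rng):
        import dendropy

        tree = simulate_gene_tree(tree_b, {s: 2 for s in tree_b.species}, rng)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 10
        root_depth = max(
            leaf.distance_from_root() for leaf in parsed.leaf_nodes()
        )
        assert root_depth == pytest.approx(tree.root_time, rel=1e-6)


class TestGeneFlow:
    def test_zero_rate_migration_keeps_rng_stream(self):
        """Migration bands with rate 0 never fire and leave the random stream
        untouched, so the simulated trees are bit-identical to plain MSC."""
        net_mig = _five_species(migrations=[MigrationBand("B", "C", 0.0)])
        net_plain = _five_species()
        for seed in range(20):
            a = simulate_gene_tree(net_mig, {s: 2 for s in net_plain.species},
                                   np.random.default_rng(seed))
            b = simulate_gene_tree(net_plain, {s: 2 for s in net_plain.species},
                                   np.random.default_rng(seed))
            assert a.newick() == b.newick()

    def test_phi_zero_matches_plain_msc_in_distribution(self, rng):
        net_i = _five_species(introgressions=[
            IntrogressionEvent("B", "C", THETA, 0.0),
            IntrogressionEvent("D", "E", THETA, 0.0),
        ])
        net_plain = _five_species()
        a = [simulate_gene_tree(net_i, {s: 2 for s in net_plain.species}, rng).root_time
             for _ in range(3000)]
        b = [simulate_gene_tree(net_plain, {s: 2 for s in net_plain.species}, rng).root_time
             for _ in range(3000)]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_phi_one_routes_every_lineage_through_donor(self, rng):
        """With phi = 1 and coalescence suppressed in the recipient branch,
        lineages sampled from the recipient must coalesce on the donor side,
        far below the root divergence."""
        tau_r = 50 * THETA
        net = SpeciesNetwork(
            "(B,C)r;", tau={"r": tau_r},
            theta={"B": THETA, "C": 1e9, "r": THETA},
            introgressions=[IntrogressionEvent("B", "C", 0.5 * THETA, 1.0)],
        )
        for _ in range(100):
            t = simulate_gene_tree(net, {"C": 2}, rng).root_time
            assert 0.5 * THETA < t < tau_r

    def test_phi_zero_strands_lineages_in_recipient(self, rng):
        """Converse control: with phi = 0 the same lineages stay in the
        huge recipient population and cannot coalesce before the root."""
        tau_r = 50 * THETA
        net = SpeciesNetwork(
            "(B,C)r;", tau={"r": tau_r},
            theta={"B": THETA, "C": 1e9, "r": THETA},
            introgressions=[IntrogressionEvent("B", "C", 0.5 * THETA, 0.0)],
        )
        for _ in range(50):
            assert simulate_gene_tree(net, {"C": 2}, rng).root_time >= tau_r

    def test_strong_migration_lowers_cross_population_divergence(self, rng):
        """Gene flow B->C reduces the B-C pair divergence relative to no
        migration (sanity direction check on the backward jump rate)."""
        net_mig = _five_species(migrations=[MigrationBand("B", "C", 2.0)])
        net_plain = _five_species()
        samples = {"B": 1, "C": 1}
        with_mig = np.mean([
            simulate_gene_tree(net_mig, samples, rng).root_time for _ in range(2000)
        ])
        without = np.mean([
            simulate_gene_tree(net_plain, samples, rng).root_time for _ in range(2000)
        ])
        assert with_mig < without


class TestInputChecks:
    def test_invalid_network_is_rejected(self, rng):
        net = SpeciesNetwork("(A,B)r;", tau={"r": 0.02}, theta=-1.0)
        with pytest.raises(ValueError, match="invalid species network"):
            simulate_gene_tree(net, {"A": 2}, rng)

    def test_fewer_than_two_alleles_rejected(self, rng, tree_b):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_gene_tree(tree_b, {"A": 1}, rng)
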