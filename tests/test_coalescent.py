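"""Multispecies-coalescent simulator and density, clock models, and the
full synthetic-replicate generator."""

import math

import numpy as np
import pytest

from speciesdelim.clock import gene_branch_rates, simulate_branch_rates
from speciesdelim.coalescent import (
    PopSizeMap,
    msc_log_density,
    simulate_gene_tree,
)
from speciesdelim.experiment import ExperimentConfig, sample_experiment_from_priors
from speciesdelim.tree import TimeTree, parse_newick


def single_species_tree():
    return TimeTree(["A"], [-1], [-1], [-1], [0.0])


def first_coalescence_labels(g):
    first = min(g.internal_nodes, key=lambda i: g.heights[i])
    labs = set()
    stack = [first]
    while stack:
        i = stack.pop()
        if g.is_leaf(i):
            labs.add(g.labels[i])
        else:
            stack.extend(g.children(i))
    return labs


class TestSimulateGeneTree:
    def test_pairwise_coalescent_mean(self, rng):
        sp = single_species_tree()
        pops = PopSizeMap.constant(sp, 0.3)
        times = [
            simulate_gene_tree(sp, pops, 2, rng)[0].root_height
            for _ in range(10000)
        ]
        se = 0.3 / math.sqrt(len(times))
        assert abs(np.mean(times) - 0.3) < 3 * se

    def test_three_species_concordance_formula(self, rng):
        tau, ne = 0.3, 0.2
        sp = parse_newick(f"((A:0.5,B:0.5):{tau},C:{0.5 + tau});")
        pops = PopSizeMap.constant(sp, ne)
        n = 20000
        match = sum(
            first_coalescence_labels(simulate_gene_tree(sp, pops, 1, rng)[0])
            == {"A_1", "B_1"}
            for _ in range(n)
        )
        theo = 1 - (2 / 3) * math.exp(-tau / ne)
        se = math.sqrt(theo * (1 - theo) / n)
        assert abs(match / n - theo) < 3 * se

    def test_concordance_limit_deep_split(self, rng):
        sp = parse_newick("((A:0.1,B:0.1):4.0,C:4.1);")
        pops = PopSizeMap.constant(sp, 0.2)
        match = sum(
            first_coalescence_labels(simulate_gene_tree(sp, pops, 1, rng)[0])
            == {"A_1", "B_1"}
            for _ in range(500)
        )
        assert match / 500 > 0.99

    def test_matches_msprime_topology_frequencies(self, rng):
        """Independent oracle: msprime's coalescent under the same 3-species
        demography yields the same species-topology concordance."""
        msprime = pytest.importorskip("msprime")
        tau, ne_time = 0.4, 0.25
        sp = parse_newick(f"((A:0.5,B:0.5):{tau},C:{0.5 + tau});")
        pops = PopSizeMap.constant(sp, ne_time)
        n = 8000
        ours = (
            sum(
                first_coalescence_labels(simulate_gene_tree(sp, pops, 1, rng)[0])
                == {"A_1", "B_1"}
                for _ in range(n)
            )
            / n
        )
        # with ploidy=1 a pair coalesces at rate 1/initial_size, matching
        # our pairwise rate 1/Ne when initial_size = Ne
        dem = msprime.Demography()
        for name in ("A", "B", "C", "AB", "ABC"):
            dem.add_population(name=name, initial_size=ne_time)
        dem.add_population_split(time=0.5, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(
            time=0.5 + tau, derived=["AB", "C"], ancestral="ABC"
        )
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1},
            demography=dem,
            ploidy=1,
            num_replicates=n,
            random_seed=123,
        )
        theirs = 0
        for ts in reps:
            tree = ts.first()
            mrca = tree.mrca(0, 1)  # samples 0,1 are A,B
            theirs += tree.num_samples(mrca) == 2
        theirs /= n
        se = math.sqrt(ours * (1 - ours) / n)
        assert abs(ours - theirs) < 4 * se

    def test_zero_sample_species_allowed(self, rng):
        sp = parse_newick("((A:0.5,B:0.5):0.3,C:0.8);")
        pops = PopSizeMap.constant(sp, 0.2)
        g, mapping = simulate_gene_tree(sp, pops, {"A": 2, "B": 1, "C": 0}, rng)
        assert g.n_leaves == 3
        assert set(mapping.values()) == {"A", "B"}

    def test_reproducible_given_seed(self):
        sp = parse_newick("((A:0.5,B:0.5):0.3,C:0.8);")
        pops = PopSizeMap.constant(sp, 0.2)
        g1, _ = simulate_gene_tree(sp, pops, 2, np.random.default_rng(7))
        g2, _ = simulate_gene_tree(sp, pops, 2, np.random.default_rng(7))
        assert g1.to_newick() == g2.to_newick()


class TestMscLogDensity:
    def test_single_species_closed_form(self, rng):
        sp = single_species_tree()
        pops = PopSizeMap.constant(sp, 0.3)
        g, mapping = simulate_gene_tree(sp, pops, 2, rng)
        t = g.root_height
        assert msc_log_density(g, sp, pops, mapping) == pytest.approx(
            -math.log(0.3) - t / 0.3
        )

    def test_simulator_density_consistency_ks(self, rng):
        """Root heights of the 2-sample simulator follow the exponential
        implied by the density's closed form (KS distance < 0.02)."""
        from scipy import stats

        sp = single_species_tree()
        pops = PopSizeMap.constant(sp, 0.4)
        heights = [
            simulate_gene_tree(sp, pops, 2, rng)[0].root_height
            for _ in range(10000)
        ]
        d, _ = stats.kstest(heights, "expon", args=(0, 0.4))
        assert d < 0.02

    def test_incompatible_gene_tree_zero_density(self):
        sp = parse_newick("((A:0.5,B:0.5):0.3,C:0.8);")
        pops = PopSizeMap.constant(sp, 0.2)
        # A/B coalesce below the species divergence at 0.5: impossible
        bad = parse_newick("((A_1:0.2,B_1:0.2):0.7,C_1:0.9);")
        mapping = {"A_1": "A", "B_1": "B", "C_1": "C"}
        assert msc_log_density(bad, sp, pops, mapping) == -math.inf

    def test_compatible_three_species_positive_density(self):
        sp = parse_newick("((A:0.5,B:0.5):0.3,C:0.8);")
        pops = PopSizeMap.constant(sp, 0.2)
        good = parse_newick("((A_1:0.6,B_1:0.6):0.4,C_1:1.0);")
        mapping = {"A_1": "A", "B_1": "B", "C_1": "C"}
        assert math.isfinite(msc_log_density(good, sp, pops, mapping))

    def test_missing_sample_in_map_raises_via_zero_density(self):
        sp = parse_newick("(A:0.5,B:0.5);")
        pops = PopSizeMap.constant(sp, 0.2)
        g = parse_newick("(A_1:0.7,B_1:0.7);")
        assert msc_log_density(g, sp, pops, {"A_1": "A"}) == -math.inf


class TestClock:
    def test_degenerate_stdev_gives_unit_rates(self, random_tree, rng):
        t = random_tree(n=6, seed=0)
        rates = simulate_branch_rates(t, 1e-4, rng)
        assert all(abs(r - 1) < 1e-3 for r in rates.values())

    def test_mean_one_parameterisation(self, rng):
        t = TimeTree(["A"], [-1], [-1], [-1], [0.0])
        s = 0.5
        draws = np.concatenate(
            [
                list(simulate_branch_rates(t, s, rng).values())
                for _ in range(30000)
            ]
        )
        se = math.sqrt((math.exp(s * s) - 1) / draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se
        med = np.median(draws)
        assert abs(med - math.exp(-s * s / 2)) < 0.01

    def test_invalid_stdev(self, random_tree, rng):
        with pytest.raises(ValueError):
            simulate_branch_rates(random_tree(seed=0), 0.0, rng)

    def test_gene_rates_are_time_weighted_averages(self, rng):
        sp = parse_newick("((A:0.5,B:0.5):0.3,C:0.8);")
        pops = PopSizeMap.constant(sp, 0.05)
        g, mapping = simulate_gene_tree(sp, pops, 1, rng)
        const = {i: 2.5 for i in range(sp.n_nodes)}
        rates = gene_branch_rates(g, sp, mapping, const)
        assert all(r == pytest.approx(2.5) for r in rates.values())
        # rates bounded by the min/max species rate
        varied = {i: 1.0 + 0.3 * i for i in range(sp.n_nodes)}
        rates = gene_branch_rates(g, sp, mapping, varied)
        lo, hi = min(varied.values()), max(varied.values())
        assert all(lo - 1e-12 <= r <= hi + 1e-12 for r in rates.values())


class TestExperimentGenerator:
    def test_deterministic_given_seed(self):
        cfg = ExperimentConfig(n_species=3, n_loci=1, sites=50, sir_particles=128)
        r1 = sample_experiment_from_priors(cfg, np.random.default_rng(11))
        r2 = sample_experiment_from_priors(cfg, np.random.default_rng(11))
        assert r1.omega == r2.omega
        assert r1.species_tree.to_newick() == r2.species_tree.to_newick()
        assert r1.genes[0].alignment == r2.genes[0].alignment

    def test_omega_marginal_matches_tilted_hyperprior(self):
        """The joint prior couples omega to the tree through the slab's
        omega-dependent normaliser.  For two taxa the normaliser is
        Z(omega) = omega + (1 - omega)/2 exactly, so the omega marginal is
        proportional to Beta(1,2)(omega) * Z(omega), whose mean is
        (1/4)/(2/3) = 3/8.  The truth sampler must reproduce it."""
        from speciesdelim.experiment import sample_truth

        cfg = ExperimentConfig(n_species=2, sir_particles=64)
        omegas = [
            sample_truth(cfg, np.random.default_rng([21, i]))[0]
            for i in range(500)
        ]
        # var of the tilted marginal: E[w^2] = 1/5 -> var ~ 0.0594
        se = math.sqrt(0.0594 / len(omegas))
        assert abs(np.mean(omegas) - 3 / 8) < 3 * se

    def test_gene_trees_respect_species_constraints(self):
        cfg = ExperimentConfig(n_species=4, n_loci=3, sites=20, sir_particles=256)
        rep = sample_experiment_from_priors(cfg, np.random.default_rng(5))
        for gene in rep.genes:
            lp = msc_log_density(
                gene.gene_tree, rep.species_tree, rep.pops, gene.mapping
            )
            assert math.isfinite(lp)
        assert rep.true_partition is not None
        assert rep.true_partition.taxa == set(rep.species_tree.labels)

    def test_replicate_round_trips_through_disk(self, tmp_path):
        from speciesdelim.experiment import read_replicate, write_replicate

        cfg = ExperimentConfig(n_species=3, n_loci=2, sites=30, sir_particles=128)
        rep = sample_experiment_from_priors(cfg, np.random.default_rng(2))
        write_replicate(rep, tmp_path)
        back = read_replicate(tmp_path)
        assert back.omega == pytest.approx(rep.omega)
        assert back.true_partition == rep.true_partition
        assert back.genes[0].alignment == rep.genes[0].alignment
        assert back.genes[1].gene_tree.to_newick(precision=9) == rep.genes[
            1
        ].gene_tree.to_newick(precision=9)
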