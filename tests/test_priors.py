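"""Collapse-prior densities: spike/slab components, birth-death and
Yule-skyline slabs, and direct simulation from the prior."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from speciesdelim.priors import (
    BirthDeathParams,
    CollapseConfig,
    SkylineConfig,
    assemble_ranked_tree,
    bd_node_log_density,
    birth_death_collapse_log_prior,
    collapse_log_prior,
    epoch_statistics,
    exp_slab_log_density,
    sample_tree_from_collapse_prior,
    sample_tree_from_ysc_prior,
    spike_log_density,
    yule_skyline_log_marginal,
    ysc_slab_log_factor,
)
from speciesdelim.tree import count_collapsed, extract_clusters, parse_newick


class TestSpikeAndExpSlab:
    def test_spike_value_and_support(self):
        eps = 0.02
        assert spike_log_density(0.5 * eps, eps) == pytest.approx(math.log(1 / eps))
        assert spike_log_density(2 * eps, eps) == -math.inf

    def test_spike_normalised(self):
        eps = 0.37
        val, _ = integrate.quad(lambda h: math.exp(spike_log_density(h, eps)), 0, eps)
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_spike_domain_error(self):
        with pytest.raises(ValueError):
            spike_log_density(0.1, -1.0)

    def test_exp_slab_at_threshold_and_support(self):
        assert exp_slab_log_density(0.1, 0.1, 3.0) == pytest.approx(math.log(3.0))
        assert exp_slab_log_density(0.05, 0.1, 3.0) == -math.inf

    def test_exp_slab_normalised(self):
        val, _ = integrate.quad(
            lambda h: math.exp(exp_slab_log_density(h, 0.1, 2.5)), 0.1, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_exp_slab_small_rate_limit(self):
        assert math.exp(exp_slab_log_density(5.0, 0.1, 1e-9)) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_mixture_normalised(self):
        eps, omega, lam = 0.1, 0.3, 2.0
        mix = lambda h: (1 - omega) * math.exp(
            exp_slab_log_density(h, eps, lam)
        ) + omega * math.exp(spike_log_density(h, eps))
        lo, _ = integrate.quad(mix, 0, eps)
        hi, _ = integrate.quad(mix, eps, np.inf)
        assert lo + hi == pytest.approx(1.0, abs=1e-8)


class TestCollapseLogPrior:
    def test_two_taxon_spike_only(self):
        t = parse_newick("(A:0.05,B:0.05);")
        cfg = CollapseConfig(0.1, 0.4)
        lp = collapse_log_prior(t, lambda h: 0.0, cfg)
        assert lp == pytest.approx(math.log(0.4 / 0.1))

    def test_omega_zero_degenerates_to_slab(self):
        cfg = CollapseConfig(0.1, 0.0)
        above = parse_newick("((A:0.2,B:0.2):0.3,C:0.5);")
        slab = lambda h: exp_slab_log_density(h, 0.1, 2.0)
        expected = sum(
            slab(float(above.heights[i])) for i in above.internal_nodes
        )
        assert collapse_log_prior(above, slab, cfg) == pytest.approx(expected)
        below = parse_newick("((A:0.05,B:0.05):0.3,C:0.35);")
        assert collapse_log_prior(below, slab, cfg) == -math.inf

    def test_all_collapsed_pure_spike_product(self):
        t = parse_newick("((A:0.01,B:0.01):0.02,C:0.03);")
        cfg = CollapseConfig(0.1, 0.4)
        lp = collapse_log_prior(t, lambda h: 0.0, cfg)
        assert lp == pytest.approx(2 * math.log(0.4 / 0.1))

    def test_omega_one_with_slab_node_zero_density(self):
        t = parse_newick("((A:0.01,B:0.01):0.5,C:0.51);")
        cfg = CollapseConfig(0.1, 1.0)
        assert collapse_log_prior(t, lambda h: 0.0, cfg) == -math.inf


class TestBirthDeathSlab:
    def test_yule_large_origin_equals_exp_slab(self):
        bd = BirthDeathParams(2.0, 0.0, 1e9)
        for h in (0.1, 0.5, 3.0):
            assert bd_node_log_density(h, bd, 0.1) == pytest.approx(
                exp_slab_log_density(h, 0.1, 2.0), abs=1e-6
            )

    @pytest.mark.parametrize("mu", [0.0, 0.7, 2.0])
    def test_node_density_normalised(self, mu):
        bd = BirthDeathParams(2.0, mu, 4.0)
        val, _ = integrate.quad(
            lambda h: math.exp(bd_node_log_density(h, bd, 0.1)), 0.1, 4.0
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_three_taxon_yule_vs_exp_slab_collapse(self):
        t = parse_newick("((A:0.3,B:0.3):0.4,C:0.7);")
        cfg = CollapseConfig(0.1, 0.3)
        bd = BirthDeathParams(1.5, 0.0, 1e9)
        got = birth_death_collapse_log_prior(t, bd, cfg)
        want = collapse_log_prior(
            t, lambda h: exp_slab_log_density(h, 0.1, 1.5), cfg
        )
        assert got == pytest.approx(want, abs=1e-6)

    def test_origin_below_root_is_error(self):
        t = parse_newick("((A:0.3,B:0.3):0.4,C:0.7);")
        with pytest.raises(ValueError):
            birth_death_collapse_log_prior(
                t, BirthDeathParams(1.0, 0.0, 0.5), CollapseConfig(0.1, 0.3)
            )

    def test_relabeling_invariance(self):
        cfg = CollapseConfig(0.1, 0.3)
        bd = BirthDeathParams(2.0, 0.5, 5.0)
        a = parse_newick("((A:0.3,B:0.3):0.4,C:0.7);")
        b = parse_newick("((C:0.3,A:0.3):0.4,B:0.7);")
        assert birth_death_collapse_log_prior(a, bd, cfg) == pytest.approx(
            birth_death_collapse_log_prior(b, bd, cfg)
        )


class TestEpochStatistics:
    def test_single_epoch_is_total_lineage_length(self):
        t = parse_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        b, L = epoch_statistics(t, 0.1, [0.1, 1.0])
        assert list(b) == [2]
        # 3 lineages on [0.1, 0.5), 2 on [0.5, 1.0)
        assert L[0] == pytest.approx(3 * 0.4 + 2 * 0.5)

    def test_two_epoch_hand_integration(self):
        t = parse_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        b, L = epoch_statistics(t, 0.1, [0.1, 0.55, 1.0])
        assert list(b) == [1, 1]
        assert L[0] == pytest.approx(3 * 0.4 + 2 * 0.05)
        assert L[1] == pytest.approx(2 * 0.45)

    def test_collapsed_clusters_count_as_single_lineages(self):
        # cherry at 0.01 is collapsed at eps=0.1: 2 lineages above eps
        t = parse_newick("((A:0.01,B:0.01):0.99,C:1.0);")
        b, L = epoch_statistics(t, 0.1, [0.1, 1.0])
        assert list(b) == [1]
        assert L[0] == pytest.approx(2 * 0.9)

    def test_totals_match_numerical_lineage_integral(self, random_tree):
        for seed in range(10):
            t = random_tree(n=7, seed=seed)
            eps = 0.1
            hs = np.sort(t.heights[t.n_leaves:])
            hs_above = hs[hs >= eps]
            if hs_above.size == 0:
                continue
            root = t.root_height
            grid = np.linspace(eps, root, 4 + 1)
            b, L = epoch_statistics(t, eps, grid)
            assert b.sum() == hs_above.size
            ts = np.linspace(eps, root, 200001)
            count = hs_above.size + 1 - np.searchsorted(hs_above, ts, side="right")
            assert L.sum() == pytest.approx(
                np.trapezoid(count, ts), rel=1e-4
            )

    def test_malformed_grid_rejected(self, random_tree):
        t = random_tree(seed=1)
        with pytest.raises(ValueError):
            epoch_statistics(t, 0.1, [0.2, 0.1])
        with pytest.raises(ValueError):
            epoch_statistics(t, 0.1, [0.3, 0.5])


class TestYuleSkylineMarginal:
    def _quad_oracle(self, tree, cfg, sky):
        """Single-epoch marginal by numeric integration over the birth rate."""
        eps = cfg.epsilon
        k = count_collapsed(tree, eps)
        n = tree.n_leaves
        b, L = epoch_statistics(
            tree, eps, [eps, tree.root_height]
        )
        yule = lambda lam: lam ** b[0] * np.exp(-lam * L[0])
        val, _ = integrate.quad(
            lambda lam: yule(lam) * stats.gamma.pdf(lam, sky.alpha, scale=1 / sky.beta),
            0,
            np.inf,
        )
        lp = math.log(val)
        if k:
            lp += k * math.log(cfg.omega / eps)
        if n - k - 1:
            lp += (n - k - 1) * math.log(1 - cfg.omega)
        return lp

    def test_single_epoch_matches_quadrature_fixed_tree(self):
        t = parse_newick("(((A:0.05,B:0.05):0.45,C:0.5):0.5,D:1.0);")
        cfg = CollapseConfig(0.1, 0.3)
        sky = SkylineConfig(1, 2.0, 0.5)
        assert yule_skyline_log_marginal(t, cfg, sky) == pytest.approx(
            self._quad_oracle(t, cfg, sky), abs=1e-6
        )

    def test_single_epoch_matches_quadrature_random_trees(self, random_tree):
        cfg = CollapseConfig(0.1, 0.3)
        sky = SkylineConfig(1, 1.7, 0.8)
        checked = 0
        for seed in range(25):
            t = random_tree(n=5, seed=seed)
            if count_collapsed(t, 0.1) == t.n_leaves - 1:
                continue
            assert yule_skyline_log_marginal(t, cfg, sky) == pytest.approx(
                self._quad_oracle(t, cfg, sky), abs=1e-6
            )
            checked += 1
        assert checked >= 20

    def test_all_collapsed_empty_slab_product(self):
        t = parse_newick("((A:0.01,B:0.01):0.02,C:0.03);")
        cfg = CollapseConfig(0.1, 0.4)
        sky = SkylineConfig(4, 2.0, 0.5)
        assert yule_skyline_log_marginal(t, cfg, sky) == pytest.approx(
            2 * math.log(0.4 / 0.1)
        )

    def test_large_shape_limit_is_fixed_rate_yule(self, random_tree):
        lam0 = 2.5
        sky = SkylineConfig(1, 1e6, 1e6 / lam0)
        for seed in range(5):
            t = random_tree(n=6, seed=seed)
            eps = 0.1
            b, L = epoch_statistics(t, eps, [eps, t.root_height])
            want = b[0] * math.log(lam0) - lam0 * L[0]
            assert ysc_slab_log_factor(t, eps, sky) == pytest.approx(want, rel=1e-3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SkylineConfig(0, 2.0, 0.5)
        with pytest.raises(ValueError):
            SkylineConfig(4, -1.0, 0.5)

    def test_exchangeable_under_relabeling(self):
        cfg = CollapseConfig(0.1, 0.3)
        sky = SkylineConfig(4, 2.0, 0.5)
        a = parse_newick("((A:0.3,B:0.3):0.4,C:0.7);")
        b = parse_newick("((B:0.3,C:0.3):0.4,A:0.7);")
        assert yule_skyline_log_marginal(a, cfg, sky) == pytest.approx(
            yule_skyline_log_marginal(b, cfg, sky)
        )


class TestPriorSampling:
    def test_omega_extremes(self, rng):
        cfg1 = CollapseConfig(0.1, 1.0)
        t = sample_tree_from_collapse_prior(6, cfg1, 2.0, rng)
        assert extract_clusters(t, 0.1).n_clusters == 1
        cfg0 = CollapseConfig(1e-6, 0.0)
        t = sample_tree_from_collapse_prior(6, cfg0, 1e-3, rng)
        assert extract_clusters(t, 1e-6).n_clusters == 6

    def test_collapsed_fraction_matches_omega(self, rng):
        cfg = CollapseConfig(0.1, 0.3)
        n, draws = 5, 10000
        ks = [
            count_collapsed(sample_tree_from_collapse_prior(n, cfg, 2.0, rng), 0.1)
            for _ in range(draws)
        ]
        frac = np.mean(ks) / (n - 1)
        se = math.sqrt(0.3 * 0.7 / (draws * (n - 1)))
        assert abs(frac - 0.3) < 3 * se

    def test_assembled_trees_are_valid(self, rng):
        heights = rng.random(7)
        t = assemble_ranked_tree(heights, [f"x{i}" for i in range(8)], rng)
        t.validate()

    def test_ysc_sampler_two_taxon_matches_closed_form(self, rng):
        """For n=2 the node height density has a closed form: the slab part of
        the coded density is alpha beta^alpha / (beta + 2(h-eps))^(alpha+1)
        (two lineages above the threshold), i.e. half a Lomax(alpha,
        scale beta/2) density.  The importance resampler must reproduce
        the normalised spike/slab mixture exactly."""
        eps, omega = 0.1, 0.3
        cfg = CollapseConfig(eps, omega)
        sky = SkylineConfig(1, 2.0, 0.7)
        draws = np.array(
            [
                sample_tree_from_ysc_prior(
                    2, cfg, sky, rng, n_particles=256
                ).root_height
                for _ in range(400)
            ]
        )
        z = omega + (1 - omega) / 2

        def cdf(h):
            h = np.asarray(h)
            spike = np.clip(h / eps, 0, 1)
            u = np.maximum(h - eps, 0)
            slab = 1.0 - (1.0 + 2 * u / sky.beta) ** (-sky.alpha)
            return (omega * spike + 0.5 * (1 - omega) * slab) / z

        stat, p = stats.kstest(draws, cdf)
        assert p > 0.01
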