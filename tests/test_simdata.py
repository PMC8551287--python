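import numpy as np
import pytest

from ssikit import simdata
from ssikit.simdata import (
    CrossingPlan,
    GeneticMap,
    TraitArchitecture,
    default_map,
    make_dh_family,
    overlapping_plan,
    sample_architecture,
    simulate_founders,
    simulate_population,
    simulate_trial,
)


class TestGeneticMap:
    def test_default_map_structure(self):
        gmap = default_map(100, 10)
        assert gmap.n_markers == 100
        assert len(np.unique(gmap.chromosome)) == 10
        for c in range(10):
            pos = gmap.position[gmap.chromosome == c]
            assert np.all(np.diff(pos) >= 0)

    def test_decreasing_positions_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneticMap([0, 0], [0.5, 0.1])


class TestFounders:
    def test_mean_presence_half(self):
        gmap = default_map(100, 5)
        F = simulate_founders(10, gmap, 0.5, seed=1)
        assert F.shape == (10, 100)
        assert abs(F.mean() - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_boundary_frequency_rejected(self):
        gmap = default_map(10, 2)
        with pytest.raises(ValueError, match="strictly"):
            simulate_founders(3, gmap, 1.0, seed=0)

    def test_deterministic(self):
        gmap = default_map(4, 2)
        a = simulate_founders(2, gmap, 0.5, seed=42)
        b = simulate_founders(2, gmap, 0.5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_too_few_founders(self):
        with pytest.raises(ValueError, match="two founders"):
            simulate_founders(1, default_map(10, 2), 0.5, seed=0)


class TestDHFamily:
    def test_identical_parents_no_segregation(self):
        gmap = default_map(30, 3)
        parent = simulate_founders(2, gmap, 0.5, seed=3)[0]
        fam = make_dh_family(parent, parent, gmap, 25, seed=4)
        assert np.all(fam == parent[None, :])

    def test_single_differing_locus_mendelian(self):
        gmap = default_map(10, 1)
        pa = np.zeros(10, dtype=int)
        pb = np.zeros(10, dtype=int)
        pb[4] = 1
        fam = make_dh_family(pa, pb, gmap, 20000, seed=5)
        freq = fam[:, 4].mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / 20000)
        assert np.all(fam[:, :4] == 0) and np.all(fam[:, 5:] == 0)

    def test_haldane_recombination_fraction(self):
        # two adjacent markers at d = 0.1 M in coupling: r = (1 - e^-0.2)/2
        gmap = GeneticMap([0, 0], [0.0, 0.1])
        pa = np.array([1, 1])
        pb = np.array([0, 0])
        n = 20000
        fam = make_dh_family(pa, pb, gmap, n, seed=6)
        recombinant = (fam[:, 0] != fam[:, 1]).mean()
        r = 0.5 * (1 - np.exp(-0.2))
        assert r == pytest.approx(0.09063, abs=1e-5)
        assert abs(recombinant - r) < 3 * np.sqrt(r * (1 - r) / n)

    def test_homozygosity_exact_01(self):
        gmap = default_map(50, 5)
        F = simulate_founders(2, gmap, 0.5, seed=7)
        fam = make_dh_family(F[0], F[1], gmap, 100, seed=8)
        assert set(np.unique(fam)) <= {0, 1}

    def test_length_mismatch(self):
        gmap = default_map(10, 2)
        with pytest.raises(ValueError, match="length"):
            make_dh_family(np.zeros(9), np.zeros(10), gmap, 5, seed=0)


class TestPlan:
    def test_invalid_parent_rejected(self):
        with pytest.raises(ValueError, match="founder pool"):
            CrossingPlan([[0, 1]], [[(0, 2)]], [5])

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError, match="no families"):
            CrossingPlan([[0, 1]], [[]], [5])

    def test_overlapping_plan_shares_parents(self):
        plan = overlapping_plan(3, 6, 2, 4, 10, seed=9)
        assert plan.n_cycles == 3
        for c in range(1, 3):
            shared = set(plan.founder_pools[c]) & set(plan.founder_pools[c - 1])
            assert len(shared) == 2


class TestArchitecture:
    def test_rho_bounds(self):
        with pytest.raises(ValueError, match="rho_g"):
            TraitArchitecture([0], np.zeros((2, 1)), rho_g=1.5, h2_true=0.5)

    def test_effect_correlation_converges(self):
        arch = sample_architecture(5000, 4000, 2, rho_g=0.6, h2_true=0.5, seed=10)
        r = np.corrcoef(arch.effects[0], arch.effects[1])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_heterogeneity_dial_monotone(self):
        rs = []
        for rho in (0.0, 0.5, 1.0):
            arch = sample_architecture(2000, 1500, 2, rho_g=rho, h2_true=0.5, seed=11)
            rs.append(np.corrcoef(arch.effects[0], arch.effects[1])[0, 1])
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] == pytest.approx(1.0)


class TestPopulation:
    def test_h2_one_noise_free(self):
        gmap = default_map(60, 4)
        plan = overlapping_plan(2, 4, 1, 3, 15, seed=12)
        arch = sample_architecture(60, 20, 2, rho_g=0.5, h2_true=1.0, seed=13)
        pop = simulate_population(plan, gmap, arch, seed=14)
        for c in (0, 1):
            mask = pop.cycles == c
            centred = pop.true_bv[mask] - pop.true_bv[mask].mean()
            np.testing.assert_allclose(pop.phenotype[mask], centred)

    def test_realized_h2_near_target(self):
        gmap = default_map(200, 10)
        plan = overlapping_plan(4, 8, 3, 10, 50, seed=15)
        arch = sample_architecture(200, 80, 4, rho_g=0.4, h2_true=0.5, seed=16)
        pop = simulate_population(plan, gmap, arch, seed=17)
        for c in range(4):
            mask = pop.cycles == c
            r2 = np.corrcoef(pop.phenotype[mask], pop.true_bv[mask])[0, 1] ** 2
            assert r2 == pytest.approx(0.5, abs=0.05)

    def test_true_bv_formula(self):
        gmap = default_map(40, 4)
        plan = overlapping_plan(2, 4, 1, 2, 10, seed=18)
        arch = sample_architecture(40, 15, 2, rho_g=0.5, h2_true=0.8, seed=19)
        pop = simulate_population(plan, gmap, arch, seed=20)
        Xq = pop.markers.X[:, arch.qtl_idx].astype(float)
        for c in (0, 1):
            mask = pop.cycles == c
            np.testing.assert_allclose(pop.true_bv[mask], Xq[mask] @ arch.effects[c])

    def test_shared_parents_raise_cross_cycle_kinship(self):
        from ssikit.kernels import additive_kernel

        gmap = default_map(200, 10)
        arch = sample_architecture(200, 50, 3, rho_g=1.0, h2_true=0.5, seed=21)
        shared = overlapping_plan(3, 6, 4, 6, 20, seed=22)
        disjoint = overlapping_plan(3, 6, 0, 6, 20, seed=22)
        kin = {}
        for tag, plan in (("shared", shared), ("disjoint", disjoint)):
            pop = simulate_population(plan, gmap, arch, seed=23)
            f = pop.markers.presence_freq()
            G = additive_kernel(pop.markers.select_markers((f > 0) & (f < 1))).values
            m0 = pop.cycles == 0
            m2 = pop.cycles == 2
            kin[tag] = G[np.ix_(m0, m2)].mean()
        assert kin["shared"] > kin["disjoint"]

    def test_deterministic(self):
        gmap = default_map(50, 5)
        plan = overlapping_plan(2, 4, 1, 3, 10, seed=24)
        arch = sample_architecture(50, 20, 2, rho_g=0.3, h2_true=0.6, seed=25)
        a = simulate_population(plan, gmap, arch, seed=26)
        b = simulate_population(plan, gmap, arch, seed=26)
        np.testing.assert_array_equal(a.markers.X, b.markers.X)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)


class TestTrial:
    @pytest.fixture(scope="class")
    def pop(self):
        gmap = default_map(50, 5)
        plan = overlapping_plan(1, 4, 1, 4, 25, seed=27)
        arch = sample_architecture(50, 20, 1, rho_g=1.0, h2_true=0.8, seed=28)
        return simulate_population(plan, gmap, arch, seed=29)

    def test_degenerate_design_equals_genotype_effect(self, pop):
        rec = simulate_trial(pop, 1, 1, 4, {"error": 0.0}, seed=30, mu=2.0)
        g = pop.true_bv - pop.true_bv.mean()
        np.testing.assert_allclose(rec["value"].to_numpy(), 2.0 + g)

    def test_record_count(self, pop):
        rec = simulate_trial(pop, 2, 2, 5, seed=31)
        assert len(rec) == 4 * pop.n_lines

    def test_block_variance_recovered(self, pop):
        # many blocks -> empirical variance of generated block effects near spec
        rec = simulate_trial(pop, 10, 2, 10, {"block": 2.0, "error": 0.1}, seed=32)
        effects = rec.groupby("block")["_block_effect"].first()
        n_blocks = len(effects)
        assert n_blocks == 200
        se = 2.0 * np.sqrt(2.0 / n_blocks)
        assert abs(effects.var(ddof=1) - 2.0) < 3 * se

    def test_negative_variance_rejected(self, pop):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_trial(pop, 1, 1, 2, {"block": -1.0})

    def test_bad_counts_rejected(self, pop):
        with pytest.raises(ValueError, match=">= 1"):
            simulate_trial(pop, 0, 1, 2)
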