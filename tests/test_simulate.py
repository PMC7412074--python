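import warnings

import numpy as np
import pytest

from clonescape.clones import assign_mlg, mismatch_matrix
from clonescape.io import AlleleFrequencies, Genotype
from clonescape.simulate import (
    SimulationConfig,
    TruePopulation,
    grid_sample,
    label_patches,
    simulate_population,
)


class TestSimulatePopulation:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=7, n_genets=30, arena=(20, 20))
        p1, p2 = simulate_population(cfg), simulate_population(cfg)
        assert np.array_equal(p1.x, p2.x) and np.array_equal(p1.y, p2.y)
        assert np.array_equal(p1.genet_id, p2.genet_id)
        assert all(a.alleles == b.alleles for a, b in zip(p1.genotypes, p2.genotypes))

    def test_no_mutation_means_genet_identical(self):
        cfg = SimulationConfig(seed=3, n_genets=20, arena=(20, 20), mutation_rate=0.0)
        pop = simulate_population(cfg)
        for g in range(pop.n_genets):
            genos = [pop.genotypes[i].alleles for i in np.nonzero(pop.genet_id == g)[0]]
            assert len(set(genos)) <= 1

    def test_mutation_rate_creates_near_clones(self):
        cfg = SimulationConfig(seed=3, n_genets=15, arena=(20, 20), mutation_rate=0.01)
        pop = simulate_population(cfg)
        mutated = sum(
            pop.genotypes[i].alleles != pop.genotypes[np.nonzero(pop.genet_id == g)[0][0]].alleles
            for g in range(pop.n_genets)
            for i in np.nonzero(pop.genet_id == g)[0]
        )
        assert mutated > 0

    def test_all_singletons_recover_full_richness(self):
        cfg = SimulationConfig(
            seed=5, n_genets=25, arena=(30, 30), clone_sizes=tuple([1] * 25)
        )
        pop = simulate_population(cfg)
        units_cfg_mm = mismatch_matrix_units(pop)
        assert units_cfg_mm.n_mlg == 25

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(seed=1, n_genets=500, arena=(5, 5), exclusion=2.0)
        with pytest.raises(RuntimeError, match="exclusion"):
            simulate_population(cfg)

    def test_selfing_inflates_homozygosity(self):
        rng_free = simulate_population(SimulationConfig(seed=11, n_genets=200, arena=(200, 200)))
        selfed = simulate_population(
            SimulationConfig(seed=11, n_genets=200, arena=(200, 200), selfing_rate=0.9)
        )

        def homozygosity(pop):
            reps = [pop.genotypes[np.nonzero(pop.genet_id == g)[0][0]] for g in range(pop.n_genets)]
            return np.mean([a == b for g in reps for a, b in g.alleles])

        assert homozygosity(selfed) > homozygosity(rng_free)


def mismatch_matrix_units(pop):
    from clonescape.io import Dataset, SampleUnit

    units = [
        SampleUnit(f"r{i:04d}", float(pop.x[i]), float(pop.y[i]), "P", pop.genotypes[i])
        for i in range(pop.n_ramets)
    ]
    m = mismatch_matrix(units)
    return assign_mlg(m, [u.sample_id for u in units], 0)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genets=12, clone_sizes=tuple([2] * 12),
                               architecture="guerrilla", sigma=3.0)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_shipped_scenario_matches_defaults(self):
        from pathlib import Path

        path = Path(__file__).resolve().parents[1] / "examples" / "default_scenario.yaml"
        assert SimulationConfig.from_yaml(path) == SimulationConfig()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mutation_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(sigma=0.0)


class TestLabelPatches:
    def test_two_distant_clusters(self):
        cfg = SimulationConfig(seed=2, n_genets=2, arena=(100, 100),
                               clone_sizes=(5, 5), exclusion=0.0)
        pop = simulate_population(cfg)
        # force two tight, distant clusters
        pop.x[:5], pop.y[:5] = np.linspace(0, 1, 5), np.zeros(5)
        pop.x[5:], pop.y[5:] = 50 + np.linspace(0, 1, 5), np.zeros(5)
        ids = label_patches(pop, connectivity_radius=2.0)
        assert len(set(ids)) == 2

    def test_isolated_ramet_own_patch(self):
        cfg = SimulationConfig(seed=2, n_genets=1, arena=(10, 10), clone_sizes=(1,))
        pop = simulate_population(cfg)
        ids = label_patches(pop, connectivity_radius=1.0)
        assert len(set(ids)) == 1 and pop.patch_outlines

    def test_components_match_networkx_oracle(self):
        import networkx as nx

        cfg = SimulationConfig(seed=9, n_genets=30, arena=(25, 25))
        pop = simulate_population(cfg)
        r = 1.5
        ids = label_patches(pop, connectivity_radius=r)
        g = nx.Graph()
        g.add_nodes_from(range(pop.n_ramets))
        for i in range(pop.n_ramets):
            for j in range(i + 1, pop.n_ramets):
                if np.hypot(pop.x[i] - pop.x[j], pop.y[i] - pop.y[j]) <= r:
                    g.add_edge(i, j)
        comps = list(nx.connected_components(g))
        assert len(set(ids)) == len(comps)
        for comp in comps:
            assert len({ids[i] for i in comp}) == 1


def _manual_population(ramets, outlines, patch_ids):
    """Build a TruePopulation by hand for sampling-rule checks."""
    n = len(ramets)
    cfg = SimulationConfig(seed=0, n_genets=n, allele_counts=(30,),
                           clone_sizes=tuple([1] * n))
    genotypes = [Genotype(((i + 1, i + 1),)) for i in range(n)]
    pop = TruePopulation(
        config=cfg,
        x=np.array([r[0] for r in ramets]),
        y=np.array([r[1] for r in ramets]),
        genet_id=np.arange(n),
        genotypes=genotypes,
        seed_points=np.array(ramets),
        allele_freqs=AlleleFrequencies(list(cfg.locus_names), [{i + 1: 1 / n for i in range(n)}]),
        patch_ids=np.array(patch_ids),
        patch_outlines=outlines,
    )
    return pop


class TestGridSample:
    def test_majority_cover_extending_patch_yields_two(self):
        # patch covers 75% of quadrant (0,0)-(1,1) and extends beyond
        outline = [(0.0, 0.0), (1.5, 0.0), (1.5, 0.75), (0.0, 0.75)]
        ramets = [(0.2, 0.2), (0.5, 0.5), (0.8, 0.3), (1.2, 0.5)]
        pop = _manual_population(ramets, {"P001": outline}, ["P001"] * 4)
        res = grid_sample(pop, seed=0)
        q = res.quadrat_counts.set_index(["cell_x", "cell_y"])
        assert q.loc[(0, 0), "n_sampled"] == 2  # >50% cover
        assert q.loc[(1, 0), "n_sampled"] == 1  # <50% cover

    def test_patch_wholly_inside_capped_by_availability(self):
        outline = [(0.2, 0.2), (0.6, 0.2), (0.6, 0.6), (0.2, 0.6)]
        pop = _manual_population([(0.4, 0.4)], {"P001": outline}, ["P001"])
        res = grid_sample(pop, seed=0)
        assert res.dataset.n_units == 1  # wants 2, only 1 ramet exists

    def test_empty_quadrant_warns_and_skips(self):
        outline = [(0.0, 0.0), (1.9, 0.0), (1.9, 0.9), (0.0, 0.9)]
        pop = _manual_population([(0.5, 0.5)], {"P001": outline}, ["P001"])
        with pytest.warns(UserWarning, match="no ramet"):
            res = grid_sample(pop, seed=0)
        assert res.dataset.n_units == 1

    def test_same_seed_identical_sample(self, sim_sampled):
        pop, res = sim_sampled
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = grid_sample(pop, seed=pop.config.seed + 1)
        assert [u.sample_id for u in res.dataset.units] == [
            u.sample_id for u in res2.dataset.units
        ]
        assert [u.genotype.alleles for u in res.dataset.units] == [
            u.genotype.alleles for u in res2.dataset.units
        ]

    def test_truth_comparison_at_zero_mutation(self, sim_sampled, sim_partition):
        pop, res = sim_sampled
        _, part = sim_partition
        truth = res.truth
        n_true_sampled = truth.true_genet.nunique()
        # distinct founder genotypes among sampled genets can collide only by
        # chance; MLG count can never exceed the sampled genet count
        assert part.n_mlg <= n_true_sampled
        # genotype-identical partition should recover the sampled genet count
        # exactly when founder genotypes are unique (check they are)
        founders = {tuple(pop.genotypes[np.nonzero(pop.genet_id == g)[0][0]].alleles)
                    for g in truth.true_genet.unique()}
        if len(founders) == n_true_sampled:
            assert part.n_mlg == n_true_sampled

    def test_requires_labelled_patches(self):
        pop = simulate_population(SimulationConfig(seed=0, n_genets=5, arena=(10, 10)))
        with pytest.raises(ValueError, match="label_patches"):
            grid_sample(pop)


def test_sampled_frequencies_consistent_with_truth(sim_sampled):
    """Allele frequencies estimated from the sample track the generating ones."""
    from clonescape.io import allele_frequencies

    pop, res = sim_sampled
    ds = res.dataset
    est = allele_frequencies(ds.units, ds.locus_names)
    n_copies = 2 * ds.n_units
    for li in range(ds.n_loci):
        for a, p in pop.allele_freqs[li].items():
            se = np.sqrt(max(p * (1 - p), 1e-6) / n_copies)
            # clonal resampling inflates variance; allow a wide but bounded band
            assert abs(est[li].get(a, 0.0) - p) < 10 * se + 0.05
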