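import warnings

import numpy as np
import pytest

from clonescape.io import Dataset, Genotype, SampleUnit
from clonescape.simulate import (
    SimulationConfig,
    grid_sample,
    label_patches,
    simulate_population,
)


def make_unit(sid, x, y, patch, pairs):
    return SampleUnit(sid, x, y, patch, Genotype(tuple(pairs)))


@pytest.fixture
def toy_dataset():
    """Six units, two loci: one 3-ramet clone, one pair, one singleton."""
    clone_a = [(100, 102), (200, 200)]
    clone_b = [(100, 104), (200, 202)]
    single = [(102, 104), (202, 204)]
    units = [
        make_unit("a1", 0.0, 0.0, "P1", clone_a),
        make_unit("a2", 0.5, 0.0, "P1", clone_a),
        make_unit("a3", 0.0, 0.5, "P1", clone_a),
        make_unit("b1", 5.0, 5.0, "P2", clone_b),
        make_unit("b2", 5.5, 5.0, "P2", clone_b),
        make_unit("c1", 9.0, 9.0, "P2", single),
    ]
    return Dataset(["locA", "locB"], units)


@pytest.fixture(scope="session")
def sim_sampled():
    """A small simulated phalanx population, grid-sampled, with truth."""
    cfg = SimulationConfig(seed=42, n_genets=40, arena=(22.0, 22.0))
    pop = simulate_population(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        label_patches(pop)
        res = grid_sample(pop)
    return pop, res


@pytest.fixture(scope="session")
def sim_partition(sim_sampled):
    from clonescape import assign_mlg, mismatch_matrix

    _, res = sim_sampled
    units = res.dataset.units
    mm = mismatch_matrix(units)
    return units, assign_mlg(mm, [u.sample_id for u in units])


def random_genotype(rng, allele_counts):
    return Genotype(
        tuple(
            (int(rng.integers(1, k + 1)), int(rng.integers(1, k + 1)))
            for k in allele_counts
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
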