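import numpy as np
import pytest

import spetkit as sk
from spetkit.simulate import SimulationConfig, SpeciesSpec


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down simulated experiment used throughout the unit tests."""
    base = dict(
        n_contigs=2,
        contig_length=120_000,
        genes_per_contig=30,
        species=[
            SpeciesSpec("crop", 0.0, 20, 6, 0.004),
            SpeciesSpec("wild_close", 0.01, 0, 3, 0.008),
            SpeciesSpec("wild_mid", 0.03, 0, 3, 0.010),
            SpeciesSpec("wild_far", 0.06, 0, 3, 0.012),
        ],
        depth_mean=40.0,
        depth_dispersion=5.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def demo_fixture():
    """The default-condition simulated experiment (full ladder, all reads)."""
    return sk.build_fixture(seed=11)


@pytest.fixture(scope="session")
def demo_genotypes(demo_fixture):
    fx = demo_fixture
    matrix, depths, report = sk.genotype_pipeline(
        fx.reads, fx.panel, fx.genome, fx.run_config
    )
    return matrix, depths, report


@pytest.fixture(scope="session")
def small_fixture():
    return sk.build_fixture(sim_config=small_sim_config(), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
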