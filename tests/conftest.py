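"""Shared fixtures: one small simulated scenario reused across test modules."""

import numpy as np
import pytest

from loadscape import genolik, simdata


@pytest.fixture(scope="session")
def small_config():
    return simdata.SimulationConfig(
        n_pops=2,
        pop_sizes=(120, 40),
        split_gens=(40,),
        selfing_rates=(0.0, 0.5),
        seq_length=120_000,
        n_genes=20,
        gene_length=900,
        mean_depth=8.0,
        seed=11,
        n_sample=(14, 10),
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simdata.simulate_populations(small_config)


@pytest.fixture(scope="session")
def small_pileup(small_truth, small_config):
    return simdata.simulate_pileups(small_truth, small_config)


@pytest.fixture(scope="session")
def small_gl(small_pileup, small_config):
    return genolik.glmatrix_from_pileup(small_pileup, small_config.error_rate)


@pytest.fixture(scope="session")
def small_variants(small_gl):
    # explicit filters: the session scenario is sequenced at 8x, far above
    # the ~2x panels the named profiles are calibrated for
    return genolik.call_snps(small_gl, min_ind=12, max_depth=10_000)


@pytest.fixture(scope="session")
def small_genotypes(small_gl, small_variants):
    return genolik.call_genotypes(small_gl, small_variants, min_depth=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
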