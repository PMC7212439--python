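"""Shared fixtures: founder populations and scheme configurations at sizes
that keep the suite fast while exercising every code path."""

from __future__ import annotations

import numpy as np
import pytest

from gocsim import GenomeSpec, SchemeConfig, run_founder


@pytest.fixture(scope="session")
def mini_spec() -> GenomeSpec:
    """Very small genome for scheme-level tests: 2 x 50 cM chromosomes,
    40 candidate loci/cM, 1 IBD tracer/cM."""
    return GenomeSpec(
        n_chromosomes=2,
        chrom_length_cM=50.0,
        loci_per_cM=40.0,
        mutation_rate=2.0e-4,
        ibd_loci_per_cM=1.0,
    )


@pytest.fixture(scope="session")
def mini_founder(mini_spec):
    return run_founder(mini_spec, 100, pop_size=50, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def reduced_founder():
    """The reduced-preset founder population used in scaled-down
    reproductions."""
    return run_founder(GenomeSpec.reduced(), 200, rng=np.random.default_rng(1))


@pytest.fixture
def mini_config() -> SchemeConfig:
    """Tiny but structurally complete scheme: 4 + 10 base animals, 40
    offspring per generation, truncation 2 x 5 x 4, OCS 5 matings x 8."""
    return SchemeConfig(
        n_base_males=4,
        n_base_females=10,
        offspring_per_generation=40,
        trunc_n_sires=2,
        trunc_dams_per_sire=5,
        trunc_offspring_per_mating=4,
        ocs_n_matings=5,
        ocs_offspring_per_mating=8,
        n_generations=8,
        metric_span=(6, 8),
        ea_budget=800,
        random_n_sires=5,
        random_n_dams=5,
    )
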