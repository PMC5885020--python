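import numpy as np
import pytest

from phagani import anib
from phagani.simgenomes import GroupDesign, SimConfig, simulate


def three_group_config(seed: int = 11) -> SimConfig:
    """Three groups plus two satellite lineages: tight within-group
    divergence, satellites at intermediate distance, deep between-group
    divergence — the discontinuity pattern the delineation relies on."""
    return SimConfig(
        genome_length=15_000,
        n_genes=22,
        gene_length_range=(300, 900),
        seed=seed,
        groups=[
            GroupDesign("A", 7, within_divergence=0.05, stem_divergence=0.13,
                        satellite_members=1,
                        satellite_divergence_range=(0.10, 0.12),
                        recomb_rate=2.0, tract_mean_len=700),
            GroupDesign("B", 5, within_divergence=0.04, stem_divergence=0.13,
                        satellite_members=1,
                        satellite_divergence_range=(0.10, 0.12)),
            GroupDesign("C", 4, within_divergence=0.06, stem_divergence=0.14),
        ],
    )


@pytest.fixture(scope="session")
def three_group_sample():
    genomes, tables, truth = simulate(three_group_config())
    return genomes, tables, truth


@pytest.fixture(scope="session")
def three_group_matrix(three_group_sample):
    genomes, _, _ = three_group_sample
    return anib.compute_all(genomes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
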