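import numpy as np
import pytest

from paleohexkit.model import Gene, Genome
from paleohexkit.simulate import SimulationConfig, simulate


def make_genome(name, chrom_sizes, ploidy_events=()):
    """A genome with consecutively numbered genes, 1 kb apart."""
    chroms = {}
    counter = 0
    for chrom, n in chrom_sizes.items():
        genes = []
        for i in range(n):
            genes.append(Gene(f"{name}g{counter}", chrom, i * 1000,
                              i * 1000 + 600))
            counter += 1
        chroms[chrom] = genes
    g = Genome(name, chroms, list(ploidy_events))
    g.sort_and_index()
    return g


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230419)


@pytest.fixture(scope="session")
def small_sim():
    """Small triplicated scenario with biased loss and planted fusions."""
    cfg = SimulationConfig(
        seed=11, n_chromosomes=4, genes_per_chromosome=120,
        descendants=("da", "db"),
        shared_events=(("EEJ", "chr1.sg1", "chr2.sg1"),),
        subgenome_loss_rates=(0.2, 0.4, 0.6))
    return simulate(cfg)
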