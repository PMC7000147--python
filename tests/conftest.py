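import numpy as np
import pytest

from splicescope import (
    SimConfig,
    simulate_gene_models,
    simulate_junction_tables,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_study(sim_config):
    """One synthetic study shared across tests: genome, models, NE genes,
    junction tables and planted truth."""
    genome, models, ne_genes = simulate_gene_models(sim_config)
    tables, truth = simulate_junction_tables(models, sim_config)
    return {
        "config": sim_config,
        "genome": genome,
        "models": models,
        "ne_genes": ne_genes,
        "tables": tables,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def codon_free_of_stops(rng, n_codons):
    """Random coding sequence with no stop codon in frame 0."""
    stops = {"TAA", "TAG", "TGA"}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in stops]
    return "".join(rng.choice(codons, size=n_codons))


@pytest.fixture()
def stopfree_seq():
    return codon_free_of_stops(np.random.default_rng(7), 400)
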