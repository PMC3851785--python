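import numpy as np
import pytest

from genomedecay.pipeline import run_comparative
from genomedecay.synthetic_data import EvolutionParams, simulate_pair

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_scenario():
    """The standard study conditions: 300 genes, 2 inversions, 5% pseudogenization,
    ~85% cross-strain protein identity, fixed seed."""
    params = EvolutionParams(seed=DEFAULT_SEED)
    ancestor, genome_a, genome_b, truth_a, truth_b = simulate_pair(params)
    return {"params": params, "ancestor": ancestor,
            "genome_a": genome_a, "genome_b": genome_b,
            "truth_a": truth_a, "truth_b": truth_b}


@pytest.fixture(scope="session")
def default_report(default_scenario):
    """Full pipeline run over the standard scenario (shared: it is the slow part)."""
    return run_comparative(default_scenario["genome_a"],
                           default_scenario["genome_b"])


@pytest.fixture(scope="session")
def small_pair():
    """A small, fast genome pair for pipeline plumbing tests."""
    params = EvolutionParams(seed=11, n_genes=30, gene_len_mean=120, gene_len_sd=20,
                             spacer_len_mean=250, spacer_len_sd=60,
                             n_inversions=1, inversion_span=8_000, rna_genes=2)
    ancestor, genome_a, genome_b, truth_a, truth_b = simulate_pair(params)
    return {"params": params, "ancestor": ancestor,
            "genome_a": genome_a, "genome_b": genome_b,
            "truth_a": truth_a, "truth_b": truth_b}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
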