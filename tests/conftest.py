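import numpy as np
import pytest

from nlrpool import SimParams, generate_pileup, generate_pool, generate_reference


@pytest.fixture(scope="session")
def small_reference():
    """30 short genes (some with introns, some minus-strand) plus models."""
    params = SimParams(n_genes=30, gene_length_bp=300, seed=11)
    seqs, genes = generate_reference(params, np.random.default_rng(11))
    return params, seqs, genes


@pytest.fixture(scope="session")
def study_pool():
    """A pool simulated under the emulated study conditions (mean depth
    346x, error rate 2e-3, pool of 20), sized for statistical power on
    recall/false-positive checks."""
    params = SimParams(
        n_genes=60,
        gene_length_bp=1200,
        polymorphic_fraction=0.5,
        snps_per_polymorphic_gene=18,
        seed=5,
    )
    rng = np.random.default_rng(5)
    reference = generate_reference(params, rng)
    truth = generate_pool(reference, params, None, rng)
    pileup = generate_pileup(reference, truth, params, rng)
    return params, reference, truth, pileup
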