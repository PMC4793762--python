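import numpy as np
import pytest

from influnet import ExpressionMatrix, GroundTruthNetwork, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_prefix="G", sample_prefix="S"):
    """Wrap a genes x samples array in an ExpressionMatrix with generated ids."""
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    return ExpressionMatrix(
        gene_ids=[f"{gene_prefix}{i:03d}" for i in range(1, n_g + 1)],
        sample_ids=[f"{sample_prefix}{j:03d}" for j in range(1, n_s + 1)],
        values=values,
    )


def random_matrix(n_genes, n_samples, seed, loc=100.0, scale=10.0):
    """Independent non-negative Gaussian expression (no structure)."""
    r = np.random.default_rng(seed)
    return make_matrix(np.abs(r.normal(loc, scale, size=(n_genes, n_samples))))


def chain_network(n_genes, beta=0.8):
    """A chain g1 -> g2 -> ... with a constant coefficient."""
    genes = [f"G{i:02d}" for i in range(1, n_genes + 1)]
    edges = [(genes[i], genes[i + 1], beta) for i in range(n_genes - 1)]
    return GroundTruthNetwork(genes=genes, edges=edges, topology_tag="chain")


@pytest.fixture
def chain_scenario():
    """10-gene chain SEM with its expression matrix and gold standard."""
    net = chain_network(10, beta=0.8)
    matrix, gold = simulate_expression(net, n_samples=500, noise_sd=1.0, baseline=10.0, seed=3)
    return net, matrix, gold
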