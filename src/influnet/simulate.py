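"""Synthetic directed regulatory networks and linear-Gaussian expression data.

The generative family is a linear structural equation model: each gene's
value per sample is

    x_g = baseline + sum_r coeff(r -> g) * x_r + Normal(0, noise_sd),

evaluated in topological order for acyclic networks (damped fixed-point
iteration for cyclic ones). Under this model every quantity the inference
pipeline computes — Pearson correlations, low-order partial correlations,
regression slopes — has a closed form, e.g. a single edge with coefficient
beta and unit noise gives corr(parent, child) = beta / sqrt(beta^2 + 1),
which makes analytic oracles possible in tests. The matrix is shifted by a
constant offset if needed so values are non-negative (recorded in metadata;
a shift changes no correlation), and the true edges are exported as a
gold-standard table with signs taken from the coefficient signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .evaluation import GoldStandardEdge
from .expression import ExpressionMatrix

__all__ = ["GroundTruthNetwork", "generate_network", "simulate_expression"]

_TOPOLOGIES = ("chain", "tree", "hub", "random_dag", "with_cycles")


@dataclass
class GroundTruthNetwork:
    """A directed, signed ground-truth regulatory network."""

    genes: list[str]
    edges: list[tuple[str, str, float]]  # (regulator, target, coefficient)
    topology_tag: str
    seed: int | None = None

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for reg, tgt, coeff in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop {reg}->{tgt}")
            if coeff == 0:
                raise ValueError(f"zero coefficient on {reg}->{tgt}")
            if reg not in gene_set or tgt not in gene_set:
                raise ValueError(f"edge {reg}->{tgt} references unknown gene")
        if self.topology_tag != "with_cycles" and not self.is_acyclic():
            raise ValueError(f"{self.topology_tag} network must be acyclic")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        for reg, tgt, coeff in self.edges:
            g.add_edge(reg, tgt, coefficient=coeff)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph())

    def gold_standard(self, reference: str = "ground-truth") -> list[GoldStandardEdge]:
        return [
            GoldStandardEdge(
                source=reg,
                target=tgt,
                sign="activation" if coeff > 0 else "inhibition",
                reference=reference,
            )
            for reg, tgt, coeff in self.edges
        ]


def _gene_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(
    n_genes: int,
    topology: str = "chain",
    edge_density: float = 0.1,
    coeff_range: tuple[float, float] = (0.6, 0.9),
    neg_fraction: float = 0.0,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Generate a directed ground-truth network of the requested topology.

    Topologies: ``chain`` (g1 -> g2 -> ... -> gn), ``tree`` (each gene past
    the root regulated by one random earlier gene), ``hub`` (g1 regulates all
    others), ``random_dag`` (each forward pair under the gene order wired
    independently with probability ``edge_density``), ``with_cycles``
    (random_dag plus back-edges at the same density — a stress-test topology
    with no accuracy promise). Coefficient magnitudes are uniform on
    ``coeff_range`` with a ``neg_fraction`` chance of negation. Deterministic
    given ``seed``.
    """
    if n_genes < 3:
        raise ValueError("n_genes must be >= 3")
    if topology not in _TOPOLOGIES:
        raise ValueError(f"topology must be one of {_TOPOLOGIES}")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    low, high = coeff_range
    if not 0 < low <= high:
        raise ValueError("coeff_range must satisfy 0 < low <= high")
    if not 0 <= neg_fraction <= 1:
        raise ValueError("neg_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    pairs: list[tuple[str, str]] = []
    if topology == "chain":
        pairs = [(genes[i], genes[i + 1]) for i in range(n_genes - 1)]
    elif topology == "tree":
        for i in range(1, n_genes):
            parent = int(rng.integers(0, i))
            pairs.append((genes[parent], genes[i]))
    elif topology == "hub":
        pairs = [(genes[0], genes[i]) for i in range(1, n_genes)]
    else:  # random_dag / with_cycles
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < edge_density:
                    pairs.append((genes[i], genes[j]))
        if topology == "with_cycles":
            for i in range(n_genes):
                for j in range(i + 1, n_genes):
                    if rng.random() < edge_density:
                        pairs.append((genes[j], genes[i]))

    edges = []
    for reg, tgt in pairs:
        coeff = float(rng.uniform(low, high))
        if rng.random() < neg_fraction:
            coeff = -coeff
        edges.append((reg, tgt, coeff))
    return GroundTruthNetwork(genes=genes, edges=edges, topology_tag=topology, seed=seed)


def simulate_expression(
    network: GroundTruthNetwork,
    n_samples: int,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
    seed: int | None = None,
    allow_cycles: bool = False,
    damping: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[ExpressionMatrix, list[GoldStandardEdge]]:
    """Sample an expression matrix from the network's structural equations.

    Acyclic networks are evaluated in one pass along a topological order.
    Cyclic networks (``allow_cycles=True``) are solved per sample by damped
    fixed-point iteration x <- (1-d) x + d (baseline + W x + eps) with the
    noise vector held fixed, converging to the equilibrium of the linear
    system when it exists. If the final matrix has negative entries a
    constant offset is added (recorded as ``meta["offset"]``), preserving all
    covariances exactly.

    Returns the matrix (genes x samples) and the matching gold-standard edge
    list sharing the same identifier namespace.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    g = network.graph()
    rng = np.random.default_rng(seed)
    idx = {gene: i for i, gene in enumerate(network.genes)}
    n = len(network.genes)
    noise = rng.normal(0.0, noise_sd, size=(n, n_samples))

    if network.is_acyclic():
        values = np.zeros((n, n_samples))
        for gene in nx.topological_sort(g):
            i = idx[gene]
            acc = baseline + noise[i]
            for reg in g.predecessors(gene):
                acc = acc + g.edges[reg, gene]["coefficient"] * values[idx[reg]]
            values[i] = acc
    else:
        if not allow_cycles:
            raise ValueError("network contains cycles; pass allow_cycles=True to iterate")
        W = np.zeros((n, n))
        for reg, tgt, coeff in network.edges:
            W[idx[tgt], idx[reg]] += coeff
        values = np.full((n, n_samples), baseline)
        drive = baseline + noise
        for _ in range(max_iter):
            nxt = (1.0 - damping) * values + damping * (drive + W @ values)
            if np.max(np.abs(nxt - values)) < tol:
                values = nxt
                break
            values = nxt
        else:
            raise RuntimeError("fixed-point iteration did not converge; system may be unstable")

    meta: dict = {"noise_sd": noise_sd, "baseline": baseline, "offset": 0.0}
    floor = values.min()
    if floor < 0:
        meta["offset"] = float(-floor)
        values = values - floor
    matrix = ExpressionMatrix(
        gene_ids=list(network.genes),
        sample_ids=[f"S{j + 1:04d}" for j in range(n_samples)],
        values=values,
        meta=meta,
    )
    return matrix, network.gold_standard()
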