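"""Synthetic OTU count tables with known ground-truth association structure.

Real microbiome composition tables are small (tens to a few hundred samples),
moderately wide (tens of taxa), overdispersed and zero-inflated (zero
fractions from a few percent to ~70%).  The generator emulates these
features with a Poisson-lognormal-style model: latent abundances are drawn
from a zero-mean multivariate Gaussian whose sparse precision matrix is the
ground-truth conditional-dependence network, mapped through an exponential
link scaled by a sequencing depth to Poisson means, and counts are then
zeroed at random until a target zero fraction is reached.  Everything is
reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import NetworkGraph
from .preprocess import OtuTable

logger = logging.getLogger(__name__)


@dataclass
class GroundTruthNetwork:
    """The simulator's latent precision matrix and its edge support."""

    precision: np.ndarray
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    edge_density: float
    seed: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.precision, dtype=float)
        adj = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(adj, adj.T) or np.any(np.diag(adj)):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        support = theta != 0
        np.fill_diagonal(support, False)
        if not np.array_equal(adj, support):
            raise ValueError("adjacency must equal the off-diagonal support of the precision")
        if np.linalg.eigvalsh(theta)[0] <= 0:
            raise ValueError("precision matrix must be positive-definite")
        self.precision = theta
        self.adjacency = adj

    @property
    def n_taxa(self) -> int:
        return self.precision.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency[np.triu_indices_from(self.adjacency, k=1)].sum())


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic table (Table-1-like defaults)."""

    n_samples: int = 300
    n_taxa: int = 50
    edge_density: float = 0.1
    target_sparsity: float = 0.35  # fraction of zero counts
    sequencing_depth: float = 50.0
    latent_variance: float = 2.0  # mean variance of latent log-abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_taxa < 2:
            raise ValueError("need n_samples >= 2 and n_taxa >= 2")
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must be in (0, 1)")
        if not 0.0 <= self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must be in [0, 1)")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.latent_variance <= 0:
            raise ValueError("latent_variance must be positive")


def sample_ground_truth(d: int, edge_density: float, seed: int,
                        max_retries: int = 10) -> GroundTruthNetwork:
    """Draw a sparse SPD precision matrix with the requested edge density.

    Off-diagonal support is Bernoulli(edge_density) on the upper triangle,
    magnitudes are uniform in [0.4, 0.8] with random signs, and the diagonal
    is set just above the row sums of absolute off-diagonals (strict diagonal
    dominance, hence SPD).  The tight dominance margin keeps partial
    correlations on true edges around 0.25-0.4, the strength of clearly
    detectable microbial associations.
    """
    if d < 2:
        raise ValueError("need d >= 2")
    if not 0.0 < edge_density < 1.0:
        raise ValueError("edge_density must be in (0, 1)")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        theta = np.zeros((d, d))
        iu = np.triu_indices(d, k=1)
        support = rng.random(len(iu[0])) < edge_density
        mags = rng.uniform(0.4, 0.8, size=len(iu[0]))
        signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
        theta[iu] = support * mags * signs
        theta += theta.T
        np.fill_diagonal(theta, 1.05 * np.abs(theta).sum(axis=1) + 0.2)
        if np.linalg.cond(theta) < 1e6:
            adjacency = theta != 0
            np.fill_diagonal(adjacency, False)
            return GroundTruthNetwork(precision=theta, adjacency=adjacency,
                                      edge_density=edge_density, seed=seed)
        logger.warning("ill-conditioned precision draw (attempt %d), retrying", attempt + 1)
    raise RuntimeError(f"could not draw a well-conditioned precision at density {edge_density}")


def simulate_counts(truth: GroundTruthNetwork, config: SimulationConfig) -> OtuTable:
    """Sample a count table whose latent dependence structure is ``truth``.

    Latent rows z ~ N(0, Theta^{-1}); counts ~ Poisson(depth * exp(z) / E[exp(z)])
    (normalizing by the lognormal mean so the depth sets the expected count).
    If the realized zero fraction falls short of ``target_sparsity``, the
    smallest nonzero counts are censored to zero (seeded random tie-breaks)
    until the target is reached — mimicking detection-limit zeros, which in
    real tables concentrate in low-abundance entries rather than uniformly
    at random.
    """
    rng = np.random.default_rng(config.seed)
    d = truth.n_taxa
    if d != config.n_taxa:
        raise ValueError("config.n_taxa does not match the ground-truth dimension")
    cov = np.linalg.inv(truth.precision)
    # rescale to the configured mean latent variance; a pure scale change,
    # so correlations, partial correlations and the edge support are untouched
    cov = cov * (config.latent_variance / np.diag(cov).mean())
    z = rng.multivariate_normal(np.zeros(d), cov, size=config.n_samples,
                                method="cholesky")
    var = np.diag(cov)
    rate = config.sequencing_depth * np.exp(z) / np.exp(var / 2.0)
    counts = rng.poisson(rate).astype(float)

    total = counts.size
    zero_now = int((counts == 0).sum())
    need = int(np.ceil(config.target_sparsity * total)) - zero_now
    if need > 0:
        flat = counts.ravel()
        nonzero_flat = np.flatnonzero(flat)
        # censor smallest counts first; jitter breaks ties reproducibly
        order = nonzero_flat[np.argsort(flat[nonzero_flat]
                                        + 0.5 * rng.random(nonzero_flat.size))]
        flat[order[:need]] = 0.0
        counts = flat.reshape(counts.shape)
    elif config.target_sparsity > 0:
        logger.warning(
            "realized zero fraction %.3f already exceeds target %.3f",
            zero_now / total, config.target_sparsity,
        )
    return OtuTable(
        counts=counts,
        sample_ids=[f"S{i}" for i in range(config.n_samples)],
        taxon_ids=[f"T{j}" for j in range(d)],
    )


def _edge_set(adjacency: np.ndarray) -> set[tuple[int, int]]:
    iu = np.triu_indices_from(adjacency, k=1)
    return {(int(i), int(j)) for i, j in zip(*iu) if adjacency[i, j]}


def recovery_metrics(inferred, truth: GroundTruthNetwork) -> tuple[float, float, float]:
    """Edge-set precision, recall and F1 of an inferred network against truth.

    ``inferred`` may be a NetworkGraph (taxon ids of the form produced by the
    simulator) or a boolean adjacency matrix.  An empty inferred set has
    precision 0 when the truth has edges and 1 when the truth is also empty.
    """
    if isinstance(inferred, NetworkGraph):
        if len(inferred.taxon_ids) != truth.n_taxa:
            raise ValueError("taxon count mismatch between inferred network and truth")
        index = {t: i for i, t in enumerate(inferred.taxon_ids)}
        inf_edges = {
            tuple(sorted((index[a], index[b])))
            for a, b in zip(inferred.edges["taxon_a"], inferred.edges["taxon_b"])
        }
    else:
        adj = np.asarray(inferred, dtype=bool)
        if adj.shape != truth.adjacency.shape:
            raise ValueError("adjacency shape mismatch between inferred network and truth")
        inf_edges = _edge_set(adj)
    true_edges = _edge_set(truth.adjacency)
    tp = len(inf_edges & true_edges)
    if inf_edges:
        precision = tp / len(inf_edges)
    else:
        precision = 1.0 if not true_edges else 0.0
    recall = tp / len(true_edges) if true_edges else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return precision, recall, f1


def random_graph_adjacency(d: int, n_edges: int, seed: int) -> np.ndarray:
    """Size-matched random baseline: n_edges pairs drawn uniformly."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(d, k=1)
    total = len(iu[0])
    pick = rng.choice(total, size=min(n_edges, total), replace=False)
    adj = np.zeros((d, d), dtype=bool)
    adj[iu[0][pick], iu[1][pick]] = True
    return adj | adj.T
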