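"""Signed co-occurrence networks from fitted models, aggregated across folds.

For correlation models the association matrix is the thresholded correlation
matrix.  For the LASSO, the per-target coefficient matrix is symmetrized as
the mean of its upper and lower triangles.  For the GGM the GLASSO precision
matrix defines the edges; weights default to partial correlations
-omega_ij / sqrt(omega_ii * omega_jj) (a raw-precision mode keeps the
unsigned entries).  The final network over K folds is the entrywise median of the fold
matrices, and each edge carries the fraction of folds in which it appeared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import predictors as P
from . import crossval as CV

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """D x D symmetric signed weights with zero diagonal."""

    weights: np.ndarray
    taxon_ids: list[str]
    source: str  # pearson | spearman | lasso | ggm

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("association weights must be finite")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("association matrix must be symmetric within 1e-10")
        if np.any(np.diag(w) != 0):
            raise ValueError("association matrix must have zero diagonal")
        self.weights = w

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights[np.triu_indices_from(self.weights, k=1)]))


@dataclass
class NetworkGraph:
    """Edge list with signs and fold-presence probabilities."""

    edges: pd.DataFrame  # taxon_a, taxon_b, weight, sign, probability
    taxon_ids: list[str]
    n_folds: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def correlation_network(model: P.CorrelationModel, threshold: float,
                        taxon_ids: list[str] | None = None) -> AssociationMatrix:
    """Keep correlations with |corr| >= threshold as signed edge weights."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    w = model.corr.copy()
    w[np.abs(w) < threshold] = 0.0
    np.fill_diagonal(w, 0.0)
    ids = taxon_ids or [f"T{i}" for i in range(w.shape[0])]
    return AssociationMatrix(weights=w, taxon_ids=ids, source=model.method)


def lasso_association(coef_matrix: np.ndarray,
                      taxon_ids: list[str] | None = None) -> AssociationMatrix:
    """Symmetrize a per-target coefficient matrix: (W + W^T) / 2.

    Row t of ``coef_matrix`` holds the coefficients of the model predicting
    taxon t from the others (0 at the diagonal).  An edge exists iff the
    symmetrized value is nonzero.
    """
    w = np.asarray(coef_matrix, dtype=float)
    if np.any(np.diag(w) != 0):
        raise ValueError("coefficient matrix must have zero diagonal")
    sym = (w + w.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    ids = taxon_ids or [f"T{i}" for i in range(w.shape[0])]
    return AssociationMatrix(weights=sym, taxon_ids=ids, source="lasso")


def ggm_association(model: P.GgmModel,
                    sign_convention: str = "partial_correlation",
                    taxon_ids: list[str] | None = None) -> AssociationMatrix:
    """Association matrix from the precision matrix.

    ``partial_correlation`` (default) uses -omega_ij / sqrt(omega_ii*omega_jj)
    so that a negative precision off-diagonal reads as a positive association;
    ``raw_precision`` keeps omega_ij as-is.  The edge set (nonzero support) is
    identical under both conventions.
    """
    theta = model.precision
    diag = np.diag(theta)
    if np.any(diag <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    if sign_convention == "partial_correlation":
        w = -theta / np.sqrt(np.outer(diag, diag))
    elif sign_convention == "raw_precision":
        w = theta.copy()
    else:
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    ids = taxon_ids or [f"T{i}" for i in range(w.shape[0])]
    return AssociationMatrix(weights=w, taxon_ids=ids, source="ggm")


def median_network(fold_matrices: list[AssociationMatrix]) -> NetworkGraph:
    """Entrywise median of per-fold association matrices.

    Edges are the nonzero entries of the median matrix; each edge's
    probability is the fraction of folds in which that entry was nonzero.
    Invariant to the order of the fold matrices.
    """
    if not fold_matrices:
        raise ValueError("need at least one fold matrix")
    ids = fold_matrices[0].taxon_ids
    source = fold_matrices[0].source
    for m in fold_matrices[1:]:
        if m.taxon_ids != ids or m.source != source:
            raise ValueError("fold matrices must share taxon_ids and source")
    stack = np.stack([m.weights for m in fold_matrices])
    med = np.median(stack, axis=0)
    presence = (stack != 0).mean(axis=0)
    d = med.shape[0]
    rows = []
    for i in range(d):
        for j in range(i + 1, d):
            if med[i, j] != 0:
                rows.append({
                    "taxon_a": ids[i],
                    "taxon_b": ids[j],
                    "weight": float(med[i, j]),
                    "sign": "+" if med[i, j] > 0 else "-",
                    "probability": float(presence[i, j]),
                })
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight", "sign", "probability"])
    return NetworkGraph(edges=edges, taxon_ids=ids, n_folds=len(fold_matrices))


# ---------------------------------------------------------------------------
# per-fold inference driver
# ---------------------------------------------------------------------------

def lasso_coef_matrix(train: np.ndarray, ratios: np.ndarray, inner_k: int,
                      seed: int) -> np.ndarray:
    """Per-target CV-selected LASSO coefficients arranged as a D x D matrix."""
    d = train.shape[1]
    curve = CV.train_hyperparameter(train, "lasso", ratios, inner_k, seed)
    coef = np.zeros((d, d))
    for t in range(d):
        rest = np.delete(np.arange(d), t)
        lam_max = P.lasso_lambda_max(train[:, rest], train[:, t])
        lam = float(curve.per_target_best[t]) * lam_max
        m = P.fit_lasso(train, t, max(lam, 1e-12))
        coef[t, rest] = m.coefficients
    return coef


def infer_network(
    data: np.ndarray,
    algorithm: str,
    taxon_ids: list[str] | None = None,
    k: int = 3,
    seed: int = 0,
    config: CV.CvConfig | None = None,
    sign_convention: str = "partial_correlation",
) -> tuple[NetworkGraph, list[AssociationMatrix]]:
    """Full network-inference pipeline for one algorithm family.

    For each of the K outer folds the hyper-parameter is selected on the
    training rows by inner cross-validation, the model is refit on the whole
    training set, and its association matrix is built; the fold matrices are
    then aggregated into the median network.
    """
    config = config or CV.CvConfig()
    x = np.asarray(data, dtype=float)
    n, d = x.shape
    ids = taxon_ids or [f"T{i}" for i in range(d)]
    folds = CV.assign_folds(n, k, CV.derive_seed(seed, "outer-folds"))
    fold_matrices: list[AssociationMatrix] = []
    for f in range(1, k + 1):
        xtr, _ = CV._fold_data(x, folds.train_rows(f), folds.test_rows(f), config)
        inner_seed = CV.derive_seed(seed, f"inner-{algorithm}-{f}")
        if algorithm in ("pearson", "spearman"):
            curve = CV.train_hyperparameter(xtr, algorithm, config.grid_for(algorithm),
                                            config.inner_k, inner_seed)
            model = P.fit_correlation(xtr, algorithm)
            fold_matrices.append(correlation_network(model, curve.best_value, ids))
        elif algorithm == "lasso":
            coef = lasso_coef_matrix(xtr, config.grid_for("lasso"), config.inner_k, inner_seed)
            fold_matrices.append(lasso_association(coef, ids))
        elif algorithm == "ggm":
            curve = CV.train_hyperparameter(xtr, "ggm", config.grid_for("ggm"),
                                            config.inner_k, inner_seed)
            s = xtr.T @ xtr / xtr.shape[0]
            model = P.fit_glasso(xtr, curve.best_value * P.glasso_lambda_max(s))
            fold_matrices.append(ggm_association(model, sign_convention, ids))
        else:
            raise ValueError(f"unknown algorithm {algorithm!r}")
    return median_network(fold_matrices), fold_matrices


# ---------------------------------------------------------------------------
# export and plotting
# ---------------------------------------------------------------------------

def write_edge_list(graph: NetworkGraph, path) -> None:
    graph.edges.to_csv(path, sep="\t", index=False)


def write_adjacency(matrix: AssociationMatrix, path) -> None:
    pd.DataFrame(matrix.weights, index=matrix.taxon_ids,
                 columns=matrix.taxon_ids).to_csv(path)


def to_networkx(graph: NetworkGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.taxon_ids)
    for row in graph.edges.itertuples(index=False):
        g.add_edge(row.taxon_a, row.taxon_b, weight=row.weight,
                   sign=row.sign, probability=row.probability)
    return g


def write_graphml(graph: NetworkGraph, path) -> None:
    nx.write_graphml(to_networkx(graph), path)


def plot_network(graph: NetworkGraph, path, top_k: int = 200, seed: int = 0) -> None:
    """Force-directed view of the top-k edges by |weight|."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = graph.edges.reindex(
        graph.edges["weight"].abs().sort_values(ascending=False).index
    ).head(top_k)
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.taxon_a, row.taxon_b, weight=row.weight, sign=row.sign)
    fig, ax = plt.subplots(figsize=(8, 8))
    if g.number_of_edges():
        pos = nx.spring_layout(g, seed=seed)
        colors = ["tab:blue" if d["sign"] == "+" else "tab:red"
                  for _, _, d in g.edges(data=True)]
        widths = [1 + 2 * abs(d["weight"]) for _, _, d in g.edges(data=True)]
        nx.draw_networkx(g, pos, ax=ax, node_size=80, font_size=6,
                         edge_color=colors, width=widths)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
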