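"""RNA velocity (steady-state kinetics) and graph pseudotime.

The steady-state model assumes that for cells at transcriptional equilibrium
the unspliced/spliced ratio equals the per-gene degradation/splicing ratio γ,
estimated by a zero-intercept regression on the extreme-quantile cells of each
gene; velocity is the residual v = u − γ·s, positive where a gene is being
induced.  Pseudotime is the min-max scaled shortest-path distance from a
chosen root cell over the kNN graph with Euclidean edge weights.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .containers import SyntheticTruth  # noqa: F401  (type reference in docs)

log = logging.getLogger(__name__)


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)


def fit_gamma(
    spliced, unspliced, quantile: float = 0.05, min_cells: int = 10
) -> pd.DataFrame:
    """Per-gene steady-state ratio γ from extreme-quantile cells.

    For each gene, cells in the union of the top and bottom ``quantile`` of
    spliced expression anchor the steady-state line; γ minimizes
    Σ(u − γ·s)² over those cells (closed form Σus/Σs²).  Genes with fewer
    than ``min_cells`` selected cells or zero Σs² are flagged unfitted.
    Scaling u by c scales γ by c; scaling s by c scales γ by 1/c.
    """
    s = _dense(spliced)
    u = _dense(unspliced)
    if s.shape != u.shape:
        raise ValueError("spliced and unspliced layers differ in shape")
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    n_cells, n_genes = s.shape
    gamma = np.full(n_genes, np.nan)
    r2 = np.full(n_genes, np.nan)
    fitted = np.zeros(n_genes, dtype=bool)
    lo_q = np.quantile(s, quantile, axis=0)
    hi_q = np.quantile(s, 1.0 - quantile, axis=0)
    for g in range(n_genes):
        sel = (s[:, g] <= lo_q[g]) | (s[:, g] >= hi_q[g])
        ss, uu = s[sel, g], u[sel, g]
        denom = (ss**2).sum()
        if sel.sum() < min_cells or denom == 0:
            continue
        gamma[g] = (uu * ss).sum() / denom
        resid = uu - gamma[g] * ss
        tot = (uu**2).sum()
        r2[g] = 1.0 - (resid**2).sum() / tot if tot > 0 else np.nan
        fitted[g] = True
    return pd.DataFrame({"gamma": gamma, "r2": r2, "fitted": fitted})


def compute_velocity(spliced, unspliced, gamma_table: pd.DataFrame) -> np.ndarray:
    """v = u − γ∘s elementwise; unfitted genes are set to 0."""
    s = _dense(spliced)
    u = _dense(unspliced)
    gamma = gamma_table["gamma"].to_numpy().copy()
    fitted = gamma_table["fitted"].to_numpy()
    gamma[~fitted] = 0.0
    v = u - gamma[None, :] * s
    v[:, ~fitted] = 0.0
    return v


def velocity_transition_graph(
    velocity: np.ndarray,
    expression: np.ndarray,
    knn_dist: sp.spmatrix,
    kernel_scale: float = 0.1,
) -> sp.csr_matrix:
    """Row-stochastic transition matrix from velocity-displacement cosines.

    For each cell i and kNN neighbor j, the score is the cosine similarity
    between v_i and the displacement x_j − x_i in gene space; transition
    probabilities are softmax(score / kernel_scale) over i's neighbors.
    Cells with a zero velocity vector get a uniform row (flagged in the log).
    """
    knn = sp.csr_matrix(knn_dist)
    n = knn.shape[0]
    rows, cols, vals = [], [], []
    n_zero = 0
    for i in range(n):
        nbrs = knn.indices[knn.indptr[i] : knn.indptr[i + 1]]
        if len(nbrs) == 0:
            continue
        v = velocity[i]
        vnorm = np.linalg.norm(v)
        if vnorm == 0:
            probs = np.full(len(nbrs), 1.0 / len(nbrs))
            n_zero += 1
        else:
            disp = expression[nbrs] - expression[i]
            dnorm = np.linalg.norm(disp, axis=1)
            cos = (disp @ v) / np.maximum(dnorm * vnorm, 1e-300)
            score = cos / kernel_scale
            score -= score.max()
            e = np.exp(score)
            probs = e / e.sum()
        rows.extend([i] * len(nbrs))
        cols.extend(nbrs)
        vals.extend(probs)
    if n_zero:
        log.info("velocity_transition_graph: %d cells with zero velocity", n_zero)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def pseudotime(
    knn_dist: sp.spmatrix, root_cell: int, embedding: np.ndarray | None = None
) -> pd.DataFrame:
    """Shortest-path pseudotime from a root cell, min-max scaled to [0, 1].

    ``knn_dist`` carries Euclidean edge weights (as produced by
    :func:`regenmap.rna_states.knn_graph`); when ``embedding`` is given the
    edge weights are recomputed from it.  Unreachable cells are flagged with
    NaN pseudotime.
    """
    graph = sp.csr_matrix(knn_dist)
    n = graph.shape[0]
    if not 0 <= root_cell < n:
        raise ValueError("root cell outside graph")
    if embedding is not None:
        coo = graph.tocoo()
        w = np.linalg.norm(embedding[coo.row] - embedding[coo.col], axis=1)
        graph = sp.csr_matrix((w, (coo.row, coo.col)), shape=graph.shape)
    sym = graph.maximum(graph.T)
    dist = dijkstra(sym, directed=False, indices=root_cell)
    reachable = np.isfinite(dist)
    if reachable.sum() <= 1:
        raise ValueError("root cell is isolated in the graph")
    finite = dist[reachable]
    span = finite.max() - finite.min()
    pt = np.where(reachable, (dist - finite.min()) / (span if span > 0 else 1.0), np.nan)
    return pd.DataFrame({"pseudotime": pt, "reachable": reachable})
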