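"""Transcriptomic state analysis: normalization, graph clustering,
hierarchical grouping of cluster profiles, marker/signature scoring, the
dichotomized perivenous/periportal zonation call, bulk deconvolution,
preranked GSEA and zonal-layer correlation.

All scoring operates on library-size normalized, log-transformed expression
(``normalize_counts``); signature scores are means of per-gene z-scores so
they are invariant to global library-size rescaling.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterResult, SignatureSet

log = logging.getLogger(__name__)


def normalize_counts(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """log(1 + count * target_sum / cell_total) per entry; zeros stay zero."""
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValueError(
            "cells with zero total counts present; run filter_cells_rna first"
        )
    x = sp.csr_matrix(adata.X, dtype=float)
    scale = target_sum / totals
    x = sp.diags(scale) @ x
    x.data = np.log1p(x.data)
    out = adata.copy()
    out.X = x
    out.uns["normalization"] = {"target_sum": target_sum, "log1p": True}
    return out


def knn_graph(embedding: np.ndarray, n_neighbors: int) -> tuple[ig.Graph, np.ndarray]:
    """Symmetrized Euclidean kNN graph; returns (igraph graph, distance csr)."""
    n = embedding.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need >= {n_neighbors + 1} cells for {n_neighbors} neighbors")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    dist = nn.kneighbors_graph(mode="distance")
    dist = dist.maximum(dist.T).tocsr()
    src, dst = dist.nonzero()
    mask = src < dst
    graph = ig.Graph(n=n, edges=list(zip(src[mask], dst[mask])))
    return graph, dist


def cluster_cells(
    data,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 30,
    is_embedding: bool = False,
) -> ClusterResult:
    """Leiden community detection on a kNN graph.

    ``data`` is either a normalized AnnData/matrix (PCA to ``n_pcs`` is
    applied first) or, with ``is_embedding=True``, a precomputed embedding
    such as the ATAC LSI.  Deterministic for a fixed seed; labels are
    contiguous from 1.
    """
    cell_ids = None
    if isinstance(data, AnnData):
        cell_ids = np.asarray(data.obs_names)
        data = data.X
    x = np.asarray(data.todense()) if sp.issparse(data) else np.asarray(data, dtype=float)
    if is_embedding:
        emb = x
    else:
        n_comp = min(n_pcs, x.shape[0] - 1, x.shape[1] - 1)
        emb = PCA(n_components=n_comp, random_state=seed).fit_transform(
            x - x.mean(axis=0)
        )
    graph, _ = knn_graph(emb, n_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing cluster size, contiguous from 1
    order = pd.Series(raw).value_counts().index.to_numpy()
    remap = {old: i + 1 for i, old in enumerate(order)}
    labels = np.array([remap[v] for v in raw])
    return ClusterResult(labels, emb, resolution, seed, cell_ids)


def cluster_mean_profiles(adata: AnnData, clusters: ClusterResult) -> pd.DataFrame:
    """Clusters x genes mean normalized expression."""
    x = np.asarray(adata.X.todense()) if sp.issparse(adata.X) else np.asarray(adata.X)
    out = {}
    for k in range(1, clusters.n_clusters + 1):
        out[k] = x[clusters.labels == k].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names).T


def hierarchical_group_clusters(
    profiles: pd.DataFrame, k_groups: int = 3
) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage agglomeration of cluster profiles on 1 - Pearson.

    Returns (cluster -> group labels contiguous from 1, scipy linkage matrix).
    """
    if len(profiles) < k_groups:
        raise ValueError("fewer clusters than requested groups")
    x = profiles.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = profiles.index[sd == 0].tolist()
        raise ValueError(f"constant profile, correlation undefined for cluster(s) {bad}")
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    z = average(squareform(dist, checks=False))
    raw = fcluster(z, t=k_groups, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    return pd.Series(labels + 1, index=profiles.index, name="group"), z


def _zscore_genes(x: np.ndarray) -> np.ndarray:
    """z per column (gene) across rows (cells); zero-variance genes -> 0."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def score_signature(adata: AnnData, signature: SignatureSet) -> pd.Series:
    """Mean per-cell z-scored normalized expression over the signature genes.

    Genes missing from the matrix are reported via a warning; an empty
    intersection is an error.
    """
    present = [g for g in sorted(signature.genes) if g in adata.var_names]
    missing = sorted(signature.genes - set(present))
    if not present:
        raise ValueError(f"signature {signature.name!r} has no genes in the matrix")
    if missing:
        log.warning("signature %s: %d genes missing (%s...)",
                    signature.name, len(missing), missing[:5])
    x = adata[:, present].X
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    z = _zscore_genes(x)
    return pd.Series(z.mean(axis=1), index=adata.obs_names, name=signature.name)


def dichotomized_zonation(
    adata: AnnData,
    pv_set: SignatureSet,
    pp_set: SignatureSet,
    tau: float = 0.5,
) -> pd.DataFrame:
    """Classify each cell perivenous / periportal / co-expressing.

    PV when pv_score - pp_score > tau (z units), PP when < -tau, else
    co-expressing.  Swapping the two sets swaps the PV/PP labels exactly.
    """
    pv = score_signature(adata, pv_set)
    pp = score_signature(adata, pp_set)
    diff = pv - pp
    cls = np.where(diff > tau, "PV", np.where(diff < -tau, "PP", "co-expressing"))
    return pd.DataFrame(
        {"pv_score": pv, "pp_score": pp, "zonation_class": cls}, index=adata.obs_names
    )


def deconvolute_bulk(
    bulk: pd.DataFrame | pd.Series,
    reference_profiles: pd.DataFrame,
    max_condition_number: float = 1e8,
) -> pd.DataFrame:
    """Cell-type fractions by non-negative least squares on marker genes.

    ``reference_profiles`` is genes x cell types; ``bulk`` one or more
    expression vectors indexed by gene.  Fractions are renormalized to sum to
    1; the NNLS residual norm is reported per sample.
    """
    if isinstance(bulk, pd.Series):
        bulk = bulk.to_frame()
    shared = reference_profiles.index.intersection(bulk.index)
    if reference_profiles.shape[1] < 2:
        raise ValueError("need >= 2 reference profiles")
    a = reference_profiles.loc[shared].to_numpy(dtype=float)
    cond = np.linalg.cond(a)
    if cond > max_condition_number:
        raise ValueError(
            f"reference profiles are collinear on the marker union "
            f"(condition number {cond:.3g})"
        )
    rows = []
    for col in bulk.columns:
        b = bulk.loc[shared, col].to_numpy(dtype=float)
        coef, res = nnls(a, b)
        total = coef.sum()
        frac = coef / total if total > 0 else np.full_like(coef, np.nan)
        rows.append(list(frac) + [res])
    return pd.DataFrame(
        rows,
        index=bulk.columns,
        columns=list(reference_profiles.columns) + ["residual_norm"],
    )


def _gsea_running_max(hit_weight: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the GSEA running sum for one ranked list."""
    n = len(in_set)
    n_hit = int(in_set.sum())
    total = hit_weight[in_set].sum()
    if total == 0:
        hit_step = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        hit_step = np.where(in_set, hit_weight / total, 0.0)
    miss_step = np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(hit_step - miss_step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranked_scores: pd.Series,
    signature: SignatureSet,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Preranked GSEA: enrichment score, NES and empirical permutation p.

    ``ranked_scores`` maps genes to ranking scores (descending order is taken
    internally; ties broken by the input order).  ES is the signed extremum of
    the running sum with hits weighted by |score|^p (normalized) and misses
    decremented by 1/(N - |S|).  The null permutes gene labels; NES divides ES
    by the mean |ES| of the sign-matched permutations, and p is the two-sided
    empirical tail (1 + #{|ES_perm| >= |ES|}) / (1 + n_perm).
    """
    if ranked_scores.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    genes = ranked_scores.index
    missing = sorted(signature.genes - set(genes))
    if missing:
        raise ValueError(f"signature genes missing from ranking: {missing[:5]}")
    if len(signature.genes) >= len(genes):
        raise ValueError("signature covers the whole ranking; miss step undefined")
    order = np.argsort(-ranked_scores.to_numpy(), kind="stable")
    scores = ranked_scores.to_numpy()[order]
    in_set = np.isin(genes.to_numpy()[order], list(signature.genes))
    weight = np.abs(scores) ** weight_p
    es = _gsea_running_max(weight, in_set)

    rng = np.random.default_rng(seed)
    n_hit = int(in_set.sum())
    perm_es = np.empty(n_perm)
    base = np.zeros(len(genes), dtype=bool)
    for i in range(n_perm):
        perm = base.copy()
        perm[rng.choice(len(genes), n_hit, replace=False)] = True
        perm_es[i] = _gsea_running_max(weight, perm)
    same_sign = perm_es * np.sign(es) > 0
    denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else np.nan
    p = (1.0 + (np.abs(perm_es) >= abs(es)).sum()) / (1.0 + n_perm)
    return {"ES": es, "NES": nes, "p_value": p, "n_perm": n_perm}


def zonal_correlation(
    cluster_scores: pd.DataFrame, zonal_profile: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate cluster expression with portal-to-central layer profiles.

    ``cluster_scores``: clusters x genes; ``zonal_profile``: layers x genes.
    Each cluster profile and each layer profile is z-scored across the shared
    genes (the 89-gene panel by default) and the two are correlated per
    (cluster, layer) pair — equivalently, the plain Pearson correlation over
    genes.  Returns the correlation matrix plus the best-layer assignment per
    cluster.  A constant profile on either side makes the correlation
    undefined and raises.
    """
    shared = cluster_scores.columns.intersection(zonal_profile.columns)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes for zonal correlation")
    c = cluster_scores[shared].to_numpy(dtype=float)
    z = zonal_profile[shared].to_numpy(dtype=float)
    if (c.std(axis=1) == 0).any():
        bad = cluster_scores.index[c.std(axis=1) == 0].tolist()
        raise ValueError(f"constant cluster profile(s) {bad}: correlation undefined")
    if (z.std(axis=1) == 0).any():
        raise ValueError("constant layer profile: correlation undefined")
    corr = np.empty((c.shape[0], z.shape[0]))
    for i in range(c.shape[0]):
        ci = c[i] - c[i].mean()
        for j in range(z.shape[0]):
            zj = z[j] - z[j].mean()
            denom = np.sqrt((ci**2).sum() * (zj**2).sum())
            corr[i, j] = (ci * zj).sum() / denom if denom > 0 else np.nan
    out = pd.DataFrame(corr, index=cluster_scores.index, columns=zonal_profile.index)
    best = out.idxmax(axis=1)
    best.name = "best_layer"
    return out, best
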