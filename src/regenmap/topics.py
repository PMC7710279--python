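"""Topic modelling of binarized accessibility and the regulon↔chromatin link.

The pipeline's centerpiece: binarize the peak matrix, fit latent Dirichlet
allocation by collapsed Gibbs sampling (cells are documents, accessible-region
occurrences are tokens), derive per-cell region probabilities, turn each scRNA
cluster's top regulons into genomic peak signatures, score those signatures
against the probability-ranked regions of each ATAC cell, and correlate the
resulting cluster-level profiles to map ATAC clusters onto RNA states.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from numba import njit
from scipy.special import gammaln

from .containers import ClusterResult, Regulon, SignatureSet, TopicModel
from .grn import recovery_auc

log = logging.getLogger(__name__)


def binarize(pmat: AnnData) -> sp.csr_matrix:
    """Cells x regions 0/1 matrix: 1 wherever the count is >= 1."""
    x = sp.csr_matrix(pmat.X)
    out = x.copy()
    out.data = np.ones_like(out.data, dtype=np.int8)
    out.eliminate_zeros()
    return out


@njit(cache=True)
def _gibbs_sweep(z, cells, regions, n_ct, n_tr, n_t, alpha, beta, u):  # pragma: no cover
    n_topics = n_tr.shape[0]
    r_beta = beta * n_tr.shape[1]
    p = np.empty(n_topics)
    for i in range(z.shape[0]):
        c, r, t_old = cells[i], regions[i], z[i]
        n_ct[c, t_old] -= 1
        n_tr[t_old, r] -= 1
        n_t[t_old] -= 1
        total = 0.0
        for t in range(n_topics):
            p[t] = (n_ct[c, t] + alpha) * (n_tr[t, r] + beta) / (n_t[t] + r_beta)
            total += p[t]
        threshold = u[i] * total
        acc = 0.0
        t_new = n_topics - 1
        for t in range(n_topics):
            acc += p[t]
            if acc >= threshold:
                t_new = t
                break
        z[i] = t_new
        n_ct[c, t_new] += 1
        n_tr[t_new, r] += 1
        n_t[t_new] += 1


def _log_joint(n_ct, n_tr, n_t, alpha, beta) -> float:
    """Collapsed log P(w, z | alpha, beta) in Dirichlet-multinomial form."""
    T, R = n_tr.shape
    C = n_ct.shape[0]
    n_c = n_ct.sum(axis=1)
    word = T * gammaln(R * beta) - gammaln(n_t + R * beta).sum()
    word += gammaln(n_tr + beta).sum() - T * R * gammaln(beta)
    doc = C * gammaln(T * alpha) - gammaln(n_c + T * alpha).sum()
    doc += gammaln(n_ct + alpha).sum() - C * T * gammaln(alpha)
    return float(word + doc)


def lda_fit(
    binary: sp.spmatrix,
    n_topics: int,
    alpha: float | None = None,
    beta: float = 0.1,
    n_iter: int = 500,
    burn_in: int = 250,
    seed: int = 0,
    region_ids=None,
    cell_ids=None,
) -> TopicModel:
    """Collapsed Gibbs LDA on a binarized cells x regions matrix.

    Defaults follow the cisTopic conventions: alpha = 50 / n_topics,
    beta = 0.1.  phi and theta are estimated from post-burn-in averaged counts
    with Dirichlet smoothing; the collapsed joint log-likelihood is recorded
    every 10 sweeps.
    """
    binary = sp.csr_matrix(binary)
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    if n_topics > binary.shape[1]:
        raise ValueError("more topics than regions")
    cell_sums = np.asarray(binary.sum(axis=1)).ravel()
    if (cell_sums == 0).any():
        raise ValueError("cells with no accessible region; run QC first")
    if alpha is None:
        alpha = 50.0 / n_topics
    coo = binary.tocoo()
    cells = coo.row.astype(np.int64)
    regions = coo.col.astype(np.int64)
    n_tokens = len(cells)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, n_topics, n_tokens)
    n_ct = np.zeros((binary.shape[0], n_topics), dtype=np.int64)
    n_tr = np.zeros((n_topics, binary.shape[1]), dtype=np.int64)
    n_t = np.zeros(n_topics, dtype=np.int64)
    np.add.at(n_ct, (cells, z), 1)
    np.add.at(n_tr, (z, regions), 1)
    np.add.at(n_t, z, 1)

    acc_tr = np.zeros_like(n_tr, dtype=np.float64)
    acc_ct = np.zeros_like(n_ct, dtype=np.float64)
    n_saved = 0
    trace = []
    for sweep in range(1, n_iter + 1):
        _gibbs_sweep(z, cells, regions, n_ct, n_tr, n_t, alpha, beta, rng.random(n_tokens))
        if sweep % 10 == 0:
            trace.append(_log_joint(n_ct, n_tr, n_t, alpha, beta))
        if sweep > burn_in and sweep % 10 == 0:
            acc_tr += n_tr
            acc_ct += n_ct
            n_saved += 1
    if n_saved == 0:  # short runs: fall back to the final state
        acc_tr, acc_ct, n_saved = n_tr.astype(float), n_ct.astype(float), 1
    phi = (acc_tr / n_saved + beta)
    phi /= phi.sum(axis=1, keepdims=True)
    theta = (acc_ct / n_saved + alpha)
    theta /= theta.sum(axis=1, keepdims=True)
    return TopicModel(
        n_topics=n_topics,
        phi=phi,
        theta=theta,
        alpha=alpha,
        beta=beta,
        log_likelihood=np.asarray(trace),
        seed=seed,
        region_ids=None if region_ids is None else np.asarray(region_ids),
        cell_ids=None if cell_ids is None else np.asarray(cell_ids),
    )


def select_topic_number(
    binary: sp.spmatrix,
    t_grid,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, TopicModel]]:
    """Fit each candidate T and pick the best-scoring model.

    The score is the post-burn-in mean of the collapsed joint log-likelihood
    log P(w, z | alpha, beta), which penalizes superfluous topics; the best T
    is its argmax.  Returns (best T, score table, fitted models).
    """
    t_grid = list(t_grid)
    if len(t_grid) < 2:
        raise ValueError("t_grid must contain >= 2 candidate topic numbers")
    models, rows = {}, []
    burn = fit_kwargs.get("burn_in", 250)
    for t in t_grid:
        model = lda_fit(binary, n_topics=t, seed=seed, **fit_kwargs)
        post = model.log_likelihood[burn // 10 :]
        score = float(post.mean()) if len(post) else float(model.log_likelihood[-1])
        models[t] = model
        rows.append({"n_topics": t, "score": score})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["score"].idxmax(), "n_topics"])
    return best, table, models


def region_cell_probability(model: TopicModel) -> np.ndarray:
    """p(region | cell) = sum_t theta[c, t] * phi[t, r]; regions x cells.

    Each cell's column is a probability vector over regions.
    """
    return (model.theta @ model.phi).T


def build_peak_signature(
    top_regulons: dict[int, list[Regulon]],
    genome: pd.DataFrame,
    peaks: pd.DataFrame,
    window: int = 2000,
) -> dict[int, SignatureSet]:
    """Per RNA cluster, the union of peaks near its top regulons' genes.

    A peak belongs to a regulon when it overlaps the gene body ±``window`` of
    the TF or any target (0-based half-open intervals); a cluster's signature
    merges its regulons' peak sets.  Clusters with no overlapping peak are
    flagged and excluded.
    """
    gene_by_id = genome.set_index("gene_id")
    peaks_by_chrom = {
        c: chunk.sort_values("start", kind="stable") for c, chunk in peaks.groupby("chrom")
    }
    signatures = {}
    for cluster, regs in top_regulons.items():
        peak_ids: set = set()
        for reg in regs:
            for gid in reg.genes:
                if gid not in gene_by_id.index:
                    log.info("build_peak_signature: gene %s not annotated", gid)
                    continue
                row = gene_by_id.loc[gid]
                chunk = peaks_by_chrom.get(row["chrom"])
                if chunk is None:
                    continue
                w_start, w_end = row["start"] - window, row["end"] + window
                hit = (chunk["start"].to_numpy() < w_end) & (
                    chunk["end"].to_numpy() > w_start
                )
                peak_ids.update(chunk["peak_id"].to_numpy()[hit])
        if not peak_ids:
            log.warning("cluster %s: empty peak signature, excluded", cluster)
            continue
        signatures[cluster] = SignatureSet(name=f"cluster{cluster}", genes=peak_ids)
    return signatures


def signature_enrichment(
    region_cell_prob: np.ndarray,
    signatures: dict[int, SignatureSet],
    region_ids,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Cells x signatures recovery-AUC of each peak signature.

    Regions are ranked per cell by p(r|c) descending; each signature is scored
    by the same recovery-AUC statistic as regulon activity, so the result
    depends only on the rank order of the probabilities.
    """
    region_ids = np.asarray(region_ids)
    cols = {}
    for name, sig in signatures.items():
        mask = np.isin(region_ids, list(sig.genes))
        if not mask.any():
            raise ValueError(f"signature {sig.name!r} shares no regions with the model")
        cols[name] = np.array(
            [
                recovery_auc(region_cell_prob[:, c], mask, top_fraction)
                for c in range(region_cell_prob.shape[1])
            ]
        )
    return pd.DataFrame(cols)


def cluster_signature_correlation(
    scores: pd.DataFrame,
    clusters: ClusterResult,
    exclusive_margin: float = 0.2,
) -> pd.DataFrame:
    """Map ATAC clusters onto RNA-cluster signatures by Pearson correlation.

    Cluster-level profiles are the mean signature scores per ATAC cluster;
    each signature column is z-scored across clusters and every cluster row is
    correlated with each signature's indicator direction.  The output carries
    per-cluster correlations, the argmax signature, and an ``exclusive`` flag
    set when the top correlation beats the runner-up by ``exclusive_margin``.
    Zero-variance signatures are dropped with a warning.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 signatures")
    if clusters.n_clusters < 2:
        raise ValueError("need >= 2 clusters")
    means = scores.groupby(clusters.labels).mean()
    sd = means.std(axis=0, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        log.warning("cluster_signature_correlation: zero-variance signatures %s", dropped)
        means = means.drop(columns=dropped)
    z = (means - means.mean(axis=0)) / means.std(axis=0, ddof=0)
    n_sig = z.shape[1]
    corr = np.empty((len(z), n_sig))
    for i in range(len(z)):
        row = z.iloc[i].to_numpy()
        for j in range(n_sig):
            e = np.zeros(n_sig)
            e[j] = 1.0
            corr[i, j] = np.corrcoef(row, e)[0, 1]
    out = pd.DataFrame(corr, index=z.index, columns=z.columns)
    ranked = np.sort(corr, axis=1)
    out["argmax_signature"] = out[z.columns].idxmax(axis=1)
    out["exclusive"] = (ranked[:, -1] - ranked[:, -2]) > exclusive_margin
    return out
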