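"""SCENIC-style regulon pipeline: tree-ensemble coexpression links, promoter
motif scanning and pruning, recovery-AUC (AUCell-style) regulon activity and
per-cluster regulon ranking.

The coexpression step fits, per target gene, a random-forest regression of the
target on the TF expression matrix; a TF's importance for that target is its
total impurity-reduction importance in the ensemble.  Regulons are the top
links per TF whose target promoters carry at least one motif hit for that TF's
PWM.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.ensemble import RandomForestRegressor

from .containers import ClusterResult, PWM, Regulon

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def infer_grn(
    adata: AnnData,
    tf_list: list[str],
    n_trees: int = 500,
    seed: int = 0,
    target_genes: list[str] | None = None,
) -> pd.DataFrame:
    """GENIE3-style TF→target links from a normalized expression matrix.

    For each candidate target (every non-TF gene by default) a random forest
    with sqrt-feature subsampling predicts the target from the TFs; link
    importance is the forest's per-TF importance, returned sorted descending.
    Constant targets get zero importances and are flagged in the output.
    """
    missing = [t for t in tf_list if t not in adata.var_names]
    if missing:
        raise ValueError(f"TFs absent from matrix: {missing}")
    if adata.n_obs < 50:
        raise ValueError("need >= 50 cells for GRN inference")
    x = adata.X
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    tf_cols = [var_index[t] for t in tf_list]
    tf_x = x[:, tf_cols]
    if target_genes is None:
        target_genes = [g for g in adata.var_names if g not in set(tf_list)]
    rng = np.random.default_rng(seed)
    rows = []
    for gene in target_genes:
        y = x[:, var_index[gene]]
        if y.std() == 0:
            rows += [
                {"tf": tf, "target": gene, "importance": 0.0, "constant_target": True}
                for tf in tf_list
            ]
            continue
        # drop the target itself when it is also a listed TF
        cols = [i for i, tf in enumerate(tf_list) if tf != gene]
        y = (y - y.mean()) / y.std()  # unit-variance target: importances
        # (variance reductions) become comparable across targets
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        ).fit(tf_x[:, cols], y)
        # unnormalized variance-reduction importances (GENIE3 semantics):
        # sklearn's feature_importances_ are rescaled to sum to 1 per forest
        raw_imp = np.mean(
            [e.tree_.compute_feature_importances(normalize=False)
             for e in model.estimators_],
            axis=0,
        )
        for i, imp in zip(cols, raw_imp):
            rows.append(
                {"tf": tf_list[i], "target": gene, "importance": float(imp),
                 "constant_target": False}
            )
    links = pd.DataFrame(rows)
    return links.sort_values("importance", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _logodds(pwm: PWM) -> np.ndarray:
    """4 x L log2(p_motif / p_background); zero probabilities give -inf."""
    with np.errstate(divide="ignore"):
        return np.log2(pwm.matrix) - np.log2(pwm.background[:, None])


def scan_promoter(
    pwm: PWM, sequence: str, threshold_fraction: float = 0.8
) -> list[tuple[int, str, float]]:
    """Scan a sequence with a PWM on both strands.

    Per window, the score is the summed log-odds log2(p_motif/p_background);
    ``N`` positions contribute 0 (the background expectation).  A hit needs
    score >= threshold_fraction x the maximum attainable score.  Returns
    (position on the forward strand, strand, score) triples.
    """
    seq = sequence.upper()
    L = pwm.length
    if len(seq) < L:
        raise ValueError("sequence shorter than motif")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    lo = _logodds(pwm)
    max_score = lo.max(axis=0).sum()
    threshold = threshold_fraction * max_score
    hits = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
        idx = np.array([_BASE_INDEX.get(b, -1) for b in s])
        for start in range(len(s) - L + 1):
            window = idx[start : start + L]
            valid = window >= 0
            score = lo[window[valid], np.flatnonzero(valid)].sum() if valid.any() else 0.0
            if score >= threshold:
                pos = start if strand == "+" else len(s) - start - L
                hits.append((pos, strand, float(score)))
    return sorted(hits)


def extract_promoters(
    genome: pd.DataFrame,
    sequences: dict[str, str] | None = None,
    upstream: int = 500,
    downstream: int = 100,
) -> dict[str, str]:
    """Strand-aware promoter windows (TSS -upstream/+downstream).

    When per-gene promoter ``sequences`` are already available (the synthetic
    path) they are passed through unchanged.
    """
    if sequences is not None:
        return dict(sequences)
    raise NotImplementedError(
        "genomic sequence extraction requires a supplied promoter dict"
    )


def prune_regulons(
    links: pd.DataFrame,
    pwms: dict[str, PWM],
    promoters: dict[str, str],
    top_k_links: int = 50,
    threshold_fraction: float = 0.8,
) -> list[Regulon]:
    """Keep, per TF, the top-k targets whose promoters hit the TF's motif.

    Targets without a promoter sequence are skipped with a log entry; TFs
    whose pruned target set is empty are dropped with a warning.
    """
    regulons = []
    for tf, chunk in links.groupby("tf", sort=True):
        if tf not in pwms:
            log.warning("prune_regulons: no PWM for TF %s, dropped", tf)
            continue
        top = chunk.sort_values("importance", ascending=False, kind="stable").head(
            top_k_links
        )
        targets, importance, motif_score = [], {}, {}
        for _, row in top.iterrows():
            gene = row["target"]
            seq = promoters.get(gene)
            if seq is None:
                log.info("prune_regulons: no promoter for %s, skipped", gene)
                continue
            hits = scan_promoter(pwms[tf], seq, threshold_fraction)
            if hits:
                targets.append(gene)
                importance[gene] = float(row["importance"])
                motif_score[gene] = max(h[2] for h in hits)
        if not targets:
            log.warning("prune_regulons: regulon for %s is empty after pruning", tf)
            continue
        regulons.append(Regulon(tf, tuple(targets), importance, motif_score))
    return regulons


def recovery_auc(
    values: np.ndarray, set_mask: np.ndarray, top_fraction: float = 0.05
) -> float:
    """Recovery AUC of a gene/region set within one ranked profile.

    Rank items by ``values`` descending (ties broken by position, stable);
    with k = ceil(top_fraction * N), AUC = sum_{i<=k} c_i / sum_{i<=k}
    min(i, |S|) where c_i counts set members in the top i.  In [0, 1].
    """
    n = len(values)
    k = math.ceil(top_fraction * n)
    order = np.argsort(-values, kind="stable")
    hits = set_mask[order[:k]]
    c = np.cumsum(hits)
    s = int(set_mask.sum())
    denom = np.minimum(np.arange(1, k + 1), s).sum()
    return float(c.sum() / denom)


def aucell_score(
    adata: AnnData, gene_set, top_fraction: float = 0.05, set_name: str = "set"
) -> pd.Series:
    """Per-cell recovery-AUC activity of a gene set (AUCell statistic).

    Depends only on each cell's expression ranks, so any monotone transform of
    the per-cell profile leaves the score unchanged.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    genes = set(gene_set.genes if hasattr(gene_set, "genes") else gene_set)
    mask = np.asarray([g in genes for g in adata.var_names])
    if not mask.any():
        raise ValueError(f"gene set {set_name!r} has no genes in the matrix")
    x = adata.X
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    scores = np.array([recovery_auc(row, mask, top_fraction) for row in x])
    return pd.Series(scores, index=adata.obs_names, name=set_name)


def score_regulons(
    adata: AnnData, regulons: list[Regulon], top_fraction: float = 0.05
) -> pd.DataFrame:
    """Cells x regulons AUCell matrix (regulon = TF plus its targets)."""
    cols = {
        r.tf: aucell_score(adata, r.genes, top_fraction, set_name=r.tf) for r in regulons
    }
    return pd.DataFrame(cols, index=adata.obs_names)


def rank_regulons_per_cluster(
    auc: pd.DataFrame, clusters: ClusterResult, top_k: int = 5
) -> pd.DataFrame:
    """Rank regulons per cluster by mean AUC; keep the top k per cluster.

    Ties break by TF name (deterministic).  Clusters with fewer than 3 cells
    are still ranked but flagged low-confidence.
    """
    if len(auc) != len(clusters.labels):
        raise ValueError("AUC matrix and clustering cover different cells")
    rows = []
    for k in range(1, clusters.n_clusters + 1):
        members = clusters.labels == k
        means = auc[members].mean(axis=0)
        ranked = means.sort_index().sort_values(ascending=False, kind="stable")
        for rank, (tf, m) in enumerate(ranked.head(top_k).items(), start=1):
            rows.append(
                {
                    "cluster": k,
                    "rank": rank,
                    "tf": tf,
                    "mean_auc": float(m),
                    "low_confidence": bool(members.sum() < 3),
                }
            )
    return pd.DataFrame(rows)
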