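"""Chromatin accessibility processing: TF-IDF/LSI embedding, pseudo-bulk
aggregation, differential accessibility at fold-change + BH thresholds,
distance-weighted gene activity scores, chromVAR-style motif deviations and
bulk time-course module discovery (moderated t + fuzzy c-means).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from anndata import AnnData
from scipy.optimize import brentq
from sklearn.decomposition import TruncatedSVD

from .containers import ClusterResult, DAResult

log = logging.getLogger(__name__)

TIME_POINTS_H = (0, 48, 72, 96)


# ---------------------------------------------------------------------------
# embedding & aggregation


def tfidf_lsi(pmat: AnnData, n_components: int = 30, seed: int = 0) -> np.ndarray:
    """TF-IDF transform + truncated SVD (latent semantic indexing).

    Counts are binarized; term frequency is per-cell peak fraction, inverse
    document frequency log(1 + n_cells / n_cells_with_peak); the transformed
    matrix log(1 + tfidf * 1e4) is decomposed by truncated SVD.  Component 1
    is dropped when it correlates with per-cell depth beyond |r| > 0.9 (the
    usual sequencing-depth artifact).
    """
    if min(pmat.shape) < n_components + 1:
        raise ValueError("need more cells and peaks than components")
    binary = sp.csr_matrix((pmat.X > 0).astype(float))
    depth = np.asarray(binary.sum(axis=1)).ravel()
    if (depth == 0).any():
        raise ValueError("all-zero cells present; run filter_nuclei_atac first")
    tf = sp.diags(1.0 / depth) @ binary
    n_with = np.asarray((binary > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + binary.shape[0] / np.maximum(n_with, 1))
    x = tf @ sp.diags(idf)
    x.data = np.log1p(x.data * 1e4)
    svd = TruncatedSVD(n_components=n_components, random_state=seed)
    emb = svd.fit_transform(x)
    r = np.corrcoef(emb[:, 0], depth)[0, 1]
    if abs(r) > 0.9:
        log.info("tfidf_lsi: dropping component 1 (depth correlation r=%.3f)", r)
        emb = emb[:, 1:]
    return emb


def pseudo_bulk(pmat: AnnData, clusters: ClusterResult) -> pd.DataFrame:
    """Clusters x peaks summed counts; totals are conserved exactly."""
    if pmat.n_obs != len(clusters.labels):
        raise ValueError("clustering covers different cells")
    x = sp.csr_matrix(pmat.X)
    out = {}
    for k in range(1, clusters.n_clusters + 1):
        out[k] = np.asarray(x[clusters.labels == k].sum(axis=0)).ravel()
    return pd.DataFrame(out, index=pmat.var_names).T


def export_bedgraph(profile: pd.Series, peaks: pd.DataFrame, path) -> None:
    """Write one pseudo-bulk profile as bedGraph for external peak callers."""
    table = peaks[["chrom", "start", "end"]].copy()
    table["value"] = profile.to_numpy()
    table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# differential accessibility


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def differential_accessibility(
    pmat: AnnData,
    group_a,
    group_b,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    target_sum: float = 1e4,
) -> DAResult:
    """Per-region Wilcoxon rank-sum DA between two cell groups.

    Counts are depth-normalized to ``target_sum`` per cell; log2FC uses a
    pseudocount of 1 on that scale.  P-values come from the two-sided
    Mann-Whitney U across cells, BH-adjusted across regions.  Direction is
    up/down/ns at the given |log2FC| and adjusted-p thresholds.  Swapping the
    groups negates every log2FC and leaves the p-values unchanged.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups overlap")
    if len(group_a) < 10 or len(group_b) < 10:
        raise ValueError("each group needs >= 10 cells")
    x = sp.csr_matrix(pmat.X, dtype=float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    norm = sp.diags(target_sum / np.maximum(totals, 1)) @ x
    idx = {c: i for i, c in enumerate(pmat.obs_names)}
    ia = [idx[c] for c in group_a] if group_a.dtype.kind in "UO" else group_a
    ib = [idx[c] for c in group_b] if group_b.dtype.kind in "UO" else group_b
    a = np.asarray(norm[ia].todense())
    b = np.asarray(norm[ib].todense())
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    stat = scipy.stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    padj = bh_adjust(stat.pvalue)
    direction = np.where(
        (np.abs(lfc) >= lfc_threshold) & (padj < padj_threshold),
        np.where(lfc > 0, "up", "down"),
        "ns",
    )
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": stat.pvalue,
            "p_adjusted": padj,
            "direction": direction,
        },
        index=pmat.var_names,
    )
    return DAResult(table)


# ---------------------------------------------------------------------------
# gene activity


def gene_activity_scores(
    pmat: AnnData,
    genome: pd.DataFrame,
    extension: int = 2000,
    decay_bp: float = 5000.0,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Genes x cells activity: distance-weighted sums of peak counts.

    A peak overlapping the gene body ±``extension`` contributes with weight 1;
    a peak within ``max_distance`` of that window contributes exp(-d/decay_bp)
    at gap distance d.  Intervals are 0-based half-open.  Peaks on
    chromosomes absent from the annotation are ignored (counted in the log).
    """
    peaks = pmat.var.reset_index().rename(columns={pmat.var.index.name or "index": "peak_id"})
    counts = sp.csr_matrix(pmat.X).T.tocsr()  # peaks x cells
    known = set(genome["chrom"])
    ignored = int((~peaks["chrom"].isin(known)).sum())
    if ignored:
        log.info("gene_activity_scores: %d peaks on unannotated chromosomes", ignored)
    scores = np.zeros((len(genome), pmat.n_obs))
    for chrom, gchunk in genome.groupby("chrom"):
        pchunk = peaks[peaks["chrom"] == chrom]
        if pchunk.empty:
            continue
        p_start = pchunk["start"].to_numpy()
        p_end = pchunk["end"].to_numpy()
        p_rows = pchunk.index.to_numpy()
        order = np.argsort(p_start, kind="stable")
        p_start, p_end, p_rows = p_start[order], p_end[order], p_rows[order]
        max_width = int((p_end - p_start).max())
        for gi, grow in gchunk.iterrows():
            w_start = grow["start"] - extension
            w_end = grow["end"] + extension
            lo = np.searchsorted(p_start, w_start - max_distance - max_width)
            hi = np.searchsorted(p_start, w_end + max_distance)
            if lo == hi:
                continue
            ps, pe, pr = p_start[lo:hi], p_end[lo:hi], p_rows[lo:hi]
            gap = np.maximum(np.maximum(w_start - pe, ps - w_end), 0)
            near = gap <= max_distance
            if not near.any():
                continue
            weight = np.where(gap == 0, 1.0, np.exp(-gap / decay_bp))[near]
            block = counts[pr[near]]
            scores[gi] += weight @ np.asarray(block.todense())
    return pd.DataFrame(scores, index=genome["gene_id"], columns=pmat.obs_names)


# ---------------------------------------------------------------------------
# chromVAR-style motif deviations


def chromvar_deviations(
    pmat: AnnData,
    motif_hits: pd.DataFrame,
    n_background: int = 50,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias-corrected motif accessibility deviation z-scores per cell.

    ``motif_hits`` is a peaks x motifs boolean table aligned to the peak set.
    Expected motif counts assume each cell distributes its total accessibility
    over peaks in proportion to the global peak fractions; the raw deviation
    (observed - expected)/expected is z-scored against ``n_background``
    matched background sets, drawn per member peak from the same
    mean-accessibility bin.  Motifs whose background deviations have zero
    spread in a cell are returned as NaN there.
    """
    if not motif_hits.index.equals(pmat.var_names):
        motif_hits = motif_hits.reindex(pmat.var_names)
    hits = motif_hits.to_numpy(dtype=bool)
    if (hits.sum(axis=0) < 5).any():
        bad = motif_hits.columns[hits.sum(axis=0) < 5].tolist()
        raise ValueError(f"motifs hitting < 5 peaks: {bad}")
    rng = np.random.default_rng(seed)
    x = sp.csr_matrix(pmat.X, dtype=float)
    peak_totals = np.asarray(x.sum(axis=0)).ravel()
    grand = peak_totals.sum()
    frac = peak_totals / grand
    cell_totals = np.asarray(x.sum(axis=1)).ravel()

    # accessibility bins for background matching
    ranks = scipy.stats.rankdata(peak_totals, method="average")
    bins = np.minimum((ranks - 1) / len(ranks) * n_bins, n_bins - 1).astype(int)
    peaks_in_bin = [np.flatnonzero(bins == b) for b in range(n_bins)]

    def _dev(hit_matrix: np.ndarray) -> np.ndarray:
        observed = np.asarray((x @ hit_matrix).T)  # motifs x cells
        expected = np.outer(frac @ hit_matrix, cell_totals)
        return (observed - expected) / np.maximum(expected, 1e-300)

    raw = _dev(hits.astype(float))
    bg = np.empty((n_background,) + raw.shape)
    for s in range(n_background):
        bg_hits = np.zeros_like(hits, dtype=float)
        for m in range(hits.shape[1]):
            members = np.flatnonzero(hits[:, m])
            sampled = np.array(
                [rng.choice(peaks_in_bin[bins[p]]) for p in members]
            )
            np.add.at(bg_hits[:, m], sampled, 1.0)
        bg[s] = _dev(bg_hits)
    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean_bg) / sd_bg
    z[sd_bg == 0] = np.nan
    return pd.DataFrame(z, index=motif_hits.columns, columns=pmat.obs_names)


# ---------------------------------------------------------------------------
# bulk time course


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment fit of the scaled-inverse-chi-square variance prior (d0, s0²).

    Under the hierarchical model s²_g | σ²_g ~ σ²_g χ²_d / d with σ²_g drawn
    from a scaled inverse chi-square with df d0 and scale s0², the first two
    moments of s² across regions identify (d0, s0²).  When the observed spread
    of s² is at or below the pure-sampling floor 2·mean²/d the prior df is
    effectively infinite (no variance heterogeneity) and a large d0 is
    returned.
    """
    m = float(np.mean(s2))
    v = float(np.var(s2))
    if m <= 0:
        return 1e6, max(m, 1e-12)
    floor = 2.0 * m * m / d

    def model_var(d0: float) -> float:
        # E[σ²] = s0²·d0/(d0-2); choose s0² so that E[s²] = m, then
        # Var[s²] = E[2σ⁴/d] + Var[σ²] with E[σ⁴] = (s0²d0)²/((d0-2)(d0-4)).
        e_sigma4 = m * m * (d0 - 2.0) / (d0 - 4.0)
        var_sigma = e_sigma4 - m * m
        return 2.0 * e_sigma4 / d + var_sigma

    if v <= model_var(1e7):
        return 1e6, m
    lo, hi = 4.0 + 1e-6, 1e7
    if v >= model_var(lo):
        d0 = lo
    else:
        d0 = brentq(lambda t: model_var(t) - v, lo, hi)
    s0 = m * (d0 - 2.0) / d0
    return float(d0), float(s0)


def moderated_ttest(
    a: np.ndarray, b: np.ndarray, d0: float | None = None, s0_sq: float | None = None
) -> pd.DataFrame:
    """Two-sample moderated t per row with empirical-Bayes variance shrinkage.

    Pooled per-row variances are shrunk to the moment-fitted prior via the
    posterior (d0·s0² + d·s²)/(d0 + d); t is referenced to d + d0 degrees of
    freedom.  d0 = 0 reduces to the ordinary two-sample t.
    """
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    if d < 1:
        raise ValueError("need >= 2 replicates overall beyond group count")
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / d
    if d0 is None:
        d0, s0_sq = _fit_variance_prior(s2, d)
    post = (d0 * s0_sq + d * s2) / (d0 + d) if d0 > 0 else s2
    se = np.sqrt(post * (1.0 / na + 1.0 / nb))
    delta = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / se
    df = d + d0
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"delta": delta, "t": t, "p_value": p, "df": df})


def _cmeans(
    x: np.ndarray, n_clusters: int, fuzzifier: float = 2.0,
    n_restarts: int = 100, n_iter: int = 200, tol: float = 1e-7, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fuzzy c-means; returns (memberships, centers, objective of best run)."""
    rng = np.random.default_rng(seed)
    best = (None, None, np.inf)
    n, p = x.shape
    for _ in range(n_restarts):
        centers = x[rng.choice(n, n_clusters, replace=False)] + rng.normal(
            0, 1e-6, (n_clusters, p)
        )
        prev = np.inf
        for _ in range(n_iter):
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (fuzzifier - 1.0))  # d^{-2/(m-1)}
            u = inv / inv.sum(axis=1, keepdims=True)
            um = u**fuzzifier
            centers = (um.T @ x) / um.sum(axis=0)[:, None]
            obj = float((um * d2).sum())
            if abs(prev - obj) < tol:
                break
            prev = obj
        if obj < best[2]:
            best = (u, centers, obj)
    return best


def timecourse_modules(
    table: pd.DataFrame,
    lfc_threshold: float = 0.5,
    padj_threshold: float = 0.05,
    n_modules: int = 6,
    seed: int = 0,
    n_restarts: int = 100,
) -> tuple[dict[int, DAResult], pd.DataFrame]:
    """Time-course DA (each time point vs 0 h) + fuzzy module clustering.

    Columns must be named ``t{hours}_r{replicate}`` over 0/48/72/96 h with
    >= 2 replicates each.  Per time point a moderated t on log2 CPM calls DA
    regions at |log2FC| > ``lfc_threshold`` and BH-adjusted p <
    ``padj_threshold``; the union of regions significant in at least one time
    point is clustered by fuzzy c-means (fuzzifier 2) on z-standardized mean
    time profiles.  Returns ({hours: DAResult}, module table with membership).
    """
    groups: dict[int, list[str]] = {}
    for col in table.columns:
        t = int(col.split("_")[0][1:])
        groups.setdefault(t, []).append(col)
    times = sorted(groups)
    if len(times) < 2 or 0 not in groups:
        raise ValueError("need a 0 h reference and >= 2 time points")
    if any(len(cols) < 2 for cols in groups.values()):
        raise ValueError("need >= 2 replicates per time point")
    counts = table.to_numpy(dtype=float)
    # median-of-ratios size factors: robust to the DA regions themselves
    # shifting library totals between time points
    logref = np.log(np.maximum(counts, 1e-12)).mean(axis=1)
    usable = np.isfinite(logref) & (counts.min(axis=1) > 0)
    sf = np.exp(
        np.median(np.log(counts[usable]) - logref[usable, None], axis=0)
    )
    logcpm = np.log2(counts / sf[None, :] + 1.0)
    col_idx = {c: i for i, c in enumerate(table.columns)}
    ref = logcpm[:, [col_idx[c] for c in groups[0]]]
    da_results: dict[int, DAResult] = {}
    union = np.zeros(len(table), dtype=bool)
    for t in times:
        if t == 0:
            continue
        cur = logcpm[:, [col_idx[c] for c in groups[t]]]
        stats = moderated_ttest(cur, ref)
        padj = bh_adjust(stats["p_value"].to_numpy())
        lfc = stats["delta"].to_numpy()
        sig = (np.abs(lfc) > lfc_threshold) & (padj < padj_threshold)
        direction = np.where(sig, np.where(lfc > 0, "up", "down"), "ns")
        da_results[t] = DAResult(
            pd.DataFrame(
                {
                    "log2_fold_change": lfc,
                    "p_value": stats["p_value"].to_numpy(),
                    "p_adjusted": padj,
                    "direction": direction,
                },
                index=table.index,
            )
        )
        union |= sig

    if not union.any():
        modules = pd.DataFrame(columns=["module", "membership"], index=table.index[:0])
        return da_results, modules
    profiles = np.column_stack(
        [logcpm[union][:, [col_idx[c] for c in groups[t]]].mean(axis=1) for t in times]
    )
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    z = (profiles - mu) / np.where(sd == 0, 1.0, sd)
    k = min(n_modules, z.shape[0])
    u, centers, _ = _cmeans(z, k, n_restarts=n_restarts, seed=seed)
    modules = pd.DataFrame(
        {"module": u.argmax(axis=1) + 1, "membership": u.max(axis=1)},
        index=table.index[union],
    )
    return da_results, modules
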