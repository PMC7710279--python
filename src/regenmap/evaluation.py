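"""Simulation benchmarks: run each pipeline stage on generated data with
planted truth and measure recovery.

These functions are the package's self-evaluation suite — each one generates
data with :mod:`regenmap.synthdata`, runs the corresponding analysis stage,
and returns a scalar recovery/error metric plus the problem size used.  They
back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import chromatin, dynamics, grn, io_qc, rna_states, synthdata, topics
from .containers import make_peak_matrix


def _match_by_vote(found: np.ndarray, planted: np.ndarray) -> dict:
    """Map each found cluster label to the planted label it mostly contains."""
    mapping = {}
    for k in np.unique(found):
        vals, counts = np.unique(planted[found == k], return_counts=True)
        mapping[k] = vals[np.argmax(counts)]
    return mapping


def rna_clustering_recovery(seed: int, n_cells: int = 600, n_clusters: int = 4) -> dict:
    """ARI of Leiden clustering against the planted RNA states."""
    adata, truth = synthdata.gen_rna_counts(
        n_cells=n_cells, n_genes=300, n_clusters=n_clusters, seed=seed
    )
    filt = io_qc.filter_cells_rna(adata)
    norm = rna_states.normalize_counts(filt)
    clusters = rna_states.cluster_cells(norm, seed=seed)
    keep = np.isin(adata.obs_names, filt.obs_names)
    ari = adjusted_rand_score(truth.cluster_labels[keep], clusters.labels)
    return {"value": float(ari), "n": int(filt.n_obs)}


def atac_clustering_recovery(seed: int, n_cells: int = 400, n_topics: int = 4) -> dict:
    """ARI of Leiden-on-LSI against the planted ATAC states."""
    pmat, _, truth = synthdata.gen_atac_data(
        n_cells=n_cells, n_regions=1500, n_topics=n_topics, seed=seed,
        make_fragments=False,
    )
    emb = chromatin.tfidf_lsi(pmat, n_components=20, seed=seed)
    clusters = rna_states.cluster_cells(
        emb, is_embedding=True, resolution=0.5, seed=seed
    )
    ari = adjusted_rand_score(truth.cluster_labels, clusters.labels)
    return {"value": float(ari), "n": int(n_cells)}


def gamma_recovery(seed: int, n_cells: int = 500, noise: float = 0.1) -> dict:
    """Median relative error of steady-state γ estimates at 10% noise."""
    adata, truth = synthdata.gen_rna_counts(
        n_cells=n_cells, n_genes=300, seed=seed, splicing_noise=noise
    )
    fit = dynamics.fit_gamma(adata.layers["spliced"], adata.layers["unspliced"])
    ok = fit["fitted"].to_numpy()
    rel = np.abs(fit["gamma"].to_numpy()[ok] / truth.gamma_true[ok] - 1.0)
    return {"value": float(np.median(rel)), "n": int(n_cells)}


def deconvolution_error(seed: int, n_reps: int = 50, noise: float = 0.05) -> dict:
    """Mean absolute cell-type fraction error of NNLS deconvolution."""
    refs = synthdata.gen_reference_profiles(seed=seed)
    errs = []
    for r in range(n_reps):
        bulk, truth = synthdata.gen_bulk_mixtures(
            refs.celltype_profiles, n_samples=1, seed=seed * 1000 + r, noise_sd=noise
        )
        frac = rna_states.deconvolute_bulk(bulk, refs.celltype_profiles)
        est = frac.iloc[0, : truth.mixing_fractions.shape[1]].to_numpy()
        errs.append(np.abs(est - truth.mixing_fractions[0]).mean())
    return {"value": float(np.mean(errs)), "n": n_reps}


def grn_edge_auroc(
    seed: int, n_cells: int = 1000, n_tfs: int = 5, targets_per_tf: int = 20,
    n_trees: int = 100,
) -> dict:
    """AUROC of GENIE3-style link importances against the planted regulons."""
    adata, truth = synthdata.gen_rna_counts(
        n_cells=n_cells, n_genes=250, n_clusters=4, n_tfs=n_tfs,
        targets_per_tf=targets_per_tf, seed=seed,
    )
    norm = rna_states.normalize_counts(adata)
    tfs = sorted(truth.regulon_map)
    links = grn.infer_grn(norm, tfs, n_trees=n_trees, seed=seed)
    is_true = np.array(
        [t in truth.regulon_map[f] for f, t in zip(links["tf"], links["target"])]
    )
    auroc = roc_auc_score(is_true, links["importance"].to_numpy())
    return {"value": float(auroc), "n": int(n_cells)}


def lda_block_purity(seed: int, n_cells: int = 200, n_regions: int = 600) -> dict:
    """Region-topic purity of a 2-topic LDA on noiseless 2-block data."""
    pmat, _, truth = synthdata.gen_atac_data(
        n_cells=n_cells, n_regions=n_regions, n_topics=2, seed=seed,
        make_fragments=False, block_mass=1.0, topic_concentration=50.0,
        off_topic_concentration=1e-3,
    )
    binary = topics.binarize(pmat)
    model = topics.lda_fit(binary, n_topics=2, n_iter=150, burn_in=75, seed=seed)
    fitted = model.phi.argmax(axis=0) + 1
    tab = pd.crosstab(truth.topic_assignments, fitted)
    purity = tab.max(axis=1).sum() / tab.to_numpy().sum()
    return {"value": float(purity), "n": int(n_regions)}


def topic_selection_hit_rate(
    seed: int, n_runs: int = 10, true_t: int = 4, grid=(2, 4, 8)
) -> dict:
    """Fraction of seeds in which model selection picks the planted T."""
    hits = 0
    for r in range(n_runs):
        pmat, _, _ = synthdata.gen_atac_data(
            n_cells=200, n_regions=1000, n_topics=true_t, seed=seed * 100 + r,
            make_fragments=False,
        )
        binary = topics.binarize(pmat)
        best, _, _ = topics.select_topic_number(
            binary, grid, seed=seed + r, n_iter=150, burn_in=75
        )
        hits += best == true_t
    return {"value": float(hits / n_runs), "n": n_runs}


def da_type1_rate(
    seed: int, n_reps: int = 50, n_regions: int = 200, n_cells_per_group: int = 50
) -> dict:
    """Mean fraction of null regions at p < 0.05 in single-cell DA."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_reps):
        counts = rng.poisson(3.0, (2 * n_cells_per_group, n_regions))
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_regions) * 1000,
                "end": np.arange(n_regions) * 1000 + 400,
                "peak_id": [f"p{i}" for i in range(n_regions)],
            }
        )
        pmat = make_peak_matrix(
            sp.csr_matrix(counts), peaks,
            [f"c{i}" for i in range(2 * n_cells_per_group)],
        )
        res = chromatin.differential_accessibility(
            pmat,
            np.arange(n_cells_per_group),
            np.arange(n_cells_per_group, 2 * n_cells_per_group),
            lfc_threshold=0.0,
        )
        fracs.append((res.table["p_value"] < 0.05).mean())
    return {"value": float(np.mean(fracs)), "n": n_reps}


def da_power(
    seed: int, n_cells_per_group: int = 100, n_regions: int = 300,
    frac_da: float = 0.1, fold: float = 4.0,
) -> dict:
    """Power for planted ``fold``-change regions at |log2FC| >= 1, Padj < 0.05."""
    rng = np.random.default_rng(seed)
    n_da = int(frac_da * n_regions)
    base = rng.lognormal(np.log(2.0), 0.4, n_regions)
    mean_a = base.copy()
    mean_a[:n_da] *= fold
    r = 1.0 / 0.3
    a = rng.negative_binomial(r, r / (r + mean_a), (n_cells_per_group, n_regions))
    b = rng.negative_binomial(r, r / (r + base), (n_cells_per_group, n_regions))
    counts = np.vstack([a, b])
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_regions) * 1000,
            "end": np.arange(n_regions) * 1000 + 400,
            "peak_id": [f"p{i}" for i in range(n_regions)],
        }
    )
    pmat = make_peak_matrix(
        sp.csr_matrix(counts), peaks, [f"c{i}" for i in range(2 * n_cells_per_group)]
    )
    res = chromatin.differential_accessibility(
        pmat,
        np.arange(n_cells_per_group),
        np.arange(n_cells_per_group, 2 * n_cells_per_group),
        lfc_threshold=1.0,
    )
    called = res.table["direction"].to_numpy()[:n_da] == "up"
    return {"value": float(called.mean()), "n": n_da}


def timecourse_null_rate(seed: int, n_regions: int = 400) -> dict:
    """Fraction of flat regions at adjusted P < 0.05 in the time course."""
    table, _ = synthdata.gen_bulk_timecourse(
        n_regions=n_regions, signal_fraction=0.0, seed=seed
    )
    da, _ = chromatin.timecourse_modules(table, seed=seed, n_restarts=10)
    frac = float(
        np.mean([(d.table["p_adjusted"] < 0.05).mean() for d in da.values()])
    )
    return {"value": frac, "n": n_regions}


def timecourse_module_recovery(seed: int, n_regions: int = 600) -> dict:
    """ARI between recovered and planted kinetic modules on DA regions."""
    table, truth = synthdata.gen_bulk_timecourse(
        n_regions=n_regions, n_modules=6, seed=seed
    )
    _, modules = chromatin.timecourse_modules(table, seed=seed, n_restarts=30)
    planted = pd.Series(truth.module_labels, index=table.index).loc[modules.index]
    ari = adjusted_rand_score(planted, modules["module"])
    return {"value": float(ari), "n": int(len(modules))}


def pseudotime_recovery(seed: int, n_cells: int = 300) -> dict:
    """Spearman correlation of graph pseudotime with the planted ordering."""
    x, _, truth = synthdata.gen_trajectory(n_cells=n_cells, seed=seed)
    _, dist = rna_states.knn_graph(x, 15)
    root = int(np.argmin(truth.trajectory_order))
    pt = dynamics.pseudotime(dist, root)
    rho = spearmanr(pt["pseudotime"], truth.trajectory_order)[0]
    return {"value": float(rho), "n": int(n_cells)}


def velocity_direction_recovery(seed: int, n_cells: int = 300) -> dict:
    """Mean transition mass sent to forward neighbors on a planted path."""
    x, v, truth = synthdata.gen_trajectory(n_cells=n_cells, seed=seed)
    _, dist = rna_states.knn_graph(x, 15)
    trans = dynamics.velocity_transition_graph(v, x, dist, kernel_scale=0.05)
    order = truth.trajectory_order
    coo = trans.tocoo()
    fwd = np.zeros(n_cells)
    for i, j, p in zip(coo.row, coo.col, coo.data):
        if order[j] > order[i]:
            fwd[i] += p
    # the last cell on the path has no forward neighbors; drop the path tail
    interior = order < np.quantile(order, 0.95)
    return {"value": float(fwd[interior].mean()), "n": int(n_cells)}


def end_to_end_linking(
    seed: int,
    n_rna_cells: int = 2000,
    n_atac_cells: int = 1500,
    n_regions: int = 5000,
    n_states: int = 9,
    tfs_per_state: int = 5,
    targets_per_tf: int = 6,
    n_trees: int = 50,
    lda_iter: int = 150,
) -> dict:
    """Full pipeline: RNA states → regulons → peak signatures → LDA →
    correspondence; returns the fraction of ATAC clusters whose argmax
    signature matches the planted state, plus whether the planted
    multi-cluster ("fetal-like") state mapped to >= 2 ATAC clusters.

    ``tfs_per_state`` regulons are planted per state so that "the top 5
    regulons in each cluster" are that state's own regulons, as in the real
    data where each cluster's top regulons are distinct.
    """
    n_tfs = tfs_per_state * n_states
    adata, truth = synthdata.gen_rna_counts(
        n_cells=n_rna_cells,
        n_genes=60 + n_tfs * (1 + targets_per_tf) + n_states * 15 + 40,
        n_clusters=n_states,
        n_tfs=n_tfs,
        targets_per_tf=targets_per_tf,
        seed=seed,
    )
    filt = io_qc.filter_cells_rna(adata, min_features=0)
    norm = rna_states.normalize_counts(filt)
    rna_clusters = rna_states.cluster_cells(norm, seed=seed, resolution=0.4)
    keep = np.isin(adata.obs_names, filt.obs_names)
    state_of_rna = _match_by_vote(rna_clusters.labels, truth.cluster_labels[keep])

    tfs = sorted(truth.regulon_map)
    links = grn.infer_grn(norm, tfs, n_trees=n_trees, seed=seed)
    refs = synthdata.gen_reference_profiles(
        seed=seed, regulon_map=truth.regulon_map, promoter_genes=list(adata.var_names)
    )
    regulons = grn.prune_regulons(links, refs.pwms, refs.promoters, top_k_links=30)
    auc = grn.score_regulons(norm, regulons)
    ranked = grn.rank_regulons_per_cluster(auc, rna_clusters, top_k=5)
    reg_by_tf = {r.tf: r for r in regulons}
    top_regulons = {
        k: [reg_by_tf[tf] for tf in chunk["tf"]]
        for k, chunk in ranked.groupby("cluster")
    }

    genome = synthdata.gen_genome(adata.n_vars, gene_ids=list(adata.var_names), seed=seed)
    pmat, _, atac_truth = synthdata.gen_atac_data(
        n_cells=n_atac_cells,
        n_regions=n_regions,
        n_topics=n_states,
        genome=genome,
        regulons=truth.regulon_map,
        seed=seed + 1,
        split_state=n_states,
        n_split=3,
        make_fragments=False,
    )
    emb = chromatin.tfidf_lsi(pmat, n_components=30, seed=seed)
    atac_clusters = rna_states.cluster_cells(
        emb, is_embedding=True, resolution=1.0, seed=seed
    )
    planted_cluster_of_found = _match_by_vote(
        atac_clusters.labels, atac_truth.atac_cluster_labels
    )

    binary = topics.binarize(pmat)
    model = topics.lda_fit(
        binary, n_topics=n_states, n_iter=lda_iter, burn_in=lda_iter // 2, seed=seed
    )
    prob = topics.region_cell_probability(model)
    peaks = pmat.var.reset_index().rename(
        columns={pmat.var.index.name or "index": "peak_id"}
    )
    signatures = topics.build_peak_signature(top_regulons, genome, peaks)
    scores = topics.signature_enrichment(prob, signatures, np.asarray(pmat.var_names))
    corr = topics.cluster_signature_correlation(scores, atac_clusters)

    # evaluate the found-cluster ↔ signature map against the planted states
    n_correct = 0
    fetal_hits = 0
    state_assigned: dict[int, set] = {}
    for found_cluster, row in corr.iterrows():
        planted_atac = planted_cluster_of_found[found_cluster]
        true_state = atac_truth.state_of_atac_cluster[planted_atac]
        mapped_state = state_of_rna[int(row["argmax_signature"])]
        state_assigned.setdefault(mapped_state, set()).add(found_cluster)
        if mapped_state == true_state:
            n_correct += 1
            if true_state == n_states:
                fetal_hits += 1
    states_correct = {
        atac_truth.state_of_atac_cluster[planted_cluster_of_found[fc]]
        for fc, row in corr.iterrows()
        if state_of_rna[int(row["argmax_signature"])]
        == atac_truth.state_of_atac_cluster[planted_cluster_of_found[fc]]
    }
    return {
        "value": float(len(states_correct) / n_states),
        "n": int(n_atac_cells),
        "states_correct": len(states_correct),
        "n_states": n_states,
        "n_atac_clusters": int(atac_clusters.n_clusters),
        "fetal_multi_cluster": bool(fetal_hits >= 2),
        "correspondence": corr,
    }
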