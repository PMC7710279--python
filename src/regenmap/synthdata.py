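"""Synthetic multi-omic data with planted ground truth.

Every generator is a pure function of its parameters and seed and emulates the
structure of the study's real inputs: cluster-structured negative-binomial
scRNA counts carrying TF→target regulons and a portal→central zonation
gradient, spliced/unspliced layers from known splicing ratios, topic-structured
binary accessibility whose peak blocks overlap the regulon gene bodies,
TSS-enriched fragment records, motif placements in promoter sequences, and a
four-time-point bulk accessibility table with planted kinetic modules.  The
planted quantities come back in a :class:`~regenmap.containers.SyntheticTruth`
so downstream stages can be tested as parameter-recovery problems.

Defaults encode what we consider a realistic regime for this tissue: 10x-scale
library sizes are scaled down ~10x, negative-binomial dispersion 0.3 (typical
scRNA overdispersion without extreme zero inflation), ~8% of regions open per
nucleus, and a 2:1 good:bad nuclei TSS-enrichment contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .containers import (
    PWM,
    SignatureSet,
    SyntheticTruth,
    make_count_matrix,
    make_genome_annotation,
    make_peak_matrix,
    validate_peaks,
)

TIME_POINTS_H = (0, 48, 72, 96)

# log2 fold-change kinetic shapes relative to 0 h at t = 0/48/72/96 h:
# early burst, sustained induction, early loss w/ recovery, sustained loss,
# late monotone gain, late monotone loss, spike-then-undershoot, V-shaped.
_MODULE_SHAPES = np.array(
    [
        [0.0, 2.0, 0.8, 0.0],
        [0.0, 1.5, 1.5, 1.5],
        [0.0, -2.0, -0.8, 0.0],
        [0.0, -1.5, -1.5, -1.5],
        [0.0, 0.0, 1.0, 2.0],
        [0.0, 0.0, -1.0, -2.0],
        [0.0, 2.0, -1.0, -2.0],
        [0.0, -2.0, 1.0, 2.0],
    ]
)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with mean ``mean`` and Var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def gen_rna_counts(
    n_cells: int = 1000,
    n_genes: int = 300,
    n_clusters: int = 4,
    n_tfs: int = 5,
    seed: int = 0,
    targets_per_tf: int = 20,
    dispersion: float = 0.3,
    marker_genes_per_cluster: int = 15,
    marker_fold: float = 6.0,
    activity_sd: float = 0.8,
    n_zonation_genes: int = 40,
    splicing_noise: float = 0.1,
    high_mito_share: float = 0.1,
    mito_threshold: float = 0.2,
    depth_sd: float = 0.25,
) -> tuple[AnnData, SyntheticTruth]:
    """Simulate a clustered scRNA count matrix with spliced/unspliced layers.

    Gene roles (``var['role']``): ``tf`` — transcription factors whose
    cell-level activity is cluster-biased; ``target`` — regulon members whose
    means scale with their TF's activity; ``marker`` — cluster-specific
    markers; ``pv``/``pp`` — perivenous (decreasing) and periportal
    (increasing) zonation genes, linear in the zonation coordinate
    (0 = central, 1 = portal); ``other`` — background.

    Unspliced counts are drawn around the steady-state line u = γ·s with
    multiplicative log-normal noise of scale ``splicing_noise`` (0 ⇒ exact).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_tfs * targets_per_tf > n_genes // 2:
        raise ValueError("n_tfs * targets_per_tf must be <= n_genes / 2")
    needed = n_tfs * (1 + targets_per_tf) + n_clusters * marker_genes_per_cluster
    if needed + n_zonation_genes > n_genes:
        raise ValueError(
            f"n_genes={n_genes} too small for requested structure ({needed} needed)"
        )
    rng = np.random.default_rng(seed)

    tf_names = [f"tf{i + 1:02d}" for i in range(n_tfs)]
    roles = ["tf"] * n_tfs
    gene_names = list(tf_names)
    regulon_map: dict[str, frozenset] = {}
    g = 0
    for tf in tf_names:
        targets = [f"g{g + j + 1:04d}" for j in range(targets_per_tf)]
        g += targets_per_tf
        regulon_map[tf] = frozenset(targets)
        gene_names += targets
        roles += ["target"] * targets_per_tf
    marker_of_cluster = {}
    for k in range(1, n_clusters + 1):
        markers = [f"g{g + j + 1:04d}" for j in range(marker_genes_per_cluster)]
        g += marker_genes_per_cluster
        marker_of_cluster[k] = markers
        gene_names += markers
        roles += ["marker"] * marker_genes_per_cluster
    n_pv = n_zonation_genes // 2
    pv = [f"pv{j + 1:03d}" for j in range(n_pv)]
    pp = [f"pp{j + 1:03d}" for j in range(n_zonation_genes - n_pv)]
    gene_names += pv + pp
    roles += ["pv"] * len(pv) + ["pp"] * len(pp)
    n_other = n_genes - len(gene_names)
    gene_names += [f"g{g + j + 1:04d}" for j in range(n_other)]
    roles += ["other"] * n_other

    labels = 1 + (np.arange(n_cells) % n_clusters)
    rng.shuffle(labels)
    zonation = rng.uniform(0.0, 1.0, n_cells)

    base = rng.lognormal(np.log(2.0), 0.5, n_genes)
    # TFs are detectably expressed (a usable TF panel is expression-filtered)
    base[:n_tfs] = rng.lognormal(np.log(4.0), 0.3, n_tfs)
    mean = np.tile(base, (n_cells, 1))

    # TF activity: high in the TF's home cluster, low elsewhere, with
    # cell-level log-normal variation that drives TF-target coexpression.
    tf_of_cluster = {}
    activity = np.empty((n_cells, n_tfs))
    for t, tf in enumerate(tf_names):
        home = (t % n_clusters) + 1
        tf_of_cluster.setdefault(home, tf)
        mu = np.where(labels == home, np.log(2.0), np.log(0.4))
        activity[:, t] = np.exp(mu + rng.normal(0.0, activity_sd, n_cells))
        mean[:, t] = base[t] * activity[:, t]
        cols = [gene_names.index(tg) for tg in sorted(regulon_map[tf])]
        mean[:, cols] = base[cols][None, :] * activity[:, t][:, None]

    for k, markers in marker_of_cluster.items():
        cols = [gene_names.index(m) for m in markers]
        fold = np.where(labels == k, marker_fold, 1.0)
        mean[:, cols] *= fold[:, None]

    for j, name in enumerate(gene_names):
        if roles[j] == "pv":
            mean[:, j] = base[j] * (0.25 + 1.75 * (1.0 - zonation))
        elif roles[j] == "pp":
            mean[:, j] = base[j] * (0.25 + 1.75 * zonation)

    depth = rng.lognormal(0.0, depth_sd, n_cells) if depth_sd > 0 else np.ones(n_cells)
    mean *= depth[:, None]

    spliced = _nb_sample(rng, mean, dispersion)
    gamma_true = rng.lognormal(np.log(0.5), 0.4, n_genes)
    noise = (
        np.exp(rng.normal(0.0, splicing_noise, spliced.shape))
        if splicing_noise > 0
        else 1.0
    )
    unspliced = spliced * gamma_true[None, :] * noise

    n_high = int(round(high_mito_share * n_cells))
    mito = np.minimum(rng.beta(2.0, 30.0, n_cells), mito_threshold * 0.95)
    high_idx = rng.choice(n_cells, n_high, replace=False)
    mito[high_idx] = rng.uniform(mito_threshold * 1.5, 0.9, n_high)

    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "mito_fraction": mito,
            "time_point_h": 48,
            "sample_id": "PHx48h",
        }
    )
    adata = make_count_matrix(
        sp.csr_matrix(spliced),
        cell_ids,
        gene_names,
        layers={"spliced": sp.csr_matrix(spliced), "unspliced": sp.csr_matrix(unspliced)},
        cell_meta=meta,
    )
    adata.var["role"] = roles
    truth = SyntheticTruth(
        cluster_labels=labels,
        regulon_map=regulon_map,
        zonation_coord=zonation,
        gamma_true=gamma_true,
        tf_of_cluster=tf_of_cluster,
    )
    return adata, truth


def gen_genome(
    n_genes: int,
    gene_ids=None,
    seed: int = 0,
    chrom_size: int = 2_000_000,
    genes_per_chrom: int = 40,
    gene_length: int = 5000,
    spacing: int = 40_000,
) -> pd.DataFrame:
    """Non-overlapping gene annotation on synthetic chromosomes.

    Genes are laid out on a regular grid with random strand so the spacing
    between gene windows is known and interval logic is easy to verify.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length mismatch")
    rows = []
    for i, gid in enumerate(gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        start = 20_000 + (i % genes_per_chrom) * spacing
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": start + gene_length,
                "strand": rng.choice(["+", "-"]),
            }
        )
    return make_genome_annotation(pd.DataFrame(rows))


def gen_atac_data(
    n_cells: int = 500,
    n_regions: int = 2000,
    n_topics: int = 4,
    genome: pd.DataFrame | None = None,
    regulons: dict | None = None,
    seed: int = 0,
    n_clusters: int | None = None,
    split_state: int | None = None,
    n_split: int = 3,
    tokens_per_cell: float | None = None,
    topic_concentration: float = 8.0,
    off_topic_concentration: float = 0.4,
    block_mass: float = 0.9,
    bad_share: float = 0.0,
    make_fragments: bool = True,
    mean_fragments_good: int = 2000,
    mean_fragments_bad: int = 1300,
    tss_fraction_good: float = 0.5,
    peak_width: int = 400,
) -> tuple[AnnData, pd.DataFrame | None, SyntheticTruth]:
    """Simulate topic-structured accessibility counts plus fragment records.

    Each region gets one dominant topic (block-structured region-topic
    multinomials); cell-topic weights are Dirichlet draws concentrated on the
    cell's cluster topic, and counts are true LDA draws from that mixture.
    Regions covering the supplied regulons' gene bodies are assigned to the
    topic of the TF's home state, planting a cluster↔regulon↔peak-block
    correspondence.  When ``split_state`` is given, that state's cells are
    divided into ``n_split`` sub-clusters that share its topic profile but
    carry small private accessible region sets (the multi-cluster "fetal-like"
    geometry).  A ``bad_share`` fraction of nuclei get TSS-uninformative
    uniform fragments.
    """
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    rng = np.random.default_rng(seed)
    n_states = n_clusters or n_topics

    if genome is None:
        gene_ids = sorted({g for ts in (regulons or {}).values() for g in ts})
        gene_ids += [t for t in (regulons or {})]
        genome = gen_genome(max(len(gene_ids), 20), gene_ids=gene_ids or None, seed=seed)
    if regulons:
        known = set(genome["gene_id"])
        missing = sorted(
            {g for ts in regulons.values() for g in ts if g not in known}
            | {t for t in regulons if t not in known}
        )
        if missing:
            raise ValueError(f"regulon genes absent from genome: {missing}")

    # --- region layout: one peak per regulon gene body, rest intergenic ---
    gene_by_id = genome.set_index("gene_id")
    topic_of_state = {s: ((s - 1) % n_topics) + 1 for s in range(1, n_states + 1)}
    tf_names = sorted(regulons) if regulons else []
    peaks = []
    topics = []
    for t, tf in enumerate(tf_names):
        state = (t % n_states) + 1
        for gid in sorted(regulons[tf] | {tf}):
            row = gene_by_id.loc[gid]
            center = (row["start"] + row["end"]) // 2
            peaks.append((row["chrom"], center - peak_width // 2, center + peak_width // 2))
            topics.append(topic_of_state[state])
    chroms = sorted(genome["chrom"].unique())
    chrom_len = int(genome.groupby("chrom")["end"].max().max()) + 100_000
    n_extra = n_regions - len(peaks)
    if n_extra < 0:
        raise ValueError("n_regions too small for the supplied regulons")
    # remaining regions are intergenic: keep clear of gene bodies ±2 kb so the
    # planted regulon peak blocks stay unmixed with random topics
    windows = {
        c: np.sort(g[["start", "end"]].to_numpy(), axis=0)
        for c, g in genome.groupby("chrom")
    }
    extra_chrom = rng.integers(0, len(chroms), n_extra)
    extra_topic = rng.integers(1, n_topics + 1, n_extra)
    for j in range(n_extra):
        chrom = chroms[extra_chrom[j]]
        win = windows.get(chrom)
        for _ in range(100):
            start = int(rng.integers(0, chrom_len - peak_width))
            if win is None or not (
                (start < win[:, 1] + 2000) & (start + peak_width > win[:, 0] - 2000)
            ).any():
                break
        peaks.append((chrom, start, start + peak_width))
        topics.append(int(extra_topic[j]))
    peak_df = pd.DataFrame(peaks, columns=["chrom", "start", "end"])
    topic_assign = np.asarray(topics)
    # sort by coordinate up front so matrix columns, topic assignments and the
    # validated PeakSet all share one order
    order = np.lexsort((peak_df["start"].to_numpy(), peak_df["chrom"].to_numpy()))
    peak_df = peak_df.iloc[order].reset_index(drop=True)
    topic_assign = topic_assign[order]
    peak_df["peak_id"] = [f"peak{i + 1:05d}" for i in range(len(peak_df))]

    # region-topic multinomials: block_mass on own block, rest spread
    phi = np.full((n_topics, n_regions), np.nan)
    for t in range(1, n_topics + 1):
        block = topic_assign == t
        n_in = max(int(block.sum()), 1)
        phi[t - 1] = (1.0 - block_mass) / (n_regions - n_in) if n_in < n_regions else 0.0
        phi[t - 1, block] = block_mass / n_in
    phi /= phi.sum(axis=1, keepdims=True)

    # --- cluster labels, with optional split of one state ---
    state_labels = 1 + (np.arange(n_cells) % n_states)
    rng.shuffle(state_labels)
    atac_labels = state_labels.copy()
    state_of_cluster = {c: c for c in range(1, n_states + 1)}
    private_sets: dict[int, np.ndarray] = {}
    if split_state is not None:
        next_label = n_states + 1
        members = np.flatnonzero(state_labels == split_state)
        parts = np.array_split(members, n_split)
        free = np.flatnonzero(topic_assign != topic_of_state[split_state])
        sub_labels = [split_state] + list(range(next_label, next_label + n_split - 1))
        for i, (part, lab) in enumerate(zip(parts, sub_labels)):
            atac_labels[part] = lab
            state_of_cluster[lab] = split_state
            k = max(n_regions // 50, 5)
            private_sets[lab] = rng.choice(free, k, replace=False)
            free = np.setdiff1d(free, private_sets[lab])

    # --- sample counts: LDA tokens + private-region Bernoulli blocks ---
    tokens_per_cell = tokens_per_cell or 0.08 * n_regions
    conc = np.full(n_topics, off_topic_concentration)
    depth = rng.lognormal(0.0, 0.3, n_cells)
    rows, cols_idx, vals = [], [], []
    for c in range(n_cells):
        a = conc.copy()
        a[topic_of_state[state_of_cluster[atac_labels[c]]] - 1] = topic_concentration
        theta = rng.dirichlet(a)
        n_tok = rng.poisson(tokens_per_cell * depth[c])
        z = rng.choice(n_topics, n_tok, p=theta)
        regions = np.empty(n_tok, dtype=np.int64)
        for t in range(n_topics):
            mask = z == t
            if mask.any():
                regions[mask] = rng.choice(n_regions, int(mask.sum()), p=phi[t])
        priv = private_sets.get(atac_labels[c])
        if priv is not None:
            opened = priv[rng.random(len(priv)) < 0.6]
            regions = np.concatenate([regions, opened])
        idx, cnt = np.unique(regions, return_counts=True)
        rows.append(np.full(len(idx), c))
        cols_idx.append(idx)
        vals.append(cnt)
    counts = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols_idx))),
        shape=(n_cells, n_regions),
        dtype=np.int64,
    ).tocsr()

    cell_ids = [f"nucleus{i + 1:05d}" for i in range(n_cells)]
    good = rng.random(n_cells) >= bad_share
    meta = pd.DataFrame({"time_point_h": 48, "sample_id": "PHx48h", "is_good_nucleus": good})
    pmat = make_peak_matrix(sp.csr_matrix(counts), validate_peaks(peak_df.copy()), cell_ids, meta)

    fragments = None
    if make_fragments:
        fragments = _gen_fragments(
            rng, genome, cell_ids, good, chrom_len,
            mean_fragments_good, mean_fragments_bad, tss_fraction_good,
        )

    truth = SyntheticTruth(
        cluster_labels=state_labels,
        atac_cluster_labels=atac_labels,
        topic_assignments=topic_assign,
        state_of_atac_cluster=state_of_cluster,
        regulon_map={tf: frozenset(ts) for tf, ts in (regulons or {}).items()},
    )
    return pmat, fragments, truth


def _gen_fragments(
    rng, genome, cell_ids, good, chrom_len, mean_good, mean_bad, tss_frac
) -> pd.DataFrame:
    """Fragment records: TSS-targeted midpoints follow a triangular density
    (±1 kb) for good nuclei; bad nuclei are uniform genome-wide.  Lengths are a
    nucleosomal mixture with modes near 80 and 230 bp."""
    tss = genome["tss"].to_numpy()
    tss_chrom = genome["chrom"].to_numpy()
    chroms = sorted(genome["chrom"].unique())
    rows_chrom, rows_start, rows_end, rows_bc = [], [], [], []
    for i, cid in enumerate(cell_ids):
        n = rng.poisson(mean_good if good[i] else mean_bad)
        frac = tss_frac if good[i] else 0.0
        n_tss = rng.binomial(n, frac)
        lengths = np.where(
            rng.random(n) < 0.6,
            np.maximum(rng.normal(80, 15, n), 20),
            np.maximum(rng.normal(230, 25, n), 20),
        ).astype(int)
        pick = rng.integers(0, len(tss), n_tss)
        mids_tss = tss[pick] + rng.triangular(-1000, 0, 1000, n_tss).astype(int)
        chrom_tss = tss_chrom[pick]
        n_uni = n - n_tss
        mids_uni = rng.integers(1000, chrom_len - 1000, n_uni)
        chrom_uni = np.asarray(chroms)[rng.integers(0, len(chroms), n_uni)]
        mids = np.concatenate([mids_tss, mids_uni])
        chrom = np.concatenate([chrom_tss, chrom_uni])
        start = np.maximum(mids - lengths // 2, 0)
        end = start + lengths
        rows_chrom.append(chrom)
        rows_start.append(start)
        rows_end.append(end)
        rows_bc.extend([cid] * n)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(rows_chrom),
            "start": np.concatenate(rows_start).astype(np.int64),
            "end": np.concatenate(rows_end).astype(np.int64),
            "barcode": rows_bc,
        }
    )


def gen_bulk_timecourse(
    n_regions: int = 600,
    n_modules: int = 6,
    replicates: int = 3,
    seed: int = 0,
    signal_fraction: float = 0.5,
    noise_sd: float = 0.15,
    base_mean: float = 200.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bulk accessibility over 0/48/72/96 h with planted kinetic modules.

    A ``signal_fraction`` share of regions follow one of ``n_modules`` log2
    fold-change shapes (early burst, sustained induction, early loss, ...)
    against a log-normal per-region baseline; the rest are flat nulls.
    Replicate noise is multiplicative log-normal with scale ``noise_sd``
    (0 ⇒ noiseless).  Columns are named ``t{hours}_r{replicate}``.
    """
    if n_modules > 8:
        raise ValueError("n_modules must be <= 8")
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rng = np.random.default_rng(seed)
    shapes = _MODULE_SHAPES[:n_modules]
    n_signal = int(round(signal_fraction * n_regions))
    module_labels = np.full(n_regions, -1)
    if n_signal and n_modules:
        module_labels[:n_signal] = np.arange(n_signal) % n_modules + 1
    rng.shuffle(module_labels)
    base = rng.lognormal(np.log(base_mean), 0.7, n_regions)
    lfc = np.zeros((n_regions, 4))
    for m in range(1, n_modules + 1):
        lfc[module_labels == m] = shapes[m - 1]
    cols, data = [], []
    for ti, t in enumerate(TIME_POINTS_H):
        for r in range(1, replicates + 1):
            cols.append(f"t{t}_r{r}")
            noise = np.exp(rng.normal(0.0, noise_sd, n_regions)) if noise_sd > 0 else 1.0
            data.append(base * 2.0 ** lfc[:, ti] * noise)
    table = pd.DataFrame(
        np.column_stack(data),
        index=[f"region{i + 1:05d}" for i in range(n_regions)],
        columns=cols,
    )
    truth = SyntheticTruth(
        module_labels=module_labels,
        module_profiles={m: 2.0 ** shapes[m - 1] for m in range(1, n_modules + 1)},
    )
    return table, truth


@dataclass
class ReferenceBundle:
    """Synthetic stand-ins for the external reference resources: zonation
    layer profiles, cell-type marker sets and expression profiles, PWMs and
    promoter sequences with known motif placements."""

    zonal_profile: pd.DataFrame  # layers L1..Ln x genes mean expression
    marker_sets: dict  # cell type -> SignatureSet
    celltype_profiles: pd.DataFrame  # genes x cell types
    pwms: dict  # tf -> PWM
    promoters: dict  # gene_id -> sequence
    truth: SyntheticTruth


def gen_reference_profiles(
    n_layers: int = 9,
    seed: int = 0,
    n_zonation_genes: int = 89,
    regulon_map: dict | None = None,
    promoter_genes=None,
    markers_per_type: int = 30,
    pwm_length: int = 8,
    promoter_length: int = 600,
) -> ReferenceBundle:
    """Synthetic references: an 89-gene zonation panel with smooth monotone or
    unimodal layer profiles over L1..L9 (L1 = central, L9 = portal), disjoint
    hepatocyte/Kupffer/endothelial marker sets with matching expression
    profiles for deconvolution, and one PWM per TF with its consensus embedded
    at a recorded offset in each true target's promoter."""
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    rng = np.random.default_rng(seed)
    layer_frac = np.linspace(0.0, 1.0, n_layers)
    profiles = {}
    for j in range(n_zonation_genes):
        name = f"zon{j + 1:03d}"
        kind = j % 4
        amp = rng.uniform(2.0, 6.0)
        base = rng.uniform(1.0, 3.0)
        if kind == 0:  # monotone portal-increasing
            prof = base + amp * layer_frac
        elif kind == 1:  # monotone central-increasing
            prof = base + amp * (1.0 - layer_frac)
        else:  # unimodal bump at a random interior layer
            center = rng.uniform(0.25, 0.75)
            prof = base + amp * np.exp(-(((layer_frac - center) / 0.2) ** 2))
        profiles[name] = prof
    zonal = pd.DataFrame(profiles, index=[f"L{i + 1}" for i in range(n_layers)])

    types = ["hepatocyte", "kupffer", "endothelial"]
    marker_sets = {}
    all_markers = []
    for k, t in enumerate(types):
        genes = [f"{t[:3]}{j + 1:03d}" for j in range(markers_per_type)]
        marker_sets[t] = SignatureSet(name=t, genes=genes)
        all_markers.append(genes)
    genes_flat = [g for gl in all_markers for g in gl]
    prof = pd.DataFrame(1.0, index=genes_flat, columns=types)
    for k, t in enumerate(types):
        prof.loc[all_markers[k], t] = rng.lognormal(np.log(25.0), 0.3, markers_per_type)

    if regulon_map is None:
        regulon_map = {
            f"tf{i + 1:02d}": frozenset(f"g{i * 10 + j + 1:04d}" for j in range(10))
            for i in range(5)
        }
    pwms = {}
    for tf in sorted(regulon_map):
        mat = np.full((4, pwm_length), 0.02)
        consensus = rng.integers(0, 4, pwm_length)
        mat[consensus, np.arange(pwm_length)] = 0.94
        pwms[tf] = PWM(motif_id=tf, matrix=mat)
    if promoter_genes is None:
        promoter_genes = sorted(
            {g for ts in regulon_map.values() for g in ts} | set(regulon_map)
        )
    bases = np.array(list("ACGT"))
    promoters = {}
    placements = []
    target_of = {g: tf for tf, ts in regulon_map.items() for g in ts}
    for gid in promoter_genes:
        seq = bases[rng.integers(0, 4, promoter_length)]
        tf = target_of.get(gid)
        if tf is not None:
            offset = int(rng.integers(0, promoter_length - pwm_length))
            seq[offset : offset + pwm_length] = list(pwms[tf].consensus)
            placements.append((gid, tf, offset))
        promoters[gid] = "".join(seq)

    truth = SyntheticTruth(
        regulon_map={tf: frozenset(ts) for tf, ts in regulon_map.items()},
        motif_placements=placements,
    )
    return ReferenceBundle(zonal, marker_sets, prof, pwms, promoters, truth)


def gen_bulk_mixtures(
    celltype_profiles: pd.DataFrame,
    n_samples: int = 3,
    seed: int = 0,
    noise_sd: float = 0.05,
    dirichlet_alpha=(20.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Bulk expression as noisy linear mixtures of the cell-type profiles.

    The default Dirichlet concentrations emulate a hepatocyte-dominated
    preparation.  Noise is multiplicative log-normal of scale ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if len(alpha) != celltype_profiles.shape[1]:
        raise ValueError("dirichlet_alpha length must match number of cell types")
    fractions = rng.dirichlet(alpha, n_samples)
    mix = fractions @ celltype_profiles.to_numpy().T
    if noise_sd > 0:
        mix = mix * np.exp(rng.normal(0.0, noise_sd, mix.shape))
    bulk = pd.DataFrame(
        mix.T,
        index=celltype_profiles.index,
        columns=[f"sample{i + 1}" for i in range(n_samples)],
    )
    return bulk, SyntheticTruth(mixing_fractions=fractions)


def gen_trajectory(
    n_cells: int = 300,
    n_genes: int = 50,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Cells along a smooth 1-D path in gene space with forward velocities.

    Returns (expression, velocity, truth) where ``truth.trajectory_order`` is
    the planted progression in [0, 1] and each cell's velocity is the path
    tangent at its position.
    """
    rng = np.random.default_rng(seed)
    order = rng.uniform(0.0, 1.0, n_cells)
    freq = rng.uniform(0.5, 1.5, n_genes)
    phase = rng.uniform(0.0, 2 * np.pi, n_genes)
    amp = rng.uniform(1.0, 3.0, n_genes)
    t = order[:, None]
    x = amp * np.sin(np.pi * freq * t + phase)
    v = amp * np.pi * freq * np.cos(np.pi * freq * t + phase)
    x = x + rng.normal(0.0, noise_sd, x.shape)
    return x, v, SyntheticTruth(trajectory_order=order)


def write_bundle(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Generate and write a full synthetic dataset from a YAML config.

    Config keys mirror the generator signatures (``rna``, ``atac``, ``bulk``,
    ``references`` sub-dicts plus a global ``seed``); outputs are MTX triplets,
    BED peak/fragment files and TSV tables under ``out_dir``, with the seed and
    parameters recorded in ``provenance.json``.  Returns the path map.
    """
    import yaml

    from . import io_qc

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "synthetic_dataset"))
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    rna, rna_truth = gen_rna_counts(seed=seed, **config.get("rna", {}))
    io_qc.write_mtx(rna, out / "rna")
    paths["rna"] = str(out / "rna")

    genome = gen_genome(
        rna.shape[1], gene_ids=list(rna.var_names), seed=seed, **config.get("genome", {})
    )
    genome.to_csv(out / "genes.tsv", sep="\t", index=False)
    paths["genes"] = str(out / "genes.tsv")

    atac, fragments, _ = gen_atac_data(
        genome=genome, regulons=rna_truth.regulon_map, seed=seed, **config.get("atac", {})
    )
    io_qc.write_mtx(atac, out / "atac")
    peaks = atac.var.reset_index().rename(columns={"index": "peak_id"})
    io_qc.write_bed(peaks, out / "peaks.bed")
    paths["atac"] = str(out / "atac")
    if fragments is not None:
        io_qc.write_bed(fragments, out / "fragments.bed")
        paths["fragments"] = str(out / "fragments.bed")

    bulk, _ = gen_bulk_timecourse(seed=seed, **config.get("bulk", {}))
    bulk.to_csv(out / "bulk_timecourse.tsv", sep="\t")
    paths["bulk_timecourse"] = str(out / "bulk_timecourse.tsv")

    refs = gen_reference_profiles(seed=seed, regulon_map=rna_truth.regulon_map,
                                  **config.get("references", {}))
    refs.zonal_profile.to_csv(out / "zonal_profile.tsv", sep="\t")
    paths["zonal_profile"] = str(out / "zonal_profile.tsv")

    with open(out / "provenance.json", "w") as fh:
        json.dump({"seed": seed, "config": {k: v for k, v in config.items()}}, fh, indent=2)
    paths["provenance"] = str(out / "provenance.json")
    return paths
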