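"""Core data containers shared across the pipeline.

Expression and accessibility matrices are carried as :class:`anndata.AnnData`
objects in the cells x features orientation (scanpy convention): ``obs`` holds
per-cell metadata, ``var`` per-feature metadata, ``layers`` optional same-shape
matrices such as spliced/unspliced counts.  The light dataclasses below hold
derived results (clusters, regulons, topic models, ...).

Genomic intervals are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData


class FormatError(ValueError):
    """A file or table violates the expected on-disk format."""


def make_count_matrix(
    values,
    cell_ids,
    feature_ids,
    layers: dict | None = None,
    cell_meta: pd.DataFrame | None = None,
) -> AnnData:
    """Assemble a validated cells x features count matrix.

    ``total_counts`` and ``n_features`` in ``obs`` are always recomputed from
    the matrix rather than trusted from ``cell_meta``.
    """
    values = sp.csr_matrix(values)
    if values.nnz and values.data.min() < 0:
        raise ValueError("counts must be non-negative")
    cell_ids = pd.Index(np.asarray(cell_ids, dtype=object), name="cell_id")
    feature_ids = pd.Index(np.asarray(feature_ids, dtype=object), name="feature_id")
    if cell_ids.has_duplicates:
        raise ValueError("duplicate cell_ids")
    if feature_ids.has_duplicates:
        raise ValueError("duplicate feature_ids")
    if values.shape != (len(cell_ids), len(feature_ids)):
        raise FormatError(
            f"matrix shape {values.shape} does not match "
            f"{len(cell_ids)} cells x {len(feature_ids)} features"
        )
    obs = pd.DataFrame(index=cell_ids)
    if cell_meta is not None:
        meta = cell_meta.copy()
        if len(meta) != len(cell_ids):
            raise FormatError("cell_meta row count does not match cell count")
        meta.index = cell_ids
        obs = meta
    totals = np.asarray(values.sum(axis=1)).ravel()
    obs["total_counts"] = totals
    obs["n_features"] = np.asarray((values > 0).sum(axis=1)).ravel()
    adata = AnnData(X=values, obs=obs, var=pd.DataFrame(index=feature_ids))
    for name, layer in (layers or {}).items():
        layer = sp.csr_matrix(layer)
        if layer.shape != values.shape:
            raise FormatError(f"layer {name!r} shape mismatch")
        adata.layers[name] = layer
    return adata


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a peak table (chrom, start, end, peak_id)."""
    required = {"chrom", "start", "end", "peak_id"}
    missing = required - set(peaks.columns)
    if missing:
        raise FormatError(f"peak table missing columns: {sorted(missing)}")
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks.index[peaks["start"] >= peaks["end"]][0]
        raise FormatError(f"peak {bad}: start >= end")
    if peaks["peak_id"].duplicated().any():
        raise ValueError("duplicate peak_id")
    return peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def make_peak_matrix(
    counts,
    peaks: pd.DataFrame,
    cell_ids,
    cell_meta: pd.DataFrame | None = None,
) -> AnnData:
    """Assemble a cells x peaks accessibility matrix.

    ``peaks`` columns (chrom, start, end, peak_id) become ``var``; peak order in
    the matrix must match the row order of ``peaks``.
    """
    counts = sp.csr_matrix(counts)
    var = peaks.set_index("peak_id")[["chrom", "start", "end"]]
    adata = make_count_matrix(counts, cell_ids, var.index, cell_meta=cell_meta)
    adata.var = var
    return adata


def make_genome_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table and derive the TSS column.

    TSS is the start for + strand genes and the end for - strand genes
    (half-open convention: the end coordinate is the first base past the gene).
    """
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    if (genes["start"] >= genes["end"]).any():
        raise FormatError("gene with start >= end")
    if not genes["strand"].isin(["+", "-"]).all():
        raise FormatError("strand must be '+' or '-'")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id")
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return genes.reset_index(drop=True)


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T with a background simplex."""

    motif_id: str
    matrix: np.ndarray  # 4 x L probabilities, rows in ACGT order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass
class SignatureSet:
    """A named gene (or peak) set, optionally directional."""

    name: str
    genes: frozenset
    direction: str | None = None  # "up" | "down" | None

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")


@dataclass
class ClusterResult:
    """Per-cell community labels plus the embedding they were computed on."""

    labels: np.ndarray  # int labels, contiguous from 1
    embedding: np.ndarray | None
    resolution: float
    seed: int
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("cluster labels must be contiguous from 1")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class Regulon:
    """A TF with its motif-supported targets and per-target provenance."""

    tf: str
    targets: tuple
    importance: dict = field(default_factory=dict)  # target -> GRN importance
    motif_score: dict = field(default_factory=dict)  # target -> best promoter hit

    @property
    def genes(self) -> tuple:
        """TF plus targets — the gene set scored as regulon activity."""
        return (self.tf,) + tuple(self.targets)


@dataclass
class TopicModel:
    """Fitted LDA over a binarized accessibility matrix."""

    n_topics: int
    phi: np.ndarray  # topics x regions, rows sum to 1
    theta: np.ndarray  # cells x topics, rows sum to 1
    alpha: float
    beta: float
    log_likelihood: np.ndarray
    seed: int
    region_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self):
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("theta rows must sum to 1")


@dataclass
class DAResult:
    """Per-region differential-accessibility statistics."""

    table: pd.DataFrame  # log2_fold_change, p_value, p_adjusted, direction

    def __post_init__(self):
        t = self.table
        if (t["p_adjusted"] < t["p_value"] - 1e-12).any():
            raise ValueError("adjusted p below raw p")

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted by the generators, consumed by tests."""

    cluster_labels: np.ndarray | None = None
    regulon_map: dict | None = None  # tf -> frozenset of target genes
    zonation_coord: np.ndarray | None = None
    gamma_true: np.ndarray | None = None
    topic_assignments: np.ndarray | None = None  # per-region dominant topic
    module_profiles: dict | None = None  # module id -> 4-vector over time
    module_labels: np.ndarray | None = None  # per-region module id (-1 = null)
    mixing_fractions: np.ndarray | None = None  # samples x cell types, rows sum 1
    motif_placements: list | None = None  # (promoter id, pwm id, offset)
    atac_cluster_labels: np.ndarray | None = None
    state_of_atac_cluster: dict | None = None  # atac cluster id -> planted RNA state
    tf_of_cluster: dict | None = None  # cluster id -> its defining TF
    trajectory_order: np.ndarray | None = None  # per-cell planted pseudotime
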