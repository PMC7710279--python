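"""Readers/writers for the standard on-disk formats and cell/nucleus QC.

Matrices travel as MTX triplets (matrix.mtx + features.tsv + barcodes.tsv,
with extra ``<layer>.mtx`` files for spliced/unspliced layers and an optional
cell_meta.tsv); genomic intervals as BED (0-based half-open); fragment records
as 4-column BED-like tables with the cell barcode in column 4.

QC follows the study design: RNA cells are filtered on mitochondrial fraction
and detected-feature count, ATAC nuclei on TSS enrichment and fragment count.
The numeric cutoffs are package defaults (``max_mito_fraction`` 0.2,
``min_features`` 200, ``min_tss_score`` 4, ``min_fragments`` 1000): the
criteria are standard, the exact values a practitioner's choice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .containers import FormatError, make_count_matrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers


def write_mtx(adata: AnnData, dir_path) -> None:
    """Write a cells x features matrix as an MTX triplet (plus layers).

    The MTX files are features x cells on disk (CellRanger convention).
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.csr_matrix(adata.X).T)
    for name, layer in adata.layers.items():
        scipy.io.mmwrite(str(d / f"{name}.mtx"), sp.csr_matrix(layer).T)
    adata.var.reset_index().to_csv(d / "features.tsv", sep="\t", index=False, header=True)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        d / "barcodes.tsv", sep="\t", index=False, header=True
    )
    meta_cols = [c for c in adata.obs.columns if c not in ("total_counts", "n_features")]
    if meta_cols:
        adata.obs[meta_cols].to_csv(d / "cell_meta.tsv", sep="\t", index=True)


def read_mtx(dir_path) -> AnnData:
    """Read an MTX triplet directory back into a cells x features AnnData.

    Any ``<name>.mtx`` beside matrix.mtx becomes a layer; cell_meta.tsv, if
    present, populates ``obs``.  Dimension mismatches raise
    :class:`FormatError` naming the offending file.
    """
    d = Path(dir_path)
    for required in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / required).exists():
            raise FormatError(f"missing file: {d / required}")
    x = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx"))).T
    features = pd.read_csv(d / "features.tsv", sep="\t")
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t")["barcode"].astype(str)
    if len(features) != x.shape[1]:
        raise FormatError(f"features.tsv has {len(features)} rows, matrix has {x.shape[1]}")
    if len(barcodes) != x.shape[0]:
        raise FormatError(f"barcodes.tsv has {len(barcodes)} rows, matrix has {x.shape[0]}")
    layers = {}
    for f in sorted(d.glob("*.mtx")):
        if f.name == "matrix.mtx":
            continue
        layer = sp.csr_matrix(scipy.io.mmread(str(f))).T
        if layer.shape != x.shape:
            raise FormatError(f"layer file {f.name} shape mismatch")
        layers[f.stem] = layer
    meta = None
    if (d / "cell_meta.tsv").exists():
        meta = pd.read_csv(d / "cell_meta.tsv", sep="\t", index_col=0)
        if len(meta) != x.shape[0]:
            raise FormatError("cell_meta.tsv row count does not match barcodes")
    id_col = features.columns[0]
    adata = make_count_matrix(x, barcodes, features[id_col].astype(str), layers, meta)
    for c in features.columns[1:]:
        adata.var[c] = features[c].to_numpy()
    return adata


def read_bed(path) -> pd.DataFrame:
    """Read a BED(-like) file: peaks (3-4 cols) or fragments (4th = barcode).

    Returns a sorted peak table with ``peak_id`` (generated when absent), or a
    fragment table (chrom/start/end/barcode) when column 4 looks like a
    barcode rather than an id.  Intervals must satisfy start < end.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{ln}: start >= end")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if df["name"].notna().any() and df["name"].duplicated().any():
        # repeated names across intervals = per-cell barcodes → fragments
        return df.rename(columns={"name": "barcode"})
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if df["name"].isna().all():
        df["name"] = [f"peak{i + 1:05d}" for i in range(len(df))]
    return df.rename(columns={"name": "peak_id"})


def write_bed(table: pd.DataFrame, path) -> None:
    """Write peaks or fragments as BED; extra column is peak_id or barcode."""
    cols = ["chrom", "start", "end"]
    extra = next((c for c in ("peak_id", "barcode", "name") if c in table.columns), None)
    out = table[cols + ([extra] if extra else [])]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC filters


def filter_cells_rna(
    adata: AnnData,
    max_mito_fraction: float = 0.2,
    min_features: int = 200,
    min_cells_per_feature: int = 3,
) -> AnnData:
    """Drop high-mitochondrial cells, low-complexity cells and rare features.

    ``mito_fraction`` is taken from ``obs`` when present, otherwise computed
    from features prefixed ``mt-``.  Per-rule removal counts go to
    ``uns['qc_report']``; removing every cell logs an explicit warning rather
    than failing silently.  Retained cells and features keep their order, and
    the filter is idempotent.
    """
    if not 0 <= max_mito_fraction <= 1:
        raise ValueError("max_mito_fraction must be in [0, 1]")
    if "mito_fraction" in adata.obs:
        mito = adata.obs["mito_fraction"].to_numpy()
    else:
        mt = adata.var_names.str.lower().str.startswith("mt-")
        totals = np.maximum(adata.obs["total_counts"].to_numpy(), 1)
        mito = np.asarray(adata[:, mt].X.sum(axis=1)).ravel() / totals
    n_feat = np.asarray((adata.X > 0).sum(axis=1)).ravel()
    keep_mito = mito <= max_mito_fraction
    keep_feat = n_feat >= min_features
    keep = keep_mito & keep_feat
    report = {
        "removed_high_mito": int((~keep_mito).sum()),
        "removed_low_features": int((~keep_feat & keep_mito).sum()),
        "cells_retained": int(keep.sum()),
    }
    if not keep.any():
        log.warning("filter_cells_rna removed every cell (%s)", report)
    sub = adata[keep].copy()
    cells_per_feature = np.asarray((sub.X > 0).sum(axis=0)).ravel()
    keep_f = cells_per_feature >= min(min_cells_per_feature, max(len(sub), 1))
    report["features_removed"] = int((~keep_f).sum())
    sub = sub[:, keep_f].copy()
    sub.obs["total_counts"] = np.asarray(sub.X.sum(axis=1)).ravel()
    sub.obs["n_features"] = np.asarray((sub.X > 0).sum(axis=1)).ravel()
    sub.uns["qc_report"] = report
    return sub


def tss_enrichment(
    fragments: pd.DataFrame,
    genome: pd.DataFrame,
    flank: int = 2000,
    center: int = 50,
) -> pd.DataFrame:
    """Per-cell TSS enrichment: center insertion depth over flank depth.

    Both endpoints of each fragment count as Tn5 insertions.  For each cell
    the score is the mean per-bp insertion depth within ±``center`` of any
    TSS divided by the mean depth in the outermost 100 bp of the ±``flank``
    window.  Cells with zero flank signal (or no fragments) score 0 and are
    flagged.
    """
    if len(genome) == 0:
        raise ValueError("annotation has no TSS")
    tss_by_chrom = {c: g["tss"].to_numpy() for c, g in genome.groupby("chrom")}
    barcodes = pd.unique(fragments["barcode"])
    center_counts = pd.Series(0.0, index=barcodes)
    flank_counts = pd.Series(0.0, index=barcodes)
    for chrom, chunk in fragments.groupby("chrom"):
        tss = np.sort(tss_by_chrom.get(chrom, np.array([])))
        if len(tss) == 0:
            continue
        ins = np.concatenate([chunk["start"].to_numpy(), chunk["end"].to_numpy() - 1])
        bc = np.concatenate([chunk["barcode"].to_numpy()] * 2)
        j = np.searchsorted(tss, ins)
        left = tss[np.clip(j - 1, 0, len(tss) - 1)]
        right = tss[np.clip(j, 0, len(tss) - 1)]
        dist = np.minimum(np.abs(ins - left), np.abs(ins - right))
        in_center = dist <= center
        in_flank = (dist <= flank) & (dist > flank - 100)
        center_counts = center_counts.add(
            pd.Series(bc[in_center]).value_counts().astype(float), fill_value=0.0
        )
        flank_counts = flank_counts.add(
            pd.Series(bc[in_flank]).value_counts().astype(float), fill_value=0.0
        )
    center_depth = center_counts / (2 * center + 1)
    flank_depth = flank_counts / 200.0
    score = np.where(flank_depth > 0, center_depth / np.maximum(flank_depth, 1e-300), 0.0)
    n_frags = fragments["barcode"].value_counts()
    return pd.DataFrame(
        {
            "tss_score": score,
            "n_fragments": n_frags.reindex(barcodes).fillna(0).astype(int),
            "flagged": flank_depth.to_numpy() == 0,
        },
        index=pd.Index(barcodes, name="barcode"),
    )


def filter_nuclei_atac(
    pmat: AnnData,
    qc: pd.DataFrame,
    min_tss_score: float = 4.0,
    min_fragments: int = 1000,
) -> AnnData:
    """Keep nuclei passing both the TSS-enrichment and fragment-count bars.

    ``qc`` is the table from :func:`tss_enrichment`.  Nuclei absent from the
    QC table fail both rules.  Per-rule removals are logged and recorded in
    ``uns['qc_report']``; the filter is idempotent and order-preserving.
    """
    qc = qc.reindex(pmat.obs_names)
    tss = qc["tss_score"].fillna(0.0).to_numpy()
    nfr = qc["n_fragments"].fillna(0).to_numpy()
    keep_tss = tss >= min_tss_score
    keep_frag = nfr >= min_fragments
    keep = keep_tss & keep_frag
    report = {
        "removed_low_tss": int((~keep_tss).sum()),
        "removed_low_fragments": int((~keep_frag & keep_tss).sum()),
        "cells_retained": int(keep.sum()),
    }
    if not keep.any():
        log.warning("filter_nuclei_atac removed every nucleus (%s)", report)
    sub = pmat[keep].copy()
    sub.obs["tss_score"] = tss[keep]
    sub.obs["n_fragments"] = nfr[keep]
    sub.uns["qc_report"] = report
    return sub


def fragment_size_histogram(fragments: pd.DataFrame, max_len: int = 1000) -> np.ndarray:
    """Counts of fragment lengths 1..max_len (index 0 unused, kept at 0)."""
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("fragment with end <= start")
    lengths = lengths.astype(np.int64)
    hist = np.bincount(lengths[lengths <= max_len], minlength=max_len + 1)
    if len(hist) > max_len + 1:
        hist = hist[: max_len + 1]
    return hist
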