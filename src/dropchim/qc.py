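"""Cell- and gene-level quality filtering.

Stage order is fixed: compute_qc -> mad_outliers -> hard_filters -> (on
surviving cells) filter_genes -> drop_gene_families. QC metrics are computed
once on all cells, before any removal, so the MAD statistics refer to the
full population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CountMatrix, PROTECTED_GENES, StageLog

MITO_CAP_PCT = 20.0
RIBO_CAP_PCT = 50.0
MAD_K = 3.0
MIN_CELL_FRACTION = 0.01

QC_METRICS = ("library_size", "n_genes", "pct_mito", "pct_ribo")


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    family: str  # mitochondrial | ribosomal_protein | other


def classify_gene(name: str) -> str:
    """Family from name prefix; sex/marker genes are always 'other'."""
    if name in PROTECTED_GENES:
        return "other"
    if name.startswith("MT-"):
        return "mitochondrial"
    if name.startswith(("RPS", "RPL")):
        return "ribosomal_protein"
    return "other"


def annotate_genes(genes: list[str]) -> list[GeneAnnotation]:
    return [GeneAnnotation(g, classify_gene(g)) for g in genes]


def compute_qc(matrix: CountMatrix, annotation: list[GeneAnnotation] | None = None) -> pd.DataFrame:
    """Per-barcode library size, genes detected, % mitochondrial, % ribosomal."""
    if annotation is None:
        annotation = annotate_genes(matrix.genes)
    fam = {a.gene: a.family for a in annotation}
    missing = [g for g in matrix.genes if g not in fam]
    if missing:
        raise ValueError(f"annotation missing genes: {missing[:5]}")
    lib = matrix.library_sizes().astype(float)
    n_genes = np.asarray((matrix.matrix > 0).sum(axis=0)).ravel()
    mito = np.array([fam[g] == "mitochondrial" for g in matrix.genes])
    ribo = np.array([fam[g] == "ribosomal_protein" for g in matrix.genes])
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(
            lib > 0, 100.0 * np.asarray(matrix.matrix[mito].sum(axis=0)).ravel() / lib, 0.0
        ) if mito.any() else np.zeros_like(lib)
        pct_ribo = np.where(
            lib > 0, 100.0 * np.asarray(matrix.matrix[ribo].sum(axis=0)).ravel() / lib, 0.0
        ) if ribo.any() else np.zeros_like(lib)
    return pd.DataFrame(
        {
            "library_size": lib,
            "n_genes": n_genes.astype(float),
            "pct_mito": pct_mito,
            "pct_ribo": pct_ribo,
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


def mad_outliers(metrics: pd.DataFrame, k: float = MAD_K, one_sided: bool = False) -> pd.Series:
    """Flag cells deviating from the per-metric median by more than k raw MADs
    on ANY of the four metrics. ``one_sided=True`` flags high values only."""
    if len(metrics) < 2:
        raise ValueError("mad_outliers requires at least 2 cells")
    flags = pd.Series(False, index=metrics.index)
    for col in QC_METRICS:
        x = metrics[col].to_numpy(dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        dev = (x - med) if one_sided else np.abs(x - med)
        flags |= pd.Series(dev > k * mad, index=metrics.index)
    return flags


def hard_filters(
    metrics: pd.DataFrame, mito_cap: float = MITO_CAP_PCT, ribo_cap: float = RIBO_CAP_PCT
) -> pd.Series:
    """Flag cells with pct_mito > 20 or pct_ribo > 50 (strict inequalities)."""
    return (metrics["pct_mito"] > mito_cap) | (metrics["pct_ribo"] > ribo_cap)


def filter_genes(matrix: CountMatrix, min_cell_fraction: float = MIN_CELL_FRACTION) -> CountMatrix:
    """Drop genes detected (count > 0) in strictly less than min_cell_fraction
    of all cells."""
    if matrix.n_barcodes < 1:
        raise ValueError("matrix has no cells")
    detected = np.asarray((matrix.matrix > 0).sum(axis=1)).ravel() / matrix.n_barcodes
    keep = np.flatnonzero(detected >= min_cell_fraction)
    return matrix.subset_genes(keep)


def drop_gene_families(
    matrix: CountMatrix, annotation: list[GeneAnnotation] | None = None
) -> CountMatrix:
    """Discard mitochondrial and ribosomal-protein genes (sex transcripts and
    macrophage markers are never family-flagged, hence never dropped)."""
    if annotation is None:
        annotation = annotate_genes(matrix.genes)
    fam = {a.gene: a.family for a in annotation}
    missing = [g for g in matrix.genes if g not in fam]
    if missing:
        raise ValueError(f"annotation missing genes: {missing[:5]}")
    keep = [i for i, g in enumerate(matrix.genes) if fam[g] == "other"]
    return matrix.subset_genes(keep)


def apply_qc(
    matrix: CountMatrix,
    mad_k: float = MAD_K,
    one_sided_mad: bool = False,
    mito_cap: float = MITO_CAP_PCT,
    ribo_cap: float = RIBO_CAP_PCT,
    min_cell_fraction: float = MIN_CELL_FRACTION,
    sample_id: str | None = None,
) -> tuple[CountMatrix, pd.DataFrame, list[StageLog]]:
    """Run the full QC chain, logging cells/genes surviving each stage."""
    annotation = annotate_genes(matrix.genes)
    metrics = compute_qc(matrix, annotation)
    logs: list[StageLog] = []

    mad_flags = mad_outliers(metrics, k=mad_k, one_sided=one_sided_mad)
    kept = matrix.subset_barcodes(np.flatnonzero(~mad_flags.to_numpy()))
    logs.append(
        StageLog(
            "qc_mad_outliers", matrix.n_barcodes, kept.n_barcodes,
            {"k": mad_k, "one_sided": one_sided_mad}, sample_id,
        )
    )

    hard_flags = hard_filters(metrics.loc[kept.barcodes], mito_cap, ribo_cap)
    kept2 = kept.subset_barcodes(np.flatnonzero(~hard_flags.to_numpy()))
    logs.append(
        StageLog(
            "qc_hard_filters", kept.n_barcodes, kept2.n_barcodes,
            {"mito_cap": mito_cap, "ribo_cap": ribo_cap}, sample_id,
        )
    )

    kept3 = filter_genes(kept2, min_cell_fraction)
    logs.append(
        StageLog(
            "qc_filter_genes", kept2.n_genes, kept3.n_genes,
            {"min_cell_fraction": min_cell_fraction}, sample_id,
        )
    )

    kept4 = drop_gene_families(kept3, annotate_genes(kept3.genes))
    logs.append(
        StageLog("qc_drop_gene_families", kept3.n_genes, kept4.n_genes, {}, sample_id)
    )
    return kept4, metrics, logs
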