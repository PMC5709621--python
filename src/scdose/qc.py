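"""Detection-rate filtering, outlier-cell removal, CPM normalization.

The quality-control convention: a cell's detection rate is the share of
genes observed (count > 0) in it, a gene's detection rate the share of
cells in which it is observed.  Both are thresholded at the same level
(default 5%).  Cells are filtered first, then gene rates are recomputed
on the surviving cells and genes filtered once — no iteration to a
fixpoint unless requested.  A rate exactly equal to the threshold is
retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import CountMatrix

logger = logging.getLogger("scdose")


@dataclass
class DetectionRates:
    """Per-cell and per-gene detection rates, computed on raw counts."""

    cell_rate: np.ndarray       # share of genes with count > 0, per cell
    gene_rate: np.ndarray       # share of cells with count > 0, per gene
    cell_ids: list
    gene_ids: list


@dataclass
class NormalizedMatrix:
    """Counts-per-million matrix with provenance of the scaling."""

    values: np.ndarray          # genes x cells, float CPM
    gene_ids: list
    cell_ids: list
    scale: float
    original_totals: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def round_to_counts(self) -> CountMatrix:
        """Round (half-to-even) to integers for count-model fitting."""
        return CountMatrix(np.rint(self.values).astype(np.int64),
                           self.gene_ids, self.cell_ids)


def compute_detection_rates(cm: CountMatrix) -> DetectionRates:
    if cm.n_genes == 0 or cm.n_cells == 0:
        raise ValueError("empty count matrix")
    detected = cm.values > 0
    return DetectionRates(
        cell_rate=detected.mean(axis=0),
        gene_rate=detected.mean(axis=1),
        cell_ids=list(cm.cell_ids),
        gene_ids=list(cm.gene_ids),
    )


def filter_by_detection(cm: CountMatrix, threshold: float,
                        iterate: bool = False) -> CountMatrix:
    """Drop cells, then genes, whose detection rate falls below ``threshold``.

    Gene rates are recomputed on surviving cells before the gene pass.
    Survivors keep their original order.  With ``iterate=True`` the two
    passes repeat until no further removal (rarely needed).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    current = cm
    while True:
        rates = compute_detection_rates(current)
        cell_keep = rates.cell_rate >= threshold
        if not cell_keep.any():
            raise ValueError("all cells removed by detection filter")
        current = current.subset(cell_mask=cell_keep)
        gene_rate = (current.values > 0).mean(axis=1)
        gene_keep = gene_rate >= threshold
        if not gene_keep.any():
            raise ValueError("all genes removed by detection filter")
        current = current.subset(gene_mask=gene_keep)
        if not iterate or (cell_keep.all() and gene_keep.all()):
            break
    logger.info("detection filter: %d/%d genes, %d/%d cells retained",
                current.n_genes, cm.n_genes, current.n_cells, cm.n_cells)
    return current


def flag_outlier_cells(cm: CountMatrix,
                       max_gene_fraction: float = 0.10) -> list:
    """Cells in which any single gene exceeds ``max_gene_fraction`` of the
    cell's total reads — the operational rule for amplification (PCR-bias)
    outliers with extreme counts concentrated in few genes.

    Returns ids sorted lexicographically; may be empty.
    """
    if cm.n_cells < 5:
        raise ValueError("outlier flagging needs at least 5 cells")
    totals = cm.values.sum(axis=0)
    flagged = []
    for j, cell in enumerate(cm.cell_ids):
        if totals[j] == 0:
            continue
        if cm.values[:, j].max() / totals[j] > max_gene_fraction:
            flagged.append(cell)
    return sorted(flagged)


def normalize_cpm(cm: CountMatrix, cpm_scale: float = 1_000_000.0) -> NormalizedMatrix:
    """Scale each cell to a common total of ``cpm_scale`` reads."""
    if cpm_scale <= 0:
        raise ValueError("cpm_scale must be > 0")
    totals = cm.values.sum(axis=0).astype(float)
    if np.any(totals == 0):
        zero = [c for c, t in zip(cm.cell_ids, totals) if t == 0]
        raise ValueError(
            f"all-zero cells {zero[:5]}: run the detection filter first")
    values = cm.values / totals[None, :] * cpm_scale
    return NormalizedMatrix(values=values, gene_ids=list(cm.gene_ids),
                            cell_ids=list(cm.cell_ids), scale=float(cpm_scale),
                            original_totals=totals)
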