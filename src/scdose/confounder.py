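"""Latent-factor correction of batch / cell-cycle confounding.

Single-cell experiments often confound treatment with batch and cell-cycle
stage.  The approach here estimates one (or a few) latent factors from the
expression of cell-cycle-annotated genes only, after projecting out the
protected treatment covariates, and then removes the factor's contribution
from every gene.  Because the factor is estimated from residuals it is
orthogonal to the treatment design by construction, so regressing it out
cannot alter treatment-group means on the log scale: the treatment signal
is mathematically protected.

This is a deliberate linear, single-axis surrogate for Gaussian-process
latent-variable approaches: the dominant cell-cycle/batch axis is what the
correction targets, and a linear factor keeps every property of the
correction testable.

All fitting happens on log2(CPM + 1); the corrected matrix is transformed
back by ``2**x - 1`` and clipped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bpglm import DesignMatrix
from .qc import NormalizedMatrix

logger = logging.getLogger("scdose")


@dataclass
class CellCycleGeneSet:
    """A cell-cycle gene-symbol list and its intersection with a matrix."""

    gene_ids: tuple            # the full fixture
    matched: tuple             # intersection with the analyzed matrix, matrix order

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @classmethod
    def from_ids(cls, fixture_ids, matrix_gene_ids) -> "CellCycleGeneSet":
        fixture = tuple(dict.fromkeys(str(g) for g in fixture_ids))
        fset = set(fixture)
        matched = tuple(g for g in matrix_gene_ids if g in fset)
        if not matched:
            raise ValueError("no cell-cycle genes matched the matrix "
                             "(gene-id matching is case-sensitive)")
        return cls(gene_ids=fixture, matched=matched)


def load_cell_cycle_genes(path, matrix_gene_ids) -> CellCycleGeneSet:
    """Load a one-symbol-per-line gene list and intersect it with the matrix.

    Matching is case-sensitive exact string equality on gene ids.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [ln for ln in lines if ln and not ln.startswith("#")]
    if not symbols:
        raise ValueError(f"{path}: empty cell-cycle gene list")
    return CellCycleGeneSet.from_ids(symbols, matrix_gene_ids)


@dataclass
class LatentFactorModel:
    """Estimated confounding factor(s) with protected-covariate context."""

    factor_scores: np.ndarray        # cells x k, zero mean, unit variance
    gene_loadings: np.ndarray        # cell-cycle genes x k (residual-scale)
    treatment_coefficients: np.ndarray   # cell-cycle genes x p (protected fit)
    fit_diagnostics: dict
    cell_ids: tuple


def log2_cpm(norm: NormalizedMatrix, gene_subset=None) -> np.ndarray:
    """log2(CPM + 1) values, optionally restricted to a gene-id subset."""
    if gene_subset is None:
        return np.log2(norm.values + 1.0)
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [index[g] for g in gene_subset]
    return np.log2(norm.values[rows, :] + 1.0)


def _design_values(design) -> np.ndarray:
    if isinstance(design, DesignMatrix):
        return design.values
    return np.asarray(design, dtype=float)


def fit_latent_factor(log_expression: np.ndarray, treatment_design,
                      n_factors: int = 1) -> LatentFactorModel:
    """Estimate latent confounding factors from cell-cycle gene expression.

    ``log_expression`` is genes x cells on the log2(CPM+1) scale, restricted
    to the matched cell-cycle genes.  Treatment covariates are regressed out
    of every gene first; the factors are the leading right singular vectors
    of the residual matrix, standardized to zero mean and unit variance.
    Residual singular vectors are orthogonal to the protected design span,
    which is what makes the later correction treatment-preserving.
    """
    Y = np.asarray(log_expression, dtype=float)
    X = _design_values(treatment_design)
    n_genes, n_cells = Y.shape
    if n_genes < 5:
        raise ValueError("need at least 5 matched cell-cycle genes")
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    if X.shape[0] != n_cells:
        raise ValueError("design rows do not match cell count")

    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)      # p x genes
    residual = Y - (X @ coef).T
    U, S, Vt = np.linalg.svd(residual, full_matrices=False)
    # absolute floor guards the numerically-zero residual of constant input
    tol = S.max() * 1e-10 + 1e-9 * np.sqrt(residual.size) if S.size else 0.0
    rank = int((S > tol).sum())
    if rank == 0:
        raise ValueError("residual matrix has rank 0: no variation to model")
    k = min(n_factors, rank)
    scores = Vt[:k].T                                   # cells x k
    sd = scores.std(axis=0, ddof=0)
    scores = (scores - scores.mean(axis=0)) / sd
    loadings = (U[:, :k] * S[:k]) / np.sqrt(n_cells)
    share = float((S[:k] ** 2).sum() / (S ** 2).sum())
    logger.info("latent factor fit: %d genes, %d cells, k=%d, "
                "residual variance share %.3f", n_genes, n_cells, k, share)
    return LatentFactorModel(
        factor_scores=scores,
        gene_loadings=loadings,
        treatment_coefficients=coef.T,
        fit_diagnostics={"variance_share": share, "singular_values": S[:k]},
        cell_ids=None,
    )


def regress_out(norm: NormalizedMatrix, model: LatentFactorModel,
                treatment_design) -> NormalizedMatrix:
    """Remove the latent factor's contribution from every gene.

    Per gene, the log2(CPM+1) profile is projected onto the factor scores
    (which are orthogonal to the protected treatment design) and that
    component is subtracted; values are transformed back to the CPM scale
    and clipped at zero.  Group means along the protected design are
    unchanged in log space.
    """
    S = model.factor_scores
    if S.shape[0] != norm.n_cells:
        raise ValueError("model was fitted on a different set of cells")
    X = _design_values(treatment_design)
    if X.shape[0] != norm.n_cells:
        raise ValueError("design rows do not match cell count")
    Y = np.log2(norm.values + 1.0)
    # factor scores are orthogonal to the design span by construction, but
    # re-orthogonalize defensively so protection holds even for user-supplied
    # score vectors
    proj, *_ = np.linalg.lstsq(X, S, rcond=None)
    S = S - X @ proj
    denom = (S * S).sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("degenerate factor scores")
    loadings = Y @ S / denom                     # genes x k
    corrected_log = Y - loadings @ S.T
    values = np.clip(np.exp2(corrected_log) - 1.0, 0.0, None)
    return NormalizedMatrix(values=values, gene_ids=list(norm.gene_ids),
                            cell_ids=list(norm.cell_ids), scale=norm.scale,
                            original_totals=norm.original_totals.copy())


@dataclass
class PCASummary:
    """Principal-component variance shares and per-cell scores."""

    component_variance_fractions: np.ndarray    # percentages, non-increasing
    cell_scores: np.ndarray                     # cells x n_components


def pca_summary(matrix: np.ndarray, n_components: int) -> PCASummary:
    """PCA on cells of a gene-centered log-expression matrix (genes x cells).

    Variance fractions are percentages of total variance; cell scores are
    the projections onto the leading components.
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 cells")
    if n_components > min(Y.shape):
        raise ValueError(
            f"n_components={n_components} exceeds matrix rank bound {min(Y.shape)}")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    total = (S ** 2).sum()
    if total == 0:
        frac = np.zeros(n_components)
    else:
        frac = (S[:n_components] ** 2) / total * 100.0
    scores = Vt[:n_components].T * S[:n_components]
    return PCASummary(component_variance_fractions=frac, cell_scores=scores)
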