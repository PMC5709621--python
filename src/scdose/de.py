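"""Differential-expression designs, Fisher combination, FDR and overlap.

Three designs are supported, mirroring a knockdown-dosage experiment:

``two_group``
    control vs. all knockdown cells; one indicator coefficient, one
    likelihood-ratio p-value per gene.
``three_group``
    control vs. detectable-knockdown vs. undetectable-knockdown; the two
    dosage indicators are tested separately and the p-values combined by
    Fisher's method (chi-squared, 4 df).
``detectable_vs_undetectable``
    knockdown cells only, indicator = zero target expression.

Per-gene q-values are Benjamini-Hochberg; direction comes from the sign
of the knockdown coefficient (the undetectable contrast for the
three-group design), with exact zero ties counted as "down".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

from .bpglm import DesignMatrix, fit_bp_glm, test_coefficient
from .core_io import CellAnnotations, CountMatrix

logger = logging.getLogger("scdose")

LN2 = float(np.log(2.0))
_P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# dosage grouping and designs
# ---------------------------------------------------------------------------

def assign_dosage_groups(counts: CountMatrix, annotations: CellAnnotations,
                         target_gene: str) -> CellAnnotations:
    """Categorize knockdown cells by observed target-gene counts.

    Uses raw (pre-correction) counts: a knockdown cell with zero target
    counts is "undetectable", with any positive count "detectable"; control
    cells are always "SCR".
    """
    try:
        row = counts.gene_index(target_gene)
    except KeyError:
        raise ValueError(f"target gene {target_gene!r} absent from matrix") from None
    ann = annotations.aligned_to(counts.cell_ids)
    target = counts.values[row, :]
    treatment = ann.column("treatment")
    dosage = np.where(treatment == "SCR", "SCR",
                      np.where(target > 0, "detectable", "undetectable"))
    df = ann.frame.copy()
    df["dosage_group"] = dosage
    return CellAnnotations(df)


def protected_design(annotations: CellAnnotations) -> DesignMatrix:
    """Intercept + knockdown indicator: the covariates protected during
    confounder correction."""
    return DesignMatrix.two_group(
        (annotations.column("treatment") == "siTARGET").astype(float))


# ---------------------------------------------------------------------------
# Fisher's method and FDR
# ---------------------------------------------------------------------------

@dataclass
class CombinedTest:
    """Fisher's-method combination of two per-coefficient p-values."""

    p1: float
    p2: float
    statistic: float            # F* = -2 ln p1 - 2 ln p2
    df: int
    p_combined: float


def fisher_combine(p1: float, p2: float) -> CombinedTest:
    """Combine two p-values: F* = -2 ln(p1) - 2 ln(p2) ~ chi-squared(4 df)
    under the null; the combined p is the survival function at F*.

    Zeros are floored at 1e-300 with a warning; values outside [0, 1] are
    an error.
    """
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    if p1 == 0.0 or p2 == 0.0:
        warnings.warn("zero p-value floored at 1e-300 before combination")
    q1, q2 = max(p1, _P_FLOOR), max(p2, _P_FLOOR)
    stat = -2.0 * (np.log(q1) + np.log(q2))
    return CombinedTest(p1=p1, p2=p2, statistic=float(stat), df=4,
                        p_combined=float(chi2.sf(stat, df=4)))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries stay NaN."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# per-design runners
# ---------------------------------------------------------------------------

def _direction(coef: float) -> str:
    return "up" if coef > 0 else "down"     # exact ties count as down


def _finalize(records, fdr_level, design_name) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records)
    df["design"] = design_name
    df["q_value"] = fdr_adjust(df["p_combined"].to_numpy())
    df["significant"] = df["q_value"] <= fdr_level
    n_failed = int(df["p_combined"].isna().sum())
    logger.info("design=%s genes=%d significant=%d fit_failures=%d",
                design_name, len(df), int(df["significant"].sum()), n_failed)
    cols = ["gene_id", "design", "p1", "p2", "p_combined", "q_value",
            "lfc1", "lfc2", "direction", "significant", "flags"]
    return df[cols]


def _run_single_indicator(counts, keep, indicator, indicator_name,
                          fdr_level, design_name, exposure=None):
    design = DesignMatrix.two_group(indicator)
    records = []
    for row, gene in enumerate(counts.gene_ids):
        y = counts.values[row, keep]
        fit = fit_bp_glm(y, design, gene_id=gene, exposure=exposure)
        p = test_coefficient(fit, "I_siTARGET", y, design, exposure=exposure)
        coef = fit.coefficients["I_siTARGET"]
        records.append({
            "gene_id": gene, "p1": p, "p2": np.nan, "p_combined": p,
            "lfc1": coef / LN2, "lfc2": np.nan,
            "direction": _direction(coef),
            "flags": ";".join(fit.flags),
        })
    df = _finalize(records, fdr_level, design_name)
    return df


def run_two_group_design(counts: CountMatrix, annotations: CellAnnotations,
                         fdr_level: float = 0.05,
                         exposure=None) -> pd.DataFrame:
    """Control vs. knockdown: per gene, LRT on the knockdown indicator.

    ``exposure`` optionally supplies per-cell sequencing-depth offsets
    (depth / 1e6); omit it for depth-equalized (CPM-scale) matrices.
    """
    ann = annotations.aligned_to(counts.cell_ids)
    kd = (ann.column("treatment") == "siTARGET").astype(float)
    if (kd == 0).sum() < 2 or (kd == 1).sum() < 2:
        raise ValueError("underpowered design: need >= 2 cells per group")
    keep = np.ones(counts.n_cells, dtype=bool)
    return _run_single_indicator(counts, keep, kd, "I_siTARGET",
                                 fdr_level, "two_group", exposure=exposure)


def run_three_group_design(counts: CountMatrix, annotations: CellAnnotations,
                           fdr_level: float = 0.05,
                           exposure=None) -> pd.DataFrame:
    """Control vs. detectable vs. undetectable knockdown.

    The two dosage indicators are tested separately per gene and the
    p-values combined by Fisher's method; q-values control FDR on the
    combined p.  If the detectable group is empty the design degenerates
    and the two-group analysis is run instead (with a warning).
    """
    ann = annotations.aligned_to(counts.cell_ids)
    dg = ann.column("dosage_group")
    if pd.isna(dg).any():
        raise ValueError("dosage groups not assigned; run assign_dosage_groups")
    n_det, n_und = int((dg == "detectable").sum()), int((dg == "undetectable").sum())
    if n_det < 2:
        warnings.warn("empty/degenerate detectable group: falling back to "
                      "the two-group design")
        return run_two_group_design(counts, annotations, fdr_level, exposure)
    if n_und < 2:
        warnings.warn("empty/degenerate undetectable group: falling back to "
                      "the two-group design")
        return run_two_group_design(counts, annotations, fdr_level, exposure)
    design = DesignMatrix.three_group((dg == "detectable").astype(float),
                                      (dg == "undetectable").astype(float))
    records = []
    for row, gene in enumerate(counts.gene_ids):
        y = counts.values[row, :]
        fit = fit_bp_glm(y, design, gene_id=gene, exposure=exposure)
        p1 = test_coefficient(fit, "I_siTARGET_detectable", y, design,
                              exposure=exposure)
        p2 = test_coefficient(fit, "I_siTARGET_undetectable", y, design,
                              exposure=exposure)
        if np.isnan(p1) or np.isnan(p2):
            p_comb = np.nan
        else:
            p_comb = fisher_combine(p1, p2).p_combined
        c1 = fit.coefficients["I_siTARGET_detectable"]
        c2 = fit.coefficients["I_siTARGET_undetectable"]
        records.append({
            "gene_id": gene, "p1": p1, "p2": p2, "p_combined": p_comb,
            "lfc1": c1 / LN2, "lfc2": c2 / LN2,
            "direction": _direction(c2),       # undetectable contrast
            "flags": ";".join(fit.flags),
        })
    return _finalize(records, fdr_level, "three_group")


def run_detectable_vs_undetectable(counts: CountMatrix,
                                   annotations: CellAnnotations,
                                   fdr_level: float = 0.05,
                                   exposure=None) -> pd.DataFrame:
    """Knockdown cells only: detectable vs. undetectable target expression."""
    ann = annotations.aligned_to(counts.cell_ids)
    dg = ann.column("dosage_group")
    if pd.isna(dg).any():
        raise ValueError("dosage groups not assigned; run assign_dosage_groups")
    keep = dg != "SCR"
    sub = counts.subset(cell_mask=keep)
    dg_kd = dg[keep]
    n_det, n_und = int((dg_kd == "detectable").sum()), int((dg_kd == "undetectable").sum())
    if n_det < 2 or n_und < 2:
        raise ValueError("statistically underpowered: need >= 2 detectable "
                         "and >= 2 undetectable knockdown cells")
    und = (dg_kd == "undetectable").astype(float)
    sub_expo = None if exposure is None else np.asarray(exposure)[keep]
    records = []
    design = DesignMatrix.two_group(und)
    for row, gene in enumerate(sub.gene_ids):
        y = sub.values[row, :]
        fit = fit_bp_glm(y, design, gene_id=gene, exposure=sub_expo)
        p = test_coefficient(fit, "I_siTARGET", y, design, exposure=sub_expo)
        coef = fit.coefficients["I_siTARGET"]
        records.append({
            "gene_id": gene, "p1": p, "p2": np.nan, "p_combined": p,
            "lfc1": coef / LN2, "lfc2": np.nan,
            "direction": _direction(coef),
            "flags": ";".join(fit.flags),
        })
    return _finalize(records, fdr_level, "detectable_vs_undetectable")


# ---------------------------------------------------------------------------
# overlap and direction-bias analyses
# ---------------------------------------------------------------------------

@dataclass
class OverlapSummary:
    """Venn-style intersections of the per-design significant gene sets."""

    sets: dict                 # design -> frozenset of gene ids
    counts: dict               # region label -> count (inclusion-exclusion exact)
    triple: tuple              # genes significant in all three designs

    def region(self, label: str) -> int:
        return self.counts[label]


def overlap_sets(results: dict) -> OverlapSummary:
    """Exact set overlaps between the three designs' significant genes.

    All result tables must cover the same gene universe.
    """
    if len(results) != 3:
        raise ValueError("need exactly three result collections")
    universes = [frozenset(df["gene_id"]) for df in results.values()]
    if len(set(universes)) != 1:
        raise ValueError("result collections cover different gene universes")
    sets = {name: frozenset(df.loc[df["significant"], "gene_id"])
            for name, df in results.items()}
    names = list(sets)
    a, b, c = (sets[n] for n in names)
    counts = {
        names[0]: len(a), names[1]: len(b), names[2]: len(c),
        f"{names[0]}&{names[1]}": len(a & b),
        f"{names[0]}&{names[2]}": len(a & c),
        f"{names[1]}&{names[2]}": len(b & c),
        "&".join(names): len(a & b & c),
    }
    return OverlapSummary(sets=sets, counts=counts,
                          triple=tuple(sorted(a & b & c)))


def direction_bias_test(results: pd.DataFrame):
    """Association between significance and direction of change.

    Builds the 2x2 table (DEG / non-DEG) x (down / up) over all genes in
    the result collection and returns ``(table, p)`` with the two-sided
    Fisher's exact p-value (hypergeometric outcomes at most as probable as
    the observed one).  A zero margin yields p = 1 with a warning.
    """
    sig = results["significant"].to_numpy(dtype=bool)
    down = (results["direction"] == "down").to_numpy()
    table = np.array([
        [int((sig & down).sum()), int((sig & ~down).sum())],
        [int((~sig & down).sum()), int((~sig & ~down).sum())],
    ])
    return contingency_fisher(table)


def contingency_fisher(table: np.ndarray):
    """Two-sided Fisher's exact test on an explicit 2x2 count table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin in contingency table: p = 1")
        return table, 1.0
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
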