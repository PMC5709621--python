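"""Data containers, readers/writers, configuration and the pipeline driver.

Conventions: genes are rows and cells are columns everywhere; matrices on
disk are MatrixMarket coordinate integer files (1-based) accompanied by
headered gene/cell annotation TSVs whose order defines the in-memory
order.  All reported indices are gene/cell identifiers, never positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger("scdose")

TREATMENTS = ("SCR", "siTARGET")
DOSAGE_GROUPS = ("SCR", "detectable", "undetectable")

#: column order of results tables written by :func:`write_results_table`
RESULT_COLUMNS = (
    "gene_id", "design", "p1", "p2", "p_combined", "q_value",
    "lfc1", "lfc2", "direction", "significant", "flags",
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene-by-cell expression counts with identifiers."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene id")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell id")
        if np.any(self.values < 0):
            raise ValueError("negative counts are not allowed")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValueError("counts must be integral")
            self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.values[np.ix_(gm, cm)],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [c for c, k in zip(self.cell_ids, cm) if k],
        )


@dataclass
class CellAnnotations:
    """Per-cell treatment, batch and (optionally) knockdown-dosage group.

    The dosage group is derived from observed target-gene counts; control
    (SCR) cells always carry dosage group ``SCR`` once assigned.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        required = {"cell_id", "treatment", "batch"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        df["cell_id"] = df["cell_id"].astype(str)
        if df["cell_id"].duplicated().any():
            raise ValueError("duplicate cell id in annotations")
        bad = set(df["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")
        if "dosage_group" in df.columns and df["dosage_group"].notna().any():
            self._check_dosage(df)
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def _check_dosage(df):
        bad = set(df["dosage_group"].dropna()) - set(DOSAGE_GROUPS)
        if bad:
            raise ValueError(f"unknown dosage groups: {sorted(bad)}")
        assigned = df["dosage_group"].notna()
        scr = df["treatment"] == "SCR"
        if not (df.loc[assigned & scr, "dosage_group"] == "SCR").all():
            raise ValueError("SCR cells must have dosage group 'SCR'")
        if (df.loc[assigned & ~scr, "dosage_group"] == "SCR").any():
            raise ValueError("knockdown cells cannot have dosage group 'SCR'")

    def aligned_to(self, cell_ids) -> "CellAnnotations":
        """Rows reordered to match ``cell_ids``; every cell must be annotated."""
        df = self.frame.set_index("cell_id")
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise ValueError(f"cells without annotation: {missing[:5]}")
        out = df.loc[list(cell_ids)].reset_index()
        return CellAnnotations(out)

    def column(self, name):
        return self.frame[name].to_numpy()

    @property
    def cell_ids(self):
        return self.frame["cell_id"].tolist()


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults follow the study's settings."""

    detection_threshold: float = 0.05
    cpm_scale: float = 1_000_000.0
    fdr_level: float = 0.05
    target_gene: str = "TARGET"
    outlier_max_gene_fraction: float = 0.10
    seed: int = 0
    cell_cycle_gene_file: str = ""      # empty -> packaged GO:0007049 fixture
    n_factors: int = 1
    iterate_filter: bool = False

    def __post_init__(self):
        for name in ("detection_threshold", "fdr_level", "outlier_max_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.cpm_scale <= 0:
            raise ValueError("cpm_scale must be > 0")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file ('#' starts a comment)."""
        kwargs = {}
        casts = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in casts:
                raise ValueError(f"unknown config key: {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def packaged_cell_cycle_file() -> Path:
    """Path of the packaged cell-cycle gene-symbol fixture (GO:0007049-derived)."""
    return Path(str(resources.files("scdose").joinpath("data/cell_cycle_go0007049.txt")))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    col = f"{kind}_id"
    if col not in df.columns:
        raise ValueError(f"{path}: expected a {col!r} column")
    if df[col].duplicated().any():
        raise ValueError(f"duplicate {kind} id in {path}")
    return df


def read_count_matrix(matrix_path, gene_path, cell_path) -> CountMatrix:
    """Read a MatrixMarket coordinate matrix plus gene/cell TSVs.

    Row order follows the gene file, column order the cell file.  Entries
    must be non-negative integers.
    """
    mat = mmread(str(matrix_path))
    genes = _read_id_table(gene_path, "gene")
    cells = _read_id_table(cell_path, "cell")
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape[0] != len(genes):
        raise ValueError(
            f"{gene_path}: {len(genes)} genes but matrix has {dense.shape[0]} rows")
    if dense.shape[1] != len(cells):
        raise ValueError(
            f"{cell_path}: {len(cells)} cells but matrix has {dense.shape[1]} columns")
    if np.any(dense < 0):
        raise ValueError(f"{matrix_path}: negative entries")
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValueError(f"{matrix_path}: non-integer entries")
    return CountMatrix(dense.astype(np.int64), genes["gene_id"].tolist(),
                       cells["cell_id"].tolist())


def write_count_matrix(cm: CountMatrix, matrix_path, gene_path, cell_path) -> None:
    sparse = coo_matrix(cm.values)
    mmwrite(str(matrix_path), sparse, field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(gene_path, sep="\t", index=False)
    pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(cell_path, sep="\t", index=False)


def write_annotations(ann: CellAnnotations, path) -> None:
    ann.frame.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> CellAnnotations:
    return CellAnnotations(pd.read_csv(path, sep="\t", dtype={"cell_id": str}))


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a DE results table as headered TSV in the documented column order.

    Numeric fields are written with 12 significant digits, which makes the
    read/write round trip lossless at that precision.
    """
    df = results.copy()
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(RESULT_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != list(RESULT_COLUMNS):
        raise ValueError(f"{path}: unexpected result columns {list(df.columns)}")
    return df


def write_run_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """End-to-end pipeline output: per-design results, overlap, report."""

    results: dict                      # design name -> results DataFrame
    overlap: object                    # OverlapSummary or None
    contingency: object                # (2x2 ndarray, p) for the two-group design
    annotations: CellAnnotations       # with dosage groups assigned
    corrected: object                  # corrected NormalizedMatrix
    report: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, counts: CountMatrix,
                 annotations: CellAnnotations,
                 cell_cycle_genes=None) -> PipelineResult:
    """Run filter -> normalize -> outlier removal -> confounder correction ->
    dosage grouping -> DE designs -> FDR -> overlap summary.

    ``cell_cycle_genes`` may be an iterable of gene ids; if omitted the
    file named in the config (or the packaged fixture) is used.
    """
    from . import confounder as cc
    from . import de, qc

    report = {"config": config.to_dict(), "seed": config.seed, "stages": []}

    def stage(name, n_genes, n_cells, **extra):
        entry = {"stage": name, "n_genes": int(n_genes), "n_cells": int(n_cells), **extra}
        report["stages"].append(entry)
        logger.info("stage=%s n_genes=%d n_cells=%d %s", name, n_genes, n_cells, extra)

    annotations = annotations.aligned_to(counts.cell_ids)
    stage("input", counts.n_genes, counts.n_cells)

    filtered = qc.filter_by_detection(counts, config.detection_threshold,
                                      iterate=config.iterate_filter)
    stage("detection_filter", filtered.n_genes, filtered.n_cells)

    outliers = qc.flag_outlier_cells(filtered, config.outlier_max_gene_fraction)
    if outliers:
        keep = np.array([c not in set(outliers) for c in filtered.cell_ids])
        filtered = filtered.subset(cell_mask=keep)
    stage("outlier_removal", filtered.n_genes, filtered.n_cells,
          removed_cells=outliers)

    annotations = annotations.aligned_to(filtered.cell_ids)
    treatment = annotations.column("treatment")
    if (treatment == "SCR").sum() < 2 or (treatment == "siTARGET").sum() < 2:
        raise ValueError("underpowered design: fewer than 2 cells in a "
                         "required group after filtering")

    norm = qc.normalize_cpm(filtered, config.cpm_scale)
    stage("cpm_normalization", filtered.n_genes, filtered.n_cells)

    if cell_cycle_genes is None:
        cc_path = config.cell_cycle_gene_file or packaged_cell_cycle_file()
        gene_set = cc.load_cell_cycle_genes(cc_path, filtered.gene_ids)
    else:
        gene_set = cc.CellCycleGeneSet.from_ids(cell_cycle_genes, filtered.gene_ids)
    design = de.protected_design(annotations)
    model = cc.fit_latent_factor(
        cc.log2_cpm(norm, gene_set.matched), design)
    corrected = cc.regress_out(norm, model, design)
    stage("confounder_correction", filtered.n_genes, filtered.n_cells,
          n_cell_cycle_matched=gene_set.n_matched,
          variance_share=model.fit_diagnostics["variance_share"])

    annotations = de.assign_dosage_groups(filtered, annotations, config.target_gene)
    dg = annotations.column("dosage_group")
    sizes = {g: int((dg == g).sum()) for g in DOSAGE_GROUPS}
    stage("dosage_grouping", filtered.n_genes, filtered.n_cells, group_sizes=sizes)

    # return corrected expression to each cell's sequencing depth and fit
    # with a log-exposure offset: the count likelihood then sees counts on
    # their native scale instead of depth-rescaled (variance-distorted) ones
    exposure = norm.original_totals / config.cpm_scale
    fit_counts = CountMatrix(
        np.rint(corrected.values * exposure[None, :]).astype(np.int64),
        corrected.gene_ids, corrected.cell_ids)
    results = {}
    results["two_group"] = de.run_two_group_design(
        fit_counts, annotations, fdr_level=config.fdr_level, exposure=exposure)

    skipped = []
    if sizes["detectable"] >= 2 and sizes["undetectable"] >= 2:
        results["three_group"] = de.run_three_group_design(
            fit_counts, annotations, fdr_level=config.fdr_level,
            exposure=exposure)
        results["detectable_vs_undetectable"] = de.run_detectable_vs_undetectable(
            fit_counts, annotations, fdr_level=config.fdr_level,
            exposure=exposure)
    else:
        skipped = [d for d in ("three_group", "detectable_vs_undetectable")]
        logger.warning("dosage subgroup below 2 cells; skipping %s", skipped)
    for name, df in results.items():
        stage(f"design:{name}", filtered.n_genes, filtered.n_cells,
              n_significant=int(df["significant"].sum()))
    if skipped:
        report["skipped_designs"] = skipped

    overlap = de.overlap_sets(results) if len(results) == 3 else None
    contingency = de.direction_bias_test(results["two_group"])
    report["direction_bias_p"] = contingency[1]
    if overlap is not None:
        report["overlap"] = overlap.counts

    # monotone non-increasing gene/cell counts through the filter stages
    dims = [(s["n_genes"], s["n_cells"]) for s in report["stages"][:4]]
    assert all(a[0] >= b[0] and a[1] >= b[1] for a, b in zip(dims, dims[1:]))

    return PipelineResult(results=results, overlap=overlap,
                          contingency=contingency, annotations=annotations,
                          corrected=corrected, report=report)
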