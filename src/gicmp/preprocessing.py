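"""Cell/gene quality control, normalization and sample-inclusion rules.

Boundary semantics follow the source conventions exactly: a cell is removed
iff it detects fewer than 500 genes, more than 6000 genes, or derives more
than 20% of its UMIs from mitochondrial genes; a gene is kept iff it is
detected in more than 10 cells; a sample enters program discovery iff it
retains at least 50 epithelial cells.  All inequalities are strict in the
removal direction, so a cell detecting exactly 500 genes is retained.

Cells violating several rules are counted once, under the first matching
rule in the fixed precedence (doublet flag, low genes, high genes, high
mito); totals are unaffected by the precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
from scipy import sparse


class QCConfigurationError(ValueError):
    """Required metadata (mito flags, major-type labels) is missing."""


class EmptyInputError(ValueError):
    """The matrix has no cells or genes left to operate on."""


@dataclass
class QCConfig:
    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 6000
    max_mito_fraction: float = 0.20
    min_cells_per_gene: int = 10
    min_epithelial_cells_per_sample: int = 50
    epithelial_label: str = "Epithelial"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be below max_genes_per_cell")
        if not 0.0 < self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in (0, 1]")


@dataclass
class QCReport:
    n_input_cells: int = 0
    removed_doublet: int = 0
    removed_low_genes: int = 0
    removed_high_genes: int = 0
    removed_high_mito: int = 0
    n_retained_cells: int = 0
    removed_genes: int = 0
    retained_samples: list[str] = field(default_factory=list)
    epithelial_cells_per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def total_removed(self) -> int:
        return (
            self.removed_doublet
            + self.removed_low_genes
            + self.removed_high_genes
            + self.removed_high_mito
        )


def _detected_per_cell(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (X > 0).sum(axis=1)


def _row_sums(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return X.sum(axis=1)


def filter_cells(adata: ad.AnnData, cfg: QCConfig | None = None) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells; itemize removals per rule.

    Requires a boolean ``mt`` column in ``var``.  A boolean ``doublet``
    column in ``obs``, when present, is honoured first (pre-computed doublet
    calls are accepted rather than re-derived).
    """
    cfg = cfg or QCConfig()
    if "mt" not in adata.var:
        raise QCConfigurationError(
            "var lacks the boolean 'mt' column flagging mitochondrial genes"
        )
    detected = _detected_per_cell(adata.X)
    total = _row_sums(adata.X)
    mito_total = _row_sums(adata[:, adata.var["mt"].to_numpy()].X)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)

    report = QCReport(n_input_cells=adata.n_obs)
    removed = np.zeros(adata.n_obs, dtype=bool)
    if "doublet" in adata.obs:
        dbl = adata.obs["doublet"].to_numpy(dtype=bool)
        report.removed_doublet = int(dbl.sum())
        removed |= dbl
    low = ~removed & (detected < cfg.min_genes_per_cell)
    report.removed_low_genes = int(low.sum())
    removed |= low
    high = ~removed & (detected > cfg.max_genes_per_cell)
    report.removed_high_genes = int(high.sum())
    removed |= high
    mito = ~removed & (mito_frac > cfg.max_mito_fraction)
    report.removed_high_mito = int(mito.sum())
    removed |= mito

    out = adata[~removed].copy()
    report.n_retained_cells = out.n_obs
    return out, report


def filter_genes(
    adata: ad.AnnData, cfg: QCConfig | None = None, report: QCReport | None = None
) -> ad.AnnData:
    """Keep genes detected in strictly more than ``min_cells_per_gene`` cells."""
    cfg = cfg or QCConfig()
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise EmptyInputError("cannot filter genes of an empty matrix")
    if sparse.issparse(adata.X):
        n_cells = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    else:
        n_cells = (adata.X > 0).sum(axis=0)
    keep = n_cells > cfg.min_cells_per_gene
    if report is not None:
        report.removed_genes = int((~keep).sum())
    return adata[:, keep].copy()


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` UMIs and apply log1p.

    Raw counts are preserved in ``layers['counts']``; ``X`` becomes the
    log-normalized matrix.  A cell with zero total counts is an error.
    """
    out = adata.copy()
    total = _row_sums(out.X)
    if np.any(total == 0):
        bad = out.obs_names[np.flatnonzero(total == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    out.layers["counts"] = out.X.copy()
    if sparse.issparse(out.X):
        X = out.X.astype(np.float64)
        scale = sparse.diags(target_sum / total)
        X = scale @ X
        X.data = np.log1p(X.data)
        out.X = X.tocsr()
    else:
        X = out.X.astype(np.float64) * (target_sum / total)[:, None]
        out.X = np.log1p(X)
    return out


def select_samples(
    adata: ad.AnnData, cfg: QCConfig | None = None, report: QCReport | None = None
) -> list[str]:
    """Samples retaining at least ``min_epithelial_cells_per_sample`` epithelial cells."""
    cfg = cfg or QCConfig()
    if "major_type" not in adata.obs:
        raise QCConfigurationError("obs lacks the 'major_type' column")
    is_epi = adata.obs["major_type"] == cfg.epithelial_label
    if not is_epi.any():
        warnings.warn(
            f"no cell carries major_type == {cfg.epithelial_label!r}; "
            "no sample qualifies for program discovery",
            stacklevel=2,
        )
        if report is not None:
            report.retained_samples = []
        return []
    counts = adata.obs.loc[is_epi, "sample"].value_counts()
    kept = sorted(counts[counts >= cfg.min_epithelial_cells_per_sample].index)
    if report is not None:
        report.retained_samples = kept
        report.epithelial_cells_per_sample = counts.to_dict()
    return kept
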