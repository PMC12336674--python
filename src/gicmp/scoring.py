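"""Rank-based AUC scoring of meta-programs, identity assignment and Ro/e.

The per-cell activity of a gene set is the normalized area under its
recovery curve within the top-ranked fraction of that cell's genes
(AUCell-style).  Genes are ranked by decreasing expression with ties broken
by ascending gene identifier so the score is fully deterministic.  With
k = ceil(threshold_fraction * n_genes),

    AUC = sum_{r=1..k} |set ∩ top-r|,   normalized by sum_{r=1..k} min(r, |set|),

which lies in [0, 1] and is invariant under any strictly monotone transform
of the expression vector.

A cell's meta-program identity is the argmax of its scores after per-MP
mean subtraction across cells.  Tissue preference of identities is
quantified by Ro/e, the ratio of observed to chi-squared-expected cell
numbers in a group x category contingency (enriched iff Ro/e > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats.contingency import expected_freq

from .metaprograms import MetaProgram


@dataclass
class MPScoreMatrix:
    scores: pd.DataFrame  # cells x MPs, values in [0, 1]
    sample_medians: pd.DataFrame  # samples x MPs
    identities: pd.Series  # cell -> mp_id
    rank_threshold_fraction: float = 0.05
    normalized_scores: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rank_matrix(X: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """1-based rank of every gene in every cell (desc expression, ties by gene id)."""
    # sort gene columns by identifier once; stable argsort on -expr then
    # breaks ties by ascending identifier
    gene_order = np.argsort(genes, kind="stable")
    Xs = X[:, gene_order]
    order = np.argsort(-Xs, axis=1, kind="stable")
    ranks_sorted = np.empty_like(order)
    ncells, ngenes = X.shape
    rows = np.arange(ncells)[:, None]
    ranks_sorted[rows, order] = np.arange(1, ngenes + 1)[None, :]
    ranks = np.empty_like(ranks_sorted)
    ranks[:, gene_order] = ranks_sorted
    return ranks


def auc_score(
    expr: np.ndarray,
    genes: list[str],
    gene_set: list[str],
    threshold_fraction: float = 0.05,
    set_name: str = "",
) -> float:
    """Normalized recovery-curve AUC of ``gene_set`` in one expression vector."""
    genes_arr = np.asarray(genes)
    members = np.isin(genes_arr, list(gene_set))
    if not members.any():
        raise ValueError(
            f"gene set {set_name or '<unnamed>'!r} has no measured genes"
        )
    ranks = _rank_matrix(np.asarray(expr, dtype=float)[None, :], genes_arr)[0]
    n = len(genes_arr)
    k = ceil(threshold_fraction * n)
    s = int(members.sum())
    r = ranks[members]
    numer = np.maximum(k - r + 1, 0).sum()
    rr = np.arange(1, k + 1)
    denom = np.minimum(rr, s).sum()
    return float(numer / denom)


def score_matrix(
    norm: ad.AnnData,
    mps: list[MetaProgram],
    threshold_fraction: float = 0.05,
    epithelial_only: bool = True,
    epithelial_label: str = "Epithelial",
) -> MPScoreMatrix:
    """Score every (epithelial) cell against every meta-program.

    Per-sample medians are taken over the scored cells of each sample;
    identities come from :func:`assign_identity`.
    """
    if epithelial_only and "major_type" in norm.obs:
        sub = norm[(norm.obs["major_type"] == epithelial_label).to_numpy()]
    else:
        sub = norm
    if sub.n_obs == 0:
        raise ValueError("no cells to score")
    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    genes = sub.var_names.to_numpy()
    ranks = _rank_matrix(X, genes)
    n = len(genes)
    k = ceil(threshold_fraction * n)
    rr = np.arange(1, k + 1)

    cols = {}
    for mp in mps:
        members = np.isin(genes, mp.signature)
        if not members.any():
            raise ValueError(f"meta-program {mp.mp_id!r} has no measured genes")
        s = int(members.sum())
        contrib = np.maximum(k - ranks[:, members] + 1, 0).sum(axis=1)
        cols[mp.mp_id] = contrib / np.minimum(rr, s).sum()
    scores = pd.DataFrame(cols, index=sub.obs_names)

    medians = scores.groupby(sub.obs["sample"].to_numpy()).median()
    medians.index.name = "sample"
    identities, normalized = assign_identity(scores, return_normalized=True)
    return MPScoreMatrix(
        scores=scores,
        sample_medians=medians,
        identities=identities,
        rank_threshold_fraction=threshold_fraction,
        normalized_scores=normalized,
    )


def assign_identity(scores: pd.DataFrame, return_normalized: bool = False):
    """Mean-subtract each MP column, then take the per-cell argmax.

    Ties resolve to the lowest MP column index (deterministic).
    """
    normalized = scores - scores.mean(axis=0)
    idx = normalized.to_numpy().argmax(axis=1)  # first max wins
    identities = pd.Series(
        np.asarray(scores.columns)[idx], index=scores.index, name="mp_identity"
    )
    if return_normalized:
        return identities, normalized
    return identities


def roe(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected cell numbers for a group x category contingency.

    Expected counts are the chi-squared expectation row_total x col_total /
    grand_total.  Cells with zero expectation get Ro/e = NaN (reported as
    missing, never divided).  Enriched iff Ro/e > 1 (strict).
    """
    obs = counts.to_numpy(dtype=float)
    if obs.min() < 0:
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("contingency table is all zero")
    exp = expected_freq(obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(exp > 0, obs / np.where(exp > 0, exp, 1.0), np.nan)
    long = []
    for i, g in enumerate(counts.index):
        for j, c in enumerate(counts.columns):
            long.append(
                {
                    "group": g,
                    "category": c,
                    "observed": obs[i, j],
                    "expected": exp[i, j],
                    "roe": ratio[i, j],
                    "enriched": bool(ratio[i, j] > 1) if exp[i, j] > 0 else False,
                }
            )
    return pd.DataFrame(long)


def score_genes_control(
    norm: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    ctrl_size: int | None = None,
    seed: int = 0,
) -> pd.Series:
    """Alternative scorer: mean set expression minus expression-matched controls.

    Bins genes by mean expression into ``n_bins`` bins and samples, per set
    gene, ``ctrl_size`` control genes from the same bin (default: as many as
    the set).  Provided as an independent validation of the AUC scorer.
    """
    rng = np.random.default_rng(seed)
    X = norm.X.toarray() if sparse.issparse(norm.X) else np.asarray(norm.X, dtype=float)
    genes = norm.var_names.to_numpy()
    members = np.isin(genes, list(gene_set))
    if not members.any():
        raise ValueError("gene set has no measured genes")
    mean = X.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(genes), dtype=int)
    bins[order] = np.arange(len(genes)) * n_bins // len(genes)
    ctrl: list[int] = []
    per_gene = ctrl_size or 1
    for gi in np.flatnonzero(members):
        pool = np.flatnonzero((bins == bins[gi]) & ~members)
        if pool.size:
            ctrl.extend(rng.choice(pool, size=min(per_gene, pool.size), replace=False))
    ctrl_idx = np.unique(ctrl) if ctrl else np.flatnonzero(~members)
    score = X[:, members].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=norm.obs_names, name="score")
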