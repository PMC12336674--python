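"""Compositional microenvironment analysis, lineage inference and metaplasia.

Four stages:

* **composition** — sample x subtype counts, relative abundances (each
  subtype divided by its parent major cell type's count in the sample) and
  per-subtype z-scored abundances across samples;
* **niche clustering** — samples clustered on 1 - Pearson correlation of
  their feature vectors (scaled subtype abundances, optionally concatenated
  with scaled epithelial meta-program identity fractions) with Ward
  linkage, after dropping thin subtypes and under-sampled samples;
* **lineage inference** — every epithelial cell is correlated (Pearson)
  against reference lineage expression profiles over the reference
  signature genes; assignment follows the cancer-type-aware rules described
  in :func:`infer_lineages`;
* **metaplasia grouping** — samples are split into metaplastic /
  non-metaplastic by the proportion of metaplastic-tissue lineages among
  their assigned epithelial cells (intestinal lineages for gastric samples,
  gastric + intestinal for oesophageal ones), either at a fixed threshold
  or by an exact 1-D two-class (2-means) split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GIC_TISSUES = ("oesophageal", "gastric", "intestinal")
CANCER_TISSUE = {"EC": "oesophageal", "GC": "gastric", "CRC": "intestinal"}
#: metaplastic tissues per cancer type: what counts as "foreign epithelium"
METAPLASTIC_TISSUES = {
    "GC": ("intestinal",),
    "EC": ("gastric", "intestinal"),
    "CRC": (),
}
NON_GI_LABEL = "Non-GI"


@dataclass
class CompositionTable:
    counts: pd.DataFrame  # samples x subtypes
    relative: pd.DataFrame  # counts / parent-major-type count (NaN if excluded)
    scaled: pd.DataFrame  # per-subtype z-score of relative across samples
    parents: dict[str, str]
    major_counts: pd.DataFrame  # samples x major types


@dataclass
class NicheConfig:
    min_cells_per_sample: int = 50
    min_cells_per_subtype: int = 100
    max_single_sample_fraction: float = 0.30
    n_groups: int = 7
    linkage: str = "ward"
    epithelial_major: str = "Epithelial"
    immune_majors: tuple[str, ...] = ("T", "B", "Myeloid", "NK")

    def __post_init__(self) -> None:
        if self.min_cells_per_sample <= 0 or self.min_cells_per_subtype <= 0:
            raise ValueError("cell thresholds must be positive")
        if not 0.0 < self.max_single_sample_fraction <= 1.0:
            raise ValueError("max_single_sample_fraction must lie in (0, 1]")


@dataclass
class ReferenceSignatures:
    """Reference lineage profiles with tissue-of-origin tags.

    ``profiles`` holds mean log-normalized expression, genes x lineages;
    ``signatures`` the marker genes per lineage; ``tissue`` maps each
    lineage to gastric / intestinal / oesophageal or a non-GI tissue label.
    """

    profiles: pd.DataFrame
    signatures: dict[str, list[str]]
    tissue: dict[str, str]

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("reference profiles must be non-negative")
        for lin, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"lineage {lin!r} has an empty signature")

    def is_gic(self, lineage: str) -> bool:
        return self.tissue.get(lineage) in GIC_TISSUES

    @property
    def cancer_association(self) -> dict[str, str | None]:
        inv = {v: k for k, v in CANCER_TISSUE.items()}
        return {lin: inv.get(t) for lin, t in self.tissue.items()}


def _zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    out = (df - mean).div(sd.replace(0.0, np.nan), axis=1)
    return out.fillna(0.0)


def composition(
    cells: pd.DataFrame,
    parents: dict[str, str],
    min_cells_per_sample: int = 50,
) -> CompositionTable:
    """Build sample x subtype counts and relative/scaled abundances.

    ``cells`` needs ``sample`` and ``subtype`` columns.  The relative
    abundance of a subtype is its count divided by the count of its parent
    major type in that sample; (sample, major type) compartments with fewer
    than ``min_cells_per_sample`` cells are excluded (NaN) from comparisons.
    """
    for col in ("sample", "subtype"):
        if col not in cells:
            raise ValueError(f"cells table lacks the {col!r} column")
    orphans = sorted(set(cells["subtype"]) - set(parents))
    if orphans:
        raise ValueError(f"subtypes without a parent major type: {orphans}")
    counts = (
        cells.groupby(["sample", "subtype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    major = cells.assign(major=cells["subtype"].map(parents))
    major_counts = (
        major.groupby(["sample", "major"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    relative = counts.astype(float).copy()
    for st in counts.columns:
        parent = parents[st]
        denom = major_counts[parent].reindex(counts.index).astype(float)
        ok = denom >= min_cells_per_sample
        relative[st] = np.where(ok, counts[st] / denom.where(denom > 0), np.nan)
    scaled = _zscore_columns(relative)
    return CompositionTable(
        counts=counts,
        relative=relative,
        scaled=scaled,
        parents=dict(parents),
        major_counts=major_counts,
    )


def cluster_niches(
    comp: CompositionTable,
    epithelial_identity_fractions: pd.DataFrame | None = None,
    cfg: NicheConfig | None = None,
    scale_jointly: bool = True,
) -> pd.Series:
    """Group samples into microenvironment niches.

    Feature matrix: scaled relative abundances of retained non-epithelial
    subtypes, concatenated with (jointly scaled) epithelial MP-identity
    fractions when given.  Subtypes with fewer than
    ``min_cells_per_subtype`` total cells or more than
    ``max_single_sample_fraction`` of their cells from one sample are
    dropped; samples with fewer than ``min_cells_per_sample`` epithelial or
    immune cells are excluded.  Distance = 1 - Pearson correlation between
    sample feature vectors; Ward linkage cut at ``n_groups``.
    """
    cfg = cfg or NicheConfig()
    counts = comp.counts
    majors = comp.major_counts

    epi = majors.get(cfg.epithelial_major, pd.Series(0, index=majors.index))
    immune_cols = [m for m in cfg.immune_majors if m in majors.columns]
    immune = majors[immune_cols].sum(axis=1) if immune_cols else pd.Series(0, index=majors.index)
    samples = majors.index[
        (epi >= cfg.min_cells_per_sample) & (immune >= cfg.min_cells_per_sample)
    ]
    if len(samples) < cfg.n_groups:
        raise ValueError(
            f"{len(samples)} samples pass the cell filters, fewer than "
            f"n_groups={cfg.n_groups}"
        )

    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        max_share = counts.max(axis=0) / totals.replace(0, np.nan)
    keep = [
        st
        for st in counts.columns
        if comp.parents[st] != cfg.epithelial_major
        and totals[st] >= cfg.min_cells_per_subtype
        and max_share[st] <= cfg.max_single_sample_fraction
    ]
    # niche features divide by the parent major-type count directly; the
    # sample-level epithelial/immune >= min_cells filter above replaces the
    # per-compartment exclusion used for abundance comparisons
    feats = pd.DataFrame(index=samples, columns=keep, dtype=float)
    for st in keep:
        denom = majors[comp.parents[st]].reindex(samples).astype(float)
        feats[st] = counts[st].reindex(samples) / denom.where(denom > 0)
    if epithelial_identity_fractions is not None:
        extra = epithelial_identity_fractions.reindex(samples)
        if scale_jointly:
            feats = pd.concat([feats, extra], axis=1)
        else:
            feats = pd.concat(
                [
                    _zscore_columns(feats.fillna(0.0)),
                    _zscore_columns(extra.fillna(0.0)),
                ],
                axis=1,
            )
    feats = _zscore_columns(feats.fillna(0.0))

    X = feats.to_numpy()
    R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=0.0)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = hierarchy.linkage(squareform(np.clip(D, 0.0, None), checks=False), method=cfg.linkage)
    labels = hierarchy.fcluster(Z, t=cfg.n_groups, criterion="maxclust")
    return pd.Series(labels, index=samples, name="niche")


def infer_lineages(
    expr: pd.DataFrame,
    cell_cancer_type: pd.Series | str,
    refs: ReferenceSignatures,
) -> pd.DataFrame:
    """Assign a reference lineage to every cell by Pearson correlation.

    ``expr`` is cells x genes, log-normalized the same way as the reference
    profiles (UMI share then log).  The Pearson correlation coefficient
    (PCC) is computed over the union of reference signature genes present
    in the data.  Assignment rules, applied per cell:

    1. among lineages with PCC > 0.3, if any shares the cell's
       cancer-type tissue of origin, assign the best such lineage
       (rule ``same-cancer``);
    2. else if the best PCC > 0.3 lineage is from another GI tissue,
       assign it (rule ``other-GIC``);
    3. else if every PCC <= 0.3 and the top-5 lineages by PCC contain no GI
       lineage, label ``Non-GI`` (rule ``non-GI``).

    Two residual cases the three rules do not cover are resolved
    deterministically: PCC <= 0.3 everywhere but a GI lineage among the
    top-5 assigns the best such lineage flagged ``low-confidence``; a best
    correlate above 0.3 that is a non-GI lineage yields ``Non-GI`` with
    rule ``non-GI-correlated``.
    """
    genes = sorted(
        set().union(*refs.signatures.values()) & set(expr.columns)
    )
    if not genes:
        raise ValueError("no overlap between data genes and reference signatures")
    lineages = list(refs.profiles.columns)
    P = refs.profiles.reindex(genes).fillna(0.0).to_numpy()  # genes x lineages
    X = expr[genes].to_numpy(dtype=float)  # cells x genes

    Xc = X - X.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=0, keepdims=True)
    xn = np.sqrt((Xc**2).sum(axis=1))
    pn = np.sqrt((Pc**2).sum(axis=0))
    denom = np.outer(xn, pn)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, (Xc @ Pc) / np.where(denom > 0, denom, 1.0), 0.0)

    if isinstance(cell_cancer_type, str):
        cancer = pd.Series(cell_cancer_type, index=expr.index)
    else:
        cancer = cell_cancer_type.reindex(expr.index)

    is_gic = np.array([refs.is_gic(l) for l in lineages])
    tissues = np.array([refs.tissue[l] for l in lineages])
    rows = []
    for ci, cell in enumerate(expr.index):
        cc = pcc[ci]
        own_tissue = CANCER_TISSUE.get(cancer.loc[cell])
        above = cc > 0.3
        best = int(np.argmax(cc))
        if above.any():
            same = above & (tissues == own_tissue)
            if same.any():
                j = int(np.argmax(np.where(same, cc, -np.inf)))
                rows.append((cell, lineages[j], cc[j], "same-cancer"))
                continue
            gic_above = above & is_gic
            if gic_above.any():
                j = int(np.argmax(np.where(gic_above, cc, -np.inf)))
                rows.append((cell, lineages[j], cc[j], "other-GIC"))
                continue
            rows.append((cell, NON_GI_LABEL, cc[best], "non-GI-correlated"))
            continue
        top5 = np.argsort(-cc, kind="stable")[:5]
        gic_top = [j for j in top5 if is_gic[j]]
        if not gic_top:
            rows.append((cell, NON_GI_LABEL, cc[best], "non-GI"))
        else:
            j = max(gic_top, key=lambda jj: cc[jj])
            rows.append((cell, lineages[j], cc[j], "low-confidence"))
    out = pd.DataFrame(rows, columns=["cell", "lineage", "pcc", "rule"]).set_index("cell")
    out["cancer_type"] = cancer
    return out


def classify_metaplasia(
    assignments: pd.DataFrame,
    refs: ReferenceSignatures,
    sample_of_cell: pd.Series,
    threshold: float | str = "auto",
) -> pd.DataFrame:
    """Split samples into metaplastic / non-metaplastic groups.

    ``assignments`` is the output of :func:`infer_lineages` for epithelial
    cells.  Per sample, the metaplastic proportion is the share of assigned
    cells whose lineage tissue counts as metaplastic for the sample's
    cancer type (intestinal for gastric samples; gastric + intestinal for
    oesophageal).  ``threshold='auto'`` performs an exact 1-D two-class
    split (2-means via exhaustive scan over sorted proportions); a numeric
    threshold classifies a sample metaplastic iff proportion >= threshold.
    """
    df = assignments.copy()
    df["sample"] = sample_of_cell.reindex(df.index)
    rows = []
    for sample, grp in df.groupby("sample"):
        n = len(grp)
        if n == 0:
            continue
        cancer = grp["cancer_type"].iloc[0]
        meta_tissues = METAPLASTIC_TISSUES.get(cancer, ())
        tiss = grp["lineage"].map(lambda l: refs.tissue.get(l, "non-GI"))
        prop = float(tiss.isin(meta_tissues).mean())
        rows.append({"sample": sample, "cancer_type": cancer, "metaplastic_proportion": prop})
    skipped = df["sample"].isna().sum()
    if skipped:
        warnings.warn(f"{skipped} cells without a sample label were skipped", stacklevel=2)
    out = pd.DataFrame(rows).set_index("sample")
    if out.empty:
        raise ValueError("no sample has assigned epithelial cells")
    props = out["metaplastic_proportion"].to_numpy()
    if threshold == "auto":
        cut = _two_means_threshold(props)
    else:
        cut = float(threshold)
    out["group"] = np.where(props >= cut, "metaplastic", "non-metaplastic")
    out["threshold"] = cut
    return out


def _two_means_threshold(values: np.ndarray) -> float:
    """Exact 1-D 2-means: the split minimizing within-class sum of squares.

    Returns the midpoint between the two class means; degenerate inputs
    (fewer than two distinct values) yield a threshold above the maximum so
    every sample falls into one class.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[0] == v[-1]:
        return float(v[-1]) + 1.0
    best = (np.inf, 0.0)
    for i in range(1, v.size):
        left, right = v[:i], v[i:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best[0] - 1e-15:
            best = (sse, (left.mean() + right.mean()) / 2.0)
    return float(best[1])


def make_synthetic_reference(
    n_background_genes: int = 100,
    block_size: int = 20,
    block_level: float = 2.0,
    seed: int = 0,
) -> ReferenceSignatures:
    """A small synthetic reference atlas for tests and examples.

    Six GI lineages (two per GI tissue) and six non-GI lineages, each with a
    dedicated marker-gene block elevated to ``block_level`` over a shared
    low background.  Profiles are non-negative mean log-normalized
    expression; signature genes are each lineage's marker block.
    """
    lineage_tissue = {
        "Oesophageal squamous": "oesophageal",
        "Oesophageal keratinocyte": "oesophageal",
        "Gastric chief": "gastric",
        "Gastric parietal": "gastric",
        "Intestinal enterocyte": "intestinal",
        "Intestinal goblet": "intestinal",
        "Hepatocyte": "liver",
        "Pneumocyte": "lung",
        "Cardiomyocyte": "heart",
        "Neuron": "brain",
        "Keratinocyte skin": "skin",
        "Podocyte": "kidney",
    }
    rng = np.random.default_rng(seed)
    lineages = list(lineage_tissue)
    n_genes = n_background_genes + block_size * len(lineages)
    gene_names = [f"RG{i + 1:05d}" for i in range(n_genes)]
    profiles = pd.DataFrame(
        rng.uniform(0.05, 0.4, size=(n_genes, len(lineages))),
        index=gene_names,
        columns=lineages,
    )
    signatures: dict[str, list[str]] = {}
    for li, lin in enumerate(lineages):
        start = n_background_genes + li * block_size
        block = gene_names[start : start + block_size]
        profiles.loc[block, lin] = block_level + rng.uniform(0, 0.5, block_size)
        signatures[lin] = block
    return ReferenceSignatures(
        profiles=profiles, signatures=signatures, tissue=lineage_tissue
    )
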