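"""Synthetic multi-sample scRNA-seq cohorts with planted ground truth.

The generator emulates the structure of a multi-cancer-type gastrointestinal
cohort: several samples per cancer type, a mix of epithelial and
non-epithelial cells, over-dispersed UMI counts, and three kinds of planted
signal that the downstream analysis is supposed to recover:

* shared and sample-private **gene programs** activated in a subset of each
  sample's epithelial cells (ground truth for NMF meta-program discovery),
* per-cell **lineage** labels tied to reference expression profiles
  (ground truth for reference-correlation lineage inference),
* per-sample **composition groups** with distinct non-epithelial subtype
  mixtures (ground truth for niche clustering).

Counts follow a gamma-Poisson (negative binomial) model: log-normal baseline
gene means, per-gene multiplicative activation ``exp(program_effect)`` in
program-active cells, per-cell library sizes drawn uniformly from
``depth_range``, and a dedicated mitochondrial gene block scaled to hit a
per-cell target mitochondrial UMI share.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse


class SpecValidationError(ValueError):
    """A cohort specification field is inconsistent or out of range."""


#: default non-epithelial subtype -> major cell type mapping
DEFAULT_SUBTYPE_PARENTS: dict[str, str] = {
    "CD4_T": "T",
    "CD8_T": "T",
    "Treg": "T",
    "Macrophage": "Myeloid",
    "DC": "Myeloid",
    "B_naive": "B",
    "Plasma": "B",
    "Fibroblast": "Stromal",
    "Endothelial": "Stromal",
}

#: two default sample-composition groups.  Because the downstream niche
#: features are relative abundances *within* each major cell type, the
#: groups are made to differ in within-major mixtures, not just in how many
#: T vs myeloid cells they carry.
DEFAULT_COMPOSITION_GROUPS: dict[str, dict[str, float]] = {
    "immune_hot": {
        "CD4_T": 0.25,
        "CD8_T": 0.05,
        "Treg": 0.05,
        "Macrophage": 0.20,
        "DC": 0.02,
        "B_naive": 0.18,
        "Plasma": 0.02,
        "Fibroblast": 0.20,
        "Endothelial": 0.03,
    },
    "stroma_rich": {
        "CD4_T": 0.05,
        "CD8_T": 0.20,
        "Treg": 0.10,
        "Macrophage": 0.05,
        "DC": 0.12,
        "B_naive": 0.03,
        "Plasma": 0.12,
        "Fibroblast": 0.05,
        "Endothelial": 0.28,
    },
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe the cohort used throughout the test suite: 12 samples
    cycling through three cancer types, 4 shared programs plus one private
    program per sample, 50-gene signatures activated at ~7.4-fold
    (``program_effect=2`` on the log scale) in 15% of epithelial cells each.
    """

    n_samples: int = 12
    cancer_types: tuple[str, ...] = ("EC", "GC", "CRC")
    n_cells_per_sample: tuple[int, int] = (200, 300)
    n_genes: int = 2000
    n_shared_programs: int = 4
    n_private_programs_per_sample: int = 1
    program_size: int = 50
    program_effect: float = 2.0
    active_fraction: float = 0.15
    program_gene_overlap: int = 0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    depth_range: tuple[int, int] = (1500, 4000)
    epithelial_fraction: float = 0.5
    mito_gene_fraction: float = 0.02
    ribo_gene_fraction: float = 0.03
    dispersion: float = 0.3
    lineage_profiles: dict[str, np.ndarray] | None = None
    composition_groups: dict[str, dict[str, float]] | None = None
    subtype_parents: dict[str, str] | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "program_size"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be strictly positive")
        if self.n_shared_programs < 0 or self.n_private_programs_per_sample < 0:
            raise SpecValidationError("program counts must be non-negative")
        if self.program_size > self.n_genes:
            raise SpecValidationError("program_size exceeds n_genes")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise SpecValidationError("active_fraction must lie in [0, 1]")
        n_prog = self.n_shared_programs + self.n_private_programs_per_sample
        if n_prog * self.active_fraction > 1.0 + 1e-12:
            raise SpecValidationError(
                "active_fraction too large: per-cell program activity is "
                "mutually exclusive, so (n programs per sample) x "
                "active_fraction must not exceed 1"
            )
        if self.n_cells_per_sample[0] > self.n_cells_per_sample[1]:
            raise SpecValidationError("n_cells_per_sample range inverted")
        if self.n_cells_per_sample[0] <= 0:
            raise SpecValidationError("n_cells_per_sample must be positive")
        if self.depth_range[0] <= 0 or self.depth_range[0] > self.depth_range[1]:
            raise SpecValidationError("depth_range invalid")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise SpecValidationError("mito_fraction_range invalid")
        if not 0.0 <= self.epithelial_fraction <= 1.0:
            raise SpecValidationError("epithelial_fraction must lie in [0, 1]")
        if self.program_gene_overlap < 0 or self.program_gene_overlap >= self.program_size:
            if self.program_gene_overlap != 0:
                raise SpecValidationError("program_gene_overlap out of range")
        groups = self.composition_groups or DEFAULT_COMPOSITION_GROUPS
        for label, mix in groups.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"composition_groups[{label!r}] proportions sum to "
                    f"{total}, expected 1"
                )
        parents = self.subtype_parents or DEFAULT_SUBTYPE_PARENTS
        for label, mix in groups.items():
            orphans = sorted(set(mix) - set(parents))
            if orphans:
                raise SpecValidationError(
                    f"composition_groups[{label!r}] contains subtypes without "
                    f"a parent major type: {orphans}"
                )


@dataclass
class GroundTruth:
    """Bookkeeping of everything planted into a generated cohort."""

    planted_program_signatures: dict[str, list[str]] = field(default_factory=dict)
    cell_program_activity: dict[str, list[str]] = field(default_factory=dict)
    cell_lineage: dict[str, str] = field(default_factory=dict)
    sample_group: dict[str, str] = field(default_factory=dict)
    qc_violations: dict[str, str] = field(default_factory=dict)
    #: program id -> sample it was planted in ("*" for shared programs)
    program_sample: dict[str, str] = field(default_factory=dict)

    def shared_program_ids(self) -> list[str]:
        return [p for p, s in self.program_sample.items() if s == "*"]


def _gene_symbols(spec: CohortSpec) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Synthetic gene symbols with MT-/RPL/RPS prefixed flag blocks."""
    n_mito = max(1, round(spec.mito_gene_fraction * spec.n_genes))
    n_ribo = max(1, round(spec.ribo_gene_fraction * spec.n_genes))
    symbols: list[str] = []
    for i in range(n_mito):
        symbols.append(f"MT-G{i + 1:04d}")
    for i in range(n_ribo):
        prefix = "RPL" if i % 2 == 0 else "RPS"
        symbols.append(f"{prefix}G{i + 1:04d}")
    for i in range(spec.n_genes - n_mito - n_ribo):
        symbols.append(f"G{i + 1:06d}")
    mito = np.zeros(spec.n_genes, dtype=bool)
    mito[:n_mito] = True
    ribo = np.zeros(spec.n_genes, dtype=bool)
    ribo[n_mito : n_mito + n_ribo] = True
    return symbols, mito, ribo


def _plant_programs(
    spec: CohortSpec,
    rng: np.random.Generator,
    symbols: list[str],
    eligible: np.ndarray,
) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Draw program gene-index sets (disjoint up to ``program_gene_overlap``)."""
    n_priv_total = spec.n_private_programs_per_sample * spec.n_samples
    n_prog = spec.n_shared_programs + n_priv_total
    fresh_per_prog = spec.program_size - spec.program_gene_overlap
    needed = n_prog * fresh_per_prog
    if needed > eligible.size:
        raise SpecValidationError(
            "n_genes too small for the requested number of disjoint programs"
        )
    pool = rng.permutation(eligible)
    signatures: dict[str, np.ndarray] = {}
    program_sample: dict[str, str] = {}
    cursor = 0
    prev: np.ndarray | None = None
    names = [f"SP{i}" for i in range(spec.n_shared_programs)]
    for s in range(spec.n_samples):
        for j in range(spec.n_private_programs_per_sample):
            names.append(f"S{s:02d}_PRIV{j}")
    for name in names:
        genes = pool[cursor : cursor + fresh_per_prog]
        cursor += fresh_per_prog
        if spec.program_gene_overlap and prev is not None:
            genes = np.concatenate([genes, prev[: spec.program_gene_overlap]])
        signatures[name] = np.sort(genes)
        program_sample[name] = "*" if name.startswith("SP") else name.split("_")[0]
        prev = signatures[name]
    return signatures, program_sample


def generate_cohort(spec: CohortSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cohort and its ground truth.

    Returns an :class:`anndata.AnnData` with integer counts in ``X``, per-cell
    metadata in ``obs`` (``sample``, ``cancer_type``, ``major_type``,
    ``subtype``) and gene flags in ``var`` (``mt``, ``ribo``). Identical
    ``spec.seed`` gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    symbols, mito, ribo = _gene_symbols(spec)
    eligible = np.flatnonzero(~mito & ~ribo)

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    signatures, program_sample = _plant_programs(spec, rng, symbols, eligible)

    groups = spec.composition_groups or DEFAULT_COMPOSITION_GROUPS
    parents = spec.subtype_parents or DEFAULT_SUBTYPE_PARENTS
    group_labels = list(groups)
    lineages = list(spec.lineage_profiles) if spec.lineage_profiles else []

    gt = GroundTruth(
        planted_program_signatures={
            p: [symbols[i] for i in idx] for p, idx in signatures.items()
        },
        program_sample=program_sample,
    )

    blocks: list[sparse.csr_matrix] = []
    obs_rows: list[dict[str, str]] = []
    cell_names: list[str] = []
    effect = math.exp(spec.program_effect)

    for s in range(spec.n_samples):
        sample_id = f"S{s:02d}"
        cancer = spec.cancer_types[s % len(spec.cancer_types)]
        group = group_labels[s % len(group_labels)]
        gt.sample_group[sample_id] = group
        n_cells = int(
            rng.integers(spec.n_cells_per_sample[0], spec.n_cells_per_sample[1] + 1)
        )
        is_epi = rng.random(n_cells) < spec.epithelial_fraction
        subtypes = np.empty(n_cells, dtype=object)
        majors = np.empty(n_cells, dtype=object)
        subtypes[is_epi] = "Epithelial"
        majors[is_epi] = "Epithelial"
        n_non = int((~is_epi).sum())
        mix = groups[group]
        mix_labels = list(mix)
        draw = rng.choice(len(mix_labels), size=n_non, p=[mix[k] for k in mix_labels])
        subtypes[~is_epi] = [mix_labels[d] for d in draw]
        majors[~is_epi] = [parents[mix_labels[d]] for d in draw]

        names = [f"{sample_id}_C{i:05d}" for i in range(n_cells)]
        cell_names.extend(names)

        # mutually exclusive program activity among this sample's programs
        sample_programs = [p for p in signatures if program_sample[p] in ("*", sample_id)]
        epi_idx = np.flatnonzero(is_epi)
        shuffled = rng.permutation(epi_idx)
        n_active = round(spec.active_fraction * epi_idx.size)
        active_of = np.full(n_cells, -1, dtype=int)
        pos = 0
        for pi, prog in enumerate(sample_programs):
            chunk = shuffled[pos : pos + n_active]
            pos += n_active
            active_of[chunk] = pi
            for c in chunk:
                gt.cell_program_activity[names[c]] = [prog]

        # per-cell expected expression
        mu = np.tile(base_mean, (n_cells, 1))
        for pi, prog in enumerate(sample_programs):
            rows = np.flatnonzero(active_of == pi)
            if rows.size:
                mu[np.ix_(rows, signatures[prog])] *= effect

        if lineages:
            lin_draw = rng.integers(0, len(lineages), size=n_cells)
            for c in np.flatnonzero(is_epi):
                lin = lineages[lin_draw[c]]
                gt.cell_lineage[names[c]] = lin
                prof = np.asarray(spec.lineage_profiles[lin], dtype=float)
                mu[c] *= np.exp(prof)

        # rescale the mitochondrial block to the per-cell target UMI share
        target_mt = rng.uniform(*spec.mito_fraction_range, size=n_cells)
        non_mt_mass = mu[:, ~mito].sum(axis=1)
        mt_mass = mu[:, mito].sum(axis=1)
        scale = target_mt / (1.0 - target_mt) * non_mt_mass / mt_mass
        mu[:, mito] *= scale[:, None]

        depth = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=n_cells)
        mu *= (depth / mu.sum(axis=1))[:, None]

        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mu * spec.dispersion)
        counts = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(counts))

        for i in range(n_cells):
            obs_rows.append(
                {
                    "sample": sample_id,
                    "cancer_type": cancer,
                    "major_type": majors[i],
                    "subtype": subtypes[i],
                }
            )

    X = sparse.vstack(blocks, format="csr")
    obs = pd.DataFrame(obs_rows, index=cell_names)
    var = pd.DataFrame({"mt": mito, "ribo": ribo}, index=symbols)
    adata = ad.AnnData(X=X, obs=obs, var=var)
    return adata, gt


def generate_violating_cells(
    spec: CohortSpec,
    n_low_genes: int = 0,
    n_high_genes: int = 0,
    n_high_mito: int = 0,
    low_gene_threshold: int = 500,
    high_gene_threshold: int = 6000,
    mito_threshold: float = 0.20,
) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cohort and append cells violating one QC rule each.

    Violations are non-overlapping by construction: low-gene and high-gene
    cells carry no mitochondrial UMIs; high-mito cells detect a gene count
    safely inside the retained band.
    """
    if min(n_low_genes, n_high_genes, n_high_mito) < 0:
        raise SpecValidationError("violator counts must be non-negative")
    if n_high_genes > 0 and spec.n_genes <= high_gene_threshold:
        raise SpecValidationError(
            f"cannot plant >{high_gene_threshold}-gene cells with "
            f"n_genes={spec.n_genes}"
        )
    adata, gt = generate_cohort(spec)
    if n_low_genes == n_high_genes == n_high_mito == 0:
        return adata, gt

    mito = adata.var["mt"].to_numpy()
    non_mito = np.flatnonzero(~mito)
    mito_idx = np.flatnonzero(mito)
    n_genes = adata.n_vars
    rows = []
    labels = []
    kinds = []

    n_low_detected = min(max(low_gene_threshold // 5, 1), low_gene_threshold - 1)
    for i in range(n_low_genes):
        row = np.zeros(n_genes, dtype=np.int64)
        row[non_mito[:n_low_detected]] = 2
        rows.append(row)
        labels.append(f"VIOL_LOW_{i:03d}")
        kinds.append("low_genes")
    if n_high_genes > 0 and non_mito.size <= high_gene_threshold:
        raise SpecValidationError(
            "not enough non-mitochondrial genes to plant a high-gene cell: "
            f"n_genes={spec.n_genes}"
        )
    for i in range(n_high_genes):
        row = np.zeros(n_genes, dtype=np.int64)
        row[non_mito[: high_gene_threshold + 1]] = 1
        rows.append(row)
        labels.append(f"VIOL_HIGH_{i:03d}")
        kinds.append("high_genes")
    n_mid_detected = min(2 * low_gene_threshold, high_gene_threshold - 1)
    for i in range(n_high_mito):
        row = np.zeros(n_genes, dtype=np.int64)
        row[non_mito[:n_mid_detected]] = 2
        # mito share just above threshold: mito UMIs = 0.5 * non-mito UMIs
        per_gene = max(1, math.ceil(n_mid_detected / mito_idx.size))
        row[mito_idx] = per_gene
        rows.append(row)
        labels.append(f"VIOL_MITO_{i:03d}")
        kinds.append("high_mito")

    extra_X = sparse.csr_matrix(np.vstack(rows))
    first = adata.obs.iloc[0]
    extra_obs = pd.DataFrame(
        {
            "sample": first["sample"],
            "cancer_type": first["cancer_type"],
            "major_type": "Epithelial",
            "subtype": "Epithelial",
        },
        index=labels,
    )
    out = ad.AnnData(
        X=sparse.vstack([adata.X, extra_X], format="csr"),
        obs=pd.concat([adata.obs, extra_obs]),
        var=adata.var.copy(),
    )
    for lab, kind in zip(labels, kinds):
        gt.qc_violations[lab] = kind
    return out, gt


def generate_lineage_cells(
    profiles: pd.DataFrame,
    n_cells_per_lineage: int,
    noise_sd: float,
    seed: int = 0,
    n_background_cells: int = 0,
    background_mixture: list[str] | None = None,
    background_sd: float = 0.4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells drawn as reference lineage profiles plus Gaussian log-scale noise.

    ``profiles`` is genes x lineages (log-normalized means); each generated
    cell is one lineage's profile plus N(0, ``noise_sd``) noise, clipped at
    zero.  ``n_background_cells`` appends cells without a single lineage
    identity (ground-truth label ``"background"``): a flat mixture of the
    ``background_mixture`` profiles (default: all) blurred with the larger
    ``background_sd``, leaving them weakly and diffusely correlated with the
    mixture's lineages and uncorrelated with the rest.  Returns
    (cells x genes, labels).
    """
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for lin in profiles.columns:
        base = profiles[lin].to_numpy(dtype=float)
        for i in range(n_cells_per_lineage):
            rows.append(np.clip(base + rng.normal(0.0, noise_sd, base.size), 0, None))
            labels.append(lin)
    if n_background_cells:
        mix_cols = background_mixture or list(profiles.columns)
        base = profiles[mix_cols].mean(axis=1).to_numpy(dtype=float)
        for i in range(n_background_cells):
            rows.append(np.clip(base + rng.normal(0.0, background_sd, base.size), 0, None))
            labels.append("background")
    idx = [f"L{i:05d}" for i in range(len(rows))]
    cells = pd.DataFrame(np.asarray(rows), index=idx, columns=profiles.index)
    return cells, pd.Series(labels, index=idx, name="lineage")


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=seed)
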