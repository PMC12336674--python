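"""Per-sample NMF program discovery and the three-criterion robustness filter.

Each sample's epithelial cells are factorized independently with
non-negative matrix factorization over an exhaustive K sweep (K = 4..9 by
default, yielding 4+5+...+9 = 39 factors per sample).  A factor is
summarized by its 50 highest-loading genes ("program").  Programs are then
screened for

1. **within-tumour robustness** — at least one other program of the same
   sample shares >= 50% of signature genes (factors recurring across K),
2. **cross-tumour recurrence** — shares >= 20% of signature genes with some
   program from a different sample,
3. **within-tumour non-redundancy** — among a sample's survivors, a program
   is dropped if it shares > 20% of signature genes with an already-selected
   program of the same sample.

"Share" here is the shared-gene fraction of the (fixed) signature size.
Criterion 3 is a greedy selection; candidates are visited in order of
decreasing cross-sample support, breaking ties by the larger maximal
within-sample share and then lexicographically by (sample, K, factor), so
the result is independent of input ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning


@dataclass
class FactorizationConfig:
    k_min: int = 4
    k_max: int = 9
    n_top_genes_input: int = 7000
    signature_size: int = 50
    within_tumour_min_share: float = 0.50
    cross_tumour_min_share: float = 0.20
    redundancy_max_share: float = 0.20
    min_within_partners: int = 1
    seed: int = 0
    max_iter: int = 400
    tol: float = 1e-4
    epithelial_label: str = "Epithelial"

    def __post_init__(self) -> None:
        if self.k_min > self.k_max or self.k_min < 1:
            raise ValueError("require 1 <= k_min <= k_max")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        for name in (
            "within_tumour_min_share",
            "cross_tumour_min_share",
            "redundancy_max_share",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class NMFProgram:
    """One factor of one sample's factorization, as a ranked gene signature."""

    sample_id: str
    k: int
    factor_index: int
    genes: tuple[str, ...]
    weights: tuple[float, ...]

    @property
    def key(self) -> str:
        return f"{self.sample_id}|K{self.k}|F{self.factor_index}"

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class RobustProgramSet:
    programs: list[NMFProgram]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.programs)


def prepare_sample_matrix(
    norm: ad.AnnData, sample_id: str, cfg: FactorizationConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build the non-negative cells x genes input for one sample's NMF.

    Subsets to the sample's epithelial cells, drops mitochondrial/ribosomal
    genes (by ``var`` flags, falling back to MT-/RPL/RPS symbol prefixes),
    keeps the ``n_top_genes_input`` genes with the highest mean normalized
    expression within the sample, z-scores each gene across the sample's
    cells and clips negative values to zero.  Zero-variance genes z-score to
    all-zero columns.
    """
    cfg = cfg or FactorizationConfig()
    mask = (norm.obs["sample"] == sample_id) & (
        norm.obs["major_type"] == cfg.epithelial_label
    )
    sub = norm[mask.to_numpy()]
    if sub.n_obs < cfg.k_max:
        raise ValueError(
            f"sample {sample_id!r} has {sub.n_obs} epithelial cells, "
            f"fewer than k_max={cfg.k_max}: factorization underdetermined"
        )
    if "mt" in sub.var:
        drop = sub.var["mt"].to_numpy() | sub.var.get(
            "ribo", pd.Series(False, index=sub.var_names)
        ).to_numpy()
    else:
        drop = np.zeros(sub.n_vars, dtype=bool)
    drop |= np.asarray(sub.var_names.str.startswith(("MT-", "RPL", "RPS")))
    sub = sub[:, ~drop]

    X = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X, dtype=float)
    mean = X.mean(axis=0)
    if sub.n_vars > cfg.n_top_genes_input:
        # stable top-N: mean descending, gene symbol ascending on ties
        order = np.lexsort((sub.var_names.to_numpy(), -mean))
        keep = np.sort(order[: cfg.n_top_genes_input])
        X = X[:, keep]
        genes = list(sub.var_names[keep])
        mean = mean[keep]
    else:
        genes = list(sub.var_names)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.clip(Z, 0.0, None), genes


def run_nmf_sweep(
    x: np.ndarray,
    genes: list[str],
    sample_id: str,
    cfg: FactorizationConfig | None = None,
) -> list[NMFProgram]:
    """Fit rank-K NMF for every K in the sweep; emit one program per factor.

    Signature = the ``signature_size`` genes with the highest loading in the
    factor's gene vector, ordered by decreasing loading (ties by gene
    symbol).  Non-convergence leaves a warning and the final iterate is used.
    """
    cfg = cfg or FactorizationConfig()
    gene_arr = np.asarray(genes)
    programs: list[NMFProgram] = []
    for k in range(cfg.k_min, cfg.k_max + 1):
        model = NMF(
            n_components=k,
            init="random",
            random_state=cfg.seed,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x)
        H = model.components_  # k x genes loadings
        for f in range(k):
            load = H[f]
            order = np.lexsort((gene_arr, -load))[: cfg.signature_size]
            programs.append(
                NMFProgram(
                    sample_id=sample_id,
                    k=k,
                    factor_index=f,
                    genes=tuple(str(g) for g in gene_arr[order]),
                    weights=tuple(float(v) for v in load[order]),
                )
            )
    return programs


def nmf_programs_for_samples(
    norm: ad.AnnData, samples: list[str], cfg: FactorizationConfig | None = None
) -> list[NMFProgram]:
    """Convenience: prepare + sweep for each retained sample."""
    cfg = cfg or FactorizationConfig()
    out: list[NMFProgram] = []
    for s in samples:
        x, genes = prepare_sample_matrix(norm, s, cfg)
        out.extend(run_nmf_sweep(x, genes, s, cfg))
    return out


def program_share(a: NMFProgram, b: NMFProgram, signature_size: int | None = None) -> float:
    """Shared-gene fraction |genes(a) n genes(b)| / signature_size."""
    size = signature_size or max(len(a.genes), len(b.genes))
    return len(a.gene_set & b.gene_set) / size


def filter_robust(
    programs: list[NMFProgram], cfg: FactorizationConfig | None = None
) -> RobustProgramSet:
    """Apply the three robustness criteria; see the module docstring."""
    cfg = cfg or FactorizationConfig()
    n = len(programs)
    if n == 0:
        return RobustProgramSet(programs=[], provenance=pd.DataFrame())

    sets = [p.gene_set for p in programs]
    samples = np.asarray([p.sample_id for p in programs])
    share = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            share[i, j] = share[j, i] = (
                len(sets[i] & sets[j]) / cfg.signature_size
            )

    same = samples[:, None] == samples[None, :]
    np.fill_diagonal(same, False)
    other = samples[:, None] != samples[None, :]

    passed_within = (
        ((share >= cfg.within_tumour_min_share) & same).sum(axis=1)
        >= cfg.min_within_partners
    )
    cross_support = ((share >= cfg.cross_tumour_min_share) & other).sum(axis=1)
    passed_cross = passed_within & (cross_support >= 1)
    max_within = np.where(same, share, -np.inf).max(axis=1)

    selected = np.zeros(n, dtype=bool)
    removed_redundant = np.zeros(n, dtype=bool)
    for sample in sorted(set(samples)):
        cand = [i for i in np.flatnonzero(passed_cross) if samples[i] == sample]
        cand.sort(
            key=lambda i: (
                -cross_support[i],
                -max_within[i],
                programs[i].sample_id,
                programs[i].k,
                programs[i].factor_index,
            )
        )
        chosen: list[int] = []
        for i in cand:
            if any(share[i, j] > cfg.redundancy_max_share for j in chosen):
                removed_redundant[i] = True
            else:
                chosen.append(i)
                selected[i] = True

    prov = pd.DataFrame(
        {
            "sample": samples,
            "passed_within": passed_within,
            "passed_cross": passed_cross,
            "cross_support": cross_support,
            "removed_redundant": removed_redundant,
            "selected": selected,
        },
        index=[p.key for p in programs],
    )
    kept = [programs[i] for i in np.flatnonzero(selected)]
    return RobustProgramSet(programs=kept, provenance=prov)
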