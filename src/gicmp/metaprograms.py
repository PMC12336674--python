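"""Meta-program construction, abundance statistics and functional annotation.

Robust per-sample NMF programs are clustered on Jaccard distance
(average-linkage hierarchical clustering on 1 - Jaccard, cut to a requested
number of meta-programs or at a distance threshold).  Each meta-program
(MP) is summarized by a consensus signature built from the genes most
frequently shared among member programs.

The per-cancer-type abundance of an MP is the statistic

    A = log2((observed + 1) / (expected + 1))

where *observed* counts the MP's member programs from that cancer type and
*expected* is the MP's size times the cancer type's share of all robust
programs.  Significance comes from a two-sided binomial test of the
observed count against that share, Bonferroni-adjusted over all (MP, cancer
type) pairs, and A is binned into absence (observed = 0) / low (A < 1) /
medium (1 <= A < 2) / high (A >= 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import binomtest, hypergeom
from statsmodels.stats.multitest import multipletests

from .factorization import NMFProgram, RobustProgramSet


@dataclass
class MetaProgram:
    mp_id: str
    member_programs: list[NMFProgram]
    signature: list[str] = field(default_factory=list)
    annotation: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_programs)


def jaccard_matrix(programs: RobustProgramSet | list[NMFProgram]) -> pd.DataFrame:
    """Pairwise Jaccard index of program gene sets (unit diagonal)."""
    progs = programs.programs if isinstance(programs, RobustProgramSet) else programs
    if len(progs) < 2:
        raise ValueError("need at least two programs")
    n = len(progs)
    sets = [p.gene_set for p in progs]
    J = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            J[i, j] = J[j, i] = inter / union if union else 0.0
    keys = [p.key for p in progs]
    return pd.DataFrame(J, index=keys, columns=keys)


def cluster_metaprograms(
    programs: RobustProgramSet | list[NMFProgram],
    n_mps: int | None = None,
    distance_threshold: float | None = None,
    curation: dict | None = None,
    linkage: str = "average",
    consensus_size: int = 50,
) -> list[MetaProgram]:
    """Cluster robust programs into meta-programs.

    Exactly one of ``n_mps`` / ``distance_threshold`` selects the cut.
    ``curation`` replaces interactive curation with declarative overrides:
    ``{"merge": [[labelA, labelB], ...], "reassign": {program_key: label}}``
    operating on the raw cluster labels.  MPs are numbered MP1, MP2, ... in
    decreasing size (ties by smallest member key) and each receives a
    consensus signature.
    """
    progs = programs.programs if isinstance(programs, RobustProgramSet) else programs
    if n_mps is not None and n_mps > len(progs):
        raise ValueError(f"n_mps={n_mps} exceeds program count {len(progs)}")
    if len(progs) == 1:
        labels = np.array([1])
    else:
        J = jaccard_matrix(progs).to_numpy()
        D = 1.0 - J
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
        if n_mps is not None:
            labels = hierarchy.fcluster(Z, t=n_mps, criterion="maxclust")
        elif distance_threshold is not None:
            labels = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
        else:
            raise ValueError("provide n_mps or distance_threshold")

    labels = labels.astype(object)
    if curation:
        for pair in curation.get("merge", []):
            a, b = pair
            labels[labels == b] = a
        for key, lab in curation.get("reassign", {}).items():
            idx = [i for i, p in enumerate(progs) if p.key == key]
            if not idx:
                raise KeyError(f"unknown program key {key!r} in curation")
            labels[idx[0]] = lab

    groups: dict[object, list[NMFProgram]] = {}
    for p, lab in zip(progs, labels):
        groups.setdefault(lab, []).append(p)
    ordered = sorted(
        groups.values(), key=lambda ms: (-len(ms), min(p.key for p in ms))
    )
    mps = []
    for i, members in enumerate(ordered, start=1):
        mp = MetaProgram(mp_id=f"MP{i}", member_programs=members)
        mp.signature = consensus_signature(mp, size=consensus_size)
        mps.append(mp)
    return mps


def consensus_signature(mp: MetaProgram, size: int = 50) -> list[str]:
    """Most frequently shared genes across an MP's member programs.

    Genes are ranked by (occurrence count across members, mean within-member
    weight rank, gene symbol); for MPs with >= 2 members only genes occurring
    in at least two members qualify, so the signature may be shorter than
    ``size``.  A single-member MP keeps its member's signature.
    """
    members = mp.member_programs
    if not members:
        raise ValueError(f"{mp.mp_id} has no member programs")
    if len(members) == 1:
        return list(members[0].genes[:size])
    count: Counter = Counter()
    rank_sum: Counter = Counter()
    for m in members:
        for r, g in enumerate(m.genes):
            count[g] += 1
            rank_sum[g] += r
    candidates = [g for g, c in count.items() if c >= 2]
    candidates.sort(key=lambda g: (-count[g], rank_sum[g] / count[g], g))
    return candidates[:size]


LEVELS = ("absence", "low", "medium", "high")


def abundance(contingency: pd.DataFrame) -> pd.DataFrame:
    """Per-(MP, cancer type) abundance table from robust program counts.

    ``contingency`` is MPs x cancer types of member-program counts.  Returns
    a long-form frame with observed, expected, A, p, p_adj (Bonferroni),
    level and significance (p_adj < 0.05).  Boundary values A = 1 and A = 2
    fall into the higher level.
    """
    counts = contingency.to_numpy(dtype=float)
    if counts.min() < 0:
        raise ValueError("contingency counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("contingency table is all zero")
    mp_totals = counts.sum(axis=1)
    ct_share = counts.sum(axis=0) / total

    rows = []
    for i, mp in enumerate(contingency.index):
        for j, ct in enumerate(contingency.columns):
            o = counts[i, j]
            e = mp_totals[i] * ct_share[j]
            A = np.log2((o + 1.0) / (e + 1.0))
            if mp_totals[i] > 0 and 0.0 < ct_share[j] < 1.0:
                p = binomtest(
                    int(o), n=int(mp_totals[i]), p=ct_share[j], alternative="two-sided"
                ).pvalue
            else:
                p = 1.0
            if o == 0:
                level = "absence"
            elif A >= 2:
                level = "high"
            elif A >= 1:
                level = "medium"
            else:
                level = "low"
            rows.append(
                {
                    "mp_id": mp,
                    "cancer_type": ct,
                    "observed": int(o),
                    "expected": e,
                    "A": A,
                    "p": p,
                    "level": level,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    out["significant"] = out["p_adj"] < 0.05
    return out


def program_contingency(mps: list[MetaProgram], sample_cancer: dict[str, str]) -> pd.DataFrame:
    """MPs x cancer types counts of member programs, from sample metadata."""
    cancers = sorted(set(sample_cancer.values()))
    table = pd.DataFrame(
        0, index=[mp.mp_id for mp in mps], columns=cancers, dtype=int
    )
    for mp in mps:
        for p in mp.member_programs:
            table.loc[mp.mp_id, sample_cancer[p.sample_id]] += 1
    return table


def enrich_hypergeometric(
    signature: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    For each gene set, tests whether the overlap with ``signature`` is larger
    than expected when drawing ``len(signature)`` genes from ``universe``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    sig = set(signature)
    if not sig <= uni:
        missing = sorted(sig - uni)[:5]
        raise ValueError(f"signature genes absent from universe: {missing} ...")
    M, N = len(uni), len(sig)
    rows = []
    for name, genes in gene_sets.items():
        K = len(set(genes) & uni)
        k = len(set(genes) & sig)
        p = float(hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        rows.append({"gene_set": name, "overlap": k, "set_size": K, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values(["p", "gene_set"]).reset_index(drop=True)
    return out
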