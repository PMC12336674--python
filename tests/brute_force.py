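"""Plain-loop reference implementations used as oracles in tests.

Deliberately written without numpy or shared share-matrix code so they stay
independent of the library's vectorized implementations.
"""

from __future__ import annotations


def brute_force_robust(programs, cfg):
    """Literal application of the three robustness rules to a program list.

    Returns the set of program keys that survive.  ``programs`` is a list of
    NMFProgram; ``cfg`` a FactorizationConfig.
    """

    def share(a, b):
        return len(set(a.genes) & set(b.genes)) / cfg.signature_size

    # rule 1: at least min_within_partners other same-sample programs >= 50%
    within = set()
    for p in programs:
        partners = [
            q
            for q in programs
            if q is not p
            and q.sample_id == p.sample_id
            and share(p, q) >= cfg.within_tumour_min_share
        ]
        if len(partners) >= cfg.min_within_partners:
            within.add(p.key)

    # rule 2: >= 20% share with some program of another sample
    def cross_support(p):
        return sum(
            1
            for q in programs
            if q.sample_id != p.sample_id and share(p, q) >= cfg.cross_tumour_min_share
        )

    candidates = [p for p in programs if p.key in within and cross_support(p) >= 1]

    def max_within_share(p):
        vals = [
            share(p, q)
            for q in programs
            if q is not p and q.sample_id == p.sample_id
        ]
        return max(vals) if vals else float("-inf")

    # rule 3: per-sample greedy by decreasing cross support
    survivors = set()
    for sample in sorted({p.sample_id for p in candidates}):
        cand = [p for p in candidates if p.sample_id == sample]
        cand.sort(
            key=lambda p: (
                -cross_support(p),
                -max_within_share(p),
                p.sample_id,
                p.k,
                p.factor_index,
            )
        )
        chosen = []
        for p in cand:
            if all(share(p, q) <= cfg.redundancy_max_share for q in chosen):
                chosen.append(p)
                survivors.add(p.key)
    return survivors


def brute_force_auc(expr, genes, gene_set, threshold_fraction):
    """Recovery-curve AUC by direct enumeration of the top-r prefixes."""
    import math

    order = sorted(range(len(genes)), key=lambda i: (-expr[i], genes[i]))
    members = set(gene_set)
    k = math.ceil(threshold_fraction * len(genes))
    s = len(members & set(genes))
    auc = 0
    hits = 0
    for r in range(1, k + 1):
        if genes[order[r - 1]] in members:
            hits += 1
        auc += hits
    max_auc = sum(min(r, s) for r in range(1, k + 1))
    return auc / max_auc


def random_program_collection(rng, n_samples, n_programs_per_sample, pool_size, sig_size):
    """Random overlapping program collections for oracle comparisons."""
    from gicmp.factorization import NMFProgram

    pool = [f"g{i:03d}" for i in range(pool_size)]
    programs = []
    for s in range(n_samples):
        for j in range(n_programs_per_sample):
            genes = list(rng.choice(pool, size=sig_size, replace=False))
            k = 2 + j // 3
            programs.append(
                NMFProgram(
                    sample_id=f"S{s}",
                    k=k,
                    factor_index=j % 3,
                    genes=tuple(genes),
                    weights=tuple(float(sig_size - i) for i in range(sig_size)),
                )
            )
    return programs
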