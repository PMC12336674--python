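"""End-to-end meta-program discovery on a cohort.

Thin orchestration over the module functions: QC -> normalization ->
sample selection -> per-sample NMF sweep -> robustness filter -> MP
clustering -> consensus signatures -> cell scoring and identity
assignment.  Returned as a plain dict so callers can pick what they need.
"""

from __future__ import annotations

import anndata as ad

from . import factorization as fx
from . import metaprograms as mp
from . import preprocessing as pp
from . import scoring as sc


def discover_metaprograms(
    adata: ad.AnnData,
    n_mps: int | None = None,
    distance_threshold: float | None = 0.8,
    qc_cfg: pp.QCConfig | None = None,
    fac_cfg: fx.FactorizationConfig | None = None,
    threshold_fraction: float = 0.05,
) -> dict:
    """Run the full discovery pipeline on raw counts.

    The meta-program cut is controlled by exactly one of ``n_mps`` (fixed
    cluster count, the paper-style curated cut) or ``distance_threshold``
    (cut the average-linkage tree where clusters stop sharing >= 20% average
    Jaccard by default — robust to stray singleton programs).

    Returns a dict with keys ``adata`` (normalized, QC-passed), ``report``,
    ``samples``, ``programs``, ``robust``, ``mps``, ``scores`` and
    ``abundance``.
    """
    if n_mps is not None:
        distance_threshold = None
    qc_cfg = qc_cfg or pp.QCConfig()
    fac_cfg = fac_cfg or fx.FactorizationConfig()

    filtered, report = pp.filter_cells(adata, qc_cfg)
    filtered = pp.filter_genes(filtered, qc_cfg, report)
    norm = pp.normalize(filtered)
    samples = pp.select_samples(norm, qc_cfg, report)

    programs = fx.nmf_programs_for_samples(norm, samples, fac_cfg)
    robust = fx.filter_robust(programs, fac_cfg)
    mps = mp.cluster_metaprograms(
        robust,
        n_mps=n_mps,
        distance_threshold=distance_threshold,
        consensus_size=fac_cfg.signature_size,
    )
    scores = sc.score_matrix(norm, mps, threshold_fraction=threshold_fraction)

    sample_cancer = (
        norm.obs.drop_duplicates("sample").set_index("sample")["cancer_type"].to_dict()
    )
    contingency = mp.program_contingency(mps, sample_cancer)
    abundance = mp.abundance(contingency)

    return {
        "adata": norm,
        "report": report,
        "samples": samples,
        "programs": programs,
        "robust": robust,
        "mps": mps,
        "scores": scores,
        "contingency": contingency,
        "abundance": abundance,
    }
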