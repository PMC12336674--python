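"""Reading and writing the standard on-disk formats.

Cohorts are stored in the familiar 10x-style triplet layout: ``matrix.mtx``
(genes x cells, Matrix Market), ``barcodes.tsv``, ``features.tsv`` (id,
symbol, feature type) plus a ``cells.tsv`` with per-cell metadata.  Gene
programs and meta-program signatures travel as GMT; reference lineage
profiles as three-column TSV (lineage, gene, weight).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse


def write_cohort(adata: ad.AnnData, outdir: str | Path, ground_truth=None) -> Path:
    """Write an AnnData cohort as MTX + TSV (and ground truth as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(outdir / "matrix.mtx"), sparse.csc_matrix(adata.X.T))
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    feats = pd.DataFrame(
        {
            "id": adata.var_names,
            "symbol": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    if ground_truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(dataclasses.asdict(ground_truth), fh)
    return outdir


def read_cohort(indir: str | Path) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(str(indir / "matrix.mtx")).T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var = pd.DataFrame(index=feats[1].astype(str))
    var["mt"] = var.index.str.startswith("MT-")
    var["ribo"] = var.index.str.startswith(("RPL", "RPS"))
    adata = ad.AnnData(X=X, obs=obs.loc[barcodes.astype(str)], var=var)
    return adata


def write_spec(spec, path: str | Path) -> None:
    d = dataclasses.asdict(spec)
    d.pop("lineage_profiles", None)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def read_spec(path: str | Path):
    from .simulate import CohortSpec

    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("n_cells_per_sample", "depth_range", "mito_fraction_range", "cancer_types"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return CohortSpec(**d)


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    """Write gene sets as GMT; values are (description, genes)."""
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into name -> gene list (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_reference_tsv(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write genes x lineages profiles as long-form TSV (lineage, gene, weight)."""
    long = profiles.stack().rename("weight").reset_index()
    long.columns = ["gene", "lineage", "weight"]
    long[["lineage", "gene", "weight"]].to_csv(path, sep="\t", index=False)


def read_reference_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-form reference TSV back into a genes x lineages frame."""
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="gene", columns="lineage", values="weight").fillna(0.0)
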