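"""Readers and writers for the plain-text exchange formats.

scRNA-seq counts travel as 10x-style Matrix Market triplets (genes x cells
``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) with a ``cells.tsv``
metadata table; DSP tables as ``probe_counts.tsv`` / ``probe_map.tsv`` /
``aoi_metadata.tsv``; gene lists as one gene per line. All writers use fixed
float formatting so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio, sparse

from .dsp import ProbeCountTable

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_sc_mtx(adata: AnnData, outdir) -> None:
    """Write counts in the 10x triplet layout (genes x cells) plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    counts = x.T.tocsc() if sparse.issparse(x) else sparse.csc_matrix(np.asarray(x).T)
    spio.mmwrite(outdir / "matrix.mtx", counts.astype(int))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    write_table(adata.obs, outdir / "cells.tsv")


def read_sc_mtx(indir) -> AnnData:
    indir = Path(indir)
    counts = spio.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    obs = pd.DataFrame(index=barcodes)
    cells_path = indir / "cells.tsv"
    if cells_path.exists():
        obs = pd.read_csv(cells_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes))


def write_dsp(table: ProbeCountTable, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(table.counts, outdir / "probe_counts.tsv")
    probe_map = pd.DataFrame({"gene": table.probe_map, "pool": table.pool})
    probe_map.index.name = "probe"
    write_table(probe_map, outdir / "probe_map.tsv")
    write_table(table.aoi_meta, outdir / "aoi_metadata.tsv")


def read_dsp(indir) -> ProbeCountTable:
    indir = Path(indir)
    counts = pd.read_csv(indir / "probe_counts.tsv", sep="\t", index_col=0)
    probe_map = pd.read_csv(indir / "probe_map.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "aoi_metadata.tsv", sep="\t", index_col=0)
    table = ProbeCountTable(counts=counts, probe_map=probe_map["gene"],
                            pool=probe_map["pool"], aoi_meta=meta)
    table.validate()
    return table


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]


def read_positions(path) -> pd.DataFrame:
    pos = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start"}
    if not required.issubset(pos.columns):
        raise ValueError(f"positions table needs columns {sorted(required)}")
    return pos


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, (pd.Index,)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
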