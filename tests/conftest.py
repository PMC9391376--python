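import warnings

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from bccniche import (CNVSegment, PipelineConfig, SimConfig, run_all)
from bccniche.dsp import ProbeCountTable

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down study for fast unit tests (same structure, fewer cells)."""
    base = dict(
        n_cells_per_type={"tumor": 120, "basal_keratinocyte": 60,
                          "diff_keratinocyte": 60, "fibroblast": 80,
                          "t_cell": 80},
        n_genes=400,
        n_program_genes=10,
        n_marker_genes=5,
        n_mito_genes=5,
        n_dissoc_genes=5,
        cnv_segments=(CNVSegment(chrom=1, start=2, length=10, multiplier=2.0),),
        n_aoi_per_group=6,
        probes_per_gene=3,
        aoi_depth=5.0e4,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def make_adata(x, gene_ids=None, cell_ids=None, obs=None) -> AnnData:
    x = np.asarray(x)
    n, m = x.shape
    gene_ids = gene_ids or [f"g{j:03d}" for j in range(m)]
    cell_ids = cell_ids or [f"c{i:03d}" for i in range(n)]
    obs = obs if obs is not None else pd.DataFrame(index=cell_ids)
    obs.index = cell_ids
    return AnnData(X=sparse.csr_matrix(x), obs=obs,
                   var=pd.DataFrame(index=gene_ids))


def make_probe_table(counts: dict, probe_gene: dict, probe_pool=None,
                     aoi_meta=None) -> ProbeCountTable:
    """Build a ProbeCountTable from {aoi: {probe: count}} dictionaries."""
    df = pd.DataFrame(counts).T
    probes = df.columns
    pool = pd.Series(probe_pool or {p: "P1" for p in probes}).reindex(probes)
    if aoi_meta is None:
        aoi_meta = pd.DataFrame({
            "sample": "s1", "compartment": "tumor", "morphology": "nodular",
            "total_reads": df.sum(axis=1).astype(int),
        }, index=df.index)
    return ProbeCountTable(counts=df,
                           probe_map=pd.Series(probe_gene).reindex(probes),
                           pool=pool, aoi_meta=aoi_meta)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across unit tests."""
    import bccniche as bn
    cfg = small_sim_config(seed=11)
    adata, truth = bn.simulate_sc_counts(cfg)
    table, truth = bn.simulate_dsp_probes(cfg, truth)
    return cfg, adata, table, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """A full default pipeline run (the study conditions), shared."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(outdir=str(outdir), seed=1)
    return cfg, run_all(cfg)
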