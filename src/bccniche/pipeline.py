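"""End-to-end orchestration: simulate (or load) → scRNA QC/clustering →
CNV → DSP → signature filtering → niche mapping → trajectory, with a JSON
manifest recording every artifact, parameter and seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import dsp as dsp_mod
from . import io as io_mod
from . import niche as niche_mod
from . import sc as sc_mod
from . import sigfilter as filt_mod
from . import trajectory as traj_mod
from .config import ConfigurationError, QCParams, SimConfig
from .simulate import (EPITHELIAL_TYPES, simulate_dsp_probes, simulate_sc_counts)

logger = logging.getLogger(__name__)

_STAGES = ("simulate_sc", "simulate_dsp", "sc", "cnv", "dsp", "filter",
           "niche", "trajectory")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: base * 10007 + stage index, mod 2^31."""
    return (base_seed * 10007 + _STAGES.index(stage)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Single configuration driving :func:`run_all`."""

    outdir: str = "bccniche_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # paths used when simulate is False
    sc_dir: Optional[str] = None
    dsp_dir: Optional[str] = None
    positions_path: Optional[str] = None
    marker_map_path: Optional[str] = None

    # scRNA-seq stage
    qc: QCParams = field(default_factory=QCParams)
    n_hvgs: int = 2000
    n_pcs: int = 25
    resolution: float = 0.8
    tumor_resolution: float = 1.0
    fibro_resolution: float = 0.3
    doublet_pairs: tuple = (("KRT14", "CD3E"),)

    # CNV stage
    cnv_window: int = 101
    cnv_min_ref_mean: float = 0.1
    cnv_clamp: float = 1.0
    shared_threshold: float = 0.15

    # DSP stage
    min_reads: int = 10_000
    grubbs_alpha: float = 0.01
    grubbs_global_fraction: float = 0.20
    dsp_log2fc_cut: float = 0.4
    dsp_p_cut: float = 0.05

    # signature filter
    f_on: float = 0.10
    r_max: float = 3.0
    u_min: float = 0.25

    # scoring / trajectory
    score_n_bins: int = 24
    score_n_ctrl: int = 100
    knn_k: int = 20
    morans_cutoff: float = 0.1

    def validate(self) -> None:
        self.qc.validate()
        if self.simulate:
            self.sim.validate()
        else:
            for name in ("sc_dir", "dsp_dir", "positions_path"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"{name} missing or absent: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        if "qc" in raw:
            raw["qc"] = QCParams(**raw["qc"])
        if "doublet_pairs" in raw:
            raw["doublet_pairs"] = tuple(tuple(p) for p in raw["doublet_pairs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["doublet_pairs"] = [list(p) for p in self.doublet_pairs]
        return d


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Reruns with an identical configuration produce byte-identical artifacts.
    Stage failures abort with the stage name in the exception message.
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": cfg.to_dict(), "seed": cfg.seed,
                      "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
                      "artifacts": {}, "metrics": {}}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path.relative_to(out))

    stage = "simulate_sc"
    try:
        # ------------------------------------------------------------------
        # data
        truth = None
        if cfg.simulate:
            sim = SimConfig.from_dict({**cfg.sim.to_dict(),
                                       "seed": stage_seed(cfg.seed, "simulate_sc")})
            adata, truth = simulate_sc_counts(sim)
            stage = "simulate_dsp"
            dsp_table, truth = simulate_dsp_probes(
                sim, truth, seed=stage_seed(cfg.seed, "simulate_dsp"))
            positions = truth.gene_positions
            marker_map = truth.marker_map
            mito = truth.mito_genes
            dissoc = truth.dissoc_genes
            sc_dir = out / "sc_input"
            io_mod.write_sc_mtx(adata, sc_dir)
            record("sc_counts", sc_dir / "matrix.mtx")
            dsp_dir = out / "dsp_input"
            io_mod.write_dsp(dsp_table, dsp_dir)
            record("dsp_counts", dsp_dir / "probe_counts.tsv")
            io_mod.write_table(positions, out / "gene_positions.tsv", index=False)
            record("gene_positions", out / "gene_positions.tsv")
            truth.to_json(out / "truth.json")
            record("truth", out / "truth.json")
        else:
            adata = io_mod.read_sc_mtx(cfg.sc_dir)
            dsp_table = io_mod.read_dsp(cfg.dsp_dir)
            positions = io_mod.read_positions(cfg.positions_path)
            with open(cfg.marker_map_path) as fh:
                marker_map = yaml.safe_load(fh)
            mito = [g for g in adata.var_names if g.startswith("MT-")]
            dissoc = list(cfg.qc.dissoc_genes)

        # ------------------------------------------------------------------
        # scRNA-seq core
        stage = "sc"
        seed_sc = stage_seed(cfg.seed, "sc")
        qc = QCParams(min_genes=cfg.qc.min_genes, max_genes=cfg.qc.max_genes,
                      max_mito_frac=cfg.qc.max_mito_frac,
                      max_dissoc_frac=cfg.qc.max_dissoc_frac,
                      mito_genes=mito, dissoc_genes=dissoc)
        adata = sc_mod.filter_cells(adata, qc)
        norm = sc_mod.lognormalize(adata)
        hvgs = sc_mod.select_hvgs(norm, n=cfg.n_hvgs)
        clusters, pcs = sc_mod.embed_and_cluster(
            norm, hvgs, n_pcs=cfg.n_pcs, resolution=cfg.resolution, seed=seed_sc)
        doublet_flags = sc_mod.flag_doublet_clusters(
            norm, clusters, [tuple(p) for p in cfg.doublet_pairs])
        annotation = sc_mod.annotate_clusters(norm, clusters, marker_map)
        keep = ~np.isin(clusters, [c for c, bad in doublet_flags.items() if bad])
        norm = norm[keep].copy()
        clusters = clusters[keep]
        pcs = pcs[keep]
        cell_types = pd.Series([annotation[int(c)] for c in clusters],
                               index=norm.obs_names, name="cell_type")
        norm.obs["cluster"] = clusters
        norm.obs["cell_type"] = cell_types
        lisi = sc_mod.lisi_score(pcs, norm.obs["sample"],
                                 k=min(30, norm.n_obs - 1))
        manifest["metrics"]["n_cells_qc"] = int(norm.n_obs)
        manifest["metrics"]["n_clusters"] = int(len(np.unique(clusters)))
        manifest["metrics"]["mean_lisi"] = float(lisi.mean())
        io_mod.write_table(norm.obs, out / "cell_metadata.tsv")
        record("cell_metadata", out / "cell_metadata.tsv")

        # ------------------------------------------------------------------
        # CNV inference
        stage = "cnv"
        ref_cells = norm.obs_names[cell_types == "t_cell"]
        epi_types = [t for t in cell_types.unique() if t in EPITHELIAL_TYPES]
        counts_adata = adata[norm.obs_names].copy()
        ref_mean = np.asarray(
            counts_adata[counts_adata.obs_names.isin(ref_cells)].X.mean(axis=0)
        ).ravel()
        shared_genes = counts_adata.var_names[ref_mean >= cfg.cnv_min_ref_mean]
        profiles, epi_by_sample = {}, {}
        for sample in sorted(norm.obs["sample"].unique()):
            in_s = norm.obs["sample"] == sample
            sub = counts_adata[in_s.to_numpy()]
            profiles[sample] = cnv_mod.infer_cnv_profile(
                sub, positions, ref_cells.intersection(sub.obs_names),
                window=cfg.cnv_window, min_ref_mean=cfg.cnv_min_ref_mean,
                clamp=cfg.cnv_clamp, gene_subset=list(shared_genes))
            epi_by_sample[sample] = norm.obs_names[
                in_s.to_numpy() & cell_types.isin(epi_types).to_numpy()]
        mask = cnv_mod.exclude_shared_changes(
            profiles, epi_by_sample, shared_threshold=cfg.shared_threshold)
        burdens = pd.concat([cnv_mod.cnv_burden(p, mask)
                             for p in profiles.values()])
        burden_cmp = cnv_mod.compare_burden(
            burdens, norm.obs_names[cell_types == "tumor"],
            norm.obs_names[cell_types == "fibroblast"])
        manifest["metrics"]["n_masked_windows"] = int(mask.sum())
        manifest["metrics"]["burden_tumor_vs_fibro_p"] = burden_cmp["p_value"]
        manifest["metrics"]["burden_tumor_median"] = burden_cmp["median_a"]
        manifest["metrics"]["burden_fibro_median"] = burden_cmp["median_b"]
        io_mod.write_table(burdens.to_frame(), out / "cnv_burden.tsv")
        record("cnv_burden", out / "cnv_burden.tsv")
        mask_tbl = profiles[next(iter(profiles))].window_map.copy()
        mask_tbl["masked"] = mask
        io_mod.write_table(mask_tbl, out / "cnv_window_mask.tsv")
        record("cnv_window_mask", out / "cnv_window_mask.tsv")

        # ------------------------------------------------------------------
        # DSP processing
        stage = "dsp"
        dsp_table = dsp_mod.aoi_qc(dsp_table, min_reads=cfg.min_reads)
        flags, excluded = dsp_mod.flag_outlier_probes(
            dsp_table, alpha=cfg.grubbs_alpha,
            global_fraction=cfg.grubbs_global_fraction)
        gene_counts = dsp_mod.collapse_probes(dsp_table, flags, excluded)
        neg = dsp_mod.negative_probe_factors(dsp_table)
        normalized = dsp_mod.q3_normalize(gene_counts, aoi_meta=dsp_table.aoi_meta,
                                          neg_factors=neg)
        deg_t = dsp_mod.dsp_deg(normalized, "tumor", cfg.dsp_log2fc_cut,
                                cfg.dsp_p_cut)
        deg_s = dsp_mod.dsp_deg(normalized, "stroma", cfg.dsp_log2fc_cut,
                                cfg.dsp_p_cut)
        raw_sigs = dsp_mod.build_raw_signatures(deg_t, deg_s)
        manifest["metrics"]["n_aoi"] = int(normalized.values.shape[1])
        manifest["metrics"]["n_excluded_probes"] = int(len(excluded))
        manifest["metrics"]["n_tumor_deg"] = len(raw_sigs.t_nod) + len(raw_sigs.t_inf)
        manifest["metrics"]["n_stroma_deg"] = len(raw_sigs.s_nod) + len(raw_sigs.s_inf)
        manifest["metrics"]["n_shared_inf"] = len(raw_sigs.overlaps["inf_shared"])
        manifest["metrics"]["n_shared_nod"] = len(raw_sigs.overlaps["nod_shared"])
        io_mod.write_table(normalized.values, out / "dsp_normalized.tsv")
        record("dsp_normalized", out / "dsp_normalized.tsv")
        io_mod.write_table(deg_t, out / "dsp_deg_tumor.tsv")
        io_mod.write_table(deg_s, out / "dsp_deg_stroma.tsv")
        record("dsp_deg_tumor", out / "dsp_deg_tumor.tsv")
        record("dsp_deg_stroma", out / "dsp_deg_stroma.tsv")

        # ------------------------------------------------------------------
        # contamination filter
        stage = "filter"
        profile = filt_mod.compartment_expression_profile(
            norm, cell_types, set(epi_types))
        sigs, decision_log = filt_mod.filter_signature(
            raw_sigs, profile, f_on=cfg.f_on, r_max=cfg.r_max, u_min=cfg.u_min)
        for name, genes in {**{f"raw_{k}": v for k, v in raw_sigs.as_dict().items()},
                            **{f"filtered_{k}": v for k, v in sigs.as_dict().items()}
                            }.items():
            io_mod.write_gene_list(genes, out / f"signature_{name}.txt")
            record(f"signature_{name}", out / f"signature_{name}.txt")
        io_mod.write_table(decision_log, out / "filter_decisions.tsv", index=False)
        record("filter_decisions", out / "filter_decisions.tsv")
        for k, v in sigs.as_dict().items():
            manifest["metrics"][f"filtered_{k}_size"] = len(v)

        # ------------------------------------------------------------------
        # niche mapping
        stage = "niche"
        seed_niche = stage_seed(cfg.seed, "niche")
        results = {}
        for comp, prefix, res, sig_inf, sig_nod in (
                ("tumor", "TC", cfg.tumor_resolution, sigs.t_inf, sigs.t_nod),
                ("fibroblast", "FC", cfg.fibro_resolution, sigs.s_inf, sigs.s_nod)):
            cells = norm.obs_names[cell_types == comp]
            sub = norm[cells].copy()
            sub_hvgs = sc_mod.select_hvgs(sub, n=min(cfg.n_hvgs, sub.n_vars))
            n_pcs = min(cfg.n_pcs, sub.n_obs - 1, len(sub_hvgs) - 1)
            sub_clusters, sub_pcs = sc_mod.embed_and_cluster(
                sub, sub_hvgs, n_pcs=n_pcs, resolution=res, seed=seed_niche)
            score_inf = sc_mod.module_score(
                sub, sig_inf, name=f"{prefix}_inf", n_bins=cfg.score_n_bins,
                n_ctrl=cfg.score_n_ctrl, seed=seed_niche)
            score_nod = sc_mod.module_score(
                sub, sig_nod, name=f"{prefix}_nod", n_bins=cfg.score_n_bins,
                n_ctrl=cfg.score_n_ctrl, seed=seed_niche + 1)
            diff = niche_mod.score_difference(score_inf, score_nod)
            ranking = niche_mod.rank_clusters(
                diff, pd.Series(sub_clusters, index=cells), prefix=prefix)
            anticorr = niche_mod.signature_anticorrelation(score_nod, score_inf)
            results[comp] = {"clusters": pd.Series(sub_clusters, index=cells),
                             "pcs": sub_pcs, "ranking": ranking, "diff": diff,
                             "score_inf": score_inf, "score_nod": score_nod}
            manifest["metrics"][f"{comp}_n_subclusters"] = len(ranking.table)
            manifest["metrics"][f"{comp}_anticorrelation_rho"] = anticorr["rho"]
            manifest["metrics"][f"{comp}_anticorrelation_p"] = anticorr["p_value"]
            io_mod.write_table(ranking.table, out / f"ranking_{comp}.tsv",
                               index=False)
            record(f"ranking_{comp}", out / f"ranking_{comp}.tsv")
            io_mod.write_table(diff.to_frame(), out / f"score_diff_{comp}.tsv")
            record(f"score_diff_{comp}", out / f"score_diff_{comp}.tsv")

        # ------------------------------------------------------------------
        # trajectory
        stage = "trajectory"
        tumor = results["tumor"]
        root = tumor["ranking"].table.iloc[0]["cluster"]
        traj = traj_mod.compute_pseudotime(tumor["pcs"], tumor["clusters"], root)
        graph = traj_mod.knn_graph(tumor["pcs"], k=cfg.knn_k)
        tumor_norm = norm[tumor["clusters"].index].copy()
        autocorr = traj_mod.morans_i_table(tumor_norm, graph)
        traj_genes = traj_mod.select_trajectory_genes(autocorr,
                                                      cutoff=cfg.morans_cutoff)
        overlap = traj_mod.overlap_with_activators(traj_genes)
        manifest["metrics"]["n_trajectory_genes"] = len(traj_genes)
        manifest["metrics"]["activator_overlap"] = overlap
        io_mod.write_table(traj.pseudotime.to_frame(), out / "pseudotime.tsv")
        record("pseudotime", out / "pseudotime.tsv")
        io_mod.write_table(autocorr, out / "autocorrelation.tsv")
        record("autocorrelation", out / "autocorrelation.tsv")
        io_mod.write_gene_list(overlap, out / "activator_overlap.txt")
        record("activator_overlap", out / "activator_overlap.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io_mod.write_json(manifest, out / "manifest.json")
    result = dict(manifest)
    result["_objects"] = {
        "norm": norm, "cell_types": cell_types, "truth": truth,
        "profiles": profiles, "mask": mask, "burdens": burdens,
        "raw_signatures": raw_sigs, "filtered_signatures": sigs,
        "niche": results, "trajectory": traj, "autocorrelation": autocorr,
        "activator_overlap": overlap, "deg_tumor": deg_t, "deg_stroma": deg_s,
    }
    return result
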