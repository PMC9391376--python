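"""Synthetic scRNA-seq + DSP study generator with recorded ground truth.

The generator emulates the statistical structure the analysis assumes:

* negative-binomial single-cell counts for five cell types with log-normal
  library-size factors;
* a latent nodular→infiltrative coordinate g ∈ [0, 1] per tumor cell driving
  two antagonistic epithelial programs (NOD ∝ 1−g, INF ∝ g) plus an
  INHBA-like paracrine driver monotone in g;
* fibroblast activation a ∈ [0, 1] driving an ECM program against a
  quiescent program;
* copy-number segments multiplying expected tumor counts on contiguous
  genomic windows, optionally restricted to a subset of samples;
* pseudo-bulk DSP areas of interest built as per-AOI contamination mixtures
  of the two compartment expectation profiles, with planted morphology
  log2 fold-changes, probe-level dispersion, negative probes and planted
  aberrant probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .config import CNVSegment, ConfigurationError, DegenerateInputError, SimConfig
from .dsp import NEGATIVE, ProbeCountTable

EPITHELIAL_TYPES = ("tumor", "basal_keratinocyte", "diff_keratinocyte")

_CANONICAL_MARKERS = {
    "tumor": ["PTCH1", "GLI1", "GLI2", "HHIP", "MYCN", "SPON2", "BCAM", "TLE4",
              "LGR5", "CNTN1"],
    "basal_keratinocyte": ["KRT5", "TP63", "COL17A1", "DST", "ITGA6", "ITGB4",
                           "KRT15", "CCND1", "SOX9", "MT1X"],
    "diff_keratinocyte": ["KRT1", "KRT10", "CALML5", "CLDN4", "DSG3", "NECTIN1",
                          "IVL", "LOR", "FLG", "SBSN"],
    "fibroblast": ["COL1A1", "COL1A2", "COL3A1", "PDGFRA", "LUM", "DCN", "FN1",
                   "POSTN", "LRRC15", "ADAMTS2"],
    "t_cell": ["CD3E", "CD3D", "CD2", "TRAC", "CD7", "IL7R", "CCL5", "CD8A",
               "GZMK", "TRBC2"],
}
_DISSOC_CANON = ["FOS", "JUN", "JUNB", "FOSB", "EGR1", "HSPA1A", "HSPA1B",
                 "HSPB1", "SOCS3", "ZFP36"]
EPITHELIAL_LINEAGE_MARKER = "KRT14"
DRIVER_GENE = "INHBA"
FLAT_CYTOKINE = "TGFB1"


@dataclass
class SyntheticTruth:
    """Ground-truth generative state needed by parameter-recovery tests."""

    gene_ids: list[str]
    cell_ids: list[str]
    cell_types: pd.Series
    samples: pd.Series
    tumor_gradient: pd.Series            # g per tumor cell
    fibro_activation: pd.Series          # a per fibroblast
    program_gene_sets: dict[str, list[str]]
    marker_map: dict[str, list[str]]
    mito_genes: list[str]
    dissoc_genes: list[str]
    gene_positions: pd.DataFrame         # gene, chrom, start
    cnv_segments: list[dict]             # resolved with explicit gene lists
    expected_profiles: pd.DataFrame      # gene x {tumor, stroma} expectations
    planted_morphology_degs: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_outlier_probes: list[str] = field(default_factory=list)
    aoi_contamination: Optional[pd.Series] = None

    def validate(self) -> None:
        if len(self.cell_types) != len(self.cell_ids):
            raise ValueError("one cell-type label per cell required")
        universe = set(self.gene_ids)
        seen: set[str] = set()
        for name, genes in self.program_gene_sets.items():
            gs = set(genes)
            if not gs <= universe:
                raise ValueError(f"program {name} leaves the gene universe")
            if gs & seen:
                raise ValueError(f"program {name} overlaps another program")
            seen |= gs

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "cell_ids": self.cell_ids,
            "cell_types": self.cell_types.to_dict(),
            "samples": self.samples.to_dict(),
            "tumor_gradient": self.tumor_gradient.to_dict(),
            "fibro_activation": self.fibro_activation.to_dict(),
            "program_gene_sets": self.program_gene_sets,
            "marker_map": self.marker_map,
            "mito_genes": self.mito_genes,
            "dissoc_genes": self.dissoc_genes,
            "gene_positions": self.gene_positions.to_dict(orient="list"),
            "cnv_segments": self.cnv_segments,
            "expected_profiles": self.expected_profiles.to_dict(orient="list"),
            "planted_morphology_degs": self.planted_morphology_degs,
            "aoi_contamination": (None if self.aoi_contamination is None
                                  else self.aoi_contamination.to_dict()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def _pad_names(base: list[str], n: int, prefix: str) -> list[str]:
    names = list(base[:n])
    i = 1
    while len(names) < n:
        cand = f"{prefix}{i:03d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names


def build_gene_universe(config: SimConfig) -> dict[str, list[str]]:
    """Lay out the named gene universe and every planted special set.

    Generic genes come first and special (marker/program/mito/dissociation)
    genes occupy the tail of the index, which keeps the default CNV segments
    (low within-chromosome indices) on generic background genes.
    """
    types = list(config.n_cells_per_type)
    markers = {
        t: _pad_names(_CANONICAL_MARKERS.get(t, []), config.n_marker_genes,
                      f"{t.upper()}_M")
        for t in types
    }
    programs = {
        "nod": _pad_names(["MPPED1"], config.n_program_genes, "NODG"),
        "inf": _pad_names(["KRT6A", "SFN"], config.n_program_genes, "INFG"),
        "ecm": _pad_names([], config.n_program_genes, "ECMG"),
        "quiescent": _pad_names([], config.n_program_genes, "QUIG"),
    }
    mito = [f"MT-G{i:02d}" for i in range(1, config.n_mito_genes + 1)]
    dissoc = _pad_names(_DISSOC_CANON, config.n_dissoc_genes, "DISSOC")
    special: list[str] = [EPITHELIAL_LINEAGE_MARKER, DRIVER_GENE, FLAT_CYTOKINE]
    for t in types:
        special += markers[t]
    for genes in programs.values():
        special += genes
    special += mito + dissoc
    if len(set(special)) != len(special):
        raise ConfigurationError("planted gene sets overlap by name")
    if len(special) > config.n_genes:
        raise ConfigurationError("gene universe smaller than planted gene sets")
    n_generic = config.n_genes - len(special)
    gene_ids = [f"G{i:04d}" for i in range(n_generic)] + special
    return {"gene_ids": gene_ids, "markers": markers, "programs": programs,
            "mito": mito, "dissoc": dissoc}


def gene_positions(gene_ids: list[str], n_chromosomes: int) -> pd.DataFrame:
    """Deterministic round-robin genomic layout over synthetic chromosomes."""
    idx = np.arange(len(gene_ids))
    chrom = idx % n_chromosomes + 1
    start = (idx // n_chromosomes + 1) * 100_000   # 1-based starts
    return pd.DataFrame({"gene": gene_ids, "chrom": chrom, "start": start})


def _segment_genes(positions: pd.DataFrame, seg: CNVSegment) -> list[str]:
    chrom = positions[positions["chrom"] == seg.chrom].sort_values("start")
    if seg.start + seg.length > len(chrom):
        raise ConfigurationError(
            f"CNV segment {seg} exceeds chromosome {seg.chrom} "
            f"({len(chrom)} genes)")
    return chrom["gene"].iloc[seg.start:seg.start + seg.length].tolist()


def simulate_sc_counts(config: SimConfig) -> tuple[AnnData, SyntheticTruth]:
    """Draw the single-cell count matrix and its ground truth.

    Counts are negative-binomial (gamma-Poisson) around per-cell expected
    means; same config + seed is bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    uni = build_gene_universe(config)
    gene_ids = uni["gene_ids"]
    gene_index = pd.Index(gene_ids)
    positions = gene_positions(gene_ids, config.n_chromosomes)

    types = list(config.n_cells_per_type)
    cell_types = np.concatenate([
        np.repeat(t, config.n_cells_per_type[t]) for t in types])
    n_cells = len(cell_types)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    samples = np.array([f"S{i % config.n_samples}" for i in range(n_cells)])
    sample_idx = np.array([i % config.n_samples for i in range(n_cells)])

    # per-gene baseline, boosted for planted program/marker genes
    base = config.baseline_mean * rng.lognormal(0.0, 1.0, size=len(gene_ids))
    boosted = set(uni["markers"].get("tumor", []))
    for t in types:
        boosted |= set(uni["markers"][t])
    for genes in uni["programs"].values():
        boosted |= set(genes)
    boosted |= {EPITHELIAL_LINEAGE_MARKER, DRIVER_GENE, FLAT_CYTOKINE}
    base[gene_index.isin(sorted(boosted))] *= config.program_base_boost
    base[gene_index.isin(uni["mito"])] *= config.mito_boost
    # the planted paracrine driver and flat cytokine get deterministic
    # baselines: their detectability is part of the planted condition, not a
    # random draw
    for gene in (DRIVER_GENE, FLAT_CYTOKINE):
        base[gene_index.get_loc(gene)] = config.baseline_mean * config.program_base_boost

    epithelial = [t for t in types if t in EPITHELIAL_TYPES]
    epi_specific = (set(uni["programs"]["nod"]) | set(uni["programs"]["inf"])
                    | {EPITHELIAL_LINEAGE_MARKER, DRIVER_GENE, FLAT_CYTOKINE})
    for t in epithelial:
        epi_specific |= set(uni["markers"][t])
    fibro_specific = (set(uni["programs"]["ecm"]) | set(uni["programs"]["quiescent"])
                      | set(uni["markers"]["fibroblast"]))
    tcell_specific = set(uni["markers"]["t_cell"])

    # latent coordinates
    g_all = np.zeros(n_cells)
    is_tumor = cell_types == "tumor"
    g_all[is_tumor] = rng.beta(*config.gradient_beta, size=is_tumor.sum())
    a_all = np.zeros(n_cells)
    is_fibro = cell_types == "fibroblast"
    a_all[is_fibro] = rng.beta(*config.gradient_beta, size=is_fibro.sum())

    mean = np.tile(base, (n_cells, 1))

    def cols(genes) -> np.ndarray:
        return gene_index.get_indexer(sorted(genes))

    # compartment specificity: specific genes leak only weakly elsewhere
    is_epi = np.isin(cell_types, epithelial)
    mean[np.ix_(~is_epi, cols(epi_specific))] *= config.compartment_leak
    mean[np.ix_(~is_fibro, cols(fibro_specific))] *= config.compartment_leak
    is_t = cell_types == "t_cell"
    mean[np.ix_(~is_t, cols(tcell_specific))] *= config.compartment_leak

    # canonical markers up in their own type; KRT14 lineage marker pan-epithelial
    for t in types:
        own = cell_types == t
        mean[np.ix_(own, cols(uni["markers"][t]))] *= 2.0 ** config.marker_log2fc
    mean[np.ix_(is_epi, cols([EPITHELIAL_LINEAGE_MARKER]))] *= 2.0 ** config.marker_log2fc

    # antagonistic programs along the latent coordinates
    d = config.program_log2fc
    g_t = g_all[is_tumor][:, None]
    mean[np.ix_(is_tumor, cols(uni["programs"]["inf"]))] *= 2.0 ** (d * g_t)
    mean[np.ix_(is_tumor, cols(uni["programs"]["nod"]))] *= 2.0 ** (d * (1.0 - g_t))
    mean[is_tumor, gene_index.get_loc(DRIVER_GENE)] *= \
        2.0 ** (config.driver_log2fc * g_all[is_tumor])
    mean[is_tumor, gene_index.get_loc(FLAT_CYTOKINE)] *= 2.0 ** 1.5
    a_f = a_all[is_fibro][:, None]
    mean[np.ix_(is_fibro, cols(uni["programs"]["ecm"]))] *= 2.0 ** (d * a_f)
    mean[np.ix_(is_fibro, cols(uni["programs"]["quiescent"]))] *= 2.0 ** (d * (1.0 - a_f))

    # copy-number segments multiply expected tumor counts
    resolved_segments = []
    for seg in config.cnv_segments:
        genes = _segment_genes(positions, seg)
        seg_samples = (tuple(range(config.n_samples)) if seg.samples is None
                       else seg.samples)
        affected = is_tumor & np.isin(sample_idx, seg_samples)
        mean[np.ix_(affected, gene_index.get_indexer(genes))] *= seg.multiplier
        resolved_segments.append({
            "chrom": seg.chrom, "start": seg.start, "length": seg.length,
            "multiplier": seg.multiplier,
            "samples": sorted(seg_samples), "shared": seg.samples is None,
            "genes": genes,
        })

    # expectation profiles per compartment (before library factors, E[factor]=1)
    tumor_profile = mean[is_tumor].mean(axis=0)
    stroma_profile = mean[is_fibro | is_t].mean(axis=0)
    expected_profiles = pd.DataFrame(
        {"tumor": tumor_profile, "stroma": stroma_profile}, index=gene_ids)

    lib = rng.lognormal(-config.libsize_sigma ** 2 / 2.0, config.libsize_sigma,
                        size=n_cells)
    lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                    scale=mean * lib[:, None] * config.nb_dispersion)
    counts = rng.poisson(lam)

    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame({"sample": samples}, index=cell_ids),
        var=pd.DataFrame(index=gene_ids),
    )
    program_sets = {name: sorted(genes) for name, genes in uni["programs"].items()}
    program_sets["activator_driver"] = [DRIVER_GENE]
    for t in types:
        program_sets[f"markers:{t}"] = sorted(uni["markers"][t])
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_types=pd.Series(cell_types, index=cell_ids, name="cell_type"),
        samples=pd.Series(samples, index=cell_ids, name="sample"),
        tumor_gradient=pd.Series(g_all[is_tumor],
                                 index=np.array(cell_ids)[is_tumor], name="g"),
        fibro_activation=pd.Series(a_all[is_fibro],
                                   index=np.array(cell_ids)[is_fibro], name="a"),
        program_gene_sets=program_sets,
        marker_map={t: sorted(uni["markers"][t]) for t in types},
        mito_genes=uni["mito"],
        dissoc_genes=uni["dissoc"],
        gene_positions=positions,
        cnv_segments=resolved_segments,
        expected_profiles=expected_profiles,
    )
    truth.validate()
    return adata, truth


# ---------------------------------------------------------------------------
# DSP pseudo-bulk simulation


def morphology_profiles(config: SimConfig, truth: SyntheticTruth
                        ) -> dict[tuple[str, str], pd.Series]:
    """Expected gene profiles per (compartment, morphology).

    Nodular profiles are the base compartment expectations; infiltrative
    profiles multiply the planted morphology DEGs by 2**log2fc. The planted
    log2 fold-changes live on the compartment that owns the program (INF/NOD
    on tumor, ECM/quiescent on stroma).
    """
    d = config.morphology_log2fc
    degs = {
        "tumor": {**{g: +d for g in truth.program_gene_sets["inf"]},
                  **{g: -d for g in truth.program_gene_sets["nod"]}},
        "stroma": {**{g: +d for g in truth.program_gene_sets["ecm"]},
                   **{g: -d for g in truth.program_gene_sets["quiescent"]}},
    }
    truth.planted_morphology_degs = degs
    out = {}
    for comp in ("tumor", "stroma"):
        base = truth.expected_profiles[comp].copy()
        out[(comp, "nodular")] = base
        infl = base.copy()
        for gene, lfc in degs[comp].items():
            infl[gene] *= 2.0 ** lfc
        out[(comp, "infiltrative")] = infl
    return out


def simulate_dsp_probes(config: SimConfig, truth: SyntheticTruth,
                        seed: Optional[int] = None
                        ) -> tuple[ProbeCountTable, SyntheticTruth]:
    """Draw the probe-level DSP table as contamination mixtures.

    Every AOI's gene expectation is (1-c)·own-compartment profile +
    c·adjacent-compartment profile of the same morphology, with c ~ Beta
    per AOI. Genes are represented by ``probes_per_gene`` probes whose
    efficiencies scatter log-normally with CV ``probe_cv``; planted outlier
    probes are ``outlier_multiplier``-fold aberrant. Counts are Poisson.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    gene_ids = truth.gene_ids
    profiles = morphology_profiles(config, truth)

    # probe universe: consistent efficiencies across AOIs, pools round-robin
    probe_ids, probe_gene, probe_pool = [], [], []
    for gi, gene in enumerate(gene_ids):
        for k in range(config.probes_per_gene):
            probe_ids.append(f"{gene}_p{k + 1}")
            probe_gene.append(gene)
            probe_pool.append(f"P{(gi + k) % config.n_pools + 1}")
    n_gene_probes = len(probe_ids)
    for j in range(config.n_negative_probes):
        probe_ids.append(f"NEG_{j + 1:02d}")
        probe_gene.append(NEGATIVE)
        probe_pool.append(f"P{j % config.n_pools + 1}")
    sigma = np.sqrt(np.log1p(config.probe_cv ** 2))
    eff = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(probe_ids))
    n_outliers = int(round(config.outlier_probe_rate * n_gene_probes))
    outlier_idx = rng.choice(n_gene_probes, size=n_outliers, replace=False)
    eff[outlier_idx] *= config.outlier_multiplier

    morphologies = ("nodular", "infiltrative")
    compartments = ("tumor", "stroma")
    rows, meta_rows, contamination = [], [], {}
    for morph in morphologies:
        for comp in compartments:
            other = "stroma" if comp == "tumor" else "tumor"
            for i in range(config.n_aoi_per_group):
                aoi = f"{comp[0].upper()}_{morph[:3]}_{i + 1:02d}"
                c = float(rng.beta(*config.contamination_beta))
                mix = ((1.0 - c) * profiles[(comp, morph)]
                       + c * profiles[(other, morph)]).to_numpy()
                depth = rng.lognormal(np.log(config.aoi_depth),
                                      config.aoi_depth_sigma)
                gene_expect = mix / mix.sum() * depth
                probe_expect = np.repeat(gene_expect / config.probes_per_gene,
                                         config.probes_per_gene)
                probe_expect = probe_expect * eff[:n_gene_probes]
                neg_expect = config.negative_mean * eff[n_gene_probes:]
                counts = rng.poisson(np.concatenate([probe_expect, neg_expect]))
                rows.append(counts)
                sample = f"{morph[:3].upper()}{i % (config.n_samples) + 1}"
                meta_rows.append({"aoi": aoi, "sample": sample,
                                  "compartment": comp, "morphology": morph,
                                  "total_reads": int(counts.sum())})
                contamination[aoi] = c

    counts = pd.DataFrame(np.vstack(rows),
                          index=[m["aoi"] for m in meta_rows],
                          columns=probe_ids)
    meta = pd.DataFrame(meta_rows).set_index("aoi")
    table = ProbeCountTable(
        counts=counts,
        probe_map=pd.Series(probe_gene, index=probe_ids, name="gene"),
        pool=pd.Series(probe_pool, index=probe_ids, name="pool"),
        aoi_meta=meta,
    )
    table.validate()
    truth.aoi_contamination = pd.Series(contamination, name="contamination")
    truth.planted_outlier_probes = [probe_ids[i] for i in sorted(outlier_idx)]
    return table, truth


def estimate_mixing_fraction(aoi_profile: np.ndarray, profile_a: np.ndarray,
                             profile_b: np.ndarray) -> float:
    """Least-squares mixing fraction c of ``(1-c)·A + c·B`` fitting the AOI.

    Closed-form projection onto the A→B segment, clipped to [0, 1]. Identical
    pure profiles are degenerate and raise.
    """
    aoi = np.asarray(aoi_profile, dtype=float)
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if aoi.shape != a.shape or a.shape != b.shape:
        raise ValueError("profiles must share one gene universe")
    if (aoi < 0).any() or (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be nonnegative")
    direction = b - a
    denom = float(direction @ direction)
    if denom <= 0.0:
        raise DegenerateInputError("pure profiles are identical")
    c = float((aoi - a) @ direction / denom)
    return min(1.0, max(0.0, c))
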