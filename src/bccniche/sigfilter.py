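"""Cross-contamination filtering of spatial signatures using scRNA-seq.

DSP areas of interest are pseudo-bulk regions; transcripts from the adjacent
compartment bleed into each AOI, so raw morphology DEG signatures contain
genes the compartment's own cells never express (the FN1/COL1A1 phenomenon).
This module rebuilds each signature keeping only genes (i) expressed in the
signature's own compartment, (ii) not dominated by the other compartment, and
(iii) not ubiquitously detected across cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .dsp import SpatialSignatures

EPS = 1e-9


@dataclass
class CompartmentProfile:
    """Per-gene expression statistics split by epithelial vs stromal cells.

    ``stats`` columns: frac_pos_epithelial, frac_pos_stromal,
    mean_norm_epithelial, mean_norm_stromal. ``frac_pos_per_type`` is gene x
    cell-type detection fractions.
    """

    stats: pd.DataFrame
    frac_pos_per_type: pd.DataFrame


def compartment_expression_profile(adata: AnnData, cell_types: pd.Series,
                                   epithelial_cell_types: set[str]
                                   ) -> CompartmentProfile:
    """Compute detection fractions and mean normalized expression per gene
    over epithelial (KRT14-positive analog) vs all other cells, plus the
    detection fraction per annotated cell type.

    ``adata`` must be log-normalized with raw counts in ``layers["counts"]``.
    """
    cell_types = cell_types.reindex(adata.obs_names)
    is_epi = cell_types.isin(epithelial_cell_types).to_numpy()
    if not is_epi.any() or is_epi.all():
        raise ValueError("both compartments must be nonempty")
    counts = adata.layers["counts"]
    norm = adata.X
    pos = (counts > 0)
    pos = pos.toarray() if sparse.issparse(pos) else np.asarray(pos)
    normd = norm.toarray() if sparse.issparse(norm) else np.asarray(norm)
    stats = pd.DataFrame({
        "frac_pos_epithelial": pos[is_epi].mean(axis=0),
        "frac_pos_stromal": pos[~is_epi].mean(axis=0),
        "mean_norm_epithelial": normd[is_epi].mean(axis=0),
        "mean_norm_stromal": normd[~is_epi].mean(axis=0),
    }, index=adata.var_names)
    per_type = {}
    for t in cell_types.dropna().unique():
        per_type[t] = pos[(cell_types == t).to_numpy()].mean(axis=0)
    return CompartmentProfile(stats=stats,
                              frac_pos_per_type=pd.DataFrame(per_type,
                                                             index=adata.var_names))


def _keep_gene(row: pd.Series, ubiquitous: bool, own: str,
               f_on: float, r_max: float) -> tuple[bool, str]:
    other = "stromal" if own == "epithelial" else "epithelial"
    if row[f"frac_pos_{own}"] < f_on:
        return False, "not_expressed_in_own_compartment"
    ratio = row[f"mean_norm_{other}"] / (row[f"mean_norm_{own}"] + EPS)
    if ratio > r_max:
        return False, "dominated_by_other_compartment"
    if ubiquitous:
        return False, "ubiquitous"
    return True, "retained"


def filter_signature(signatures: SpatialSignatures, profile: CompartmentProfile,
                     f_on: float = 0.10, r_max: float = 3.0,
                     u_min: float = 0.25
                     ) -> tuple[SpatialSignatures, pd.DataFrame]:
    """Apply the three contamination rules to the four raw signatures.

    Tumor-signature genes must be detected in >= ``f_on`` of epithelial cells,
    must not exceed ``r_max``-fold stromal/epithelial mean expression, and
    must not be detected in >= ``u_min`` of cells of *every* cell type
    (ubiquitous); stroma signatures apply the mirrored criteria. Returns the
    filtered signatures plus a per-gene decision log with the rule that
    removed each gene.
    """
    if signatures.stage != "raw":
        warnings.warn("filtering signatures not at stage 'raw'")
    ubiquitous = (profile.frac_pos_per_type >= u_min).all(axis=1)
    log_rows = []
    filtered = {}
    for sig_name, own in (("t_nod", "epithelial"), ("t_inf", "epithelial"),
                          ("s_nod", "stromal"), ("s_inf", "stromal")):
        raw_genes = getattr(signatures, sig_name)
        kept = []
        for gene in raw_genes:
            if gene not in profile.stats.index:
                warnings.warn(f"{sig_name}: gene {gene} missing from profile; dropped")
                log_rows.append({"gene": gene, "signature": sig_name,
                                 "decision": "removed", "rule": "missing_from_scrna"})
                continue
            keep, rule = _keep_gene(profile.stats.loc[gene],
                                    bool(ubiquitous.get(gene, False)),
                                    own, f_on, r_max)
            if keep:
                kept.append(gene)
            row = {"gene": gene, "signature": sig_name,
                   "decision": "retained" if keep else "removed", "rule": rule}
            row.update(profile.stats.loc[gene].to_dict())
            log_rows.append(row)
        filtered[sig_name] = kept
    out = SpatialSignatures(stage="filtered", overlaps=signatures.overlaps,
                            **filtered)
    out.validate()
    return out, pd.DataFrame(log_rows)
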