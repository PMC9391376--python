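"""Inferred copy-number profiles from scRNA-seq against a reference population.

Relative expression is smoothed along genomic coordinates (inferCNV-style
moving average), centered per cell, and clamped; a shared-change exclusion
masks windows that move the same way in every sample's epithelial cells
(lineage-driven transcription rather than genomic change); per-cell burden
summarizes the remaining aberration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats

from .sc import lognormalize


@dataclass
class CNVProfile:
    """Cells x windows smoothed, centered relative-expression matrix.

    One window per retained gene (centered moving average truncated at
    chromosome ends), ordered by chromosome then position.
    """

    values: pd.DataFrame          # cells x windows
    window_map: pd.DataFrame      # window -> (chrom, gene, start)
    reference_cells: pd.Index
    params: dict

    def validate(self) -> None:
        clamp = self.params.get("clamp", np.inf)
        if np.abs(self.values.to_numpy()).max() > clamp + 1e-9:
            raise ValueError("profile exceeds clamp")
        if not set(self.reference_cells) <= set(self.values.index):
            raise ValueError("reference cells missing from the profile")


def _moving_average_truncated(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over the last axis, truncated at the ends."""
    n = x.shape[-1]
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), x.cumsum(axis=-1)],
                          axis=-1)
    lo = np.maximum(np.arange(n) - half_lo, 0)
    hi = np.minimum(np.arange(n) + half_hi + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def infer_cnv_profile(adata: AnnData, positions: pd.DataFrame,
                      reference_cells, window: int = 101,
                      min_ref_mean: float = 0.1, clamp: float = 1.0,
                      gene_subset: Optional[list[str]] = None) -> CNVProfile:
    """Infer smoothed relative copy-number profiles against reference cells.

    Steps, in order: (1) drop genes whose mean raw count among reference
    cells is below ``min_ref_mean`` (or force ``gene_subset`` when given, so
    multiple samples can share one window map); (2) log-normalize; (3)
    subtract the reference-cell mean per gene; (4) per chromosome, centered
    moving average over ``window`` genes ordered by start, truncated at the
    ends; (5) subtract each cell's median across all windows; (6) clamp to
    ±``clamp``.

    ``adata.X`` must hold raw counts. ``positions`` needs columns
    gene/chrom/start (1-based starts).
    """
    reference_cells = pd.Index(reference_cells)
    if len(reference_cells) == 0:
        raise ValueError("reference cell set is empty")
    pos = positions.set_index("gene")
    shared = adata.var_names.intersection(pos.index)
    adata = adata[:, shared]
    ref_mask = adata.obs_names.isin(reference_cells)
    if gene_subset is None:
        x = adata.X
        ref_mean = np.asarray(x[ref_mask].mean(axis=0)).ravel()
        keep_genes = adata.var_names[ref_mean >= min_ref_mean]
    else:
        keep_genes = adata.var_names.intersection(pd.Index(gene_subset))
    adata = adata[:, keep_genes].copy()
    pos = pos.loc[keep_genes].sort_values(["chrom", "start"])
    if not (pos.groupby("chrom").size() >= window).any():
        raise ValueError(f"no chromosome retains >= {window} genes")
    norm = lognormalize(adata)
    x = norm.X.toarray() if sparse.issparse(norm.X) else np.asarray(norm.X)
    x = pd.DataFrame(x, index=norm.obs_names, columns=norm.var_names)
    x = x[pos.index]                       # genomic order
    centered = x.to_numpy() - x.to_numpy()[ref_mask].mean(axis=0)

    smoothed = np.empty_like(centered)
    col = 0
    for chrom, genes in pos.groupby("chrom", sort=True):
        k = len(genes)
        smoothed[:, col:col + k] = _moving_average_truncated(
            centered[:, col:col + k], min(window, k))
        col += k
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    smoothed = np.clip(smoothed, -clamp, clamp)

    window_map = pd.DataFrame({
        "window": [f"w{i:05d}" for i in range(len(pos))],
        "chrom": pos["chrom"].to_numpy(),
        "gene": pos.index.to_numpy(),
        "start": pos["start"].to_numpy(),
    }).set_index("window")
    profile = CNVProfile(
        values=pd.DataFrame(smoothed, index=x.index, columns=window_map.index),
        window_map=window_map,
        reference_cells=pd.Index(reference_cells),
        params={"window": window, "min_ref_mean": min_ref_mean, "clamp": clamp},
    )
    profile.validate()
    return profile


def exclude_shared_changes(profiles_by_sample: dict[str, CNVProfile],
                           epithelial_cells_by_sample: dict[str, pd.Index],
                           shared_threshold: float = 0.15) -> pd.Series:
    """Mask windows whose epithelial mean exceeds the threshold with the same
    sign in every sample (lineage effects, not genomic changes).

    Returns a boolean Series over windows; ``True`` = masked.
    """
    if len(profiles_by_sample) < 2:
        raise ValueError("need profiles from >= 2 samples")
    maps = [p.window_map for p in profiles_by_sample.values()]
    for m in maps[1:]:
        if not maps[0].index.equals(m.index) or not maps[0]["gene"].equals(m["gene"]):
            raise ValueError("window maps differ between samples")
    means = []
    for sample, profile in profiles_by_sample.items():
        cells = pd.Index(epithelial_cells_by_sample[sample])
        cells = cells.intersection(profile.values.index)
        if len(cells) == 0:
            raise ValueError(f"sample {sample} has no epithelial cells in profile")
        means.append(profile.values.loc[cells].mean(axis=0))
    stacked = pd.concat(means, axis=1)
    mask = ((stacked > shared_threshold).all(axis=1)
            | (stacked < -shared_threshold).all(axis=1))
    mask.name = "masked"
    return mask


def cnv_burden(profile: CNVProfile, mask: Optional[pd.Series] = None) -> pd.Series:
    """Per-cell aberration burden: mean squared profile over unmasked windows."""
    values = profile.values
    if mask is not None:
        keep = mask.index[~mask]
        if len(keep) == 0:
            raise ValueError("all windows are masked")
        values = values[keep]
    return (values ** 2).mean(axis=1).rename("cnv_burden")


def compare_burden(burden: pd.Series, cells_a, cells_b) -> dict:
    """Two-sided rank-sum comparison of burden between two cell groups."""
    a = burden.loc[pd.Index(cells_a)]
    b = burden.loc[pd.Index(cells_b)]
    stat, p = stats.ranksums(a, b)
    return {"median_a": float(a.median()), "median_b": float(b.median()),
            "statistic": float(stat), "p_value": float(p)}


def call_segments(profile: CNVProfile, cells, threshold: float = 0.15,
                  mask: Optional[pd.Series] = None) -> pd.Series:
    """Boolean per-window call: |mean profile over ``cells``| > threshold."""
    mean = profile.values.loc[pd.Index(cells)].mean(axis=0)
    call = mean.abs() > threshold
    if mask is not None:
        call &= ~mask
    return call
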