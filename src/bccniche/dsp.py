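"""Probe-level digital spatial profiling (DSP) processing.

Implements the GeoMx-style probe QC and normalization chain: AOI read-depth
QC, per-target Grubbs outlier flagging, geometric-mean probe collapse,
negative-probe background factors, upper-quartile (Q3) normalization, and
compartment-wise morphology differential expression, ending in the four raw
spatial signatures (T^NOD, T^INF, S^NOD, S^INF).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NEGATIVE = "NEGATIVE"


@dataclass
class ProbeCountTable:
    """AOI x probe raw counts with the probe and AOI annotations.

    ``counts`` rows are AOIs, columns probes. ``probe_map`` maps each probe to
    its target gene (or ``"NEGATIVE"`` for no-target background probes),
    ``pool`` to its probe-pool label. ``aoi_meta`` is indexed by AOI and holds
    ``sample``, ``compartment`` (tumor/stroma), ``morphology``
    (nodular/infiltrative) and ``total_reads``.
    """

    counts: pd.DataFrame
    probe_map: pd.Series
    pool: pd.Series
    aoi_meta: pd.DataFrame

    def validate(self) -> None:
        if not self.counts.columns.equals(self.probe_map.index):
            missing = self.counts.columns.difference(self.probe_map.index)
            if len(missing):
                raise ValueError(f"unmapped probes: {list(missing)[:5]}")
            self.probe_map = self.probe_map.reindex(self.counts.columns)
            self.pool = self.pool.reindex(self.counts.columns)
        if not self.counts.index.equals(self.aoi_meta.index):
            raise ValueError("aoi_meta must have one row per AOI in counts order")
        neg = self.probe_map[self.probe_map == NEGATIVE]
        for pool_label in self.pool.unique():
            if not (self.pool.loc[neg.index] == pool_label).any():
                raise ValueError(f"pool {pool_label!r} has no negative probe")

    def subset_aois(self, keep: pd.Index) -> "ProbeCountTable":
        return ProbeCountTable(self.counts.loc[keep], self.probe_map,
                               self.pool, self.aoi_meta.loc[keep])

    @property
    def gene_probes(self) -> pd.Index:
        return self.probe_map.index[self.probe_map != NEGATIVE]

    @property
    def negative_probes(self) -> pd.Index:
        return self.probe_map.index[self.probe_map == NEGATIVE]


@dataclass
class NormalizedAOITable:
    """Gene x AOI Q3-normalized expression plus the normalization factors."""

    values: pd.DataFrame                 # gene x AOI
    q3_factors: pd.Series                # per AOI
    aoi_meta: pd.DataFrame
    neg_factors: Optional[pd.DataFrame] = None   # AOI x pool
    qc_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


@dataclass
class SpatialSignatures:
    """The four compartment x morphology gene lists.

    ``stage`` is ``"raw"`` straight out of the DSP DEG tables and
    ``"filtered"`` after the scRNA-seq cross-contamination filter. Overlaps
    between tumor and stroma lists of the same direction are reported as a
    contamination diagnostic, not asserted.
    """

    t_nod: list[str]
    t_inf: list[str]
    s_nod: list[str]
    s_inf: list[str]
    stage: str = "raw"
    overlaps: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.t_nod) & set(self.t_inf):
            raise ValueError("tumor NOD and INF signatures must be disjoint")
        if set(self.s_nod) & set(self.s_inf):
            raise ValueError("stroma NOD and INF signatures must be disjoint")

    def as_dict(self) -> dict[str, list[str]]:
        return {"t_nod": list(self.t_nod), "t_inf": list(self.t_inf),
                "s_nod": list(self.s_nod), "s_inf": list(self.s_inf)}


# ---------------------------------------------------------------------------
# QC and probe collapse


def aoi_qc(table: ProbeCountTable, min_reads: int = 10_000) -> ProbeCountTable:
    """Drop AOIs with fewer than ``min_reads`` total reads (inclusive minimum)."""
    if table.counts.shape[0] == 0:
        raise ValueError("empty probe count table")
    keep = table.aoi_meta.index[table.aoi_meta["total_reads"] >= min_reads]
    dropped = table.aoi_meta.index.difference(keep)
    if len(dropped):
        logger.info("aoi_qc dropped %d AOIs below %d reads: %s",
                    len(dropped), min_reads, list(dropped))
    if len(keep) == 0:
        raise ValueError(f"all AOIs fall below the {min_reads}-read minimum")
    return table.subset_aois(keep)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at level ``alpha``."""
    if n < 3:
        return np.inf
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def flag_outlier_probes(table: ProbeCountTable, alpha: float = 0.01,
                        global_fraction: float = 0.20,
                        ) -> tuple[pd.DataFrame, pd.Index]:
    """Per-(target, AOI) Grubbs outlier flags on log2(count+1) probe values.

    For every target with >=3 probes and every AOI, the single most extreme
    probe is flagged when G = max|x - mean| / sd exceeds the two-sided Grubbs
    critical value at ``alpha``. Zero-variance probe sets are never flagged.
    A probe flagged in at least ``global_fraction`` of AOIs is globally
    excluded. Returns ``(flags, excluded)`` where ``flags`` is an AOI x probe
    boolean frame over gene probes.
    """
    gene_probes = table.gene_probes
    flags = pd.DataFrame(False, index=table.counts.index, columns=gene_probes)
    logx = np.log2(table.counts[gene_probes].to_numpy(dtype=float) + 1.0)
    col_of = {p: j for j, p in enumerate(gene_probes)}
    for gene, probes in table.probe_map.loc[gene_probes].groupby(table.probe_map):
        pnames = probes.index
        n = len(pnames)
        if n < 3:
            continue  # 1-2 probe targets pass untested
        crit = grubbs_critical_value(n, alpha)
        sub = logx[:, [col_of[p] for p in pnames]]
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.abs(sub - mean) / sd
        g = np.where(np.isfinite(g), g, 0.0)          # zero variance -> skip
        extreme = g.argmax(axis=1)
        hit = g[np.arange(g.shape[0]), extreme] > crit
        for i in np.nonzero(hit)[0]:
            flags.iloc[i, flags.columns.get_loc(pnames[extreme[i]])] = True
    excluded = flags.columns[flags.mean(axis=0) >= global_fraction]
    if len(excluded):
        logger.info("globally excluded %d outlier probes: %s",
                    len(excluded), list(excluded)[:10])
    return flags, excluded


def _geometric_mean(values: np.ndarray) -> np.ndarray:
    """Geometric mean along the last axis; zeros are replaced by 0.5."""
    safe = np.where(values > 0, values, 0.5)
    return np.exp(np.log(safe).mean(axis=-1))


def collapse_probes(table: ProbeCountTable,
                    flags: Optional[pd.DataFrame] = None,
                    excluded: Optional[pd.Index] = None) -> pd.DataFrame:
    """Collapse probes to one gene-level metric per AOI by geometric mean.

    Globally ``excluded`` probes are removed everywhere; per-AOI ``flags``
    remove single observations. Zero counts enter the geometric mean as 0.5
    (the background pseudocount convention); strictly positive probe sets are
    untouched pure geometric means. Genes whose probes are all excluded are
    dropped with a warning. Negative probes never enter the gene table.
    """
    gene_probes = table.gene_probes
    if excluded is not None:
        gene_probes = gene_probes.difference(excluded, sort=False)
    counts = table.counts[gene_probes].to_numpy(dtype=float)
    mask = np.ones_like(counts, dtype=bool)
    if flags is not None:
        f = flags.reindex(index=table.counts.index, columns=gene_probes,
                          fill_value=False).to_numpy()
        mask &= ~f
    genes = table.probe_map.loc[gene_probes]
    out = {}
    for gene, probes in genes.groupby(genes):
        idx = [gene_probes.get_loc(p) for p in probes.index]
        sub = counts[:, idx]
        submask = mask[:, idx]
        if not submask.any():
            warnings.warn(f"gene {gene} lost all probes; dropped")
            continue
        safe_log = np.log(np.where(sub > 0, sub, 0.5))
        k = submask.sum(axis=1)
        # AOIs where every probe was flagged locally fall back to all probes
        fallback = k == 0
        use = submask | fallback[:, None]
        k = np.where(fallback, sub.shape[1], k)
        out[gene] = np.exp(np.where(use, safe_log, 0.0).sum(axis=1) / k)
    result = pd.DataFrame(out, index=table.counts.index).T
    result = result.reindex(sorted(result.index))
    return result


def negative_probe_factors(table: ProbeCountTable) -> pd.DataFrame:
    """Per-AOI, per-pool geometric mean of negative-probe counts (background)."""
    negs = table.negative_probes
    if len(negs) == 0:
        raise ValueError("no negative probes present")
    out = {}
    pools = table.pool.loc[negs]
    for pool_label, probes in pools.groupby(pools):
        vals = table.counts[probes.index].to_numpy(dtype=float)
        if (vals == 0).all():
            logger.info("pool %s negatives are all zero; factor from 0.5 pseudocount",
                        pool_label)
        out[pool_label] = _geometric_mean(vals)
    for pool_label in table.pool.unique():
        if pool_label not in out:
            raise ValueError(f"pool {pool_label!r} has no negative probes")
    return pd.DataFrame(out, index=table.counts.index)


def q3_normalize(gene_counts: pd.DataFrame,
                 aoi_meta: Optional[pd.DataFrame] = None,
                 neg_factors: Optional[pd.DataFrame] = None,
                 mad_sigma: float = 3.0) -> NormalizedAOITable:
    """Upper-quartile normalization of a gene x AOI table.

    Each AOI is scaled by f_i = q3_i / geomean(q3), so every post-normalization
    75th percentile equals the geometric mean of the raw 75th percentiles
    exactly. Factors whose log2 deviates from the cohort median by more than
    ``mad_sigma`` median absolute deviations are QC-flagged.
    """
    q3 = gene_counts.quantile(0.75, axis=0, interpolation="linear")
    bad = q3.index[q3 <= 0]
    if len(bad):
        raise ValueError(f"non-positive 75th percentile in AOI(s) {list(bad)}")
    geo = float(np.exp(np.log(q3).mean()))
    factors = q3 / geo
    values = gene_counts / factors
    logf = np.log2(factors)
    mad = float((logf - logf.median()).abs().median())
    if mad == 0:
        flags = pd.Series(False, index=factors.index)
    else:
        flags = (logf - logf.median()).abs() > mad_sigma * mad
    if aoi_meta is None:
        aoi_meta = pd.DataFrame(index=gene_counts.columns)
    return NormalizedAOITable(values=values, q3_factors=factors,
                              aoi_meta=aoi_meta.loc[gene_counts.columns],
                              neg_factors=neg_factors, qc_flags=flags)


# ---------------------------------------------------------------------------
# Morphology differential expression and raw signatures


def dsp_deg(norm: NormalizedAOITable, compartment: str,
            log2fc_cut: float = 0.4, p_cut: float = 0.05) -> pd.DataFrame:
    """Welch t-test of infiltrative vs nodular AOIs within one compartment.

    Tests log2(normalized + 1) values per gene; log2fc is the difference of
    group means on that scale (infiltrative minus nodular). ``significant``
    requires |log2fc| > ``log2fc_cut`` and p < ``p_cut``, both strict.
    """
    meta = norm.aoi_meta
    sel = meta.index[meta["compartment"] == compartment]
    morph = meta.loc[sel, "morphology"]
    inf_a = sel[morph == "infiltrative"]
    nod_a = sel[morph == "nodular"]
    if len(inf_a) < 2 or len(nod_a) < 2:
        raise ValueError(
            f"compartment {compartment!r} needs >=2 AOIs per morphology "
            f"(got {len(inf_a)} infiltrative, {len(nod_a)} nodular)")
    x = np.log2(norm.values[inf_a].to_numpy(dtype=float) + 1.0)
    y = np.log2(norm.values[nod_a].to_numpy(dtype=float) + 1.0)
    lfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    tbl = pd.DataFrame({
        "gene": norm.values.index,
        "log2fc": lfc,
        "p_value": p,
        "p_adjusted": padj,
        "mean_infiltrative": x.mean(axis=1),
        "mean_nodular": y.mean(axis=1),
    }).set_index("gene")
    tbl["significant"] = (np.abs(tbl["log2fc"]) > log2fc_cut) & (tbl["p_value"] < p_cut)
    return tbl.sort_values("p_value")


def build_raw_signatures(deg_tumor: pd.DataFrame,
                         deg_stroma: pd.DataFrame) -> SpatialSignatures:
    """Partition significant morphology DEGs into the four raw spatial signatures."""

    def split(tbl: pd.DataFrame) -> tuple[list[str], list[str]]:
        if tbl.empty:
            return [], []
        sig = tbl[tbl["significant"]]
        inf = sig.index[sig["log2fc"] > 0].tolist()
        nod = sig.index[sig["log2fc"] < 0].tolist()
        return sorted(nod), sorted(inf)

    t_nod, t_inf = split(deg_tumor)
    s_nod, s_inf = split(deg_stroma)
    overlaps = {
        "nod_shared": sorted(set(t_nod) & set(s_nod)),
        "inf_shared": sorted(set(t_inf) & set(s_inf)),
    }
    sig = SpatialSignatures(t_nod=t_nod, t_inf=t_inf, s_nod=s_nod, s_inf=s_inf,
                            stage="raw", overlaps=overlaps)
    sig.validate()
    return sig
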