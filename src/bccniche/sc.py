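"""scRNA-seq core: QC, normalization, feature selection, clustering,
annotation, differential expression, mixing diagnostics and module scoring.

Cells live in AnnData objects (cells x genes). Raw counts sit in ``.X`` until
:func:`lognormalize` moves them to ``layers["counts"]`` and replaces ``.X``
with log-normalized values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .config import QCParams

logger = logging.getLogger(__name__)


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# QC and normalization


def filter_cells(adata: AnnData, qc: QCParams) -> AnnData:
    """Retain cells by detected-gene count and mito/dissociation read fractions.

    Gene-count bounds are inclusive; the fraction thresholds are strict upper
    bounds. Order of retained cells is preserved.
    """
    qc.validate()
    counts = adata.X
    for name, genes in (("mitochondrial", qc.mito_genes),
                        ("dissociation", qc.dissoc_genes)):
        missing = set(genes) - set(adata.var_names)
        if missing:
            warnings.warn(f"{len(missing)} {name} genes absent from the matrix")
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    total_safe = np.where(total > 0, total, 1.0)

    def frac(genes) -> np.ndarray:
        cols = adata.var_names.isin(genes)
        if not cols.any():
            return np.zeros(adata.n_obs)
        return np.asarray(counts[:, cols].sum(axis=1)).ravel() / total_safe

    keep = ((detected >= qc.min_genes) & (detected <= qc.max_genes)
            & (frac(qc.mito_genes) < qc.max_mito_frac)
            & (frac(qc.dissoc_genes) < qc.max_dissoc_frac))
    if not keep.any():
        raise ValueError("cell QC removed every cell")
    logger.info("filter_cells kept %d/%d cells", int(keep.sum()), adata.n_obs)
    return adata[keep].copy()


def lognormalize(adata: AnnData, scale_factor: float = 10_000.0) -> AnnData:
    """ln(1 + count * scale_factor / cell_total) normalization.

    Returns a copy with normalized ``.X`` and raw counts preserved in
    ``layers["counts"]``. Zero-total cells are an error.
    """
    total = np.asarray(adata.X.sum(axis=1)).ravel().astype(float)
    zero = np.nonzero(total == 0)[0]
    if len(zero):
        raise ValueError(f"zero-total cell(s): {list(adata.obs_names[zero])}")
    out = adata.copy()
    out.layers["counts"] = adata.X.copy()
    x = adata.X.astype(float)
    if sparse.issparse(x):
        x = x.tocsr(copy=True)
        scale = scale_factor / total
        x = sparse.diags(scale) @ x
        x.data = np.log1p(x.data)
        out.X = x.tocsr()
    else:
        out.X = np.log1p(x * (scale_factor / total)[:, None])
    return out


def select_hvgs(adata: AnnData, n: int = 2000) -> list[str]:
    """Top-``n`` highly variable genes against a fitted mean-variance trend.

    The trend is a degree-2 polynomial of log variance on log mean fitted over
    genes with nonzero variance; genes are ranked by their residual (observed
    minus predicted log variance), ties broken by gene id. When fewer than
    ``n`` genes are eligible, all of them are returned with a warning.
    """
    x = _dense(adata.X)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    eligible = (var > 0) & (mean > 0)
    genes = adata.var_names[eligible]
    if len(genes) < n:
        warnings.warn(f"only {len(genes)} genes with nonzero variance; "
                      f"returning all of them")
    logm = np.log(mean[eligible])
    logv = np.log(var[eligible])
    coeffs = np.polyfit(logm, logv, deg=2)
    resid = logv - np.polyval(coeffs, logm)
    order = pd.DataFrame({"gene": genes, "resid": resid}).sort_values(
        ["resid", "gene"], ascending=[False, True])
    return order["gene"].head(n).tolist()


# ---------------------------------------------------------------------------
# Embedding and clustering


def scale_and_pca(adata: AnnData, hvgs: list[str], n_pcs: int = 25,
                  clip: float = 10.0, seed: int = 0) -> np.ndarray:
    """Scale-and-center the HVG submatrix (clip at ±``clip``) and run PCA."""
    sub = _dense(adata[:, hvgs].X)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.clip((sub - mu) / sd, -clip, clip)
    if n_pcs >= min(z.shape):
        raise ValueError(f"n_pcs={n_pcs} too large for matrix {z.shape}")
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(z)


def snn_graph(pcs: np.ndarray, k: int = 20, prune: float = 1 / 15
              ) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph: Jaccard weights of kNN sets, pruned.

    Neighbor sets include the cell itself (Seurat convention). Weights below
    ``prune`` are dropped; the result is symmetric.
    """
    n = pcs.shape[0]
    k_eff = min(k, n)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k_eff)
    adj = sparse.csr_matrix((np.ones(n * k_eff), (rows, idx.ravel())),
                            shape=(n, n))
    adj.setdiag(1)
    adj.data[:] = 1
    shared = adj @ adj.T                      # |N_i ∩ N_j|
    shared = shared.tocoo()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    union = sizes[shared.row] + sizes[shared.col] - shared.data
    jac = shared.data / union
    keep = (jac >= prune) & (shared.row != shared.col)
    return sparse.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])),
                             shape=(n, n))


def cluster_graph(graph: sparse.csr_matrix, resolution: float = 0.8,
                  seed: int = 0) -> pd.Categorical:
    """Leiden modularity clustering; labels contiguous, ordered by size."""
    coo = sparse.triu(graph, k=1).tocoo()
    g = ig.Graph(n=graph.shape[0],
                 edges=list(zip(coo.row.tolist(), coo.col.tolist())),
                 edge_attrs={"weight": coo.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    labels = np.asarray(part.membership)
    order = pd.Series(labels).value_counts().index.tolist()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def embed_and_cluster(adata: AnnData, hvgs: list[str], n_pcs: int = 25,
                      resolution: float = 0.8, k: int = 20,
                      prune: float = 1 / 15, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Scale → PCA → kNN → SNN → modularity clustering, deterministically.

    Returns ``(cluster_labels, pcs)``; labels are contiguous integers ordered
    by decreasing cluster size.
    """
    pcs = scale_and_pca(adata, hvgs, n_pcs=n_pcs, seed=seed)
    graph = snn_graph(pcs, k=k, prune=prune)
    labels = cluster_graph(graph, resolution=resolution, seed=seed)
    return labels, pcs


# ---------------------------------------------------------------------------
# Annotation


def flag_doublet_clusters(adata: AnnData, clusters: np.ndarray,
                          incompatible_pairs: list[tuple[str, str]]
                          ) -> dict[int, bool]:
    """Flag clusters where both genes of any incompatible pair are detected
    (>0) in more than half of the cluster's cells."""
    flags = {int(c): False for c in np.unique(clusters)}
    for ga, gb in incompatible_pairs:
        if ga not in adata.var_names or gb not in adata.var_names:
            warnings.warn(f"marker pair ({ga}, {gb}) not fully present; skipped")
            continue
        da = _dense(adata[:, ga].X).ravel() > 0
        db = _dense(adata[:, gb].X).ravel() > 0
        for c in flags:
            in_c = clusters == c
            if da[in_c].mean() > 0.5 and db[in_c].mean() > 0.5:
                flags[c] = True
    return flags


def annotate_clusters(adata: AnnData, clusters: np.ndarray,
                      marker_map: dict[str, list[str]]) -> dict[int, str]:
    """Assign each cluster the cell type whose markers have the highest mean
    expression there; ties break alphabetically with a warning."""
    means = {}
    for cell_type, genes in marker_map.items():
        present = [gene for gene in genes if gene in adata.var_names]
        if not present:
            raise ValueError(f"no markers of {cell_type} present")
        means[cell_type] = _dense(adata[:, present].X).mean(axis=1)
    out = {}
    for c in np.unique(clusters):
        in_c = clusters == c
        scores = {t: float(v[in_c].mean()) for t, v in means.items()}
        best = max(scores.values())
        winners = sorted(t for t, v in scores.items() if v == best)
        if len(winners) > 1:
            warnings.warn(f"cluster {c}: marker tie between {winners}; "
                          f"assigning {winners[0]}")
        out[int(c)] = winners[0]
    return out


# ---------------------------------------------------------------------------
# Differential expression


def rank_sum_deg(adata: AnnData, cells_a, cells_b,
                 correction: str = "fdr_bh") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DEG table between two cell groups.

    P-values come from the normal approximation with tie correction; log2
    fold-change back-transforms the log-normalized means through expm1 with a
    1e-9 pseudocount. Genes invariant across both groups get p = 1, lfc = 0.
    """
    cells_a, cells_b = pd.Index(cells_a), pd.Index(cells_b)
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both groups must be nonempty")
    if len(cells_a.intersection(cells_b)):
        raise ValueError("groups overlap")
    xa = _dense(adata[cells_a].X)
    xb = _dense(adata[cells_b].X)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    flat = (xa.std(axis=0) == 0) & (xb.std(axis=0) == 0) & (xa.mean(axis=0) == xb.mean(axis=0))
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    lfc = np.log2((mean_a + 1e-9) / (mean_b + 1e-9))
    lfc = np.where(flat, 0.0, lfc)
    padj = multipletests(p, method=correction)[1]
    return pd.DataFrame({
        "gene": adata.var_names, "log2fc": lfc, "p_value": p,
        "p_adjusted": np.maximum(padj, p),
        "mean_a": mean_a, "mean_b": mean_b,
    }).set_index("gene").sort_values("p_value")


# ---------------------------------------------------------------------------
# Module (signature) scoring


@dataclass
class ModuleScoreResult:
    scores: pd.Series
    signature_name: str
    n_bins: int
    n_ctrl: int
    seed: int


def _expression_bins(gene_means: pd.Series, n_bins: int) -> pd.Series:
    """Equal-frequency bins of genes by mean expression (rank-based cut)."""
    ranks = gene_means.rank(method="first")
    return pd.qcut(ranks, q=min(n_bins, len(gene_means)), labels=False)


def module_score(adata: AnnData, signature: list[str], name: str = "signature",
                 n_bins: int = 24, n_ctrl: int = 100, seed: int = 0
                 ) -> ModuleScoreResult:
    """Per-cell signature score with expression-matched random controls.

    Genes are binned into ``n_bins`` equal-frequency bins by mean expression;
    each signature gene contributes ``n_ctrl`` control genes drawn with
    replacement from its bin (``default_rng(seed)``, signature genes in the
    given order). The score is the mean signature expression minus the mean
    over all drawn control genes.
    """
    present = [gene for gene in signature if gene in adata.var_names]
    dropped = len(signature) - len(present)
    if dropped:
        warnings.warn(f"{name}: {dropped} signature genes absent, dropped")
    if not present:
        raise ValueError(f"{name}: no signature genes present in the matrix")
    x = _dense(adata.X)
    gene_means = pd.Series(x.mean(axis=0), index=adata.var_names)
    bins = _expression_bins(gene_means, n_bins)
    rng = np.random.default_rng(seed)
    ctrl_cols: list[np.ndarray] = []
    col_of = {gene: j for j, gene in enumerate(adata.var_names)}
    for gene in present:
        members = bins.index[bins == bins[gene]]
        picks = rng.choice(len(members), size=n_ctrl, replace=True)
        ctrl_cols.append(np.array([col_of[members[i]] for i in picks]))
    sig_expr = x[:, [col_of[gene] for gene in present]].mean(axis=1)
    ctrl_expr = x[:, np.concatenate(ctrl_cols)].mean(axis=1)
    scores = pd.Series(sig_expr - ctrl_expr, index=adata.obs_names, name=name)
    return ModuleScoreResult(scores=scores, signature_name=name,
                             n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)


# ---------------------------------------------------------------------------
# Mixing diagnostics


def lisi_score(embedding: np.ndarray, labels, k: int = 30) -> pd.Series:
    """Local inverse Simpson's index of ``labels`` over k nearest neighbors.

    1.0 means a one-label neighborhood; the maximum is the number of labels.
    """
    labels = pd.Series(np.asarray(labels))
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    idx = idx[:, 1:]                       # drop self
    codes = labels.astype("category").cat.codes.to_numpy()
    neigh = codes[idx]
    out = np.empty(n)
    n_labels = codes.max() + 1
    for i in range(n):
        p = np.bincount(neigh[i], minlength=n_labels) / k
        out[i] = 1.0 / float((p ** 2).sum())
    return pd.Series(out, name="lisi")
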