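"""Pseudotime ordering and graph autocorrelation screening.

Tumor cells are ordered along a deterministic trajectory: a minimum spanning
tree over cluster centroids in PC space, onto which each cell is projected;
pseudotime is the geodesic distance along the tree from the root centroid.
Genes varying along the trajectory are screened with Moran's I on a cell
neighbor graph, and the positive-autocorrelation set is intersected with a
curated list of secreted CAF activators (TGF-beta superfamily including the
activin subunit INHBA, PDGFs, EGF family, FGFs, SHH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


@dataclass
class TrajectoryResult:
    pseudotime: pd.Series
    tree_edges: list[tuple[int, int, float]]   # (cluster u, cluster v, length)
    root_cluster: int
    centroids: np.ndarray


def default_caf_activators() -> list[str]:
    """The shipped secreted CAF-activator gene list."""
    text = resources.files("bccniche.data").joinpath("caf_activators.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def compute_pseudotime(pcs: np.ndarray, clusters: pd.Series,
                       root_cluster) -> TrajectoryResult:
    """Centroid-MST pseudotime rooted at ``root_cluster``.

    Builds the Euclidean minimum spanning tree over cluster centroids,
    projects every cell onto its nearest tree edge, and returns the geodesic
    distance along the tree from the root centroid to the projection point.
    Deterministic; a single cluster degenerates to distance-to-centroid.
    """
    clusters = pd.Series(np.asarray(clusters), index=clusters.index
                         if isinstance(clusters, pd.Series) else None)
    labels = sorted(pd.unique(clusters))
    if root_cluster not in labels:
        raise ValueError(f"root cluster {root_cluster!r} not present")
    cent = np.vstack([pcs[(clusters == c).to_numpy()].mean(axis=0)
                      for c in labels])
    idx_of = {c: i for i, c in enumerate(labels)}
    root = idx_of[root_cluster]
    index = clusters.index if clusters.index is not None else pd.RangeIndex(len(pcs))

    if len(labels) == 1:
        warnings.warn("single cluster: pseudotime is distance to the centroid")
        pt = np.linalg.norm(pcs - cent[0], axis=1)
        return TrajectoryResult(pd.Series(pt, index=index, name="pseudotime"),
                                [], root_cluster, cent)

    dmat = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
    mst = minimum_spanning_tree(dmat).tocoo()
    edges = [(int(u), int(v), float(w))
             for u, v, w in zip(mst.row, mst.col, mst.data)]
    adj = sparse.csr_matrix((mst.data, (mst.row, mst.col)),
                            shape=dmat.shape)
    node_dist = dijkstra(adj, directed=False, indices=root)

    # project every cell onto its nearest tree edge
    pt = np.empty(len(pcs))
    best = np.full(len(pcs), np.inf)
    for u, v, w in edges:
        a, b = cent[u], cent[v]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((pcs - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(pcs - proj, axis=1)
        better = d < best
        # geodesic to the projection point through the nearer route
        geo = np.minimum(node_dist[u] + t * w, node_dist[v] + (1.0 - t) * w)
        pt[better] = geo[better]
        best[better] = d[better]
    pt = pt - pt.min()
    return TrajectoryResult(pd.Series(pt, index=index, name="pseudotime"),
                            edges, root_cluster, cent)


def knn_graph(pcs: np.ndarray, k: int = 20) -> sparse.csr_matrix:
    """Symmetrized binary k-nearest-neighbor graph in PC space."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    idx = idx[:, 1:]
    rows = np.repeat(np.arange(n), idx.shape[1])
    w = sparse.csr_matrix((np.ones(idx.size), (rows, idx.ravel())), shape=(n, n))
    w = w.maximum(w.T)
    w.setdiag(0)
    w.eliminate_zeros()
    return w


def morans_i(x: np.ndarray, graph: sparse.spmatrix) -> tuple[float, float]:
    """Moran's I of ``x`` on a symmetric nonnegative weight graph, with a
    two-sided p-value from the randomization-assumption normal approximation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    z = x - x.mean()
    s2 = float(z @ z)
    if s2 == 0:
        raise ValueError("Moran's I undefined for constant input")
    w = sparse.csr_matrix(graph, dtype=float)
    w = w - sparse.diags(w.diagonal())
    W = float(w.sum())
    if W <= 0:
        raise ValueError("graph has zero total weight")
    num = float(z @ (w @ z))
    I = n / W * num / s2
    if n < 4:
        return I, 1.0       # randomization variance needs n >= 4

    EI = -1.0 / (n - 1)
    wt = w + w.T
    s1 = 0.5 * float(wt.multiply(wt).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2_ = float(((row + col) ** 2).sum())
    b2 = n * float((z ** 4).sum()) / s2 ** 2
    n2 = n * n
    var = ((n * ((n2 - 3 * n + 3) * s1 - n * s2_ + 3 * W ** 2)
            - b2 * ((n2 - n) * s1 - 2 * n * s2_ + 6 * W ** 2))
           / ((n - 1) * (n - 2) * (n - 3) * W ** 2)) - EI ** 2
    if var <= 0:
        return I, 1.0
    zscore = (I - EI) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return I, float(p)


def morans_i_table(adata_or_matrix, graph: sparse.spmatrix,
                   genes=None) -> pd.DataFrame:
    """Moran's I per gene on the cell graph, vectorized, with BH q-values.

    Accepts an AnnData (log-normalized ``.X``) or a cells x genes DataFrame.
    Constant genes get I = 0 and p = 1.
    """
    if hasattr(adata_or_matrix, "var_names"):
        names = (pd.Index(genes) if genes is not None
                 else adata_or_matrix.var_names)
        sub = adata_or_matrix[:, [g for g in names
                                  if g in adata_or_matrix.var_names]]
        x = sub.X.toarray() if sparse.issparse(sub.X) else np.asarray(sub.X)
        names = sub.var_names
    else:
        df = adata_or_matrix if genes is None else adata_or_matrix[genes]
        x, names = df.to_numpy(dtype=float), df.columns
    n = x.shape[0]
    w = sparse.csr_matrix(graph, dtype=float)
    w = w - sparse.diags(w.diagonal())
    W = float(w.sum())
    z = x - x.mean(axis=0)
    s2 = (z ** 2).sum(axis=0)
    num = (z * (w @ z)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = n / W * num / s2

    EI = -1.0 / (n - 1)
    wt = w + w.T
    s1 = 0.5 * float(wt.multiply(wt).sum())
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2_ = float(((row + col) ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = n * (z ** 4).sum(axis=0) / s2 ** 2
    n2 = n * n
    var = ((n * ((n2 - 3 * n + 3) * s1 - n * s2_ + 3 * W ** 2)
            - b2 * ((n2 - n) * s1 - 2 * n * s2_ + 6 * W ** 2))
           / ((n - 1) * (n - 2) * (n - 3) * W ** 2)) - EI ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        zscore = (I - EI) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(zscore))
    bad = ~np.isfinite(I)
    I = np.where(bad, 0.0, I)
    p = np.where(bad | ~np.isfinite(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": names, "morans_i": I, "p_value": p,
                         "q_value": q}).set_index("gene")


def select_trajectory_genes(table: pd.DataFrame, cutoff: float = 0.1
                            ) -> list[str]:
    """Genes with Moran's I strictly above ``cutoff``, by decreasing I."""
    sel = table[table["morans_i"] > cutoff].sort_values(
        "morans_i", ascending=False)
    return sel.index.tolist()


def overlap_with_activators(trajectory_genes: list[str],
                            activators=None) -> list[str]:
    """Trajectory genes that are known CAF activators, preserving the
    autocorrelation ordering."""
    if activators is None:
        activators = default_caf_activators()
    activators = set(activators)
    return [g for g in trajectory_genes if g in activators]
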