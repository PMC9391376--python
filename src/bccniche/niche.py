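"""Niche mapping: project filtered spatial signatures onto single cells,
rank subclusters by the INF-NOD score difference, and quantify the
NOD/INF anticorrelation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .sc import ModuleScoreResult


@dataclass
class ClusterRanking:
    """Subclusters ordered by mean INF-NOD score difference.

    ``table`` rows follow ascending mean difference; columns: cluster (the
    original label), rank_label (TC1..TCk or FC1..FCk), mean_diff, group.
    """

    table: pd.DataFrame
    group_boundaries: tuple[int, ...]
    prefix: str = "TC"

    @property
    def ordered_clusters(self) -> list:
        return self.table["cluster"].tolist()

    def group_of(self) -> dict:
        return dict(zip(self.table["cluster"], self.table["group"]))


def score_difference(score_inf: ModuleScoreResult,
                     score_nod: ModuleScoreResult) -> pd.Series:
    """Per-cell INF minus NOD module score."""
    if not score_inf.scores.index.equals(score_nod.scores.index):
        raise ValueError("score vectors cover different cells")
    return (score_inf.scores - score_nod.scores).rename("score_diff")


def _default_groups(k: int) -> tuple[tuple[int, ...], list[str]]:
    """Quantile grouping: quartile singleton-style split for k=4, else
    25%/75% cuts into Low/Med/High."""
    if k == 1:
        return (1,), ["Med"]
    if k == 2:
        return (1, 1), ["Low", "High"]
    if k == 3:
        return (1, 1, 1), ["Low", "Med", "High"]
    if k == 4:
        return (1, 1, 1, 1), ["Low", "MedLow", "MedHigh", "High"]
    lo = int(round(0.25 * k))
    hi = int(round(0.75 * k))
    lo = max(1, lo)
    hi = min(k - 1, max(lo + 1, hi))
    return (lo, hi - lo, k - hi), ["Low", "Med", "High"]


def rank_clusters(diff: pd.Series, clusters: pd.Series,
                  group_spec: Optional[Sequence[int]] = None,
                  group_names: Optional[Sequence[str]] = None,
                  prefix: str = "TC") -> ClusterRanking:
    """Rank clusters by ascending mean score difference and group them.

    ``group_spec`` gives explicit contiguous group sizes (must sum to the
    cluster count); by default groups follow cluster-count quantile cuts at
    25%/75% (Low/Med/High), or four quartile groups when there are exactly
    four clusters. Ties in mean difference break by original cluster id.
    """
    clusters = clusters.reindex(diff.index)
    if clusters.isna().any():
        raise ValueError("every cell must be clustered")
    means = diff.groupby(clusters, observed=True).mean()
    sizes = clusters.value_counts()
    if (sizes == 0).any():
        raise ValueError("empty cluster")
    order = means.reset_index()
    order.columns = ["cluster", "mean_diff"]
    order["cluster_str"] = order["cluster"].astype(str)
    order = order.sort_values(["mean_diff", "cluster_str"]).reset_index(drop=True)
    k = len(order)
    if group_spec is None:
        spec, names = _default_groups(k)
    else:
        spec = tuple(int(s) for s in group_spec)
        if sum(spec) != k:
            raise ValueError(f"group sizes {spec} do not sum to {k} clusters")
        names = list(group_names) if group_names is not None else \
            [f"G{i + 1}" for i in range(len(spec))]
    groups = []
    for name, size in zip(names, spec):
        groups += [name] * size
    order["rank_label"] = [f"{prefix}{i + 1}" for i in range(k)]
    order["group"] = groups
    boundaries = tuple(np.cumsum(spec)[:-1].tolist())
    return ClusterRanking(table=order[["cluster", "rank_label", "mean_diff",
                                       "group"]],
                          group_boundaries=boundaries, prefix=prefix)


def signature_anticorrelation(score_nod: Union[ModuleScoreResult, pd.Series],
                              score_inf: Union[ModuleScoreResult, pd.Series]
                              ) -> dict:
    """Pearson correlation (with two-sided p) between the NOD and INF scores;
    Spearman reported alongside."""
    nod = score_nod.scores if isinstance(score_nod, ModuleScoreResult) else score_nod
    inf = score_inf.scores if isinstance(score_inf, ModuleScoreResult) else score_inf
    if len(nod) < 3:
        raise ValueError("need at least 3 cells")
    if float(np.std(nod)) == 0 or float(np.std(inf)) == 0:
        raise ValueError("zero variance in a score vector")
    pear = stats.pearsonr(nod, inf)
    spear = stats.spearmanr(nod, inf)
    return {"rho": float(pear.statistic), "p_value": float(pear.pvalue),
            "spearman_rho": float(spear.statistic),
            "spearman_p": float(spear.pvalue)}
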