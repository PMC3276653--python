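"""Molecular subtype identification by hierarchical clustering of animals.

Animals are clustered on per-gene standardized (factor-adjusted) expression
restricted to a trait-associated gene list; subgroups are then named by their
majority fat/lean status (fat1, fat2, lean1, lean2, mixed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .simulate import trait_status

__all__ = ["SubtypeAssignment", "cluster_animals", "label_subtypes", "suggest_k"]


@dataclass
class SubtypeAssignment:
    """A partition of the animals with its dendrogram.

    ``labels`` maps animal id -> integer subgroup (1..k); ``names`` (after
    :func:`label_subtypes`) maps animal id -> a fat1/fat2/lean1/lean2/mixed
    style name.  ``linkage`` is the scipy merge tree; cutting it into ``k``
    clusters reproduces ``labels``.
    """

    labels: pd.Series
    linkage: np.ndarray
    k: int
    method: str
    metric: str
    names: pd.Series | None = None
    status: pd.Series | None = None

    @property
    def groups(self) -> dict:
        key = self.names if self.names is not None else self.labels
        return {g: list(key.index[key == g]) for g in key.unique()}


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def cluster_animals(
    expr: pd.DataFrame,
    gene_list,
    k: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> SubtypeAssignment:
    """Agglomerative clustering of animals on standardized expression.

    Parameters
    ----------
    expr : DataFrame, genes x animals (typically factor-adjusted values)
    gene_list : iterable of gene ids to cluster on (must be non-empty)
    k : int, number of subgroups to cut
    method, metric : scipy linkage/pdist options; Ward on Euclidean distances
        of per-gene z-scores is the default and the one used throughout.

    The per-gene standardization makes the result invariant to per-gene
    affine rescaling; gene order does not matter.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list is empty; nothing to cluster on")
    missing = [g for g in gene_list if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing[:5]}")
    if k < 1 or k > expr.shape[1]:
        raise ValueError("k must lie in [1, n_animals]")
    data = _standardize(expr.loc[gene_list].to_numpy(dtype=float)).T  # animals x genes
    if method == "ward" and metric != "euclidean":
        raise ValueError("Ward linkage requires Euclidean distances")
    Z = hierarchy.linkage(pdist(data, metric=metric), method=method)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=expr.columns, name="subgroup")
    return SubtypeAssignment(labels=labels, linkage=Z, k=k, method=method, metric=metric)


def label_subtypes(assignment: SubtypeAssignment, trait: pd.Series) -> SubtypeAssignment:
    """Name subgroups by majority fat/lean status.

    Fat-majority groups become fat1, fat2, ... and lean-majority groups
    lean1, lean2, ..., each ordered by decreasing size (ties broken by mean
    trait, fatter first for fat groups and leaner first for lean groups);
    anything else, including groups with no fat or lean member, is "mixed".
    """
    status = trait_status(trait.reindex(assignment.labels.index))
    names = pd.Series("", index=assignment.labels.index, dtype=object)
    records = []
    for g in np.unique(assignment.labels):
        members = assignment.labels.index[assignment.labels == g]
        st = status.loc[members]
        n_f, n_l = int((st == "F").sum()), int((st == "L").sum())
        mean_trait = float(trait.loc[members].mean())
        if n_f > len(members) / 2:
            kind = "fat"
        elif n_l > len(members) / 2:
            kind = "lean"
        else:
            kind = "mixed"
        records.append((g, kind, len(members), mean_trait))
    for kind, fatter_first in (("fat", True), ("lean", False)):
        group_ids = [r for r in records if r[1] == kind]
        group_ids.sort(key=lambda r: (-r[2], -r[3] if fatter_first else r[3]))
        for rank, (g, _, _, _) in enumerate(group_ids, start=1):
            names[assignment.labels == g] = f"{kind}{rank}"
    n_mixed = sum(1 for r in records if r[1] == "mixed")
    for g, kind, _, _ in records:
        if kind == "mixed":
            names[assignment.labels == g] = "mixed"
    if n_mixed > 1:
        # disambiguate multiple mixed groups
        rank = 1
        for g, kind, _, _ in records:
            if kind == "mixed":
                names[assignment.labels == g] = f"mixed{rank}"
                rank += 1
    assignment.names = names
    assignment.status = status
    return assignment


def suggest_k(expr: pd.DataFrame, gene_list, k_range=range(2, 9), method="ward", metric="euclidean") -> int:
    """Silhouette-based suggestion for k (advisory only, never auto-applied)."""
    from scipy.spatial.distance import squareform

    gene_list = list(gene_list)
    data = _standardize(expr.loc[gene_list].to_numpy(dtype=float)).T
    D = squareform(pdist(data, metric=metric))
    Z = hierarchy.linkage(pdist(data, metric=metric), method=method)
    best_k, best_s = None, -np.inf
    for k in k_range:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        s = _mean_silhouette(D, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = D.shape[0]
    vals = []
    for i in range(n):
        own = labels == labels[i]
        if own.sum() <= 1:
            vals.append(0.0)
            continue
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(
            D[i, labels == g].mean() for g in np.unique(labels) if g != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
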