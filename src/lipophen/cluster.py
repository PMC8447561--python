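"""Patient phenotyping by hierarchical clustering on Spearman-correlation
distance with Ward's minimum-variance linkage.

Patients are compared by the Spearman rank correlation ρ between their
z-scored feature profiles; the dissimilarity is d = 1 − ρ ∈ [0, 2].  Ward
linkage is run on these dissimilarities through the Lance–Williams recurrence
in its squared-update form: pairwise squared heights S start at d² and merge
(A∪B) against K updates as

    S[(A∪B), K] = ((n_A+n_K) S[A,K] + (n_B+n_K) S[B,K] − n_K S[A,B]) / (n_A+n_B+n_K)

with merge height √S — for Euclidean inputs this is exactly Ward's
minimum-variance criterion; on a correlation dissimilarity it is the same
heuristic combination the phenotyping protocol prescribes.  Ties are broken
deterministically by the lowest (i, j) index pair, so runs need no seed.

The "first two clusters" (the k=2 cut) become the Hypolipoprotein /
Normolipoprotein phenotypes; the semantic labelling anchors on the cluster
median of HDL-C rather than dendrogram drawing order, which is
layout-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "DistanceMatrix", "LinkageTree", "ClusterAssignment", "ClusterQuality",
    "spearman_distance", "ward_linkage", "cut_tree", "calinski_harabasz",
    "elbow_curve", "label_clusters", "SpearmanWardClusterer",
    "HYPO", "NORMO",
]

HYPO = "hypolipoprotein"
NORMO = "normolipoprotein"


class ClusteringError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric patient-by-patient dissimilarity d = 1 − ρ_spearman."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = self.values
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ClusteringError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ClusteringError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ClusteringError("distance matrix diagonal not zero")
        if d.min() < -1e-10 or d.max() > 2.0 + 1e-10:
            raise ClusteringError("distances outside [0, 2]")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class LinkageTree:
    """Sequence of n−1 agglomerative merges in the 4-column convention
    (left id, right id, height, merged size); leaves are 0..n−1, merge i
    creates node n+i."""

    merges: np.ndarray      # (n-1, 4)
    ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def leaf_order(self) -> list[int]:
        """Dendrogram leaf ordering by depth-first traversal (left first)."""
        n = self.n_leaves
        if n == 1:
            return [0]
        children = {n + i: (int(m[0]), int(m[1])) for i, m in enumerate(self.merges)}
        order: list[int] = []
        stack = [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return order

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ClusterAssignment:
    """Per-patient cluster index for one k, with semantic labels at k=2."""

    index: np.ndarray               # cluster index per patient
    ids: list[str]
    k: int
    labels: Optional[dict[int, str]] = None     # cluster index -> semantic label

    def semantic(self) -> pd.Series:
        if self.labels is None:
            raise ClusteringError("semantic labels defined only after label_clusters")
        return pd.Series([self.labels[int(c)] for c in self.index],
                         index=self.ids, name="phenotype")

    def members(self, cluster: int) -> list[str]:
        return [pid for pid, c in zip(self.ids, self.index) if c == cluster]


@dataclass
class ClusterQuality:
    """Elbow (within-cluster SS) and Calinski–Harabasz diagnostics per k."""

    k_values: list[int]
    within_ss: dict[int, float] = field(default_factory=dict)
    ch_score: dict[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values,
            "within_ss": [self.within_ss.get(k, np.nan) for k in self.k_values],
            "calinski_harabasz": [self.ch_score.get(k, np.nan) for k in self.k_values],
        })

    def best_k(self) -> int:
        """k maximizing the Calinski–Harabasz score (ties to the smaller k)."""
        ks = [k for k in self.k_values if k in self.ch_score]
        return min(ks, key=lambda k: (-self.ch_score[k], k))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def spearman_distance(z_matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise patient dissimilarity 1 − ρ_spearman between feature profiles.

    Ranks use average tie handling.  A patient whose profile has zero rank
    variance (all features tied) has undefined correlations and raises.
    """
    if z_matrix.isna().any().any():
        raise ClusteringError("z-matrix contains missing values")
    n, p = z_matrix.shape
    if n < 2 or p < 2:
        raise ClusteringError("need >= 2 patients and >= 2 features")
    X = z_matrix.to_numpy(dtype=float)
    ranks = rankdata(X, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    flat = np.where(norms == 0)[0]
    if flat.size:
        bad = [z_matrix.index[i] for i in flat]
        raise ClusteringError(f"all-tied feature profile (undefined ρ): {bad}")
    rho = (centered @ centered.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(values=d, ids=list(map(str, z_matrix.index)))


def ward_linkage(dist: DistanceMatrix) -> LinkageTree:
    """Agglomerate by Ward's criterion via the Lance–Williams recurrence.

    Works on squared dissimilarities; heights are the square roots, so two
    singletons merge at exactly their input distance.  Tie-break: the pair
    with the lowest (smaller index, larger index) among minimal distances.
    """
    n = len(dist)
    if n < 2:
        raise ClusteringError("need >= 2 patients to cluster")
    # clusters are indexed by the slot of their lowest-index member; a merge
    # keeps the lower slot, so row-major argmin ties resolve to the lowest
    # (i, j) pair among minimal distances
    S = dist.values.astype(float) ** 2          # squared heights
    np.fill_diagonal(S, np.inf)
    node_of = np.arange(n)                      # slot -> tree node id
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        flat = np.argmin(S)
        a, b = divmod(int(flat), n)
        if a > b:
            a, b = b, a
        sab = S[a, b]
        height = np.sqrt(max(sab, 0.0))
        na, nb = sizes[a], sizes[b]
        merges[step] = (node_of[a], node_of[b], height, na + nb)

        # Lance–Williams Ward update of (a∪b) against every other cluster
        others = alive.copy()
        others[[a, b]] = False
        nc = sizes[others]
        upd = ((na + nc) * S[a, others] + (nb + nc) * S[b, others]
               - nc * sab) / (na + nb + nc)
        S[a, others] = upd
        S[others, a] = upd
        S[b, :] = np.inf
        S[:, b] = np.inf
        alive[b] = False
        sizes[a] = na + nb
        node_of[a] = n + step

    return LinkageTree(merges=merges, ids=list(dist.ids))


def cut_tree(tree: LinkageTree, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k clusters by removing the k−1 highest merges.

    Cluster indices are assigned by order of first patient appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} out of range [1, {n}]")
    parent = list(range(n + max(n - 1, 0)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n - k):          # apply all but the k-1 highest merges
        left, right, _, _ = tree.merges[i]
        node = n + i
        parent[find(int(left))] = node
        parent[find(int(right))] = node

    index = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
        index[leaf] = seen[root]
    return ClusterAssignment(index=index, ids=list(tree.ids), k=k)


def calinski_harabasz(z_matrix: pd.DataFrame, assignment: ClusterAssignment) -> float:
    """Variance-ratio criterion CH = [B/(k−1)] / [W/(n−k)] on the z-matrix.

    B is the size-weighted squared distance of cluster centroids from the
    grand centroid, W the pooled within-cluster squared distance (Euclidean).
    Perfectly compact clusters (W = 0) return +inf with a warning.
    """
    X = z_matrix.to_numpy(dtype=float)
    labels = assignment.index
    n = len(X)
    k = assignment.k
    if k < 2:
        raise ClusteringError("CH requires k >= 2")
    if n <= k:
        raise ClusteringError("CH requires n > k")
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise ClusteringError("empty cluster in assignment")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for j in range(k):
        pts = X[labels == j]
        c = pts.mean(axis=0)
        B += len(pts) * float(((c - grand) ** 2).sum())
        W += float(((pts - c) ** 2).sum())
    if W == 0.0:
        warnings.warn("zero within-cluster dispersion; CH is +inf")
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def elbow_curve(z_matrix: pd.DataFrame, tree: LinkageTree,
                k_range: Sequence[int]) -> ClusterQuality:
    """Within-cluster SS per k (elbow) plus CH for k ≥ 2 from tree cuts."""
    X = z_matrix.to_numpy(dtype=float)
    n = len(X)
    quality = ClusterQuality(k_values=list(k_range))
    for k in k_range:
        assign = cut_tree(tree, k)
        W = 0.0
        for j in range(k):
            pts = X[assign.index == j]
            W += float(((pts - pts.mean(axis=0)) ** 2).sum())
        quality.within_ss[k] = W
        if 2 <= k < n:
            quality.ch_score[k] = calinski_harabasz(z_matrix, assign)
    return quality


def label_clusters(assignment: ClusterAssignment, table: pd.DataFrame,
                   anchor_feature: str = "hdl_c") -> ClusterAssignment:
    """Attach Hypo/Normo semantics to a k=2 cut.

    The cluster with the lower median of the anchor feature (HDL-C by
    default, the top discriminating feature) is the Hypolipoprotein
    phenotype.  Median ties fall back to the lower mean, then the cluster
    index, with a warning.
    """
    if assignment.k != 2:
        raise ClusteringError("semantic labels are defined only for k=2")
    if anchor_feature not in table.columns:
        raise ClusteringError(f"anchor feature {anchor_feature!r} not in table")
    vals = table[anchor_feature]
    med = [float(vals.loc[assignment.members(c)].median()) for c in (0, 1)]
    if med[0] != med[1]:
        hypo = 0 if med[0] < med[1] else 1
    else:
        mean = [float(vals.loc[assignment.members(c)].mean()) for c in (0, 1)]
        warnings.warn("anchor medians tied; breaking tie by mean then index")
        hypo = 0 if mean[0] < mean[1] or mean[0] == mean[1] else 1
    labels = {hypo: HYPO, 1 - hypo: NORMO}
    return ClusterAssignment(index=assignment.index.copy(), ids=list(assignment.ids),
                             k=2, labels=labels)


class SpearmanWardClusterer(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper over the full distance → linkage → cut chain.

    Parameters
    ----------
    n_clusters : int
        Number of clusters to extract (2 for the phenotyping protocol).
    anchor_feature : str or None
        Feature anchoring the Hypo/Normo semantics at ``n_clusters=2``; pass
        None to skip labelling.

    Attributes (after fit)
    ----------------------
    distance_, linkage_, assignment_, labels_, quality_
    """

    def __init__(self, n_clusters: int = 2, anchor_feature: Optional[str] = "hdl_c",
                 k_range: Optional[Sequence[int]] = None):
        self.n_clusters = n_clusters
        self.anchor_feature = anchor_feature
        self.k_range = k_range

    def fit(self, X: pd.DataFrame, y=None) -> "SpearmanWardClusterer":
        # rows are processed in sorted patient-id order so the whole pipeline
        # is invariant to input row permutations (tie-breaks included)
        Xs = X.iloc[np.argsort(X.index.astype(str), kind="stable")]
        self.distance_ = spearman_distance(Xs)
        self.linkage_ = ward_linkage(self.distance_)
        assign = cut_tree(self.linkage_, self.n_clusters)
        if self.n_clusters == 2 and self.anchor_feature is not None:
            assign = label_clusters(assign, Xs, anchor_feature=self.anchor_feature)
        self.assignment_ = assign
        id_to_cluster = dict(zip(assign.ids, assign.index))
        self.labels_ = np.array([id_to_cluster[str(i)] for i in X.index])
        ks = self.k_range if self.k_range is not None \
            else range(1, min(11, len(X)))
        self.quality_ = elbow_curve(Xs, self.linkage_, list(ks))
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
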