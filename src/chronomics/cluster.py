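"""Consensus clustering of expression time profiles.

Robust clusters are obtained by averaging over many randomized K-means runs:

1. :func:`kmeans_scan` — repeated K-means on the gene-wise normalized rows
   (default 30 repeats for every k in 6..14, i.e. 270 runs);
2. :func:`co_occurrence` — the gene x gene empirical probability of falling
   in the same cluster across runs;
3. :func:`consensus_cut` — Ward hierarchical clustering of the dissimilarity
   ``1 - co-occurrence``, cut into K consensus clusters (default 12), each
   summarized by its mean +/- sd time profile.

Genes that co-cluster in most runs have near-zero dissimilarity and are
grouped reliably; chance co-clusterings average out. A stability diagnostic
(within/between co-occurrence per K) supports the user's choice of K, and
optimal leaf ordering arranges dendrogram leaves to minimize adjacent
dissimilarity for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import ValidationError
from .preprocess import NormalizedMatrix

__all__ = [
    "Partition",
    "PartitionSet",
    "CoOccurrenceMatrix",
    "ClusterAssignment",
    "kmeans_scan",
    "co_occurrence",
    "consensus_cut",
    "stability_diagnostic",
    "optimal_leaf_order",
    "export_heatmap_tables",
    "ConsensusClusterModel",
    "ConsensusClusterResults",
]


@dataclass
class Partition:
    k: int
    repeat: int
    labels: np.ndarray  # one label in 0..k-1 per gene


@dataclass
class PartitionSet:
    gene_ids: list[str]
    partitions: list[Partition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partitions)


@dataclass
class CoOccurrenceMatrix:
    """Pairwise co-membership probability over a set of clustering runs."""

    gene_ids: list[str]
    values: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValidationError("co-occurrence matrix shape mismatch")


@dataclass
class ClusterAssignment:
    """Consensus partition with dendrogram, leaf order and time profiles."""

    gene_ids: list[str]
    labels: np.ndarray           # consensus cluster id 1..K per gene
    linkage: np.ndarray          # scipy linkage matrix on 1 - C
    leaf_order: np.ndarray       # gene indices in display order
    group_labels: list[str]
    profile_mean: np.ndarray     # K x n_groups
    profile_sd: np.ndarray       # K x n_groups

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def cluster_genes(self, cluster_id: int) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.labels) if c == cluster_id]

    def membership(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(c) for c in self.labels)))


def kmeans_scan(norm: NormalizedMatrix, k_min: int = 6, k_max: int = 14,
                repeats: int = 30,
                seed: int | np.random.SeedSequence | None = 0) -> PartitionSet:
    """Run K-means ``repeats`` times for every k in ``k_min..k_max``.

    Each run uses random-point initialization, Lloyd iterations capped at
    300, and Euclidean distance on the normalized rows. Degenerate
    (constant) genes must be dropped before scanning.
    """
    if norm.degenerate.any():
        norm = norm.drop_degenerate()
    X = norm.values
    n = X.shape[0]
    if not 1 <= k_min <= k_max:
        raise ValidationError("need 1 <= k_min <= k_max")
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < number of genes ({n})")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    child_seeds = ss.generate_state((k_max - k_min + 1) * repeats) % (2 ** 31)
    pset = PartitionSet(list(norm.gene_ids))
    i = 0
    for k in range(k_min, k_max + 1):
        for rep in range(repeats):
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                km = KMeans(n_clusters=k, init="random", n_init=1, max_iter=300,
                            algorithm="lloyd", random_state=int(child_seeds[i]))
                labels = km.fit_predict(X)
            pset.partitions.append(Partition(k, rep, labels))
            i += 1
    return pset


def co_occurrence(pset: PartitionSet) -> CoOccurrenceMatrix:
    """Exact co-membership frequency over all partitions."""
    if not pset.partitions:
        raise ValidationError("need at least one partition")
    n = len(pset.gene_ids)
    counts = np.zeros((n, n))
    for part in pset.partitions:
        lab = part.labels
        counts += lab[:, None] == lab[None, :]
    C = counts / len(pset.partitions)
    np.fill_diagonal(C, 1.0)
    return CoOccurrenceMatrix(list(pset.gene_ids), C, len(pset.partitions))


def _ward_linkage(C: CoOccurrenceMatrix) -> np.ndarray:
    D = 1.0 - C.values
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return hierarchy.linkage(squareform(D, checks=False), method="ward")


def _olo_exact(Z: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Exact leaf-order DP: min total adjacent dissimilarity over all
    dendrogram-consistent orders.

    For every internal node and every (leftmost, rightmost) leaf pair from
    its two subtrees, the cheapest ordering cost is computed bottom-up with
    two min-plus products per merge; backpointers reconstruct the order.
    """
    n = Z.shape[0] + 1
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    info: dict[int, tuple] = {}
    for k in range(Z.shape[0]):
        a, b = int(Z[k, 0]), int(Z[k, 1])
        La, Lb = leaves[a], leaves[b]
        v = n + k
        Dab = D[np.ix_(La, Lb)]
        # T[u, j] = min_m M[a][u, m] + D[m, j]  (m, u in La; j in Lb)
        S = M[a][:, :, None] + Dab[None, :, :]
        m_arg = S.argmin(axis=1)
        T = np.take_along_axis(S, m_arg[:, None, :], axis=1)[:, 0, :]
        # R[u, w] = min_j T[u, j] + M[b][j, w]
        S2 = T[:, :, None] + M[b][None, :, :]
        k_arg = S2.argmin(axis=1)
        R = np.take_along_axis(S2, k_arg[:, None, :], axis=1)[:, 0, :]
        p, q = len(La), len(Lb)
        Mv = np.full((p + q, p + q), np.inf)
        Mv[:p, p:] = R
        Mv[p:, :p] = R.T
        leaves[v] = La + Lb
        M[v] = Mv
        info[v] = (a, b, {u: i for i, u in enumerate(La)},
                   {w: j for j, w in enumerate(Lb)}, m_arg, k_arg)
        del M[a], M[b]

    root = n + Z.shape[0] - 1
    ui, wi = np.unravel_index(int(np.argmin(M[root])), M[root].shape)
    L = leaves[root]

    def build(v: int, u: int, w: int) -> list[int]:
        if v < n:
            return [u]
        a, b, ia, ib, m_arg, k_arg = info[v]
        if u in ia:
            j = k_arg[ia[u], ib[w]]
            m = m_arg[ia[u], j]
            return build(a, u, leaves[a][m]) + build(b, leaves[b][j], w)
        return build(v, w, u)[::-1]

    return np.array(build(root, L[ui], L[wi]))


def optimal_leaf_order(Z: np.ndarray, D: np.ndarray,
                       exact_cap: int = 300) -> np.ndarray:
    """Dendrogram-consistent leaf order minimizing adjacent dissimilarity.

    Uses an exact dynamic program up to ``exact_cap`` leaves (cubic cost);
    beyond that, falls back to a fast near-optimal subtree reordering.
    """
    n = Z.shape[0] + 1
    if n <= 2:
        return hierarchy.leaves_list(Z)
    Dn = ((D + D.T) / 2.0).copy()
    np.fill_diagonal(Dn, 0.0)
    if n > exact_cap:
        Zo = hierarchy.optimal_leaf_ordering(Z, squareform(Dn, checks=False))
        return hierarchy.leaves_list(Zo)
    return _olo_exact(Z, Dn)


def consensus_cut(C: CoOccurrenceMatrix, n_clusters: int,
                  norm: NormalizedMatrix | None = None,
                  olo_cap: int = 2000) -> ClusterAssignment:
    """Cut the Ward tree of ``1 - C`` into the consensus partition.

    Consensus cluster ids are renumbered 1..K in dendrogram leaf order so
    adjacent clusters in a heatmap get consecutive ids. When ``norm`` is
    given, per-cluster mean and sd time profiles are computed from its
    group means.
    """
    n = len(C.gene_ids)
    if not 1 <= n_clusters <= n:
        raise ValidationError("need 1 <= K <= number of genes")
    Z = _ward_linkage(C)
    raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    D = 1.0 - C.values
    leaf_order = optimal_leaf_order(Z, D, exact_cap=olo_cap)
    # relabel clusters by order of first appearance along the leaves
    relabel: dict[int, int] = {}
    for idx in leaf_order:
        relabel.setdefault(int(raw[idx]), len(relabel) + 1)
    labels = np.array([relabel[int(c)] for c in raw])
    K = labels.max()

    if norm is not None:
        if norm.degenerate.any():
            norm = norm.drop_degenerate()
        if list(norm.gene_ids) != list(C.gene_ids):
            norm_idx = {g: i for i, g in enumerate(norm.gene_ids)}
            rows = [norm_idx[g] for g in C.gene_ids]
            values = norm.values[rows]
        else:
            values = norm.values
        groups = norm.groups
        gcols = norm.group_columns()
        pm = np.zeros((K, len(groups)))
        psd = np.zeros((K, len(groups)))
        for c in range(1, K + 1):
            rows = labels == c
            for j, g in enumerate(groups):
                block = values[np.ix_(rows, gcols[g])]
                pm[c - 1, j] = block.mean()
                psd[c - 1, j] = block.std(ddof=1) if block.size > 1 else 0.0
    else:
        groups, pm, psd = [], np.zeros((K, 0)), np.zeros((K, 0))

    return ClusterAssignment(list(C.gene_ids), labels, Z, leaf_order,
                             list(groups), pm, psd)


def stability_diagnostic(C: CoOccurrenceMatrix,
                         k_range: Sequence[int]) -> pd.DataFrame:
    """Within/between co-occurrence of the consensus cut across K.

    Cohesion is the mean co-occurrence over within-cluster gene pairs,
    separation the mean over between-cluster pairs; both guide the choice
    of K (a planted block structure gives cohesion 1 / separation 0 at the
    true K).
    """
    Z = _ward_linkage(C)
    n = len(C.gene_ids)
    iu = np.triu_indices(n, k=1)
    vals = C.values[iu]
    rows = []
    for K in k_range:
        if not 1 <= K <= n:
            raise ValidationError("K out of range")
        lab = hierarchy.fcluster(Z, t=K, criterion="maxclust")
        same = lab[iu[0]] == lab[iu[1]]
        cohesion = float(vals[same].mean()) if same.any() else 1.0
        separation = float(vals[~same].mean()) if (~same).any() else 0.0
        rows.append({"K": K, "cohesion": cohesion, "separation": separation,
                     "n_within_pairs": int(same.sum())})
    return pd.DataFrame(rows)


def export_heatmap_tables(assignment: ClusterAssignment, norm: NormalizedMatrix,
                          outdir: str | Path | None = None
                          ) -> dict[int, pd.DataFrame]:
    """Per-cluster gene x array tables of normalized values in leaf order."""
    if norm.degenerate.any():
        norm = norm.drop_degenerate()
    norm_idx = {g: i for i, g in enumerate(norm.gene_ids)}
    tables: dict[int, pd.DataFrame] = {}
    label_of = dict(zip(assignment.gene_ids, assignment.labels))
    for c in range(1, assignment.n_clusters + 1):
        genes = [assignment.gene_ids[i] for i in assignment.leaf_order
                 if label_of[assignment.gene_ids[i]] == c]
        rows = [norm_idx[g] for g in genes]
        tables[c] = pd.DataFrame(norm.values[rows], index=pd.Index(genes, name="gene_id"),
                                 columns=norm.array_ids)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for c, df in tables.items():
            df.to_csv(outdir / f"cluster_{c:02d}_heatmap.tsv", sep="\t",
                      float_format="%.6g")
    return tables


class ConsensusClusterModel:
    """K-means co-occurrence consensus clustering of normalized profiles.

    Parameters mirror the scan defaults: 30 repeats of K-means for each k in
    6..14 (270 runs), Ward consensus tree of ``1 - co-occurrence``, cut at
    ``n_clusters`` (default 12, a user judgment supported by the stability
    diagnostic).
    """

    def __init__(self, norm: NormalizedMatrix, k_min: int = 6, k_max: int = 14,
                 repeats: int = 30, n_clusters: int = 12, olo_cap: int = 2000):
        if repeats < 1:
            raise ValidationError("repeats must be >= 1")
        self.norm = norm.drop_degenerate() if norm.degenerate.any() else norm
        self.k_min, self.k_max, self.repeats = k_min, k_max, repeats
        self.n_clusters = n_clusters
        self.olo_cap = olo_cap

    def fit(self, seed: int | np.random.SeedSequence | None = 0
            ) -> "ConsensusClusterResults":
        pset = kmeans_scan(self.norm, self.k_min, self.k_max, self.repeats, seed)
        C = co_occurrence(pset)
        assignment = consensus_cut(C, self.n_clusters, self.norm, self.olo_cap)
        diag = stability_diagnostic(C, range(max(2, self.n_clusters - 4),
                                             self.n_clusters + 5))
        return ConsensusClusterResults(self, pset, C, assignment, diag)


@dataclass
class ConsensusClusterResults:
    model: ConsensusClusterModel
    partitions: PartitionSet
    co_occurrence: CoOccurrenceMatrix
    assignment: ClusterAssignment
    stability: pd.DataFrame

    @property
    def cluster_sizes(self) -> dict[int, int]:
        lab = self.assignment.labels
        return {int(c): int((lab == c).sum()) for c in range(1, lab.max() + 1)}

    def summary(self) -> str:
        sizes = self.cluster_sizes
        at_k = self.stability[self.stability["K"] == self.assignment.n_clusters]
        lines = [
            "Consensus clustering (K-means co-occurrence + Ward cut)",
            "=" * 56,
            f"genes clustered     {len(self.assignment.gene_ids)}",
            f"k-means runs        {len(self.partitions)} "
            f"(k={self.model.k_min}..{self.model.k_max} x {self.model.repeats} repeats)",
            f"consensus clusters  {self.assignment.n_clusters}",
            "cluster sizes       " + ", ".join(f"{c}:{n}" for c, n in sizes.items()),
        ]
        if len(at_k):
            lines.append(f"cohesion/separation {at_k['cohesion'].iloc[0]:.3f} / "
                         f"{at_k['separation'].iloc[0]:.3f} at K={self.assignment.n_clusters}")
        return "\n".join(lines)

    def profiles_frame(self) -> pd.DataFrame:
        a = self.assignment
        rows = []
        for c in range(1, a.n_clusters + 1):
            for j, g in enumerate(a.group_labels):
                rows.append({"cluster": c, "group": g,
                             "mean": a.profile_mean[c - 1, j],
                             "sd": a.profile_sd[c - 1, j]})
        return pd.DataFrame(rows)
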