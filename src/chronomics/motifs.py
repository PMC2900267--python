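"""Promoter PWM scanning and motif over-representation Z scores.

Each PWM is turned into a log-odds scorer against the background base
composition; a promoter position (on either strand) is a site when its
windowed log-odds score reaches a fraction (default 0.80) of the motif's
maximum achievable score. For a cluster's promoter set, the observed site
count is compared with a binomial null whose per-window hit rate is pooled
from the background promoter set (the full DE promoter collection):

.. math:: Z = \\frac{O - W\\hat p}{\\sqrt{W \\hat p (1-\\hat p)}}

with W the number of scannable foreground windows. Positive Z means
over-representation, negative under-representation; |Z| > 3 is the
reporting rule. The clusters x motifs Z matrix is summarized by two-way
hierarchical clustering (unit-variance columns) and by PCA of the
per-cluster Z vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cluster import ClusterAssignment, optimal_leaf_order
from .errors import ValidationError
from .io import BASES, PWM, PromoterSet
from .simulate import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ScoredPWM",
    "build_scorer",
    "background_composition",
    "count_sites",
    "count_windows",
    "zscore_overrep",
    "ZScoreMatrix",
    "zscore_matrix",
    "zmatrix_cluster",
    "zmatrix_pca",
    "MotifOverrepresentationModel",
    "MotifOverrepresentationResults",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class ScoredPWM:
    """A PWM with its log-odds weights and absolute score threshold."""

    pwm: PWM
    background: np.ndarray
    pseudocount: float
    threshold_fraction: float
    log_odds: np.ndarray = field(init=False)
    max_score: float = field(init=False)
    threshold: float = field(init=False)
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValidationError("background must be a 4-vector summing to 1")
        if np.any(bg <= 0):
            raise ValidationError("background frequencies must be positive")
        if not 0 < self.threshold_fraction <= 1:
            raise ValidationError("threshold fraction must be in (0, 1]")
        counts = self.pwm.matrix
        colsum = counts.sum(axis=0, keepdims=True)
        probs = (counts + self.pseudocount * bg[:, None]) / (colsum + self.pseudocount)
        self.log_odds = np.log(probs / bg[:, None])
        self.max_score = float(self.log_odds.max(axis=0).sum())
        if self.max_score <= 0:
            # a PWM indistinguishable from background has no meaningful hits
            self.degenerate = True
            self.threshold = np.inf
        else:
            self.threshold = self.threshold_fraction * self.max_score
        self.background = bg

    @property
    def length(self) -> int:
        return self.pwm.length

    @property
    def motif_id(self) -> str:
        return self.pwm.motif_id


def build_scorer(pwm: PWM, background_freqs: Sequence[float],
                 pseudocount: float = 0.01,
                 threshold_fraction: float = 0.80) -> ScoredPWM:
    """Log-odds scorer: ``log(((count + pc*bg)/(colsum + pc)) / bg)``.

    The absolute hit threshold is ``threshold_fraction`` times the maximum
    achievable log-odds score (sum of column maxima).
    """
    return ScoredPWM(pwm, np.asarray(background_freqs, float), pseudocount,
                     threshold_fraction)


def background_composition(promoters: PromoterSet) -> np.ndarray:
    """A/C/G/T frequencies pooled over a promoter set (N ignored)."""
    counts = np.zeros(4)
    for seq in promoters.sequences.values():
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        raise ValidationError("promoter set contains no A/C/G/T bases")
    counts += 1.0  # Laplace floor keeps log-odds finite for absent bases
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(idx: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = W.shape[1]
    n_win = idx.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n_win, -np.inf)
    if valid.any():
        v = win[valid]
        scores[valid] = W[v, np.arange(L)[None, :]].sum(axis=1)
    return scores


def count_sites(seq: str, scorer: ScoredPWM) -> int:
    """Number of hits on both strands (overlaps counted, N windows skipped)."""
    if scorer.degenerate:
        return 0
    total = 0
    for s in (seq, reverse_complement(seq)):
        scores = _window_scores(_encode(s), scorer.log_odds)
        total += int(np.sum(scores >= scorer.threshold))
    return total


def count_windows(seq: str, motif_length: int) -> int:
    """Scannable (N-free) windows on both strands."""
    idx = _encode(seq)
    n_win = idx.size - motif_length + 1
    if n_win <= 0:
        return 0
    win = np.lib.stride_tricks.sliding_window_view(idx, motif_length)
    return 2 * int((win >= 0).all(axis=1).sum())


def _set_counts(promoters: PromoterSet, scorer: ScoredPWM) -> tuple[int, int]:
    hits = windows = 0
    for seq in promoters.sequences.values():
        hits += count_sites(seq, scorer)
        windows += count_windows(seq, scorer.length)
    return hits, windows


def zscore_overrep(foreground: PromoterSet, background: PromoterSet,
                   scorer: ScoredPWM) -> tuple[float, int, float, float]:
    """Z score of motif-site over-representation in a foreground set.

    The per-window hit probability is pooled from the background; the
    foreground count is referred to the binomial null over its scannable
    windows. Returns ``(Z, observed, expected, sd)``; Z is NaN when the
    null is degenerate (pooled rate 0 or 1).
    """
    if not set(foreground.sequences) <= set(background.sequences):
        raise ValidationError("foreground genes must be a subset of the background")
    bg_hits, bg_windows = _set_counts(background, scorer)
    if bg_windows == 0:
        return float("nan"), 0, 0.0, 0.0
    p_hat = bg_hits / bg_windows
    obs, W = _set_counts(foreground, scorer)
    expected = W * p_hat
    sd = float(np.sqrt(W * p_hat * (1.0 - p_hat)))
    if p_hat in (0.0, 1.0) or sd == 0.0:
        return float("nan"), obs, expected, sd
    return float((obs - expected) / sd), obs, expected, sd


@dataclass
class ZScoreMatrix:
    """Clusters x motifs Z scores with per-cell counts and the |Z|>3 calls."""

    cluster_ids: list[int]
    motif_ids: list[str]
    z: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    sd: np.ndarray
    z_cut: float = 3.0

    def calls(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cluster_ids):
            for j, m in enumerate(self.motif_ids):
                z = self.z[i, j]
                if np.isnan(z):
                    call = "undefined"
                elif z > self.z_cut:
                    call = "over"
                elif z < -self.z_cut:
                    call = "under"
                else:
                    call = "none"
                rows.append({"cluster": c, "motif": m, "z": z,
                             "observed": self.observed[i, j],
                             "expected": self.expected[i, j],
                             "sd": self.sd[i, j], "call": call})
        return pd.DataFrame(rows)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=pd.Index(self.cluster_ids, name="cluster"),
                            columns=self.motif_ids)


def zscore_matrix(cluster_promoters: Mapping[int, PromoterSet],
                  background: PromoterSet, scorers: Sequence[ScoredPWM],
                  z_cut: float = 3.0) -> ZScoreMatrix:
    """Full clusters x motifs Z matrix against the pooled background."""
    cluster_ids = sorted(cluster_promoters)
    motif_ids = [s.motif_id for s in scorers]
    shape = (len(cluster_ids), len(motif_ids))
    z = np.full(shape, np.nan)
    obs = np.zeros(shape)
    exp = np.zeros(shape)
    sd = np.zeros(shape)
    for j, scorer in enumerate(scorers):
        bg_hits, bg_windows = _set_counts(background, scorer)
        if bg_windows == 0 or bg_hits in (0, bg_windows):
            logger.warning("motif %s: degenerate background rate, Z undefined",
                           scorer.motif_id)
            continue
        p_hat = bg_hits / bg_windows
        for i, c in enumerate(cluster_ids):
            o, W = _set_counts(cluster_promoters[c], scorer)
            e = W * p_hat
            s = float(np.sqrt(W * p_hat * (1 - p_hat)))
            obs[i, j], exp[i, j], sd[i, j] = o, e, s
            if s > 0:
                z[i, j] = (o - e) / s
    return ZScoreMatrix(cluster_ids, motif_ids, z, obs, exp, sd, z_cut)


def zmatrix_cluster(zm: ZScoreMatrix) -> dict:
    """Two-way Ward/Euclidean ordering of the Z matrix.

    Columns are the per-cluster Z vectors; each retained column is scaled to
    unit variance first (constant or undefined columns are dropped with a
    warning). Returns the row/column linkages and optimal leaf orders.
    """
    A = zm.z.T.copy()  # motifs x clusters; columns = clusters
    keep_cols = []
    for j in range(A.shape[1]):
        col = A[:, j]
        if np.isnan(col).any() or np.std(col, ddof=1) == 0:
            warnings.warn(f"cluster {zm.cluster_ids[j]} excluded from two-way "
                          "ordering (constant or undefined Z vector)")
        else:
            keep_cols.append(j)
    keep_rows = [i for i in range(A.shape[0])
                 if not np.isnan(A[i, keep_cols]).any()]
    A = A[np.ix_(keep_rows, keep_cols)]
    if A.shape[0] < 2 or A.shape[1] < 2:
        raise ValidationError("need at least 2 motifs and 2 clusters with defined Z")
    A = A / A.std(axis=0, ddof=1, keepdims=True)
    row_link = hierarchy.linkage(pdist(A), method="ward")
    col_link = hierarchy.linkage(pdist(A.T), method="ward")
    from scipy.spatial.distance import squareform
    row_order = optimal_leaf_order(row_link, squareform(pdist(A)))
    col_order = optimal_leaf_order(col_link, squareform(pdist(A.T)))
    return {
        "matrix": A,
        "motif_ids": [zm.motif_ids[i] for i in keep_rows],
        "cluster_ids": [zm.cluster_ids[j] for j in keep_cols],
        "row_linkage": row_link, "col_linkage": col_link,
        "row_order": row_order, "col_order": col_order,
    }


def zmatrix_pca(zm: ZScoreMatrix) -> pd.DataFrame:
    """First two principal components of the per-cluster Z vectors.

    Clusters are observations, motifs features; features are centered and
    the covariance eigen-decomposed. The sign of each component is fixed so
    its largest-magnitude loading is positive.
    """
    keep = [i for i in range(len(zm.cluster_ids)) if not np.isnan(zm.z[i]).any()]
    X = zm.z[keep]
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 clusters with defined Z")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.sum(evals > 1e-10 * max(evals.max(), 1.0)) < 2:
        raise ValidationError("Z matrix has rank < 2; PCA undefined")
    comps = evecs[:, :2]
    for k in range(2):
        j = np.argmax(np.abs(comps[:, k]))
        if comps[j, k] < 0:
            comps[:, k] = -comps[:, k]
    proj = Xc @ comps
    return pd.DataFrame({"cluster": [zm.cluster_ids[i] for i in keep],
                         "pc1": proj[:, 0], "pc2": proj[:, 1],
                         "var_pc1": evals[0], "var_pc2": evals[1]})


class MotifOverrepresentationModel:
    """Cluster-promoter motif over/under-representation analysis.

    Parameters
    ----------
    assignment : ClusterAssignment or mapping cluster id -> gene list
    promoters : PromoterSet over (at least) the clustered genes; genes with
        no promoter are logged and excluded.
    pwms : motif matrices to scan.
    threshold_fraction, pseudocount : scanner settings (0.80, 0.01).
    z_cut : reporting cutoff on |Z| (default 3).
    """

    def __init__(self, assignment: ClusterAssignment | Mapping[int, Sequence[str]],
                 promoters: PromoterSet, pwms: Sequence[PWM],
                 threshold_fraction: float = 0.80, pseudocount: float = 0.01,
                 z_cut: float = 3.0):
        if isinstance(assignment, ClusterAssignment):
            members: dict[int, list[str]] = {
                c: assignment.cluster_genes(c)
                for c in range(1, assignment.n_clusters + 1)}
        else:
            members = {int(c): list(g) for c, g in assignment.items()}
        have = set(promoters.sequences)
        self.cluster_genes = {}
        for c, genes in members.items():
            missing = [g for g in genes if g not in have]
            if missing:
                logger.warning("cluster %s: %d gene(s) without promoter excluded",
                               c, len(missing))
            self.cluster_genes[c] = [g for g in genes if g in have]
        self.promoters = promoters
        self.pwms = list(pwms)
        self.threshold_fraction = threshold_fraction
        self.pseudocount = pseudocount
        self.z_cut = z_cut

    def fit(self) -> "MotifOverrepresentationResults":
        all_genes = sorted({g for gs in self.cluster_genes.values() for g in gs})
        background = self.promoters.subset(all_genes)
        bg_freqs = background_composition(background)
        scorers = [build_scorer(p, bg_freqs, self.pseudocount,
                                self.threshold_fraction) for p in self.pwms]
        cluster_promoters = {c: self.promoters.subset(gs)
                             for c, gs in self.cluster_genes.items() if gs}
        zm = zscore_matrix(cluster_promoters, background, scorers, self.z_cut)
        return MotifOverrepresentationResults(self, zm, bg_freqs, scorers)


@dataclass
class MotifOverrepresentationResults:
    model: MotifOverrepresentationModel
    zmatrix: ZScoreMatrix
    background_freqs: np.ndarray
    scorers: list[ScoredPWM]

    def calls(self) -> pd.DataFrame:
        return self.zmatrix.calls()

    def two_way_ordering(self) -> dict:
        return zmatrix_cluster(self.zmatrix)

    def pca(self) -> pd.DataFrame:
        return zmatrix_pca(self.zmatrix)

    def summary(self) -> str:
        calls = self.calls()
        n_over = int((calls["call"] == "over").sum())
        n_under = int((calls["call"] == "under").sum())
        lines = [
            "Motif over-representation (promoter PWM scan, binomial Z)",
            "=" * 58,
            f"clusters x motifs   {len(self.zmatrix.cluster_ids)} x "
            f"{len(self.zmatrix.motif_ids)}",
            "background A/C/G/T  " + "/".join(f"{f:.3f}" for f in self.background_freqs),
            f"score threshold     {self.model.threshold_fraction:g} of max log-odds",
            f"calls at |Z|>{self.zmatrix.z_cut:g}      {n_over} over, {n_under} under",
        ]
        return "\n".join(lines)
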