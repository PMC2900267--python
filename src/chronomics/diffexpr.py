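"""Moderated multi-test differential expression across time groups.

Genes violating the null of equal mean across all time groups are found with
three ANOVA-style statistics that regularize the per-gene variance in
different ways, then combined:

* :func:`limma_moderated_f` — empirical-Bayes moderated F: the residual
  variance is shrunk toward a common prior value, with prior degrees of
  freedom and prior variance estimated by moment-matching the marginal
  distribution of the log sample variances (the scaled-F marginal of the
  inverse-chi-square prior).
* :func:`cybert_f` — Cyber-T-style regularized F: the per-gene variance is
  averaged with a background variance taken from a sliding window of genes
  of similar mean expression, with a pseudo-count of ``n0`` prior
  observations.
* :func:`sam_multiclass` — the multiclass SAM d statistic
  ``d = r/(s + s0)`` with the fudge factor ``s0`` chosen by the
  coefficient-of-variation criterion, and a permutation-based FDR.

P-values from the first two tests are converted to FDRs by fitting a
beta-uniform mixture to the p-value distribution (:func:`allison_fdr`);
SAM's FDR comes from label permutations. A conglomerate ranking (mean of the
three per-test ranks) with a median-of-FDRs conversion yields the final
differential-expression call at an FDR threshold (default 0.02).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaComponents",
    "anova_decomposition",
    "classical_f",
    "limma_moderated_f",
    "cybert_f",
    "sam_multiclass",
    "allison_fdr",
    "conglomerate_rank",
    "DifferentialExpressionModel",
    "DifferentialExpressionResults",
]


# ---------------------------------------------------------------------------
# Classical one-way ANOVA decomposition
# ---------------------------------------------------------------------------

@dataclass
class AnovaComponents:
    """Per-gene one-way ANOVA pieces shared by all three tests."""

    gene_ids: list[str]
    group_labels: list[str]
    group_sizes: np.ndarray
    group_means: np.ndarray      # genes x groups
    grand_mean: np.ndarray
    ss_between: np.ndarray
    ss_within: np.ndarray
    df_between: int
    df_within: int
    s2: np.ndarray               # within variance, floored (see below)
    mean_expr: np.ndarray

    @property
    def ms_between(self) -> np.ndarray:
        return self.ss_between / self.df_between

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def anova_decomposition(em: ExpressionMatrix) -> AnovaComponents:
    """Classical one-way ANOVA sums of squares per gene.

    Each time group is a separate condition. Zero within-group variance is
    floored at machine epsilon times the gene's mean square so that
    noise-free fixtures yield a large finite F instead of infinity.
    """
    cols = em.group_columns()
    sizes = np.array([len(ix) for ix in cols.values()])
    if np.any(sizes < 2):
        raise ValidationError("every group needs at least two arrays")
    X = em.values
    M = X.shape[1]
    k = len(cols)
    means = np.column_stack([X[:, ix].mean(axis=1) for ix in cols.values()])
    grand = X.mean(axis=1)
    ss_between = ((means - grand[:, None]) ** 2 * sizes[None, :]).sum(axis=1)
    ss_within = np.zeros(X.shape[0])
    for j, ix in enumerate(cols.values()):
        ss_within += ((X[:, ix] - means[:, [j]]) ** 2).sum(axis=1)
    df_between, df_within = k - 1, M - k
    s2 = ss_within / df_within
    floor = np.finfo(float).eps * np.maximum((X ** 2).mean(axis=1), 1.0)
    s2 = np.maximum(s2, floor)
    return AnovaComponents(list(em.gene_ids), list(cols), sizes, means, grand,
                           ss_between, ss_within, df_between, df_within, s2,
                           grand.copy())


def classical_f(comp: AnovaComponents) -> tuple[np.ndarray, np.ndarray]:
    """Plain one-way ANOVA F and p (the no-moderation reference)."""
    F = comp.ms_between / comp.s2
    p = stats.f.sf(F, comp.df_between, comp.df_within)
    return F, p


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated F
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration for psi'(x) = y, y > 0
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (prior df d0, prior variance s0^2) from sample variances.

    Under the inverse-chi-square prior the log sample variances follow a
    shifted log-F law; matching mean and variance of ``log s2`` gives closed
    forms up to a trigamma inversion. Returns ``d0 = inf`` when the observed
    spread is no larger than the sampling spread (all genes share a variance).
    """
    z = np.log(s2)
    if np.ptp(z) < 1e-10:
        # all genes share one variance exactly: the common value is that
        # variance and shrinkage toward it is a no-op
        return np.inf, float(np.exp(z.mean()))
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid = evar - float(special.polygamma(1, df / 2.0))
    if resid > 0:
        d0 = 2.0 * _trigamma_inverse(resid)
        s02 = float(np.exp(emean + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def limma_moderated_f(comp: AnovaComponents, prior_df: float | None = None,
                      prior_var: float | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Empirical-Bayes moderated F test.

    The shrunken variance is ``(d0*s0^2 + d*s2) / (d0 + d)`` and the
    moderated F is referred to an F distribution on
    ``(k-1, d0 + d)`` degrees of freedom. ``prior_df=0`` disables shrinkage
    (classical ANOVA F); by default the prior is estimated from the ensemble,
    which needs at least 10 genes.

    Returns ``(F, p, d0, s0^2)``.
    """
    if not np.all(np.isfinite(comp.s2)):
        raise ValidationError("non-finite variance estimates")
    if prior_df is None:
        if comp.n_genes < 10:
            raise ValidationError("prior estimation needs at least 10 genes")
        d0, s02 = estimate_variance_prior(comp.s2, comp.df_within)
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else float(np.median(comp.s2))
    d = comp.df_within
    if np.isinf(d0):
        s2_tilde = np.full_like(comp.s2, s02)
    elif d0 == 0:
        s2_tilde = comp.s2
    else:
        s2_tilde = (d0 * s02 + d * comp.s2) / (d0 + d)
    F = comp.ms_between / s2_tilde
    dfd = min(d0 + d, 1e6)  # F quantiles saturate well below this
    p = stats.f.sf(F, comp.df_between, dfd)
    return F, p, d0, s02


# ---------------------------------------------------------------------------
# Cyber-T-style windowed regularization
# ---------------------------------------------------------------------------

def cybert_f(comp: AnovaComponents, window_size: int = 101, n0: float = 10.0,
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regularized F with a sliding-window background variance.

    Genes are ranked by mean expression; the background variance of gene g is
    the mean sample variance over a centered window of ``window_size`` genes
    (truncated at the edges). The regularized variance is
    ``(n0*bg + d*s2) / (n0 + d)`` and F is referred to
    ``(k-1, n0 + d)`` degrees of freedom; ``n0 = 0`` recovers the classical
    test exactly.

    Returns ``(F, p, regularized variance)``.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValidationError("window_size must be odd and >= 3")
    if window_size > comp.n_genes:
        raise ValidationError("window larger than the gene count")
    if n0 < 0:
        raise ValidationError("confidence n0 must be >= 0")
    order = np.argsort(comp.mean_expr, kind="stable")
    s2_sorted = comp.s2[order]
    h = window_size // 2
    csum = np.concatenate([[0.0], np.cumsum(s2_sorted)])
    n = comp.n_genes
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    bg_sorted = (csum[hi] - csum[lo]) / (hi - lo)
    bg = np.empty(n)
    bg[order] = bg_sorted
    d = comp.df_within
    reg = (n0 * bg + d * comp.s2) / (n0 + d) if n0 > 0 else comp.s2.copy()
    F = comp.ms_between / reg
    p = stats.f.sf(F, comp.df_between, n0 + d)
    return F, p, reg


# ---------------------------------------------------------------------------
# Multiclass SAM with permutation FDR
# ---------------------------------------------------------------------------

def _sam_rs(X: np.ndarray, group_cols: Sequence[np.ndarray]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Between-group contrast magnitude r and pooled standard-error s."""
    sizes = np.array([len(ix) for ix in group_cols], dtype=float)
    n = sizes.sum()
    K = len(group_cols)
    grand = X.mean(axis=1)
    num = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for ix, nk in zip(group_cols, sizes):
        mk = X[:, ix].mean(axis=1)
        num += nk * (mk - grand) ** 2
        ss_within += ((X[:, ix] - mk[:, None]) ** 2).sum(axis=1)
    fac = n / np.prod(sizes)
    r = np.sqrt(fac * num)
    pooled = ss_within / (n - K)
    s = np.sqrt(pooled * np.sum(1.0 / sizes))
    return r, s


def _choose_s0(r: np.ndarray, s: np.ndarray, n_windows: int = 100) -> float:
    """SAM fudge factor: the s-percentile grid point minimizing the CV of the
    windowed median absolute deviation of d."""
    candidates = np.unique(np.percentile(s, np.arange(0, 101, 5)))
    qs = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    bins = np.clip(np.searchsorted(qs[1:-1], s, side="right"), 0, n_windows - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = r / (s + s0)
        mads = []
        for b in range(n_windows):
            db = d[bins == b]
            if db.size:
                mads.append(np.median(np.abs(db - np.median(db))))
        mads = np.array(mads)
        m = mads.mean()
        cv = mads.std(ddof=1) / m if m > 0 and mads.size > 1 else np.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


@dataclass
class SamResult:
    d: np.ndarray
    s0: float
    fdr: np.ndarray
    pi0: float
    n_perm: int


def _count_distinct_label_perms(sizes: Sequence[int]) -> float:
    n = sum(sizes)
    logc = lgamma(n + 1) - sum(lgamma(s + 1) for s in sizes)
    return float(np.exp(min(logc, 700)))


def sam_multiclass(em: ExpressionMatrix, n_perm: int = 1000,
                   seed: int | np.random.SeedSequence | None = 0,
                   s0: float | None = None) -> SamResult:
    """Multiclass SAM statistic with a permutation FDR.

    ``d = r/(s + s0)`` per gene; the null distribution of d comes from
    ``n_perm`` random permutations of the group labels (enumerated without
    replacement when there are fewer distinct assignments than ``n_perm``).
    The per-gene FDR at cutoff ``|d_g|`` is the pi0-corrected median over
    permutations of the number of permuted ``|d|`` values at or above the
    cutoff, divided by the observed count, then made monotone along the
    ranking.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    cols = em.group_columns()
    if len(cols) < 2:
        raise ValidationError("group labels are not permutable with one group")
    group_cols = list(cols.values())
    X = em.values
    M = X.shape[1]
    r, s = _sam_rs(X, group_cols)
    if s0 is None:
        s0 = _choose_s0(r, s)
    d = r / (s + s0)

    rng = np.random.default_rng(seed)
    sizes = [len(ix) for ix in group_cols]
    base_labels = np.concatenate([[j] * sz for j, sz in enumerate(sizes)])
    label_vectors: list[np.ndarray]
    if _count_distinct_label_perms(sizes) <= n_perm:
        from sympy.utilities.iterables import multiset_permutations
        label_vectors = [np.array(lv) for lv in multiset_permutations(list(base_labels))]
    else:
        label_vectors = [rng.permutation(base_labels) for _ in range(n_perm)]

    abs_d = np.abs(d)
    obs_sorted = np.sort(abs_d)
    n = abs_d.size
    obs_ge = n - np.searchsorted(obs_sorted, abs_d, side="left")
    perm_counts = np.empty((len(label_vectors), n))
    pooled_for_pi0 = []
    for i, lv in enumerate(label_vectors):
        cols_p = [np.flatnonzero(lv == j) for j in range(len(sizes))]
        rp, sp = _sam_rs(X, cols_p)
        dp = rp / (sp + s0)
        pooled_for_pi0.append(dp)
        dp_sorted = np.sort(np.abs(dp))
        perm_counts[i] = n - np.searchsorted(dp_sorted, abs_d, side="left")
    pooled = np.concatenate(pooled_for_pi0)
    q25, q75 = np.percentile(pooled, [25, 75])
    pi0 = min(1.0, np.sum((d > q25) & (d < q75)) / (0.5 * n))
    med = np.median(perm_counts, axis=0)
    fdr = np.minimum(1.0, pi0 * med / np.maximum(obs_ge, 1))
    # monotone non-decreasing along the |d| ranking (best first)
    order = np.argsort(-abs_d, kind="stable")
    fdr[order] = np.maximum.accumulate(fdr[order])
    return SamResult(d, float(s0), fdr, float(pi0), len(label_vectors))


# ---------------------------------------------------------------------------
# Beta-uniform mixture FDR for p-value tests
# ---------------------------------------------------------------------------

def _bum_negloglik(params: np.ndarray, p: np.ndarray) -> float:
    lam, r, s = params
    lam = min(max(lam, 1e-6), 1 - 1e-6)
    pdf = lam + (1 - lam) * np.exp(stats.beta.logpdf(p, r, s))
    return float(-np.sum(np.log(np.maximum(pdf, 1e-300))))


def allison_fdr(p: np.ndarray, return_fit: bool = False, method: str = "bum"):
    """Convert p-values to FDRs via a uniform + beta mixture fit.

    The p-value ensemble is modelled as ``lam*U(0,1) + (1-lam)*Beta(r,s)``
    fitted by maximum likelihood (box-constrained, three fixed restarts).
    Because the uniform weight is not identifiable when the beta component
    is itself near-uniform, the null weight used for FDR is the
    conservative ``pi0 = min_p fhat(p)`` — the uniform floor of the fitted
    density (>= lam by construction). The FDR of a gene with p-value t is
    then ``pi0*t / Fhat(t)`` with ``Fhat`` the fitted mixture CDF, made
    non-decreasing in t. If no restart converges — or ``method="bh"`` is
    requested — Benjamini-Hochberg step-up FDRs are used instead, with a
    logged warning in the fallback case.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("bum", "bh"):
        raise ValidationError(f"unknown FDR method {method!r}")
    if method == "bh":
        fdr = multipletests(p, method="fdr_bh")[1]
        if return_fit:
            return fdr, {"method": "bh"}
        return fdr
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    starts = [(0.8, 0.5, 2.0), (0.5, 0.3, 10.0), (0.95, 1.0, 1.0)]
    bounds = [(1e-4, 1 - 1e-4), (0.01, 100.0), (0.01, 100.0)]
    best = None
    for x0 in starts:
        res = optimize.minimize(_bum_negloglik, x0=np.array(x0), args=(pc,),
                                method="L-BFGS-B", bounds=bounds)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        logger.warning("beta-uniform mixture fit failed to converge; "
                       "falling back to Benjamini-Hochberg")
        fdr = multipletests(p, method="fdr_bh")[1]
        fit = {"method": "bh"}
    else:
        lam, r, s = best.x
        grid = np.linspace(0.01, 0.999, 200)
        dens = lam + (1 - lam) * stats.beta.pdf(grid, r, s)
        pi0 = float(min(1.0, dens.min()))
        cdf = lam * pc + (1 - lam) * stats.beta.cdf(pc, r, s)
        fdr = np.minimum(1.0, pi0 * pc / np.maximum(cdf, 1e-300))
        order = np.argsort(pc, kind="stable")
        fdr[order] = np.maximum.accumulate(fdr[order])
        fit = {"method": "bum", "lambda": pi0, "lambda_raw": float(lam),
               "r": float(r), "s": float(s)}
    if return_fit:
        return fdr, fit
    return fdr


# ---------------------------------------------------------------------------
# Conglomerate ranking
# ---------------------------------------------------------------------------

def conglomerate_rank(gene_ids: Sequence[str], ranks: np.ndarray,
                      fdrs: np.ndarray, alpha: float = 0.02,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Combine per-test ranks and FDRs into the final call.

    The conglomerate score is the mean of the per-test ranks (smaller =
    more significant); the conglomerate FDR is the per-gene median of the
    per-test FDRs, made non-decreasing along the conglomerate ordering by a
    running maximum. Genes with conglomerate FDR <= alpha are called.

    Returns ``(score, conglomerate rank, conglomerate FDR, DE flag)``.
    """
    ranks = np.asarray(ranks, float)
    fdrs = np.asarray(fdrs, float)
    n = len(gene_ids)
    if ranks.shape != (3, n) or fdrs.shape != (3, n):
        raise ValidationError("need 3 x n_genes rank and FDR arrays on one gene set")
    score = ranks.mean(axis=0)
    order = np.lexsort((np.asarray(gene_ids), score))  # stable: ties by gene id
    cong_rank = np.empty(n)
    cong_rank[order] = np.arange(1, n + 1)
    cong_fdr = np.median(fdrs, axis=0)
    cong_fdr[order] = np.maximum.accumulate(cong_fdr[order])
    de = cong_fdr <= alpha
    return score, cong_rank, cong_fdr, de


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DifferentialExpressionModel:
    """Three moderated ANOVA tests plus conglomerate ranking on a matrix.

    Parameters
    ----------
    em : ExpressionMatrix
        Log2 expression with a group design (each group >= 2 arrays).
    alpha : float
        Conglomerate FDR threshold for the DE call (default 0.02).
    n_perm : int
        Label permutations for the SAM FDR (>= 100, default 1000).
    window_size, n0 : int, float
        Cyber-T window (odd) and prior-observation count.
    """

    def __init__(self, em: ExpressionMatrix, alpha: float = 0.02,
                 n_perm: int = 1000, window_size: int = 101, n0: float = 10.0):
        if not 0 < alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        self.em = em
        self.alpha = alpha
        self.n_perm = n_perm
        self.window_size = window_size
        self.n0 = n0

    def fit(self, seed: int | np.random.SeedSequence | None = 0,
            ) -> "DifferentialExpressionResults":
        em = self.em
        comp = anova_decomposition(em)
        f_lim, p_lim, d0, s02 = limma_moderated_f(comp)
        window = min(self.window_size, comp.n_genes if comp.n_genes % 2 else comp.n_genes - 1)
        f_cyb, p_cyb, _ = cybert_f(comp, window_size=window, n0=self.n0)
        sam = sam_multiclass(em, n_perm=self.n_perm, seed=seed)

        fdr_lim, fit_lim = allison_fdr(p_lim, return_fit=True)
        fdr_cyb, fit_cyb = allison_fdr(p_cyb, return_fit=True)

        rank_lim = stats.rankdata(p_lim, method="average")
        rank_cyb = stats.rankdata(p_cyb, method="average")
        rank_sam = stats.rankdata(-np.abs(sam.d), method="average")
        ranks = np.vstack([rank_lim, rank_cyb, rank_sam])
        fdrs = np.vstack([fdr_lim, fdr_cyb, sam.fdr])
        score, cong_rank, cong_fdr, de = conglomerate_rank(
            em.gene_ids, ranks, fdrs, alpha=self.alpha)

        table = pd.DataFrame({
            "gene_id": em.gene_ids,
            **{f"mean_{g}": comp.group_means[:, j]
               for j, g in enumerate(comp.group_labels)},
            "f_limma": f_lim, "p_limma": p_lim, "fdr_limma": fdr_lim,
            "rank_limma": rank_lim,
            "f_cybert": f_cyb, "p_cybert": p_cyb, "fdr_cybert": fdr_cyb,
            "rank_cybert": rank_cyb,
            "d_sam": sam.d, "fdr_sam": sam.fdr, "rank_sam": rank_sam,
            "cong_score": score, "cong_rank": cong_rank, "cong_fdr": cong_fdr,
            "de": de,
        }).set_index("gene_id", drop=False)
        return DifferentialExpressionResults(
            self, table, prior_df=d0, prior_var=s02, sam_s0=sam.s0,
            sam_pi0=sam.pi0, mixture_fits={"limma": fit_lim, "cybert": fit_cyb})


@dataclass
class DifferentialExpressionResults:
    """Per-gene statistics, ranks and FDRs from the three tests."""

    model: DifferentialExpressionModel
    table: pd.DataFrame
    prior_df: float = np.nan
    prior_var: float = np.nan
    sam_s0: float = np.nan
    sam_pi0: float = np.nan
    mixture_fits: dict = field(default_factory=dict)

    @property
    def de_genes(self) -> list[str]:
        """Genes called at the conglomerate FDR threshold, best first."""
        t = self.table[self.table["de"]].sort_values("cong_rank")
        return list(t["gene_id"])

    @property
    def n_de(self) -> int:
        return int(self.table["de"].sum())

    def summary(self) -> str:
        t = self.table
        a = self.model.alpha
        lines = [
            "Differential expression (moderated multi-test ANOVA)",
            "=" * 56,
            f"genes tested                {len(t)}",
            f"groups                      {len(self.model.em.groups)} "
            f"({', '.join(self.model.em.groups)})",
            f"moderated-F prior df        {self.prior_df:.3g}  "
            f"(prior variance {self.prior_var:.3g})",
            f"SAM fudge factor s0         {self.sam_s0:.4g}  (pi0 {self.sam_pi0:.3f})",
            f"called at per-test FDR<={a:g}:  "
            f"limma {int((t['fdr_limma'] <= a).sum())}, "
            f"cybert {int((t['fdr_cybert'] <= a).sum())}, "
            f"sam {int((t['fdr_sam'] <= a).sum())}",
            f"conglomerate DE calls       {self.n_de} at FDR <= {a:g}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
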