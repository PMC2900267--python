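"""Expression-matrix normalization.

Two normalizations are provided:

* :func:`quantile_normalize` — forces every array (column) to share the same
  distribution, namely the across-array mean of order statistics. This is the
  standard correction applied to expression summaries before any cross-array
  comparison.
* :func:`normalize_gene_wise` — the gene-wise rescaling used before
  clustering, so that genes cluster by the *shape* of their time profile and
  not by expression magnitude:

  .. math:: \\hat y_{nm} = \\frac{y_{nm} - \\bar y_n}{\\max_m |y_{nm} - \\bar y_n|}

  which centers each gene at zero and confines it to [-1, +1], with the bound
  attained for every non-constant gene. Constant genes have an undefined
  direction of change; they are set to zero and flagged degenerate so that
  clustering can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = ["NormalizedMatrix", "quantile_normalize", "normalize_gene_wise"]


@dataclass
class NormalizedMatrix:
    """Gene-wise normalized expression in [-1, +1].

    Carries the per-gene center (the row mean) and scale (the row max
    absolute deviation) so the transform can be inverted, plus a boolean
    ``degenerate`` flag marking constant rows (scale zero, values all zero).
    """

    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    design: dict[str, str]
    center: np.ndarray
    scale: np.ndarray
    degenerate: np.ndarray

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.array_ids:
            seen.setdefault(self.design[a], None)
        return list(seen)

    def group_columns(self) -> dict[str, np.ndarray]:
        labels = np.array([self.design[a] for a in self.array_ids])
        return {g: np.flatnonzero(labels == g) for g in self.groups}

    def drop_degenerate(self) -> "NormalizedMatrix":
        """Restrict to non-constant genes (the clustered gene set)."""
        keep = ~self.degenerate
        return NormalizedMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.array_ids), self.values[keep], dict(self.design),
            self.center[keep], self.scale[keep], self.degenerate[keep],
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean of order statistics.

    After normalization every column holds the identical multiset of values.
    Ties within a column all receive the mean of the reference values across
    their shared rank span, which makes the map deterministic and idempotent.
    """
    if em.n_arrays < 2:
        raise ValidationError("quantile normalization needs at least two arrays")
    X = em.values
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average the reference values over tie spans
        s = pd.Series(mapped)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return em.with_values(out)


def normalize_gene_wise(em: ExpressionMatrix) -> NormalizedMatrix:
    """Center each gene and scale by its maximum absolute deviation.

    Non-constant rows end up with zero mean and maximum absolute value
    exactly 1; constant rows become all-zero and are flagged degenerate.
    """
    X = em.values
    center = X.mean(axis=1)
    dev = X - center[:, None]
    scale = np.abs(dev).max(axis=1)
    degenerate = scale == 0
    safe = np.where(degenerate, 1.0, scale)
    values = dev / safe[:, None]
    values[degenerate] = 0.0
    return NormalizedMatrix(list(em.gene_ids), list(em.array_ids), values,
                            dict(em.design), center, scale, degenerate)
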