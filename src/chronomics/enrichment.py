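"""Per-cluster annotation over-representation with term grouping.

Each consensus cluster is tested for over-representation of annotation terms
against the full differentially-expressed gene set as background, with a
one-sided hypergeometric test. Significant, mutually overlapping terms are
grouped (edges where the overlap coefficient ``|A∩B|/min(|A|,|B|)`` of
cluster-restricted member sets is at least 0.70; groups are connected
components), a group is significant if it contains a term with p below 0.03,
and each significant group is summarized by a representative term — the most
specific significant member (smallest background total, ties by smallest p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import AnnotationSet

__all__ = [
    "TermStat",
    "TermGroup",
    "term_enrichment",
    "group_terms",
    "TermEnrichmentModel",
    "TermEnrichmentResults",
]


@dataclass
class TermStat:
    """One term's enrichment in one cluster."""

    term_id: str
    term_class: str
    description: str
    count: int            # cluster genes carrying the term
    total: int            # background genes carrying the term
    p: float
    cluster_members: frozenset[str] = field(default_factory=frozenset)


@dataclass
class TermGroup:
    """A connected component of mutually overlapping significant terms."""

    members: list[TermStat]
    significant: bool
    representative: TermStat | None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def min_p(self) -> float:
        return min(t.p for t in self.members)


def term_enrichment(cluster_genes: Iterable[str], background_genes: Iterable[str],
                    annotations: AnnotationSet, ease: bool = False
                    ) -> list[TermStat]:
    """Hypergeometric upper-tail enrichment of each term in a cluster.

    ``p = P(X >= count)`` for X hypergeometric with population the
    background, ``total`` term members in it, and a sample of cluster size.
    With ``ease=True`` one cluster member is jackknifed from the overlap
    before testing (the conservative EASE variant).
    """
    cluster = set(cluster_genes)
    background = set(background_genes)
    if not cluster <= background:
        raise ValidationError("cluster genes must be a subset of the background")
    B, n = len(background), len(cluster)
    out: list[TermStat] = []
    for term in annotations:
        members = set(term.members) & background
        total = len(members)
        if total == 0:
            continue
        overlap = members & cluster
        count = len(overlap)
        eff = max(count - 1, 0) if ease else count
        p = float(stats.hypergeom.sf(eff - 1, B, total, n)) if eff > 0 else 1.0
        p = min(p, 1.0)
        out.append(TermStat(term.term_id, term.term_class, term.description,
                            count, total, p, frozenset(overlap)))
    return out


def _overlap_coefficient(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def group_terms(terms: Sequence[TermStat], overlap_threshold: float = 0.70,
                p_threshold: float = 0.03) -> list[TermGroup]:
    """Group terms by gene overlap and extract representative terms.

    Terms are nodes; an edge joins two terms whose cluster-restricted member
    sets have overlap coefficient >= ``overlap_threshold``. Groups are the
    connected components (so overlap chains are grouped transitively). A
    group is significant when it contains a term with ``p < p_threshold``;
    its representative is the significant term with the smallest background
    total, ties broken by smaller p then term id.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValidationError("overlap_threshold must be in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(range(len(terms)))
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            if _overlap_coefficient(terms[i].cluster_members,
                                    terms[j].cluster_members) >= overlap_threshold:
                g.add_edge(i, j)
    groups: list[TermGroup] = []
    for comp in nx.connected_components(g):
        members = sorted((terms[i] for i in comp), key=lambda t: (t.p, t.term_id))
        sig = [t for t in members if t.p < p_threshold]
        rep = min(sig, key=lambda t: (t.total, t.p, t.term_id)) if sig else None
        groups.append(TermGroup(members, bool(sig), rep))
    groups.sort(key=lambda gr: gr.min_p)
    return groups


class TermEnrichmentModel:
    """Cluster-wise term over-representation against the DE background.

    Parameters
    ----------
    cluster_genes : mapping cluster id -> gene list
    background_genes : the full differentially-expressed gene set
    annotations : AnnotationSet
    overlap_threshold, p_threshold : the grouping thresholds (0.70, 0.03)
    ease : use the jackknifed (count - 1) hypergeometric variant
    """

    def __init__(self, cluster_genes: dict[int, Sequence[str]],
                 background_genes: Iterable[str], annotations: AnnotationSet,
                 overlap_threshold: float = 0.70, p_threshold: float = 0.03,
                 ease: bool = False):
        if not 0 < p_threshold <= 1:
            raise ValidationError("p_threshold must be in (0, 1]")
        self.cluster_genes = {int(c): list(g) for c, g in cluster_genes.items()}
        self.background_genes = list(background_genes)
        self.annotations = annotations
        self.overlap_threshold = overlap_threshold
        self.p_threshold = p_threshold
        self.ease = ease

    def fit(self) -> "TermEnrichmentResults":
        stats_by_cluster: dict[int, list[TermStat]] = {}
        groups_by_cluster: dict[int, list[TermGroup]] = {}
        for c, genes in self.cluster_genes.items():
            ts = term_enrichment(genes, self.background_genes, self.annotations,
                                 ease=self.ease)
            stats_by_cluster[c] = ts
            groups_by_cluster[c] = group_terms(ts, self.overlap_threshold,
                                               self.p_threshold)
        return TermEnrichmentResults(self, stats_by_cluster, groups_by_cluster)


@dataclass
class TermEnrichmentResults:
    model: TermEnrichmentModel
    term_stats: dict[int, list[TermStat]]
    term_groups: dict[int, list[TermGroup]]

    def significant_groups(self, cluster: int) -> list[TermGroup]:
        return [g for g in self.term_groups[cluster] if g.significant]

    def table(self) -> pd.DataFrame:
        """Significant groups: cluster, representative, count/total, p."""
        rows = []
        for c in sorted(self.term_groups):
            for grp in self.significant_groups(c):
                rep = grp.representative
                rows.append({"cluster": c, "representative": rep.term_id,
                             "class": rep.term_class, "description": rep.description,
                             "count": rep.count, "total": rep.total,
                             "terms_in_group": grp.size, "p": rep.p})
        return pd.DataFrame(rows, columns=["cluster", "representative", "class",
                                           "description", "count", "total",
                                           "terms_in_group", "p"])

    def summary(self) -> str:
        n_sig = {c: len(self.significant_groups(c)) for c in sorted(self.term_groups)}
        lines = [
            "Term over-representation (hypergeometric + overlap grouping)",
            "=" * 60,
            f"background genes    {len(self.model.background_genes)}",
            f"annotation terms    {len(self.model.annotations)}",
            f"overlap threshold   {self.model.overlap_threshold:g}, "
            f"group p threshold {self.model.p_threshold:g}",
            "significant groups  " + ", ".join(f"{c}:{n}" for c, n in n_sig.items()),
        ]
        return "\n".join(lines)
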