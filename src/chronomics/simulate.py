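"""Synthetic study generator with planted structure.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any external download:

* an expression matrix over five time groups (default sizes 4, 6, 5, 8, 8
  arrays, 31 in total) in which each planted gene follows one of a set of
  cluster time profiles plus i.i.d. Gaussian log2 noise, and null genes are
  pure noise around a per-gene baseline;
* promoter sequences (default 1200 bp, matching a 1000 bp upstream / 200 bp
  downstream window) with Poisson-planted PWM binding sites at elevated rates
  in chosen clusters over an i.i.d. background;
* GMT annotations whose planted terms draw members preferentially from a
  target cluster.

Every generated gene is recorded exactly once in :class:`SimTruth`, the
ground truth consumed by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import BASES, AnnotationSet, AnnotationTerm, ExpressionMatrix, PromoterSet, PWM

__all__ = [
    "ProfileSpec",
    "SimTruth",
    "DEFAULT_GROUP_SIZES",
    "default_profiles",
    "default_profile_specs",
    "simulate_expression",
    "simulate_promoters",
    "simulate_annotations",
    "simulate_pwms",
]

#: Arrays per time group in the emulated design (days 0, 2, 7, 21, 60).
DEFAULT_GROUP_SIZES = (4, 6, 5, 8, 8)

#: Twelve well-separated time-profile shapes over five groups, values in
#: [-1, 1]. They mimic the qualitative families seen in injury time courses:
#: monotone late down/up-regulation, transient early responses, and delayed
#: switches.
_DEFAULT_PROFILES: tuple[tuple[float, ...], ...] = (
    (1.0, 0.6, 0.1, -0.5, -1.0),    # monotone down
    (1.0, 0.2, -0.6, -1.0, -0.8),   # fast down, slight recovery
    (0.5, 1.0, 0.2, -0.6, -1.0),    # brief rise then down
    (0.8, -0.2, -1.0, -0.6, 0.0),   # transient down
    (-0.6, 1.0, 0.4, -0.4, -0.8),   # early up transient
    (-1.0, -0.4, 0.3, 0.7, 1.0),    # monotone up
    (-0.8, 0.4, 1.0, 0.8, 0.6),     # early up sustained
    (-1.0, -0.8, 0.0, 0.9, 1.0),    # delayed up
    (-0.2, -1.0, -0.4, 0.5, 1.0),   # dip then late up
    (0.0, -0.6, -1.0, 0.2, 0.9),    # deep dip then up
    (0.6, -0.6, -1.0, -0.2, 0.4),   # early down transient
    (1.0, 0.4, 0.8, -0.8, -0.4),    # oscillating down
)


@dataclass
class ProfileSpec:
    """One planted cluster: its mean time profile and gene-level noise."""

    cluster_id: int
    profile: tuple[float, ...]
    n_genes: int
    amplitude: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        self.profile = tuple(float(x) for x in self.profile)
        if max(abs(x) for x in self.profile) > 1 + 1e-12:
            raise ValidationError("profile values must lie in [-1, 1]")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated study.

    ``gene_cluster`` maps every simulated gene to its planted cluster id or
    ``None`` for null genes; ``cluster_motifs``/``cluster_terms`` record which
    motifs/terms were planted as enriched in which cluster.
    """

    gene_cluster: dict[str, int | None] = field(default_factory=dict)
    cluster_motifs: dict[int, list[str]] = field(default_factory=dict)
    cluster_terms: dict[int, list[str]] = field(default_factory=dict)

    def cluster_genes(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.gene_cluster.items() if c == cluster_id]

    @property
    def planted_genes(self) -> list[str]:
        return [g for g, c in self.gene_cluster.items() if c is not None]

    @property
    def null_genes(self) -> list[str]:
        return [g for g, c in self.gene_cluster.items() if c is None]


def default_profiles(n_groups: int = 5) -> list[tuple[float, ...]]:
    """The twelve built-in profile shapes, truncated/cycled to ``n_groups``."""
    if n_groups == 5:
        return [tuple(p) for p in _DEFAULT_PROFILES]
    return [tuple((p * 3)[:n_groups]) for p in _DEFAULT_PROFILES]


def default_profile_specs(n_genes_per_cluster: int = 40, amplitude: float = 2.0,
                          noise_sd: float = 0.5, n_clusters: int = 12,
                          n_groups: int = 5) -> list[ProfileSpec]:
    """Specs for ``n_clusters`` (<=12) planted clusters with the built-in shapes."""
    profiles = default_profiles(n_groups)
    if n_clusters > len(profiles):
        raise ValidationError(f"at most {len(profiles)} built-in profiles")
    return [ProfileSpec(c + 1, profiles[c], n_genes_per_cluster, amplitude, noise_sd)
            for c in range(n_clusters)]


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(specs: Sequence[ProfileSpec], n_null: int,
                        group_sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
                        baseline_range: tuple[float, float] = (6.0, 12.0),
                        noise_sd_null: float | None = None,
                        seed: int | np.random.SeedSequence | None = 0,
                        ) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a log2 expression matrix with planted time-profile clusters.

    Planted gene g of cluster c on array m in group t(m):
    ``y_gm = b_g + amplitude_c * profile_c[t(m)] + eps``,
    ``eps ~ Normal(0, noise_sd_c^2)``; null genes are ``b_g + eps`` with
    ``noise_sd_null`` (default: the first spec's noise, or 0.5 with no
    specs). Baselines ``b_g`` are uniform over ``baseline_range``.
    """
    group_sizes = [int(s) for s in group_sizes]
    if any(s < 2 for s in group_sizes) or len(group_sizes) < 2:
        raise ValidationError("need >= 2 groups with >= 2 arrays each")
    for spec in specs:
        if len(spec.profile) != len(group_sizes):
            raise ValidationError(
                f"cluster {spec.cluster_id}: profile length {len(spec.profile)} "
                f"!= number of groups {len(group_sizes)}")
    rng = np.random.default_rng(seed)
    n_planted = sum(s.n_genes for s in specs)
    n_genes = n_planted + n_null
    gene_ids = _gene_ids(n_genes)

    groups = [f"day{t}" for t in (0, 2, 7, 21, 60)] if len(group_sizes) == 5 \
        else [f"group{t}" for t in range(len(group_sizes))]
    array_ids, design = [], {}
    group_of_col = []
    for gi, (g, size) in enumerate(zip(groups, group_sizes)):
        for r in range(size):
            aid = f"{g}_r{r + 1}"
            array_ids.append(aid)
            design[aid] = g
            group_of_col.append(gi)
    group_of_col = np.array(group_of_col)

    baselines = rng.uniform(*baseline_range, size=n_genes)
    values = np.empty((n_genes, len(array_ids)))
    truth = SimTruth()
    row = 0
    for spec in specs:
        prof = np.array(spec.profile)[group_of_col]
        block = (baselines[row:row + spec.n_genes, None]
                 + spec.amplitude * prof[None, :]
                 + rng.normal(0.0, spec.noise_sd, (spec.n_genes, len(array_ids))))
        values[row:row + spec.n_genes] = block
        for g in gene_ids[row:row + spec.n_genes]:
            truth.gene_cluster[g] = spec.cluster_id
        row += spec.n_genes
    sd0 = noise_sd_null if noise_sd_null is not None else \
        (specs[0].noise_sd if specs else 0.5)
    values[row:] = baselines[row:, None] + rng.normal(0.0, sd0, (n_null, len(array_ids)))
    for g in gene_ids[row:]:
        truth.gene_cluster[g] = None

    em = ExpressionMatrix(gene_ids, array_ids, values, design)
    return em, truth


def simulate_pwms(n_motifs: int = 4, length: int = 8, sharpness: float = 20.0,
                  seed: int | np.random.SeedSequence | None = 0) -> list[PWM]:
    """Generate informative random count PWMs.

    Each column is a Dirichlet draw concentrated on one random base
    (``sharpness`` pseudo-counts on the preferred base, 1 elsewhere), scaled
    to 100 counts — sharply peaked motifs a scanner can find.
    """
    if length < 4:
        raise ValidationError("motif length must be >= 4")
    rng = np.random.default_rng(seed)
    pwms = []
    for m in range(n_motifs):
        cols = []
        for _ in range(length):
            alpha = np.ones(4)
            alpha[rng.integers(4)] = sharpness
            cols.append(rng.dirichlet(alpha) * 100.0)
        pwms.append(PWM(f"MOTIF{m + 1:02d}", np.column_stack(cols), "transfac"))
    return pwms


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    probs = pwm.matrix / pwm.matrix.sum(axis=0, keepdims=True)
    idx = [rng.choice(4, p=probs[:, j]) for j in range(pwm.length)]
    return "".join(BASES[i] for i in idx)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_promoters(truth: SimTruth, pwms: Sequence[PWM], length: int = 1200,
                       planted_rates: Mapping[int, Mapping[str, float]] | None = None,
                       background_rate: float = 0.0,
                       base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                       upstream_bp: int | None = None, downstream_bp: int = 200,
                       seed: int | np.random.SeedSequence | None = 0) -> PromoterSet:
    """Simulate promoters with Poisson-planted motif sites.

    Background sequence is i.i.d. from ``base_composition``. For every
    promoter, each motif receives ``Poisson(rate)`` site insertions — rate
    ``background_rate`` everywhere plus the cluster-specific extra rate from
    ``planted_rates[cluster][motif]`` — placed at uniform non-overlapping
    positions on a random strand, with site letters drawn per column from the
    PWM's column distributions. Planted (above-background) cluster->motif
    pairs are recorded in ``truth.cluster_motifs``.
    """
    base_composition = np.asarray(base_composition, float)
    if base_composition.shape != (4,) or abs(base_composition.sum() - 1) > 1e-9:
        raise ValidationError("base_composition must be a 4-vector summing to 1")
    planted_rates = {int(c): dict(m) for c, m in (planted_rates or {}).items()}
    if background_rate < 0 or any(r < 0 for m in planted_rates.values() for r in m.values()):
        raise ValidationError("site rates must be >= 0")
    by_id = {p.motif_id: p for p in pwms}
    for c, rates in planted_rates.items():
        for mid in rates:
            if mid not in by_id:
                raise ValidationError(f"unknown motif {mid!r} in planted_rates")
    if any(p.length > length for p in pwms):
        raise ValidationError("motif longer than promoter length")

    if upstream_bp is None:  # keep the recorded window consistent with length
        upstream_bp = max(length - downstream_bp, 0)
        downstream_bp = length - upstream_bp
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for gid, cluster in truth.gene_cluster.items():
        arr = rng.choice(4, size=length, p=base_composition)
        seq = list("".join(BASES[i] for i in arr))
        occupied = np.zeros(length, dtype=bool)
        for pwm in pwms:
            rate = background_rate
            if cluster is not None:
                rate += planted_rates.get(cluster, {}).get(pwm.motif_id, 0.0)
            n_sites = rng.poisson(rate)
            placed = 0
            attempts = 0
            while placed < n_sites and attempts < 50 * (n_sites + 1):
                attempts += 1
                pos = int(rng.integers(0, length - pwm.length + 1))
                if occupied[pos:pos + pwm.length].any():
                    continue
                site = _sample_site(pwm, rng)
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                seq[pos:pos + pwm.length] = site
                occupied[pos:pos + pwm.length] = True
                placed += 1
        sequences[gid] = "".join(seq)

    for c, rates in planted_rates.items():
        planted = [m for m, r in rates.items() if r > 0]
        if planted:
            truth.cluster_motifs.setdefault(c, []).extend(
                m for m in planted if m not in truth.cluster_motifs.get(c, []))
    return PromoterSet(sequences, upstream_bp, downstream_bp)


def simulate_annotations(truth: SimTruth, n_terms: int,
                         term_size_range: tuple[int, int] = (10, 50),
                         enrichment_factor: float = 1.0,
                         planted_clusters: Sequence[int] | None = None,
                         seed: int | np.random.SeedSequence | None = 0) -> AnnotationSet:
    """Simulate GMT annotations with terms enriched in chosen clusters.

    One planted term is created per entry of ``planted_clusters``; it draws
    members with probability weight ``enrichment_factor`` for genes of its
    target cluster and weight 1 elsewhere (factor 1 makes planted terms
    indistinguishable from background). Remaining terms draw uniformly.
    Planted terms are recorded in ``truth.cluster_terms``.
    """
    if enrichment_factor < 1:
        raise ValidationError("enrichment_factor must be >= 1")
    lo, hi = int(term_size_range[0]), int(term_size_range[1])
    genes = list(truth.gene_cluster)
    if not (1 <= lo <= hi <= len(genes)):
        raise ValidationError(f"term_size_range {term_size_range} infeasible "
                              f"for {len(genes)} genes")
    planted_clusters = list(planted_clusters or [])
    if len(planted_clusters) > n_terms:
        raise ValidationError("more planted clusters than terms")
    rng = np.random.default_rng(seed)
    gene_arr = np.array(genes)
    cluster_arr = np.array([-1 if c is None else c
                            for c in truth.gene_cluster.values()])
    terms: list[AnnotationTerm] = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if i < len(planted_clusters):
            target = planted_clusters[i]
            w = np.where(cluster_arr == target, enrichment_factor, 1.0)
            members = rng.choice(gene_arr, size=size, replace=False, p=w / w.sum())
            tid = f"TERM{i + 1:04d}"
            truth.cluster_terms.setdefault(target, []).append(tid)
            terms.append(AnnotationTerm(tid, "SIM", f"planted cluster {target}",
                                        sorted(members)))
        else:
            members = rng.choice(gene_arr, size=size, replace=False)
            terms.append(AnnotationTerm(f"TERM{i + 1:04d}", "SIM", "background",
                                        sorted(members)))
    return AnnotationSet(terms)
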