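"""End-to-end orchestration: simulate -> normalize -> de -> cluster -> enrich -> motif.

A single :class:`RunConfig` carries every stage parameter (defaults match
the study settings: FDR 0.02, k-range 6-14 with 30 repeats, 12 consensus
clusters, 70% overlap / p 0.03, 1000/200 bp promoter window, |Z| cutoff 3)
plus one master seed that fans out deterministically to named per-stage
substreams. :func:`run_all` executes the stages in order, writes each
stage's TSV outputs to the output directory, and finishes with a YAML run
manifest recording versions, seeds, parameters and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ConsensusClusterModel, export_heatmap_tables
from .diffexpr import DifferentialExpressionModel
from .enrichment import TermEnrichmentModel
from .errors import ValidationError
from .io import (read_annotations, read_expression,
                 read_fasta_promoters, read_pwms, write_annotations,
                 write_expression, write_fasta_promoters, write_pwms)
from .motifs import MotifOverrepresentationModel
from .preprocess import normalize_gene_wise, quantile_normalize
from .simulate import (DEFAULT_GROUP_SIZES, default_profile_specs,
                       simulate_annotations, simulate_expression,
                       simulate_promoters, simulate_pwms)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_STAGES = ("simulate", "normalize", "de", "cluster", "enrich", "motif")


@dataclass
class RunConfig:
    """All pipeline inputs, outputs and stage parameters."""

    outdir: str = "chronomics_run"
    seed: int = 0

    # inputs (ignored when simulate=True)
    simulate: bool = True
    expression_path: str | None = None
    design_path: str | None = None
    promoter_path: str | None = None
    pwm_path: str | None = None
    pwm_dialect: str = "transfac"
    annotation_path: str | None = None

    # synthetic-data stage
    sim_n_clusters: int = 12
    sim_genes_per_cluster: int = 40
    sim_n_null: int = 500
    sim_amplitude: float = 2.0
    sim_noise_sd: float = 0.5
    sim_group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    sim_n_motifs: int = 4
    sim_motif_length: int = 8
    sim_planted_site_rate: float = 3.0
    sim_background_site_rate: float = 0.25
    sim_n_terms: int = 30
    sim_enrichment_factor: float = 20.0

    # normalize
    quantile: bool = True

    # differential expression
    alpha: float = 0.02
    n_perm: int = 1000
    window_size: int = 101
    n0: float = 10.0

    # consensus clustering
    k_min: int = 6
    k_max: int = 14
    repeats: int = 30
    n_clusters: int = 12

    # enrichment
    overlap_threshold: float = 0.70
    p_threshold: float = 0.03
    ease: bool = False

    # motifs
    promoter_upstream: int = 1000
    promoter_downstream: int = 200
    threshold_fraction: float = 0.80
    pseudocount: float = 0.01
    z_cut: float = 3.0

    def validate(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValidationError("p_threshold must be in (0, 1]")
        if not 0 < self.overlap_threshold <= 1:
            raise ValidationError("overlap_threshold must be in (0, 1]")
        if not 0 < self.threshold_fraction <= 1:
            raise ValidationError("threshold_fraction must be in (0, 1]")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if not 1 <= self.k_min <= self.k_max:
            raise ValidationError("need 1 <= k_min <= k_max")
        if self.n_clusters < 1 or self.repeats < 1:
            raise ValidationError("n_clusters and repeats must be >= 1")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValidationError("window_size must be odd and >= 3")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValidationError("promoter window must be non-negative")
        if self.z_cut <= 0:
            raise ValidationError("z_cut must be positive")
        if not self.simulate:
            for name in ("expression_path", "design_path"):
                if getattr(self, name) is None:
                    raise ValidationError(f"{name} required when simulate=False")

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sim_group_sizes"] = list(self.sim_group_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "sim_group_sizes" in d:
            d["sim_group_sizes"] = tuple(d["sim_group_sizes"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest (also written
    to ``<outdir>/manifest.yaml``). Any stage error aborts with the stage
    name attached."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package": "chronomics",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "master_seed": config.seed,
        "stage_seeds": {s: list(map(int, seeds[s].entropy if isinstance(seeds[s].entropy, tuple) else [seeds[s].entropy]))
                        for s in _STAGES},
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }
    manifest["parameters"]["sim_group_sizes"] = list(config.sim_group_sizes)

    stage = "simulate"
    try:
        if config.simulate:
            specs = default_profile_specs(config.sim_genes_per_cluster,
                                          config.sim_amplitude, config.sim_noise_sd,
                                          config.sim_n_clusters,
                                          len(config.sim_group_sizes))
            sim_ss = seeds["simulate"].spawn(4)
            em, truth = simulate_expression(specs, config.sim_n_null,
                                            config.sim_group_sizes, seed=sim_ss[0])
            pwms = simulate_pwms(config.sim_n_motifs, config.sim_motif_length,
                                 seed=sim_ss[1])
            # plant motif m in cluster m+1 (one planted pair per motif)
            planted = {m + 1: {pwms[m].motif_id: config.sim_planted_site_rate}
                       for m in range(min(config.sim_n_motifs, config.sim_n_clusters))}
            promoters = simulate_promoters(
                truth, pwms, config.promoter_upstream + config.promoter_downstream,
                planted, config.sim_background_site_rate,
                upstream_bp=config.promoter_upstream,
                downstream_bp=config.promoter_downstream, seed=sim_ss[2])
            annotations = simulate_annotations(
                truth, config.sim_n_terms, enrichment_factor=config.sim_enrichment_factor,
                planted_clusters=list(range(1, config.sim_n_clusters + 1)),
                seed=sim_ss[3])
            write_expression(em, outdir / "expression.tsv", outdir / "design.tsv")
            write_fasta_promoters(promoters, outdir / "promoters.fa")
            write_pwms(pwms, outdir / "motifs.transfac", "transfac")
            write_annotations(annotations, outdir / "annotations.gmt")
            pd.DataFrame({"gene_id": list(truth.gene_cluster),
                          "cluster": ["null" if c is None else c
                                      for c in truth.gene_cluster.values()]}
                         ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {
                "genes": em.n_genes, "arrays": em.n_arrays,
                "planted_clusters": config.sim_n_clusters,
                "null_genes": config.sim_n_null, "motifs": len(pwms),
                "terms": len(annotations)}
            logger.info("simulate: %d genes x %d arrays, %d motifs, %d terms",
                        em.n_genes, em.n_arrays, len(pwms), len(annotations))
        else:
            em = read_expression(config.expression_path, config.design_path)
            promoters = (read_fasta_promoters(config.promoter_path,
                                              config.promoter_upstream,
                                              config.promoter_downstream)
                         if config.promoter_path else None)
            pwms = (read_pwms(config.pwm_path, config.pwm_dialect)
                    if config.pwm_path else [])
            annotations = (read_annotations(config.annotation_path)
                           if config.annotation_path else None)
            for key in ("expression_path", "design_path", "promoter_path",
                        "pwm_path", "annotation_path"):
                p = getattr(config, key)
                if p:
                    manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
            manifest["stages"]["simulate"] = {"skipped": True, "genes": em.n_genes}

        stage = "normalize"
        if config.quantile:
            em = quantile_normalize(em)
        norm = normalize_gene_wise(em)
        pd.DataFrame(norm.values, index=pd.Index(norm.gene_ids, name="gene_id"),
                     columns=norm.array_ids).to_csv(outdir / "normalized.tsv",
                                                    sep="\t", float_format="%.6g")
        degenerate = [g for g, d in zip(norm.gene_ids, norm.degenerate) if d]
        (outdir / "degenerate_genes.txt").write_text("\n".join(degenerate) + "\n"
                                                     if degenerate else "")
        manifest["stages"]["normalize"] = {"genes": norm.n_genes,
                                           "degenerate": len(degenerate),
                                           "quantile": config.quantile}
        logger.info("normalize: %d genes, %d degenerate", norm.n_genes, len(degenerate))

        stage = "de"
        de_model = DifferentialExpressionModel(em, alpha=config.alpha,
                                               n_perm=config.n_perm,
                                               window_size=config.window_size,
                                               n0=config.n0)
        de = de_model.fit(seed=seeds["de"])
        de.to_tsv(outdir / "de_table.tsv")
        (outdir / "de_genes.txt").write_text("\n".join(de.de_genes) + "\n")
        manifest["stages"]["de"] = {"genes_in": em.n_genes, "genes_called": de.n_de,
                                    "alpha": config.alpha}
        logger.info("de: %d of %d genes called at FDR<=%g", de.n_de, em.n_genes,
                    config.alpha)
        if de.n_de <= config.k_max:
            raise ValidationError(
                f"only {de.n_de} DE genes called; cannot scan k up to {config.k_max}")

        stage = "cluster"
        de_norm = _subset_norm(norm, de.de_genes)
        cc = ConsensusClusterModel(de_norm, config.k_min, config.k_max,
                                   config.repeats, config.n_clusters
                                   ).fit(seed=seeds["cluster"])
        memb = pd.DataFrame({"gene_id": cc.assignment.gene_ids,
                             "cluster": cc.assignment.labels})
        memb.to_csv(outdir / "membership.tsv", sep="\t", index=False)
        pd.DataFrame(cc.co_occurrence.values,
                     index=pd.Index(cc.co_occurrence.gene_ids, name="gene_id"),
                     columns=cc.co_occurrence.gene_ids
                     ).to_csv(outdir / "cooccurrence.tsv", sep="\t",
                              float_format="%.4g")
        (outdir / "dendrogram.nwk").write_text(
            linkage_to_newick(cc.assignment.linkage, cc.assignment.gene_ids))
        cc.profiles_frame().to_csv(outdir / "profiles.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        export_heatmap_tables(cc.assignment, de_norm, outdir / "heatmaps")
        cc.stability.to_csv(outdir / "stability.tsv", sep="\t", index=False,
                            float_format="%.6g")
        manifest["stages"]["cluster"] = {"genes": len(cc.assignment.gene_ids),
                                         "runs": len(cc.partitions),
                                         "clusters": cc.assignment.n_clusters,
                                         "sizes": cc.cluster_sizes}
        logger.info("cluster: %d genes, %d runs, %d clusters",
                    len(cc.assignment.gene_ids), len(cc.partitions),
                    cc.assignment.n_clusters)

        stage = "enrich"
        if annotations is not None:
            clusters = {c: cc.assignment.cluster_genes(c)
                        for c in range(1, cc.assignment.n_clusters + 1)}
            enr = TermEnrichmentModel(clusters, de.de_genes, annotations,
                                      config.overlap_threshold, config.p_threshold,
                                      config.ease).fit()
            enr.table().to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                               float_format="%.4g")
            n_groups = int(len(enr.table()))
            manifest["stages"]["enrich"] = {"terms": len(annotations),
                                            "significant_groups": n_groups}
            logger.info("enrich: %d terms, %d significant groups",
                        len(annotations), n_groups)
        else:
            manifest["stages"]["enrich"] = {"skipped": True}

        stage = "motif"
        if promoters is not None and pwms:
            mo = MotifOverrepresentationModel(cc.assignment, promoters, pwms,
                                              config.threshold_fraction,
                                              config.pseudocount, config.z_cut).fit()
            mo.zmatrix.frame().to_csv(outdir / "zmatrix.tsv", sep="\t",
                                      float_format="%.4g")
            mo.calls().to_csv(outdir / "motif_calls.tsv", sep="\t", index=False,
                              float_format="%.4g")
            try:
                mo.pca().to_csv(outdir / "zmatrix_pca.tsv", sep="\t", index=False,
                                float_format="%.6g")
            except ValidationError as exc:
                logger.warning("motif PCA skipped: %s", exc)
            n_over = int((mo.calls()["call"] == "over").sum())
            manifest["stages"]["motif"] = {"motifs": len(pwms),
                                           "clusters": len(mo.zmatrix.cluster_ids),
                                           "over_calls": n_over}
            logger.info("motif: %d motifs x %d clusters, %d over-representation calls",
                        len(pwms), len(mo.zmatrix.cluster_ids), n_over)
        else:
            manifest["stages"]["motif"] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    Path(outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def _subset_norm(norm, gene_ids):
    from .preprocess import NormalizedMatrix
    idx = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = [idx[g] for g in gene_ids]
    return NormalizedMatrix([norm.gene_ids[i] for i in rows], list(norm.array_ids),
                            norm.values[rows], dict(norm.design),
                            norm.center[rows], norm.scale[rows],
                            norm.degenerate[rows])


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = Z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    trees = {i: leaf_names[i] for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        trees[n + i] = f"({trees[a]}:{la:.6g},{trees[b]}:{lb:.6g})"
        heights[n + i] = h
    return trees[n + Z.shape[0] - 1] + ";\n"
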