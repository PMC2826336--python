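"""End-to-end orchestration: calls -> overlap -> clusters -> motifs ->
enrichment -> network -> QTL, with deterministic seed fan-out and a
checksum manifest over every written artifact."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from chillregnet import coexpression, element_enrichment, network_inference, qtl_enrichment
from chillregnet.expression_calls import (
    CallConfig,
    call_downregulated,
    call_h2o2_responsive,
    call_upregulated,
    calls_to_frame,
    overlap_sets,
)
from chillregnet.motif_discovery import (
    DiscoveryConfig,
    background_filter,
    discover_motifs,
    write_meme,
)
from chillregnet.synthetic_data import StudyBundle

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "write_report",
    "evaluate_primary_recovery",
    "PipelineError",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    call: CallConfig = CallConfig()
    k: int = 18
    n_restarts: int = 8
    discovery: DiscoveryConfig = DiscoveryConfig()
    n_background: int = 200
    alpha_e: float = 1e-3
    min_similarity: float = 0.75
    min_occurrence: float = 50.0
    qtl_alpha: float = 0.25
    seed: int = 0

    def stage_seed(self, index: int) -> int:
        seeds = np.random.SeedSequence(self.seed).generate_state(8)
        return int(seeds[index] % (2**31))


@dataclass
class PipelineResult:
    up_calls: list
    down_calls: list
    h2o2_set: set
    overlap: object
    clusters: list
    motifs: dict  # cluster_id -> list[MotifModel]
    enrichments: dict  # cluster_id -> list[ClassEnrichment]
    edges: list
    qtl_result: object
    associations: pd.DataFrame
    qtl_by_trait: list = field(default_factory=list)
    tf_calls: list = field(default_factory=list)


def _validate_bundle(bundle: StudyBundle) -> None:
    if bundle.chilling.ratios.empty:
        raise PipelineError("validate", "empty chilling expression matrix")
    if bundle.universe.empty:
        raise PipelineError("validate", "empty gene annotation table")
    known = set(bundle.universe["gene_id"])
    missing = set(bundle.chilling.genes) - known
    if missing:
        raise PipelineError(
            "validate", f"{len(missing)} expression gene ids missing from annotation"
        )


def run_pipeline(bundle: StudyBundle, config: PipelineConfig = PipelineConfig(),
                 outdir=None, log=None) -> PipelineResult:
    """Run every stage on a loaded bundle; optionally write the report.

    The single pipeline seed is fanned out through a seed sequence so each
    stochastic stage (clustering restarts, per-cluster motif discovery,
    background sampling) is independently reproducible.
    """
    records = []

    def _log(stage, **kw):
        rec = {"stage": stage, "t": time.time(), **kw}
        records.append(rec)
        if log:
            log.write(json.dumps(rec) + "\n")

    _validate_bundle(bundle)
    universe = bundle.universe
    is_tf = dict(zip(universe["gene_id"], universe["is_tf"]))
    tf_family = dict(zip(universe["gene_id"], universe["tf_family"]))

    t0 = time.time()
    up_calls = call_upregulated(bundle.chilling, config.call)
    down_calls = call_downregulated(bundle.chilling, config.call)
    h2o2_set = call_h2o2_responsive(bundle.h2o2)
    up_set = {c.gene for c in up_calls}
    overlap = overlap_sets(up_set, h2o2_set)
    _log("calls", n_up=len(up_calls), n_down=len(down_calls),
         n_h2o2=len(h2o2_set), n_overlap=len(overlap.intersection),
         seconds=round(time.time() - t0, 2))

    t0 = time.time()
    ntf_up = [g for g in up_set if not is_tf.get(g, False)]
    profiles = bundle.chilling.ratios.loc[sorted(ntf_up)]
    clusters = coexpression.kmeans_cluster(
        profiles, k=config.k, seed=config.stage_seed(1),
        n_restarts=config.n_restarts, call_config=config.call,
    )
    for cl in clusters:
        coexpression.h2o2_fraction(cl, h2o2_set)
    _log("clustering", k=config.k, n_genes=len(profiles),
         seconds=round(time.time() - t0, 2))

    t0 = time.time()
    rng_bg = np.random.default_rng(config.stage_seed(2))
    non_stress = [g for g in bundle.promoters.sequences if g not in up_set]
    n_bg = min(config.n_background, len(non_stress))
    bg_genes = list(rng_bg.choice(non_stress, size=n_bg, replace=False)) if n_bg else []
    background = bundle.promoters.subset(bg_genes)
    catalog = element_enrichment.load_default_catalog()
    motifs_by_cluster, enrich_by_cluster = {}, {}
    for ci, cl in enumerate(clusters):
        promoters = bundle.promoters.subset(cl.members)
        if len(promoters) < 5:
            motifs_by_cluster[cl.cluster_id] = []
            enrich_by_cluster[cl.cluster_id] = []
            continue
        dcfg = replace(config.discovery, seed=config.stage_seed(3) + ci)
        motifs = discover_motifs(promoters, dcfg)
        if len(background):
            motifs = background_filter(
                motifs, promoters, background, alpha_e=config.alpha_e, config=dcfg
            )
        for m in motifs:
            element_enrichment.match_element_class(m, catalog, config.min_similarity)
        motifs_by_cluster[cl.cluster_id] = motifs
        enrich_by_cluster[cl.cluster_id] = element_enrichment.class_scores(
            cl.cluster_id, motifs, config.min_occurrence
        )
    _log("motifs", n_clusters=len(clusters),
         n_motifs=sum(len(v) for v in motifs_by_cluster.values()),
         seconds=round(time.time() - t0, 2))

    t0 = time.time()
    tf_calls = [c for c in up_calls if is_tf.get(c.gene, False)]
    edges = network_inference.infer_edges(
        clusters, enrich_by_cluster, tf_calls, tf_family
    )
    _log("network", n_edges=len(edges), seconds=round(time.time() - t0, 2))

    t0 = time.time()
    associations = qtl_enrichment.colocalize_genes(universe, bundle.qtl)
    tf_up_genes = {c.gene for c in tf_calls}
    all_genes = set(universe["gene_id"])
    qtl_result = qtl_enrichment.fisher_enrichment(
        tf_up_genes, all_genes, associations, alpha=config.qtl_alpha
    )
    qtl_by_trait = [
        qtl_enrichment.fisher_enrichment(
            tf_up_genes, all_genes, associations, alpha=config.qtl_alpha,
            trait=trait,
        )
        for trait in sorted(set(bundle.qtl["trait"]))
    ]
    _log("qtl", p=qtl_result.p_value, enriched=qtl_result.enriched,
         seconds=round(time.time() - t0, 2))

    result = PipelineResult(
        up_calls=up_calls, down_calls=down_calls, h2o2_set=h2o2_set,
        overlap=overlap, clusters=clusters, motifs=motifs_by_cluster,
        enrichments=enrich_by_cluster, edges=edges, qtl_result=qtl_result,
        qtl_by_trait=qtl_by_trait, associations=associations,
        tf_calls=tf_calls,
    )
    if outdir is not None:
        write_report(result, outdir, log_records=records)
    return result


def write_report(result: PipelineResult, outdir, log_records=None) -> Path:
    """Write the per-stage tables (motif table mirrors the published
    cluster/motif/element/%(TIC)/e-value layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    calls_to_frame(result.up_calls + result.down_calls).to_csv(
        outdir / "calls.tsv", sep="\t", index=False
    )
    membership, summary = coexpression.clusters_to_frames(result.clusters)
    membership.to_csv(outdir / "cluster_membership.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)

    motif_rows = []
    all_motifs = []
    for cid, motifs in sorted(result.motifs.items()):
        for m in motifs:
            all_motifs.append(m)
            motif_rows.append(
                {
                    "cluster": cid,
                    "motif": m.consensus,
                    "element_class": m.element_class or "unassigned",
                    "tf_family": m.tf_family or "unassigned",
                    "pct_tic": f"{m.occurrence_pct:.0f} ({m.tic:.2f})",
                    "e_value": f"{m.e_value:.0e}" if m.e_value is not None else "NA",
                    "secondary_class": m.secondary_class or "",
                }
            )
    pd.DataFrame(
        motif_rows,
        columns=["cluster", "motif", "element_class", "tf_family", "pct_tic",
                 "e_value", "secondary_class"],
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    write_meme(all_motifs, outdir / "motifs.meme")

    score_rows = [
        {
            "cluster": cid,
            "broad_category": e.broad_category,
            "total_score": round(e.total_score, 1),
            "n_species": e.n_motif_species,
            "motifs": ",".join(e.motifs),
        }
        for cid, enr in sorted(result.enrichments.items())
        for e in enr
    ]
    pd.DataFrame(
        score_rows,
        columns=["cluster", "broad_category", "total_score", "n_species", "motifs"],
    ).to_csv(outdir / "class_scores.tsv", sep="\t", index=False)

    network_inference.export_network(result.edges, "json", outdir / "network.json")
    pd.DataFrame(
        [
            {
                "trait": q.trait or "pooled",
                "subset_assoc": q.table[0][0],
                "subset_non": q.table[0][1],
                "rest_assoc": q.table[1][0],
                "rest_non": q.table[1][1],
                "subset_ratio": round(q.subset_ratio, 4),
                "genome_ratio": round(q.genome_ratio, 4),
                "p_value": q.p_value,
                "enriched": q.enriched,
            }
            for q in [result.qtl_result, *result.qtl_by_trait]
        ]
    ).to_csv(outdir / "qtl_enrichment.tsv", sep="\t", index=False)

    if log_records is not None:
        with open(outdir / "log.jsonl", "w") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec) + "\n")
    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name in ("manifest.json", "log.jsonl") or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def evaluate_primary_recovery(result: PipelineResult, truth) -> float:
    """Fraction of fitted clusters whose primary edge matches the planted
    regulator class of the majority truth group among its members."""
    primary = {
        e.target_cluster: e.source_class
        for e in result.edges
        if e.rank == "primary"
    }
    n_eval, n_hit = 0, 0
    for cl in result.clusters:
        truth_labels = [truth.gene_cluster.get(g) for g in cl.members]
        truth_labels = [t for t in truth_labels if t is not None]
        if not truth_labels:
            continue
        majority = max(set(truth_labels), key=truth_labels.count)
        planted = truth.cluster_elements.get(majority)
        if planted is None:
            continue
        n_eval += 1
        if primary.get(cl.cluster_id) == planted:
            n_hit += 1
    return n_hit / n_eval if n_eval else 0.0
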