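"""End-to-end orchestration: raw tables in, report bundle out.

Glue around the analysis modules; every statistic is computed by the stage
modules and only assembled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusterview, fluidcorr, mixedfx, pathtopo, prep, setrich
from .iolayer import RunConfig

logger = logging.getLogger("urometab")


@dataclass
class PipelineResult:
    config: RunConfig
    urine: prep.ProcessedTable
    plasma: prep.ProcessedTable | None
    lmm: pd.DataFrame
    enrichment: dict            # mode -> {contrast -> records}
    topology: dict              # mode -> report
    correlations: pd.DataFrame | None
    census: pd.DataFrame | None
    screen_hits: pd.DataFrame | None
    cluster: clusterview.ClusterResult | None
    summary: dict = field(default_factory=dict)


def run_pipeline(urine_raw: pd.DataFrame, samples: pd.DataFrame,
                 annotation: pd.DataFrame,
                 plasma_raw: pd.DataFrame | None = None,
                 graphs: dict | None = None,
                 config: RunConfig | None = None,
                 cluster_k: int = 3) -> PipelineResult:
    """Run preprocessing, mixed models, enrichment, topology, correlations
    and clustering on one study's tables."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)

    urine_proc = prep.preprocess(urine_raw, samples, annotation, config)
    lmm = mixedfx.contrast_table(urine_proc, samples, config)

    enrichment = {}
    retained_lmm = lmm
    enrichment["subpathway"] = setrich.enrich_contrasts(
        retained_lmm, annotation, mode="subpathway", config=config)
    if annotation["cluster_id"].notna().any():
        enrichment["cluster"] = setrich.enrich_contrasts(
            retained_lmm, annotation, mode="cluster", config=config)

    topology = {}
    if graphs:
        post_ids = samples.loc[(samples["fluid"] == "urine")
                               & (samples["timepoint"] == "U3"), "sample_id"]
        post_vals = urine_proc.filtered_values.loc[
            urine_proc.filtered_values.index.intersection(post_ids)]
        topology["timepoint"] = pathtopo.topology_analysis(
            graphs, annotation, post_vals, samples, mode="timepoint",
            config=config, rng=rng)
        ratios = prep.make_ratios(urine_proc.filtered_values, samples,
                                  "U3", "U1")
        topology["ratio"] = pathtopo.topology_analysis(
            graphs, annotation, ratios, samples, mode="ratio",
            config=config, rng=rng)

    correlations = census = hits = None
    plasma_proc = None
    if plasma_raw is not None:
        plasma_proc = prep.preprocess(plasma_raw, samples, annotation, config)
        correlations, census = fluidcorr.correlation_census(
            urine_proc.values, plasma_proc.values, samples, config)
        hits = fluidcorr.differential_screen(correlations, config)

    cluster = None
    heat = clusterview.select_post_exercise_matrix(
        lmm, urine_proc.centered, samples, q_threshold=config.lmm_q)
    if heat.shape[1] >= 1 and heat.shape[0] >= cluster_k:
        cluster = clusterview.cluster_subjects(heat, k=cluster_k)

    summary = {
        "n_metabolites_measured": int(urine_raw.shape[1]),
        "n_metabolites_retained": int(len(urine_proc.retained)),
        "n_significant": {
            name: int((lmm.loc[lmm["contrast"] == name, "q"]
                       < config.lmm_q).sum())
            for name in mixedfx.CONTRASTS},
        "n_enriched_subpathways": {
            name: int((rec["q"] < config.subpathway_q).sum())
            for name, rec in enrichment["subpathway"].items()},
        "thresholds": {"lmm_q": config.lmm_q,
                       "subpathway_q": config.subpathway_q,
                       "cluster_q": config.cluster_q,
                       "topology_q": config.topology_q,
                       "corr_q": config.corr_q},
    }
    if census is not None:
        summary["n_screen_hits"] = int(len(hits))
        summary["n_shared_metabolites"] = int(
            correlations["metabolite_id"].nunique())
    if topology:
        summary["n_significant_pathways"] = {
            mode: int(rep["significant"].sum()) if len(rep) else 0
            for mode, rep in topology.items()}
    return PipelineResult(config=config, urine=urine_proc, plasma=plasma_proc,
                          lmm=lmm, enrichment=enrichment, topology=topology,
                          correlations=correlations, census=census,
                          screen_hits=hits, cluster=cluster, summary=summary)


def write_report(result: PipelineResult, samples: pd.DataFrame,
                 outdir: str | Path) -> dict:
    """Assemble the plot-ready stage tables and write the report bundle."""
    volcano = pd.concat(
        [mixedfx.volcano_table(result.lmm, name, result.config.lmm_q)
         .assign(contrast=name) for name in mixedfx.CONTRASTS],
        ignore_index=True)
    enr_bubbles = setrich.bubble_table(
        result.enrichment["subpathway"], result.config.subpathway_q)
    if "cluster" in result.enrichment:
        cl = setrich.bubble_table(result.enrichment["cluster"],
                                  result.config.cluster_q)
        enr_bubbles = pd.concat([enr_bubbles.assign(mode="subpathway"),
                                 cl.assign(mode="cluster")], ignore_index=True)
    else:
        enr_bubbles = enr_bubbles.assign(mode="subpathway")
    topo = (pd.concat([rep.assign(mode=mode)
                       for mode, rep in result.topology.items()],
                      ignore_index=True)
            if result.topology else pd.DataFrame(
                columns=["pathway_id", "n_matched", "global_stat", "global_p",
                         "impact", "q", "significant", "mode"]))
    heat = clusterview.select_post_exercise_matrix(
        result.lmm, result.urine.centered, samples,
        q_threshold=result.config.lmm_q)
    merges = (result.cluster.merge_table if result.cluster is not None
              else pd.DataFrame(columns=["node_a", "node_b", "height",
                                         "new_id"]))
    inter = result.lmm[(result.lmm["contrast"] == "interaction")
                       & (result.lmm["q"] < result.config.lmm_q)]
    traj = clusterview.trajectory_table(
        result.urine.values, samples[samples["fluid"] == "urine"],
        inter["metabolite_id"].tolist())
    census = (result.census if result.census is not None
              else pd.DataFrame(columns=["cohort", "pairing_id", "kind",
                                         "n_strong_positive",
                                         "n_strong_negative", "n_tested"]))
    if result.correlations is not None and result.screen_hits is not None:
        screen = fluidcorr.screen_heatmap_table(result.correlations,
                                                result.screen_hits)
        corr_records = result.correlations
    else:
        screen = pd.DataFrame(columns=["metabolite_id", "pairing_id", "kind",
                                       "cohort", "R", "R_masked"])
        corr_records = pd.DataFrame(columns=["metabolite_id", "cohort",
                                             "pairing_id", "kind", "n", "R",
                                             "p", "q"])
    stages = {
        "volcano": volcano,
        "enrichment_bubble": enr_bubbles,
        "topology_bubble": topo,
        "post_exercise_matrix": heat,
        "cluster_merges": merges,
        "subject_trajectories": traj,
        "correlation_census": census,
        "screen_heatmap": screen,
        "correlation_records": corr_records,
        "summary": result.summary,
    }
    return clusterview.report_bundle(stages, outdir)
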