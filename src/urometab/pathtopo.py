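"""Pathway quantitative enrichment (global test) and topology impact scores.

Pathways are undirected graphs over HMDB-namespace compound nodes.  Measured
metabolites are matched to nodes by HMDB id (first-duplicate rule: when
several metabolites share one HMDB id, only the first in annotation order is
kept).  Node importance is relative betweenness centrality — Brandes
shortest-path counting with fractional credit for ties, endpoints excluded —
rescaled so the most central node of each pathway has importance 1.  The
impact score of a pathway is the sum of the importances of its matched nodes.

The quantitative enrichment statistic is the global test score

    Q = (y - ybar)' X X' (y - ybar) / m

with X the column-standardized matrix of the pathway's matched metabolites
and y the 0/1 cohort labels; it asks whether the pathway's metabolites help
separate the cohorts, under the null that no member differs between groups.
Inference is by label permutation (empirical p with add-one smoothing),
exact at this study's sample sizes.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .iolayer import RunConfig
from .mixedfx import bh_adjust

logger = logging.getLogger("urometab")


def match_hmdb(annot: pd.DataFrame, graphs: dict[str, nx.Graph],
               restrict_to: pd.Index | None = None) -> pd.Series:
    """Map metabolites to pathway nodes by HMDB id.

    Returns a Series metabolite_id -> HMDB node id covering metabolites whose
    id occurs in at least one pathway graph.  Duplicated HMDB ids keep only
    the first metabolite in annotation order (the rest are logged as dropped).
    """
    universe = set()
    for g in graphs.values():
        universe.update(g.nodes)
    annotated = annot.dropna(subset=["hmdb_id"])
    if restrict_to is not None:
        annotated = annotated[annotated.index.isin(restrict_to)]
    dup = annotated["hmdb_id"].duplicated()
    if dup.any():
        logger.info("match_hmdb: dropped %d duplicate-HMDB metabolites: %s",
                    int(dup.sum()), list(annotated.index[dup][:5]))
    annotated = annotated[~dup.to_numpy()]
    mapping = annotated.loc[annotated["hmdb_id"].isin(universe), "hmdb_id"]
    logger.info("match_hmdb: %d / %d annotated metabolites matched to "
                "pathway nodes", len(mapping), len(annotated))
    return mapping


def node_importance(graph: nx.Graph) -> dict:
    """Relative betweenness centrality, rescaled to max 1 per pathway.

    All-zero centralities (complete graphs, isolated nodes, graphs with < 3
    nodes) yield importances of 0 everywhere.
    """
    if graph.number_of_nodes() == 0:
        return {}
    bc = nx.betweenness_centrality(graph, normalized=True)
    top = max(bc.values())
    if top <= 0:
        return {node: 0.0 for node in bc}
    return {node: v / top for node, v in bc.items()}


def global_test_stat(X: np.ndarray, y: np.ndarray) -> float:
    """Global test score statistic for a standardized pathway matrix."""
    yc = y - y.mean()
    s = X.T @ yc
    return float(s @ s) / X.shape[1]


def global_test(values: pd.DataFrame, labels: np.ndarray, n_perm: int = 9999,
                rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Permutation global test of one pathway's matched metabolite matrix.

    Parameters
    ----------
    values
        samples (or subjects) x matched metabolites.
    labels
        binary cohort labels aligned with the rows.

    Returns (Q, p).  The permutation p-value uses add-one smoothing:
    (1 + #{Q_perm >= Q}) / (n_perm + 1).
    """
    if values.shape[1] < 2:
        raise ValueError("global test needs >= 2 matched metabolites")
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both cohort labels must be present")
    rng = rng or np.random.default_rng()
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    q_obs = global_test_stat(X, y)
    yc = y - y.mean()
    perms = np.empty((n_perm, len(y)))
    for i in range(n_perm):
        perms[i] = rng.permutation(yc)
    scores = perms @ X                     # n_perm x m
    q_perm = np.einsum("ij,ij->i", scores, scores) / X.shape[1]
    p = (1.0 + float(np.sum(q_perm >= q_obs - 1e-12))) / (n_perm + 1.0)
    return q_obs, p


def topology_report(graphs: dict[str, nx.Graph], mapping: pd.Series,
                    values: pd.DataFrame, labels: np.ndarray,
                    n_perm: int = 9999,
                    rng: np.random.Generator | None = None,
                    q_threshold: float = 0.2) -> pd.DataFrame:
    """Per-pathway global test p, BH q, and topology impact score.

    ``values`` is the per-sample transformed matrix for timepoint comparisons
    or the per-subject ratio matrix for recovery comparisons; ``mapping``
    comes from :func:`match_hmdb`.  Pathways with fewer than 2 matched
    metabolites are skipped.
    """
    rng = rng or np.random.default_rng()
    node_to_met = {node: met for met, node in mapping.items()}
    rows, skipped = [], []
    for pid, graph in graphs.items():
        importance = node_importance(graph)
        matched_nodes = [n for n in graph.nodes if n in node_to_met]
        matched_mets = [node_to_met[n] for n in matched_nodes
                        if node_to_met[n] in values.columns]
        matched_nodes = [n for n in matched_nodes
                         if node_to_met[n] in values.columns]
        if len(matched_mets) < 2:
            skipped.append(pid)
            continue
        impact = float(sum(importance[n] for n in matched_nodes))
        q_stat, p = global_test(values[matched_mets], labels,
                                n_perm=n_perm, rng=rng)
        rows.append({"pathway_id": pid, "n_matched": len(matched_mets),
                     "global_stat": q_stat, "global_p": p, "impact": impact,
                     "matched_importances": ";".join(
                         f"{node_to_met[n]}={importance[n]:.4g}"
                         for n in matched_nodes)})
    if skipped:
        logger.info("topology: skipped %d pathways with < 2 matched "
                    "metabolites: %s", len(skipped), skipped[:10])
    report = pd.DataFrame(rows)
    if len(report):
        report["q"] = bh_adjust(report["global_p"].to_numpy())
        report["significant"] = report["q"] < q_threshold
    else:
        report["q"] = pd.Series(dtype=float)
        report["significant"] = pd.Series(dtype=bool)
    return report


def topology_analysis(graphs: dict[str, nx.Graph], annot: pd.DataFrame,
                      values: pd.DataFrame, samples: pd.DataFrame,
                      mode: str = "timepoint",
                      config: RunConfig | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Convenience wrapper choosing labels for either analysis mode.

    ``mode="timepoint"``: rows of ``values`` are samples (one timepoint),
    labels are the samples' cohorts.  ``mode="ratio"``: rows are subjects
    (per-subject log10 ratios), labels are the subjects' cohorts.
    """
    config = config or RunConfig()
    if mode == "timepoint":
        meta = samples.set_index("sample_id").loc[values.index]
        labels = (meta["cohort"] == "mecfs").to_numpy(dtype=float)
    elif mode == "ratio":
        cohorts = (samples.drop_duplicates("subject_id")
                   .set_index("subject_id")["cohort"])
        labels = (cohorts.reindex(values.index) == "mecfs").to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown topology mode {mode!r}")
    mapping = match_hmdb(annot, graphs, restrict_to=values.columns)
    return topology_report(graphs, mapping, values, labels,
                           n_perm=config.n_perm, rng=rng,
                           q_threshold=config.topology_q)
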