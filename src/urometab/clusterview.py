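"""Hierarchical clustering of subjects and assembly of report tables.

Clustering is agglomerative with Euclidean distances and Ward.D2 linkage
(the Lance-Williams update on squared distances), as implemented by scipy's
``linkage(..., method="ward")``.  Merge heights are monotone non-decreasing
for this combination, and the merge sequence is deterministic given the
input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import iolayer

logger = logging.getLogger("urometab")


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray      # scipy (n-1) x 4 merge table
    merge_table: pd.DataFrame       # node_a, node_b, height, new_id
    labels: pd.Series               # subject -> cluster id at the requested cut
    order: list                     # subjects in dendrogram leaf order


def cluster_subjects(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Ward.D2/Euclidean agglomerative clustering of the rows.

    ``matrix`` is subjects x selected metabolites with no missing cells;
    ``k`` is the number of clusters to cut the dendrogram into.
    """
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} subjects into {k} clusters")
    if matrix.isna().any().any():
        raise ValueError("clustering input contains missing cells")
    X = matrix.to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    if np.any(np.diff(Z[:, 2]) < -1e-9):
        logger.warning("non-monotone merge heights in Ward clustering")
    merge = pd.DataFrame({
        "node_a": Z[:, 0].astype(int),
        "node_b": Z[:, 1].astype(int),
        "height": Z[:, 2],
        "new_id": np.arange(n, n + Z.shape[0]),
    })
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=matrix.index, name="cluster")
    from scipy.cluster.hierarchy import leaves_list
    order = [matrix.index[i] for i in leaves_list(Z)]
    return ClusterResult(Z, merge, labels, order)


def select_post_exercise_matrix(results: pd.DataFrame, centered: pd.DataFrame,
                                samples: pd.DataFrame, q_threshold: float = 0.1,
                                contrast: str = "case_vs_ctrl@post",
                                timepoint: str = "U3") -> pd.DataFrame:
    """Subjects x metabolites matrix backing the post-exercise heatmap.

    Rows are subjects' post-exercise samples; columns are the metabolites
    significant at q < threshold in the case-vs-control post contrast; values
    are normalized (median-centered) concentrations.
    """
    sub = results[(results["contrast"] == contrast)
                  & (results["q"] < q_threshold)]
    mets = sub["metabolite_id"].tolist()
    meta = samples.set_index("sample_id")
    post_ids = [s for s in centered.index
                if meta.loc[s, "timepoint"] == timepoint]
    mat = centered.loc[post_ids, mets]
    mat.index = meta.loc[post_ids, "subject_id"].to_numpy()
    mat.index.name = "subject_id"
    return mat


REPORT_TABLES = ("volcano", "enrichment_bubble", "topology_bubble",
                 "post_exercise_matrix", "cluster_merges",
                 "subject_trajectories", "correlation_census",
                 "screen_heatmap", "correlation_records")


def trajectory_table(values: pd.DataFrame, samples: pd.DataFrame,
                     metabolites) -> pd.DataFrame:
    """Per-subject per-timepoint values for selected metabolites (the
    spaghetti-plot input)."""
    meta = samples.set_index("sample_id").loc[values.index]
    long = (values[list(metabolites)]
            .assign(subject_id=meta["subject_id"].to_numpy(),
                    cohort=meta["cohort"].to_numpy(),
                    timepoint=meta["timepoint"].to_numpy())
            .melt(id_vars=["subject_id", "cohort", "timepoint"],
                  var_name="metabolite_id", value_name="value"))
    return long.sort_values(["metabolite_id", "subject_id",
                             "timepoint"]).reset_index(drop=True)


def report_bundle(stages: dict, outdir: str | Path) -> dict[str, Path]:
    """Write the plot-ready report tables plus a JSON run summary.

    ``stages`` must contain every key in :data:`REPORT_TABLES` (DataFrames)
    plus ``"summary"`` (dict).  A missing stage raises a named error.  No
    statistic is recomputed here: every table is written as handed in.
    """
    missing = [k for k in REPORT_TABLES if k not in stages]
    if missing:
        raise KeyError(f"report_bundle missing stage outputs: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in REPORT_TABLES:
        path = outdir / f"{name}.tsv"
        table = stages[name]
        index = table.index.name is not None
        table.to_csv(path, sep="\t", index=index, na_rep="")
        paths[name] = path
    summary_path = outdir / "run_summary.json"
    iolayer.write_run_summary(stages.get("summary", {}), summary_path)
    paths["summary"] = summary_path
    logger.info("report: wrote %d tables to %s", len(REPORT_TABLES), outdir)
    return paths
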