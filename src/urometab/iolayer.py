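"""Tabular I/O, study-design validation, and run configuration.

All matrices move through the pipeline as wide pandas DataFrames indexed by
``sample_id`` with one column per ``metabolite_id``.  Missing cells are a
first-class state (``NaN``), distinct from a measured value of 0: drug and
tobacco compounds are legitimately imputed as 0 downstream, so zeros must
survive every stage.

Accepted on input are both wide matrices (first column = sample ids, header =
metabolite ids) and three-column long tables (``sample_id``, ``metabolite_id``,
``value``); wide is canonical on output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("urometab")

COHORTS = ("control", "mecfs")
FLUIDS = ("urine", "plasma")
URINE_TIMEPOINTS = ("U1", "U3")
PLASMA_TIMEPOINTS = ("P1", "P2", "P3", "P4")

SAMPLE_COLUMNS = ["sample_id", "subject_id", "cohort", "fluid", "timepoint",
                  "age", "bmi", "osmolality"]
ANNOTATION_COLUMNS = ["metabolite_id", "name", "superpathway", "subpathway",
                      "is_drug_or_tobacco", "status", "hmdb_id", "cluster_id"]
STATUSES = ("known", "partially_characterized", "unknown")


class DesignError(ValueError):
    """Raised when an input table violates a study-design invariant."""


@dataclass
class RunConfig:
    """Significance thresholds and numeric switches for a full run.

    Defaults are the thresholds used throughout the analysis: per-metabolite
    mixed-model significance at q < 0.1, subpathway enrichment at q < 0.05,
    chemical-cluster enrichment at q < 0.15, pathway topology at q < 0.2,
    urine-plasma correlations at q < 0.15, and member-level significance for
    altered ratios at p < 0.05.
    """

    lmm_q: float = 0.1
    subpathway_q: float = 0.05
    cluster_q: float = 0.15
    topology_q: float = 0.2
    corr_q: float = 0.15
    member_p: float = 0.05
    detection_fraction: float = 0.8
    strong_r: float = 0.7
    outlier_z: float = 6.0
    transform: str = "glog"          # "glog" or "log10"
    ks_alternative: str = "greater"  # one-sided toward enrichment; or "two-sided"
    df_method: str = "satterthwaite"  # or "residual"
    corr_family: str = "per_pairing"  # BH family; or "global"
    screen_weak_abs: bool = True      # screen rule (2) "R < 0.3" read as |R| < 0.3
    n_perm: int = 9999
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lmm_q", "subpathway_q", "cluster_q", "topology_q",
                     "corr_q", "member_p", "detection_fraction", "strong_r"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.outlier_z <= 0:
            raise ValueError(f"outlier_z must be positive, got {self.outlier_z!r}")
        if self.transform not in ("glog", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError(f"unknown df_method {self.df_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "," if path.suffix.lower() == ".csv" else "\t"


def _validate_abundance(df: pd.DataFrame) -> pd.DataFrame:
    dup_samples = df.index[df.index.duplicated()].unique()
    if len(dup_samples):
        raise DesignError(f"duplicate sample rows: {list(map(str, dup_samples))}")
    dup_mets = df.columns[df.columns.duplicated()].unique()
    if len(dup_mets):
        raise DesignError(f"duplicate metabolite columns: {list(map(str, dup_mets))}")
    values = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isfinite(values) & ~np.isnan(values)
        neg = values < 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise DesignError(f"non-finite value at ({df.index[r]}, {df.columns[c]})")
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise DesignError(
            f"negative value {values[r, c]} at ({df.index[r]}, {df.columns[c]})")
    df = df.astype(float)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    df.columns.name = "metabolite_id"
    return df


def read_abundance(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a raw peak-area matrix, returning the canonical wide DataFrame.

    Long format is autodetected by its three-column header
    (``sample_id``, ``metabolite_id``, ``value``).  Empty cells and "NA"
    parse as missing.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    head = pd.read_csv(path, sep=sep, nrows=0)
    if list(head.columns[:3]) == ["sample_id", "metabolite_id", "value"]:
        long = pd.read_csv(path, sep=sep, na_values=["NA", ""],
                           float_precision="round_trip",
                           dtype={"sample_id": str, "metabolite_id": str})
        dup = long.duplicated(subset=["sample_id", "metabolite_id"])
        if dup.any():
            row = long.loc[dup.idxmax()]
            raise DesignError(
                f"duplicate cell ({row['sample_id']}, {row['metabolite_id']})")
        wide = long.pivot(index="sample_id", columns="metabolite_id", values="value")
        # preserve file order of first appearance
        wide = wide.reindex(index=long["sample_id"].unique(),
                            columns=long["metabolite_id"].unique())
        return _validate_abundance(wide)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""],
                     float_precision="round_trip")
    return _validate_abundance(df)


def write_abundance(table: pd.DataFrame, path: str | Path,
                    dialect: str | None = None) -> None:
    """Write a wide abundance matrix; missing cells serialize as empty."""
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path, dialect), na_rep="")


# ---------------------------------------------------------------------------
# sample metadata and annotation
# ---------------------------------------------------------------------------

def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate sample metadata against the study-design invariants."""
    missing = set(SAMPLE_COLUMNS[:-1]) - set(samples.columns)
    if missing:
        raise DesignError(f"sample table lacks columns: {sorted(missing)}")
    samples = samples.copy()
    if "osmolality" not in samples.columns:
        samples["osmolality"] = np.nan
    for col in ("sample_id", "subject_id", "cohort", "fluid", "timepoint"):
        samples[col] = samples[col].astype(str)
    dup = samples["sample_id"].duplicated()
    if dup.any():
        raise DesignError(f"duplicate sample_id {samples.loc[dup.idxmax(), 'sample_id']}")
    bad_cohort = ~samples["cohort"].isin(COHORTS)
    if bad_cohort.any():
        raise DesignError(f"unknown cohort {samples.loc[bad_cohort.idxmax(), 'cohort']!r}")
    bad_fluid = ~samples["fluid"].isin(FLUIDS)
    if bad_fluid.any():
        raise DesignError(f"unknown fluid {samples.loc[bad_fluid.idxmax(), 'fluid']!r}")
    for fluid, tps in (("urine", URINE_TIMEPOINTS), ("plasma", PLASMA_TIMEPOINTS)):
        sub = samples[samples["fluid"] == fluid]
        bad = ~sub["timepoint"].isin(tps)
        if bad.any():
            raise DesignError(
                f"{fluid} timepoint must be one of {tps}, "
                f"got {sub.loc[bad.idxmax(), 'timepoint']!r}")
    dup = samples.duplicated(subset=["subject_id", "fluid", "timepoint"])
    if dup.any():
        row = samples.loc[dup.idxmax()]
        raise DesignError(
            f"subject {row['subject_id']} has duplicate {row['fluid']} "
            f"sample at {row['timepoint']}")
    urine = samples[samples["fluid"] == "urine"]
    bad_osm = ~(urine["osmolality"] > 0)
    if bad_osm.any():
        raise DesignError(
            f"urine sample {urine.loc[bad_osm.idxmax(), 'sample_id']} lacks a "
            "positive osmolality")
    for col in ("age", "bmi"):
        per_subject = samples.groupby("subject_id")[col].nunique()
        varying = per_subject[per_subject > 1]
        if len(varying):
            raise DesignError(f"{col} varies within subject {varying.index[0]}")
        multi_cohort = samples.groupby("subject_id")["cohort"].nunique()
        if (multi_cohort > 1).any():
            raise DesignError(
                f"subject {multi_cohort[multi_cohort > 1].index[0]} appears in "
                "both cohorts")
    return samples


def read_samples(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), na_values=["NA", ""],
                     float_precision="round_trip")
    return validate_samples(df)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep=_sep_for(Path(path), None), index=False, na_rep="")


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS[:6]) - set(annot.columns)
    if missing:
        raise DesignError(f"annotation lacks columns: {sorted(missing)}")
    annot = annot.copy()
    for col in ("hmdb_id", "cluster_id"):
        if col not in annot.columns:
            annot[col] = None
    dup = annot["metabolite_id"].duplicated()
    if dup.any():
        raise DesignError(
            f"duplicate metabolite_id {annot.loc[dup.idxmax(), 'metabolite_id']}")
    bad = ~annot["status"].isin(STATUSES)
    if bad.any():
        raise DesignError(f"unknown status {annot.loc[bad.idxmax(), 'status']!r}")
    known = annot[annot["status"] != "unknown"]
    no_sub = known["subpathway"].isna()
    if no_sub.any():
        raise DesignError(
            f"characterized metabolite {known.loc[no_sub.idxmax(), 'metabolite_id']} "
            "lacks a subpathway")
    annot["is_drug_or_tobacco"] = annot["is_drug_or_tobacco"].astype(bool)
    return annot.set_index("metabolite_id", drop=False)


def read_annotation(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path), dialect),
                     na_values=["NA", ""])
    return validate_annotation(df)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep=_sep_for(Path(path), None), index=False, na_rep="")


# ---------------------------------------------------------------------------
# design summary
# ---------------------------------------------------------------------------

@dataclass
class DesignSummary:
    subjects_per_cohort: dict = field(default_factory=dict)
    counts: pd.DataFrame | None = None     # cohort x fluid x timepoint sample counts
    incomplete: dict = field(default_factory=dict)  # fluid -> {subject: missing tps}
    warnings: list = field(default_factory=list)


def validate_design(samples: pd.DataFrame) -> DesignSummary:
    """Summarize subjects per cohort x fluid x timepoint and flag gaps.

    Subjects missing a timepoint are reported; paired analyses downstream use
    complete pairs only.  A cohort with fewer than 3 subjects triggers a
    warning because a correlation at n < 3 has no residual degrees of freedom.
    """
    samples = validate_samples(samples)
    summary = DesignSummary()
    summary.subjects_per_cohort = (
        samples.groupby("cohort")["subject_id"].nunique().to_dict())
    summary.counts = (samples.groupby(["cohort", "fluid", "timepoint"])
                      ["sample_id"].count().rename("n_samples").reset_index())
    for fluid, tps in (("urine", URINE_TIMEPOINTS), ("plasma", PLASMA_TIMEPOINTS)):
        sub = samples[samples["fluid"] == fluid]
        gaps = {}
        for subject, grp in sub.groupby("subject_id"):
            missing_tps = sorted(set(tps) - set(grp["timepoint"]))
            if missing_tps:
                gaps[subject] = missing_tps
        if gaps:
            summary.incomplete[fluid] = gaps
        if len(sub) and sub["subject_id"].nunique() == 0:
            pass
        if fluid == "urine" and len(sub) == 0 and len(samples):
            msg = "no urine samples in metadata"
            summary.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    for cohort, n in summary.subjects_per_cohort.items():
        if n < 3:
            msg = (f"cohort {cohort!r} has only {n} subject(s); "
                   "correlation analyses need n >= 3")
            summary.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
    logger.info("design: %s", summary.subjects_per_cohort)
    return summary


# ---------------------------------------------------------------------------
# pathway graphs
# ---------------------------------------------------------------------------

def read_pathway_graphs(path: str | Path,
                        nodes_path: str | Path | None = None) -> dict[str, nx.Graph]:
    """Read undirected pathway graphs from a 3-column edge list.

    Columns: pathway_id, node_a, node_b (node ids in the HMDB namespace).
    An optional node list file (pathway_id, node) adds isolated nodes.
    Self-loops are rejected.
    """
    edges = pd.read_csv(Path(path), sep=_sep_for(Path(path), None),
                        dtype=str, header=0)
    if edges.shape[1] < 3:
        raise DesignError("pathway edge list needs 3 columns "
                          "(pathway_id, node_a, node_b)")
    edges.columns = ["pathway_id", "node_a", "node_b"] + list(edges.columns[3:])
    graphs: dict[str, nx.Graph] = {}
    for pid, grp in edges.groupby("pathway_id", sort=False):
        g = nx.Graph(name=str(pid))
        for a, b in zip(grp["node_a"], grp["node_b"]):
            if a == b:
                raise DesignError(f"self-loop on node {a} in pathway {pid}")
            g.add_edge(a, b)
        graphs[str(pid)] = g
    if nodes_path is not None:
        nodes = pd.read_csv(Path(nodes_path), sep=_sep_for(Path(nodes_path), None),
                            dtype=str, header=0)
        nodes.columns = ["pathway_id", "node"] + list(nodes.columns[2:])
        for pid, grp in nodes.groupby("pathway_id", sort=False):
            graphs.setdefault(str(pid), nx.Graph(name=str(pid)))
            graphs[str(pid)].add_nodes_from(grp["node"])
    return graphs


def write_pathway_graphs(graphs: dict[str, nx.Graph], path: str | Path) -> None:
    rows = [(pid, a, b) for pid, g in graphs.items() for a, b in g.edges()]
    pd.DataFrame(rows, columns=["pathway_id", "node_a", "node_b"]).to_csv(
        Path(path), sep=_sep_for(Path(path), None), index=False)


def write_run_summary(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
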