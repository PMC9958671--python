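"""Raw abundances to the analysis-ready matrix.

Fixed stage order: osmolality normalization -> imputation -> median centering
-> variance-stabilizing log10 transform -> detection filtering.  The
pre-imputation detection mask is carried alongside the values so that the
modified 80% rule always reflects what the assay actually detected, no matter
where in the chain it is applied.

The variance-stabilizing transform is the generalized log,

    glog10(x) = log10((x + sqrt(x^2 + lambda^2)) / 2),

with lambda set to one tenth of the smallest positive value in the matrix.
It is strictly increasing, approaches log10(x) for x >> lambda, and stays
finite at x = 0, which matters because drug and tobacco compounds are imputed
as 0.  A strict log10 is available via ``RunConfig.transform = "log10"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iolayer import DesignError, RunConfig

logger = logging.getLogger("urometab")

LOG2_FROM_LOG10 = 1.0 / np.log10(2.0)


@dataclass
class ProcessedTable:
    """Transformed values plus per-cell imputation flags and detection mask."""

    values: pd.DataFrame            # samples x metabolites, log10 scale
    centered: pd.DataFrame          # median-centered, pre-transform scale
    detected: pd.DataFrame          # bool, pre-imputation presence
    imputed: pd.DataFrame           # bool, cell was filled in
    lam: float                      # glog offset (0 for strict log10)
    retained: pd.Index              # metabolites passing the detection filter
    dropped: dict = field(default_factory=dict)  # metabolite -> reason

    @property
    def filtered_values(self) -> pd.DataFrame:
        return self.values[self.retained]


def normalize_osmolality(raw: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Divide each urine sample's values by its osmolality.

    Plasma rows pass through unchanged; missing cells stay missing.
    """
    meta = samples.set_index("sample_id")
    missing = raw.index.difference(meta.index)
    if len(missing):
        raise DesignError(f"samples absent from metadata: {list(missing[:5])}")
    out = raw.copy()
    urine_ids = [s for s in raw.index if meta.loc[s, "fluid"] == "urine"]
    if urine_ids:
        osm = meta.loc[urine_ids, "osmolality"].astype(float)
        if not (osm > 0).all():
            bad = osm.index[~(osm > 0)][0]
            raise DesignError(f"urine sample {bad} lacks a positive osmolality")
        out.loc[urine_ids] = raw.loc[urine_ids].div(osm, axis=0)
    return out


def impute(norm: pd.DataFrame, annot: pd.DataFrame
           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fill missing cells: per-metabolite minimum, or 0 for drugs/tobacco.

    Returns (imputed table, boolean imputation flags, dropped metabolites).
    An all-missing non-drug metabolite has no minimum and is dropped.
    """
    flags = norm.isna()
    out = norm.copy()
    dropped: dict[str, str] = {}
    is_drug = annot["is_drug_or_tobacco"].reindex(norm.columns).fillna(False)
    drug_cols = norm.columns[is_drug.to_numpy(dtype=bool)]
    out[drug_cols] = out[drug_cols].fillna(0.0)
    other = norm.columns.difference(drug_cols, sort=False)
    mins = norm[other].min(axis=0)
    all_missing = mins.index[mins.isna()]
    for met in all_missing:
        dropped[str(met)] = "all values missing"
    keep = other.difference(all_missing, sort=False)
    out[keep] = out[keep].fillna(mins[keep])
    out = out.drop(columns=all_missing)
    flags = flags.drop(columns=all_missing)
    if dropped:
        logger.info("impute: dropped %d all-missing metabolites", len(dropped))
    logger.info("impute: filled %d cells (%d as 0 for drug/tobacco)",
                int(flags.to_numpy().sum()),
                int(flags[drug_cols].to_numpy().sum()))
    return out, flags, dropped


def median_center(imputed: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Scale each metabolite so its median across samples equals 1.

    A metabolite whose median is 0 (possible for drug compounds imputed as 0)
    is scaled by its smallest positive value instead; with no positive value
    at all it is dropped.
    """
    if imputed.isna().any().any():
        raise DesignError("median_center requires a fully imputed table")
    med = imputed.median(axis=0)
    scale = med.copy()
    dropped: dict[str, str] = {}
    degenerate = scale.index[scale <= 0]
    for met in degenerate:
        col = imputed[met]
        positive = col[col > 0]
        if len(positive):
            scale[met] = positive.min()
            logger.info("median_center: %s has median 0; scaled by smallest "
                        "positive value %g", met, scale[met])
        else:
            dropped[str(met)] = "no positive value"
    out = imputed.drop(columns=list(dropped)).div(scale.drop(list(dropped)), axis=1)
    if dropped:
        logger.info("median_center: dropped %d metabolites with no positive "
                    "value", len(dropped))
    return out, dropped


def glog10(x, lam: float):
    """Generalized log10: finite at 0, ~log10(x) for x >> lam."""
    x = np.asarray(x, dtype=float)
    return np.log10((x + np.sqrt(x * x + lam * lam)) / 2.0)


def vst_log10(centered: pd.DataFrame, transform: str = "glog",
              lam: float | None = None) -> tuple[pd.DataFrame, float]:
    """Variance-stabilizing log10 transform of the centered matrix.

    With ``transform="glog"`` the offset lambda defaults to (smallest positive
    value in the matrix) / 10.  ``transform="log10"`` applies a strict log10
    and requires strictly positive values.
    """
    arr = centered.to_numpy(dtype=float)
    if (arr < 0).any():
        raise DesignError("vst_log10 requires non-negative values")
    if transform == "log10":
        if (arr <= 0).any():
            raise DesignError("strict log10 requires strictly positive values")
        return pd.DataFrame(np.log10(arr), index=centered.index,
                            columns=centered.columns), 0.0
    if lam is None:
        positive = arr[arr > 0]
        if positive.size == 0:
            raise DesignError("matrix has no positive values")
        lam = float(positive.min()) / 10.0
    out = pd.DataFrame(glog10(arr, lam), index=centered.index,
                       columns=centered.columns)
    return out, float(lam)


def filter_80pct(detected: pd.DataFrame, samples: pd.DataFrame,
                 threshold: float = 0.8) -> tuple[pd.Index, pd.DataFrame]:
    """Modified 80% rule: keep metabolites detected in >= threshold of the
    samples of at least one cohort (both timepoints pooled per cohort).

    Returns (retained metabolite index, per-cohort detection report).
    """
    meta = samples.set_index("sample_id")
    cohorts = meta.loc[detected.index, "cohort"]
    frac = detected.groupby(cohorts.to_numpy()).mean()  # cohort x metabolite
    keep = (frac >= threshold).any(axis=0)
    report = frac.T
    report.columns = [f"detected_frac_{c}" for c in report.columns]
    report["retained"] = keep
    report.index.name = "metabolite_id"
    logger.info("filter_80pct: retained %d / %d metabolites at >= %.0f%%",
                int(keep.sum()), len(keep), 100 * threshold)
    return detected.columns[keep], report


def make_ratios(values: pd.DataFrame, samples: pd.DataFrame,
                post_tp: str, base_tp: str) -> pd.DataFrame:
    """Per-subject log10 post/baseline ratios: value(post) - value(base).

    Subjects lacking either timepoint are omitted (logged).  Applies
    identically to urine (U3 vs U1) and plasma (e.g. P4 vs P1).
    """
    meta = samples.set_index("sample_id").loc[values.index]
    post_subj = meta.loc[meta["timepoint"] == post_tp, "subject_id"]
    base_subj = meta.loc[meta["timepoint"] == base_tp, "subject_id"]
    common = [s for s in post_subj if s in set(base_subj)]
    skipped = set(post_subj).symmetric_difference(base_subj)
    if skipped:
        logger.info("make_ratios %s/%s: omitted incomplete subjects %s",
                    post_tp, base_tp, sorted(skipped))
    post_vals = (values.loc[post_subj.index]
                 .set_axis(post_subj.to_numpy(), axis=0).loc[common])
    base_vals = (values.loc[base_subj.index]
                 .set_axis(base_subj.to_numpy(), axis=0).loc[common])
    out = post_vals - base_vals
    out.index.name = "subject_id"
    return out


def log2_from_log10(value):
    """Change of base: log2 fc = log10 fc / log10(2)."""
    return np.asarray(value, dtype=float) * LOG2_FROM_LOG10


def preprocess(raw: pd.DataFrame, samples: pd.DataFrame, annot: pd.DataFrame,
               config: RunConfig | None = None) -> ProcessedTable:
    """Run the full prep chain on one fluid's raw matrix."""
    config = config or RunConfig()
    detected = raw.notna()
    norm = normalize_osmolality(raw, samples)
    imputed_table, imputed_flags, dropped = impute(norm, annot)
    centered, dropped_center = median_center(imputed_table)
    dropped.update(dropped_center)
    values, lam = vst_log10(centered, transform=config.transform)
    detected = detected[values.columns]
    retained, _report = filter_80pct(detected, samples,
                                     config.detection_fraction)
    return ProcessedTable(values=values, centered=centered, detected=detected,
                          imputed=imputed_flags[values.columns], lam=lam,
                          retained=retained, dropped=dropped)
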