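"""Urine-plasma correlation analysis and the differential-correlation screen.

Per shared metabolite, per cohort, Pearson correlations are computed across
subjects at seven pairings: same-day timepoints (U1~P1, U1~P2, U3~P3, U3~P4)
and post-exercise recovery ratios (U3/U1 against P4/P1, P3/P2 and P3/P1).
This analysis deliberately uses ALL shared metabolites — the detection filter
is not applied here.

p-values come from the t-test of R = 0 (t = R sqrt((n-2)/(1-R^2)), df = n-2)
with BH adjustment within each cohort x pairing family.  The census counts
strong correlations (|R| > 0.7) per cohort and pairing.

Outlier handling mirrors compound-level removal: the modified z-score
z = 0.6745 (x - median)/MAD is computed per metabolite on each variable
vector (cohorts pooled, urine and plasma separately); a compound with an
outlier (|z| > 6) in timepoint data is excluded from all timepoint pairings
only, and one with an outlier in ratio data from all ratio pairings only.

The three-criteria screen flags compounds whose urine-plasma relationship
differs between cohorts: (1) |R| > 0.7 with p < 0.05 and q < 0.15 in one
cohort; (2) in the other cohort, |R| < 0.3 or an R of opposite sign;
(3) outlier-carrying compounds removed as above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iolayer import RunConfig
from .mixedfx import bh_adjust
from .prep import make_ratios

logger = logging.getLogger("urometab")

MODIFIED_Z_SCALE = 0.6745


@dataclass(frozen=True)
class PairingSpec:
    pairing_id: str
    urine_var: str     # "U1", "U3" or "U3/U1"
    plasma_var: str    # "P1".."P4" or e.g. "P4/P1"
    kind: str          # "timepoint" or "ratio"


DEFAULT_PAIRINGS = (
    PairingSpec("U1~P1", "U1", "P1", "timepoint"),
    PairingSpec("U1~P2", "U1", "P2", "timepoint"),
    PairingSpec("U3~P3", "U3", "P3", "timepoint"),
    PairingSpec("U3~P4", "U3", "P4", "timepoint"),
    PairingSpec("U3/U1~P4/P1", "U3/U1", "P4/P1", "ratio"),
    PairingSpec("U3/U1~P3/P2", "U3/U1", "P3/P2", "ratio"),
    PairingSpec("U3/U1~P3/P1", "U3/U1", "P3/P1", "ratio"),
)


def shared_metabolites(urine_cols, plasma_cols) -> pd.Index:
    """Metabolites measured in both fluids, in urine panel order."""
    plasma_set = set(plasma_cols)
    shared = pd.Index([m for m in urine_cols if m in plasma_set])
    if len(shared) == 0:
        raise ValueError("no metabolites shared between the urine and plasma "
                         "panels")
    return shared


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson R and its two-sided p from the t-test of R = 0.

    t = R sqrt((n-2)/(1-R^2)) on n-2 df; R = +/-1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    n = len(x)
    if n < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:  # exact linear relation up to rounding
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def detect_outliers(values, z_threshold: float = 6.0
                    ) -> tuple[np.ndarray, bool]:
    """Modified z-score outlier mask: z = 0.6745 (x - median)/MAD, |z| > 6.

    Returns (mask, mad_is_zero).  A zero MAD makes no outlier callable; the
    flag reports that degenerate state.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("outlier detection needs n >= 3")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(len(x), dtype=bool), True
    z = MODIFIED_Z_SCALE * (x - med) / mad
    return np.abs(z) > z_threshold, False


def _subject_variables(proc_values: pd.DataFrame, samples: pd.DataFrame,
                       fluid: str) -> dict[str, pd.DataFrame]:
    """Per-subject wide tables for every timepoint and ratio variable."""
    meta = samples.set_index("sample_id")
    present = proc_values.index
    meta = meta.loc[present]
    out: dict[str, pd.DataFrame] = {}
    tps = ("U1", "U3") if fluid == "urine" else ("P1", "P2", "P3", "P4")
    for tp in tps:
        ids = meta.index[(meta["fluid"] == fluid) & (meta["timepoint"] == tp)]
        tab = proc_values.loc[ids]
        tab.index = meta.loc[ids, "subject_id"].to_numpy()
        out[tp] = tab
    ratio_specs = (("U3/U1", "U3", "U1") if fluid == "urine"
                   else (("P4/P1", "P4", "P1"), ("P3/P2", "P3", "P2"),
                         ("P3/P1", "P3", "P1")))
    if fluid == "urine":
        out["U3/U1"] = make_ratios(proc_values, samples, "U3", "U1")
    else:
        for rid, post, base in ratio_specs:
            out[rid] = make_ratios(proc_values, samples, post, base)
    return out


def _outlier_removal(variables: dict[str, pd.DataFrame],
                     shared: pd.Index, z_threshold: float
                     ) -> dict[str, set]:
    """Compounds to drop per variable kind ('timepoint' / 'ratio')."""
    timepoint_vars = [v for v in variables if "/" not in v]
    ratio_vars = [v for v in variables if "/" in v]
    removed = {"timepoint": set(), "ratio": set()}
    for kind, var_names in (("timepoint", timepoint_vars), ("ratio", ratio_vars)):
        for var in var_names:
            tab = variables[var]
            for met in shared:
                col = tab[met].dropna().to_numpy()
                if len(col) < 3:
                    continue
                mask, _ = detect_outliers(col, z_threshold)
                if mask.any():
                    removed[kind].add(met)
    return removed


def correlation_census(urine_values: pd.DataFrame, plasma_values: pd.DataFrame,
                       samples: pd.DataFrame,
                       config: RunConfig | None = None,
                       pairings: tuple[PairingSpec, ...] = DEFAULT_PAIRINGS
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All urine-plasma correlations plus the strong-correlation census.

    Returns (records, census).  Records: one row per metabolite x cohort x
    pairing with n, R, p, q and the outlier-removal flag.  Census: counts of
    R > 0.7 and R < -0.7 per cohort x pairing.
    """
    config = config or RunConfig()
    shared = shared_metabolites(urine_values.columns, plasma_values.columns)
    u_vars = _subject_variables(urine_values[shared], samples, "urine")
    p_vars = _subject_variables(plasma_values[shared], samples, "plasma")
    variables = {**u_vars, **p_vars}
    removed = _outlier_removal(variables, shared, config.outlier_z)
    logger.info("fluidcorr: %d shared metabolites; outlier-removed %d "
                "(timepoint) / %d (ratio)", len(shared),
                len(removed["timepoint"]), len(removed["ratio"]))

    cohorts = (samples.drop_duplicates("subject_id")
               .set_index("subject_id")["cohort"])
    rows = []
    for spec in pairings:
        u_tab = variables[spec.urine_var]
        p_tab = variables[spec.plasma_var]
        common_subjects = u_tab.index.intersection(p_tab.index)
        coh = cohorts.reindex(common_subjects)
        for cohort in ("control", "mecfs"):
            subj = common_subjects[(coh == cohort).to_numpy()]
            for met in shared:
                if met in removed[spec.kind]:
                    continue
                x = u_tab.loc[subj, met].to_numpy(dtype=float)
                y = p_tab.loc[subj, met].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                n = int(ok.sum())
                if n < 3:
                    continue
                try:
                    r, p = pearson_r(x[ok], y[ok])
                except ValueError:
                    continue  # zero variance: record skipped
                rows.append((met, cohort, spec.pairing_id, spec.kind, n, r, p))
    records = pd.DataFrame(rows, columns=["metabolite_id", "cohort",
                                          "pairing_id", "kind", "n", "R", "p"])
    records["q"] = np.nan
    if config.corr_family == "global":
        records["q"] = bh_adjust(records["p"].to_numpy())
    else:
        for (_, _), idx in records.groupby(["cohort", "pairing_id"]).groups.items():
            records.loc[idx, "q"] = bh_adjust(records.loc[idx, "p"].to_numpy())

    census_rows = []
    for (cohort, pairing), grp in records.groupby(["cohort", "pairing_id"]):
        census_rows.append((cohort, pairing, grp["kind"].iloc[0],
                            int((grp["R"] > config.strong_r).sum()),
                            int((grp["R"] < -config.strong_r).sum()),
                            len(grp)))
    census = pd.DataFrame(census_rows, columns=["cohort", "pairing_id", "kind",
                                                "n_strong_positive",
                                                "n_strong_negative", "n_tested"])
    return records, census


def differential_screen(records: pd.DataFrame,
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Three-criteria differential-correlation screen.

    A (metabolite, pairing) is a hit when one cohort shows |R| > 0.7 with
    p < 0.05 and q < 0.15, while the other cohort shows |R| < 0.3 or an R of
    opposite sign.  (Outlier-carrying compounds never reach this point; they
    were removed from the corresponding pairings upstream.)
    """
    config = config or RunConfig()
    wide = records.pivot_table(index=["metabolite_id", "pairing_id"],
                               columns="cohort", values=["R", "p", "q", "n"],
                               aggfunc="first")
    rows = []
    for (met, pairing), row in wide.iterrows():
        for sig, other in (("mecfs", "control"), ("control", "mecfs")):
            r_sig = row.get(("R", sig), np.nan)
            r_oth = row.get(("R", other), np.nan)
            if not (np.isfinite(r_sig) and np.isfinite(r_oth)):
                continue
            crit1 = (abs(r_sig) > config.strong_r
                     and row.get(("p", sig), 1.0) < 0.05
                     and row.get(("q", sig), 1.0) < config.corr_q)
            if not crit1:
                continue
            weak = (abs(r_oth) < 0.3 if config.screen_weak_abs
                    else r_oth < 0.3)
            opposite = np.sign(r_oth) == -np.sign(r_sig)
            if weak or opposite:
                rows.append((met, pairing,
                             row.get(("R", "mecfs"), np.nan),
                             row.get(("R", "control"), np.nan), sig))
                break  # one hit per (metabolite, pairing)
    hits = pd.DataFrame(rows, columns=["metabolite_id", "pairing_id",
                                       "R_case", "R_control",
                                       "significant_cohort"])
    logger.info("screen: %d differential-correlation hits", len(hits))
    return hits


def screen_heatmap_table(records: pd.DataFrame, hits: pd.DataFrame
                         ) -> pd.DataFrame:
    """Heatmap-ready long table of R for both cohorts; cells that are not
    part of a qualifying (metabolite, pairing) are masked with NaN."""
    key = set(zip(hits["metabolite_id"], hits["pairing_id"]))
    mets = hits["metabolite_id"].unique()
    sub = records[records["metabolite_id"].isin(mets)].copy()
    qualifies = [(m, p) in key for m, p in zip(sub["metabolite_id"],
                                               sub["pairing_id"])]
    sub["R_masked"] = np.where(qualifies, sub["R"], np.nan)
    return sub[["metabolite_id", "pairing_id", "kind", "cohort", "R",
                "R_masked"]]
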