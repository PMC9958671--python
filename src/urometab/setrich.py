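"""Non-overlapping-set enrichment over subpathways or chemical clusters.

Each metabolite belongs to at most one set (subpathway assignments, or a
precomputed chemical-similarity cluster column).  Enrichment of a set is
assessed with a one-sample Kolmogorov-Smirnov test of the member p-values
against Uniform(0, 1), one-sided toward "stochastically smaller than uniform"
by default — the direction a genuinely enriched set pulls its members.  Set
q-values are BH-adjusted across sets.

Two descriptive ratios accompany each set: the altered ratio, the fraction of
measured members with member-level p below the threshold (0.05), and the
increased ratio, the fraction of those altered members whose fold change is
positive.  An altered ratio of 1 means every measured compound in the set
moved; an increased ratio of 1 means every one of them moved up.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .iolayer import DesignError, RunConfig
from .mixedfx import bh_adjust

logger = logging.getLogger("urometab")


def ks_enrich(member_p, alternative: str = "greater") -> float:
    """One-sample KS p-value of member p-values against Uniform(0, 1).

    ``alternative="greater"`` tests whether the empirical CDF lies above the
    uniform CDF, i.e. members are stochastically smaller than uniform (the
    enrichment direction); "two-sided" is available for symmetry checks.
    Requires at least 2 members.
    """
    member_p = np.asarray(member_p, dtype=float)
    if member_p.size < 2:
        raise ValueError("KS enrichment needs at least 2 member p-values")
    if (member_p < 0).any() or (member_p > 1).any():
        raise ValueError("member p-values must lie in [0, 1]")
    res = stats.ks_1samp(member_p, stats.uniform.cdf, alternative=alternative)
    return float(res.pvalue)


def ks_statistic(member_p, alternative: str = "greater") -> float:
    """The KS statistic itself (D+ for the one-sided enrichment test)."""
    member_p = np.asarray(member_p, dtype=float)
    return float(stats.ks_1samp(member_p, stats.uniform.cdf,
                                alternative=alternative).statistic)


def _set_order(sets: pd.Series, annot: pd.DataFrame | None) -> list:
    """Fixed reporting order: superpathways alphabetical, sets in annotation
    (chemical-similarity) order within each superpathway."""
    first_seen = {}
    for i, s in enumerate(sets):
        first_seen.setdefault(s, i)
    if annot is None or "superpathway" not in annot:
        return sorted(first_seen, key=first_seen.get)
    supers = {}
    for met, s in sets.items():
        if s not in supers and met in annot.index:
            sp = annot.loc[met, "superpathway"]
            supers[s] = sp if isinstance(sp, str) else ""
    return sorted(first_seen, key=lambda s: (supers.get(s, ""), first_seen[s]))


def enrich_all(results: pd.DataFrame, sets: pd.Series,
               annot: pd.DataFrame | None = None,
               member_p_threshold: float = 0.05,
               alternative: str = "greater") -> pd.DataFrame:
    """Enrichment records for every set of one contrast family.

    Parameters
    ----------
    results
        One contrast family's rows: columns ``metabolite_id``, ``p`` and
        ``fc_log10`` (fold change of mean normalized concentration, log10).
    sets
        metabolite_id -> set_id mapping (non-overlapping by construction; a
        duplicated metabolite is an error naming the offender).
    """
    if sets.index.duplicated().any():
        met = sets.index[sets.index.duplicated()][0]
        raise DesignError(f"metabolite {met} assigned to more than one set")
    sets = sets.dropna()
    sub = results[results["metabolite_id"].isin(sets.index)]
    member_p = sub.set_index("metabolite_id")["p"]
    member_fc = sub.set_index("metabolite_id")["fc_log10"]
    order = _set_order(sets, annot)

    rows, skipped = [], []
    for set_id in order:
        members = sets.index[sets == set_id]
        members = members[members.isin(member_p.index)]
        if len(members) < 2:
            skipped.append(set_id)
            continue
        p_vals = member_p.loc[members].to_numpy()
        fc = member_fc.loc[members].to_numpy()
        altered = p_vals < member_p_threshold
        n_altered = int(altered.sum())
        altered_ratio = n_altered / len(members)
        increased_ratio = (float(np.mean(fc[altered] > 0))
                           if n_altered else np.nan)
        superpathway = ""
        if annot is not None and members[0] in annot.index:
            sp = annot.loc[members[0], "superpathway"]
            superpathway = sp if isinstance(sp, str) else ""
        rows.append({
            "set_id": set_id,
            "superpathway": superpathway,
            "set_size": len(members),
            "ks_p": ks_enrich(p_vals, alternative=alternative),
            "n_altered": n_altered,
            "altered_ratio": altered_ratio,
            "increased_ratio": increased_ratio,
            "members": ";".join(map(str, members)),
        })
    if skipped:
        logger.info("enrich: skipped %d sets with < 2 measured members: %s",
                    len(skipped), skipped[:10])
    records = pd.DataFrame(rows)
    if len(records):
        records["q"] = bh_adjust(records["ks_p"].to_numpy())
    else:
        records["q"] = pd.Series(dtype=float)
    return records


def enrich_contrasts(results: pd.DataFrame, annot: pd.DataFrame,
                     mode: str = "subpathway",
                     config: RunConfig | None = None,
                     contrasts: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Run enrichment for each requested contrast family.

    ``mode="subpathway"`` uses the non-overlapping subpathway assignments of
    known/partially characterized metabolites; ``mode="cluster"`` uses the
    precomputed chemical-similarity ``cluster_id`` column.
    """
    config = config or RunConfig()
    if mode == "subpathway":
        known = annot[annot["status"] == "known"]
        sets = known["subpathway"].dropna()
    elif mode == "cluster":
        sets = annot["cluster_id"].dropna()
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    contrasts = contrasts or sorted(results["contrast"].unique())
    out = {}
    for name in contrasts:
        sub = results[results["contrast"] == name]
        out[name] = enrich_all(sub, sets, annot=annot,
                               member_p_threshold=config.member_p,
                               alternative=config.ks_alternative)
    return out


def bubble_table(records_by_comparison: dict[str, pd.DataFrame],
                 q_threshold: float) -> pd.DataFrame:
    """Long plot-ready table of sets below the q threshold, per comparison.

    Columns: comparison, set_id, superpathway, altered_ratio (bubble size),
    increased_ratio (bubble color), q.  Sets with no altered member never
    appear as bubbles.
    """
    rows = []
    for comparison, records in records_by_comparison.items():
        if records.empty:
            continue
        sig = records[(records["q"] < q_threshold) & (records["n_altered"] > 0)]
        for _, rec in sig.iterrows():
            rows.append((comparison, rec["set_id"], rec["superpathway"],
                         rec["set_size"], rec["altered_ratio"],
                         rec["increased_ratio"], rec["q"]))
    return pd.DataFrame(rows, columns=["comparison", "set_id", "superpathway",
                                       "set_size", "altered_ratio",
                                       "increased_ratio", "q"])
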