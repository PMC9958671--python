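"""Synthetic paired urine/plasma metabolomics studies with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two cohorts of female subjects (8 sedentary controls, 10 patients by
default), two urine timepoints (baseline U1 and 24 h post-exercise U3), four
plasma timepoints (P1-P4), ~1400 metabolites organized into non-overlapping
subpathways, subject random intercepts, age/BMI covariates, left-censored
missingness at a per-metabolite detection limit, per-sample urine osmolality,
and a group-by-time response in which designated "responder" subpathways
increase post-exercise in controls but not in patients.

The log10-scale latent value for a urine sample of subject j, metabolite m at
timepoint t is

    x = mu_m + u_j + s_jm + a_m * age_j + b_m * bmi_j + delta_m * case_j
        + (gamma_m + eta_m * case_j) * post_t + r_jm * post_t + eps

where u_j is the subject intercept (shared across metabolites and fluids),
s_jm a stable subject-by-metabolite deviate, and r_jm a subject-by-metabolite
exercise-response deviate.  The raw urine value is osmolality_s * 10^x; cells
with 10^x below the detection limit L_m are censored to missing.  Plasma
values share u_j directly and couple to the urine-specific deviates s_jm and
r_jm with per-metabolite correlation rho_m (post indicator: P3/P4), so that
both timepoint-level and ratio-level urine-plasma Pearson correlations are
tunable through rho.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import iolayer
from .iolayer import PLASMA_TIMEPOINTS, URINE_TIMEPOINTS

# Plausible Metabolon-style subpathway names used for the default layout.
_SUBPATHWAY_POOL = [
    ("Urea Cycle; Arginine and Proline Metabolism", "Amino Acid"),
    ("Methionine, Cysteine, SAM and Taurine Metabolism", "Amino Acid"),
    ("Polyamine Metabolism", "Amino Acid"),
    ("Leucine, Isoleucine and Valine Metabolism", "Amino Acid"),
    ("Tryptophan Metabolism", "Amino Acid"),
    ("Tyrosine Metabolism", "Amino Acid"),
    ("Histidine Metabolism", "Amino Acid"),
    ("Glycine, Serine and Threonine Metabolism", "Amino Acid"),
    ("Lysine Metabolism", "Amino Acid"),
    ("Alanine and Aspartate Metabolism", "Amino Acid"),
    ("Glutamate Metabolism", "Amino Acid"),
    ("Phenylalanine Metabolism", "Amino Acid"),
    ("Glutathione Metabolism", "Amino Acid"),
    ("Creatine Metabolism", "Amino Acid"),
    ("Glycolysis, Gluconeogenesis and Pyruvate Metabolism", "Carbohydrate"),
    ("Fructose, Mannose and Galactose Metabolism", "Carbohydrate"),
    ("Pentose Metabolism", "Carbohydrate"),
    ("Aminosugar Metabolism", "Carbohydrate"),
    ("Glycogen Metabolism", "Carbohydrate"),
    ("TCA Cycle", "Energy"),
    ("Oxidative Phosphorylation", "Energy"),
    ("Acyl Carnitine, Medium Chain", "Lipid"),
    ("Acyl Carnitine, Dicarboxylate", "Lipid"),
    ("Acyl Carnitine, Hydroxy", "Lipid"),
    ("Acyl Glycine", "Lipid"),
    ("Acyl Glutamine", "Lipid"),
    ("Androgenic Steroids", "Lipid"),
    ("Corticosteroids", "Lipid"),
    ("Pregnenolone Steroids", "Lipid"),
    ("Progestin Steroids", "Lipid"),
    ("Secondary Bile Acid Metabolism", "Lipid"),
    ("Primary Bile Acid Metabolism", "Lipid"),
    ("Fatty Acid, Dicarboxylate", "Lipid"),
    ("Fatty Acid, Monohydroxy", "Lipid"),
    ("Carnitine Metabolism", "Lipid"),
    ("Phospholipid Metabolism", "Lipid"),
    ("Sphingolipid Metabolism", "Lipid"),
    ("Lysophospholipid", "Lipid"),
    ("Ketone Bodies", "Lipid"),
    ("Purine Metabolism, Adenine containing", "Nucleotide"),
    ("Purine Metabolism, (Hypo)Xanthine/Inosine containing", "Nucleotide"),
    ("Pyrimidine Metabolism, Uracil containing", "Nucleotide"),
    ("Pyrimidine Metabolism, Cytidine containing", "Nucleotide"),
    ("Nicotinate and Nicotinamide Metabolism", "Cofactors and Vitamins"),
    ("Ascorbate and Aldarate Metabolism", "Cofactors and Vitamins"),
    ("Tocopherol Metabolism", "Cofactors and Vitamins"),
    ("Pantothenate and CoA Metabolism", "Cofactors and Vitamins"),
    ("Riboflavin Metabolism", "Cofactors and Vitamins"),
    ("Dipeptide", "Peptide"),
    ("Gamma-glutamyl Amino Acid", "Peptide"),
    ("Xanthine Metabolism", "Xenobiotics"),
    ("Benzoate Metabolism", "Xenobiotics"),
    ("Food Component/Plant", "Xenobiotics"),
    ("Drug - Analgesics, Anesthetics", "Xenobiotics"),
    ("Tobacco Metabolite", "Xenobiotics"),
    ("Chemical", "Xenobiotics"),
]

DEFAULT_RESPONDER_SUBPATHWAYS = (
    "Polyamine Metabolism",
    "Leucine, Isoleucine and Valine Metabolism",
    "Urea Cycle; Arginine and Proline Metabolism",
    "Methionine, Cysteine, SAM and Taurine Metabolism",
    "Acyl Carnitine, Medium Chain",
    "Acyl Carnitine, Dicarboxylate",
    "Corticosteroids",
    "Androgenic Steroids",
)


@dataclass
class SimScenario:
    """Generative parameters for one synthetic study."""

    n_control: int = 8
    n_case: int = 10
    n_metabolites: int = 1403
    n_subpathways: int = 84
    known_fraction: float = 0.63
    partial_fraction: float = 0.046
    responder_subpathways: tuple[str, ...] = DEFAULT_RESPONDER_SUBPATHWAYS
    gamma: float = 0.3            # control post-exercise log10 shift (responders)
    eta: float | None = None      # interaction offset; default -gamma (no case change)
    delta: float = 0.0            # cohort offset at baseline
    sigma_u: float = 0.1          # subject intercept SD (log10)
    sigma_s: float = 0.35         # subject-by-metabolite stable deviate SD
    sigma_e: float = 0.15         # residual SD
    sigma_r: float = 0.15         # subject-by-metabolite response deviate SD
    covariate_slope_sd: float = 0.003  # SD of per-metabolite age and BMI slopes
    rho: float | tuple[float, float] = (0.4, 0.95)  # urine-plasma coupling
    rho_case: float | tuple[float, float] | None = None  # cohort-specific override
    mu_mean: float = 4.0          # mean log10 raw area
    mu_sd: float = 1.0
    frac_low_detect: float = 0.18
    low_detect_range: tuple[float, float] = (0.2, 0.75)
    high_detect_range: tuple[float, float] = (0.96, 1.0)
    drug_rate: float = 0.6        # drug/tobacco flag rate within drug subpathways
    hmdb_fraction: float = 0.6    # fraction of known metabolites with an HMDB id
    cluster_fraction: float = 0.7  # fraction of knowns with a chemical cluster
    osmolality_log_mean: float = np.log(600.0)
    osmolality_log_sd: float = 0.35
    age_mean: float = 52.0
    age_sd: float = 5.0
    bmi_control: float = 33.0
    bmi_case: float = 24.0
    bmi_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_case, self.n_metabolites) <= 0:
            raise ValueError("cohort sizes and metabolite count must be positive")
        for name in ("sigma_u", "sigma_s", "sigma_e", "sigma_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eta is None:
            self.eta = -self.gamma

    @classmethod
    def noise_free(cls, **kwargs) -> "SimScenario":
        """All random SDs zero and no censoring: the exact-algebra limit."""
        kwargs.setdefault("sigma_u", 0.0)
        kwargs.setdefault("sigma_s", 0.0)
        kwargs.setdefault("sigma_e", 0.0)
        kwargs.setdefault("sigma_r", 0.0)
        kwargs.setdefault("covariate_slope_sd", 0.0)
        kwargs.setdefault("frac_low_detect", 0.0)
        kwargs.setdefault("high_detect_range", (1.0, 1.0))
        return cls(**kwargs)

    def null(self) -> "SimScenario":
        """No group, time, or interaction effects anywhere (type-I scenario)."""
        return replace(self, gamma=0.0, eta=0.0, delta=0.0, sigma_r=0.0)


@dataclass
class SimTruth:
    """Per-metabolite generative parameters, aligned with the generated panel."""

    table: pd.DataFrame            # delta, gamma, eta, rho, responder, L, mu
    responder_subpathways: tuple[str, ...]

    @property
    def responders(self) -> pd.Index:
        return self.table.index[self.table["responder"]]


@dataclass
class SimStudy:
    urine: pd.DataFrame
    plasma: pd.DataFrame
    samples: pd.DataFrame
    annotation: pd.DataFrame
    truth: SimTruth


def _default_layout(scenario: SimScenario,
                    rng: np.random.Generator) -> list[tuple[str, int, str]]:
    """(name, size, superpathway) triples covering the characterized panel."""
    n_char = int(round(scenario.n_metabolites
                       * (scenario.known_fraction + scenario.partial_fraction)))
    n_sub = min(scenario.n_subpathways, max(1, n_char))
    names = list(_SUBPATHWAY_POOL)
    while len(names) < n_sub:
        k = len(names) - len(_SUBPATHWAY_POOL) + 1
        names.append((f"Uncharacterized Subpathway {k}", "Xenobiotics"))
    names = names[:n_sub]
    # lognormal size profile: a few large subpathways, many small ones
    weights = rng.lognormal(0.0, 0.8, size=n_sub)
    sizes = np.maximum(1, np.floor(weights / weights.sum() * n_char)).astype(int)
    i = 0
    while sizes.sum() < n_char:
        sizes[i % n_sub] += 1
        i += 1
    while sizes.sum() > n_char:
        j = int(np.argmax(sizes))
        sizes[j] -= 1
    return [(nm, int(sz), sp) for (nm, sp), sz in zip(names, sizes)]


def _build_annotation(scenario: SimScenario,
                      rng: np.random.Generator) -> pd.DataFrame:
    layout = _default_layout(scenario, rng)
    rows = []
    idx = 0
    for name, size, superpathway in layout:
        is_drug_sub = name.startswith("Drug") or name.startswith("Tobacco")
        for _ in range(size):
            idx += 1
            mid = f"M{idx:05d}"
            status = ("partially_characterized"
                      if rng.random() < scenario.partial_fraction
                      / max(1e-12, scenario.known_fraction + scenario.partial_fraction)
                      else "known")
            is_drug = bool(is_drug_sub and rng.random() < scenario.drug_rate)
            hmdb = (f"SYNHMDB{idx:05d}"
                    if status == "known" and rng.random() < scenario.hmdb_fraction
                    else None)
            cluster = (f"CL{rng.integers(1, 61):03d}"
                       if status == "known" and rng.random() < scenario.cluster_fraction
                       else None)
            rows.append((mid, f"compound-{idx:05d}", superpathway, name,
                         is_drug, status, hmdb, cluster))
    n_unknown = scenario.n_metabolites - idx
    for _ in range(max(0, n_unknown)):
        idx += 1
        rows.append((f"M{idx:05d}", f"X-{10000 + idx}", None, None,
                     False, "unknown", None, None))
    annot = pd.DataFrame(rows, columns=iolayer.ANNOTATION_COLUMNS)
    return iolayer.validate_annotation(annot)


def _draw_rho(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    return rng.uniform(lo, hi, size=n)


def simulate_study(scenario: SimScenario) -> SimStudy:
    """Generate one paired urine/plasma study from a scenario.

    The seed in the scenario fully determines the output.
    """
    rng = np.random.default_rng(scenario.seed)
    annot = _build_annotation(scenario, rng)
    mets = annot.index.to_numpy()
    m = len(mets)

    subjects = ([f"C{i + 1:02d}" for i in range(scenario.n_control)]
                + [f"P{i + 1:02d}" for i in range(scenario.n_case)])
    case = np.array([0] * scenario.n_control + [1] * scenario.n_case)
    n_subj = len(subjects)
    age = np.clip(rng.normal(scenario.age_mean, scenario.age_sd, n_subj), 18, 70)
    bmi = np.clip(rng.normal(np.where(case == 1, scenario.bmi_case,
                                      scenario.bmi_control),
                             scenario.bmi_sd), 16, 55)
    age_c = age - age.mean()
    bmi_c = bmi - bmi.mean()

    # per-metabolite parameters
    mu = rng.normal(scenario.mu_mean, scenario.mu_sd, m)
    a_m = rng.normal(0.0, scenario.covariate_slope_sd, m)
    b_m = rng.normal(0.0, scenario.covariate_slope_sd, m)
    responder = annot["subpathway"].isin(scenario.responder_subpathways).to_numpy()
    gamma_m = np.where(responder, scenario.gamma, 0.0)
    eta_m = np.where(responder, scenario.eta, 0.0)
    delta_m = np.where(responder, scenario.delta, 0.0)
    rho_ctrl = _draw_rho(scenario.rho, m, rng)
    rho_case = (_draw_rho(scenario.rho_case, m, rng)
                if scenario.rho_case is not None else rho_ctrl.copy())

    # latent subject effects
    u = rng.normal(0.0, scenario.sigma_u, n_subj)                     # (subj,)
    s_urine = rng.normal(0.0, scenario.sigma_s, (n_subj, m))          # stable deviate
    r_urine = rng.normal(0.0, scenario.sigma_r, (n_subj, m))          # response deviate
    rho = np.where(case[:, None] == 1, rho_case[None, :], rho_ctrl[None, :])
    mix = np.sqrt(np.clip(1.0 - rho ** 2, 0.0, None))
    s_plasma = rho * s_urine + mix * rng.normal(0.0, scenario.sigma_s, (n_subj, m))
    r_plasma = rho * r_urine + mix * rng.normal(0.0, scenario.sigma_r, (n_subj, m))

    fixed = (mu[None, :] + u[:, None] + a_m[None, :] * age_c[:, None]
             + b_m[None, :] * bmi_c[:, None] + delta_m[None, :] * case[:, None])
    shift = gamma_m[None, :] + eta_m[None, :] * case[:, None]   # post-exercise shift

    # detection limits from the marginal latent distribution
    detect_target = np.where(
        rng.random(m) < scenario.frac_low_detect,
        rng.uniform(*scenario.low_detect_range, size=m),
        rng.uniform(*scenario.high_detect_range, size=m))
    marg_sd = np.sqrt(scenario.sigma_u ** 2 + scenario.sigma_s ** 2
                      + scenario.sigma_e ** 2)
    with np.errstate(divide="ignore"):
        limit = np.where(
            detect_target >= 1.0, 0.0,
            10.0 ** (mu + stats.norm.ppf(1.0 - detect_target) * max(marg_sd, 1e-12)))

    sample_rows = []
    urine_rows, urine_ids = [], []
    osm_all = np.exp(rng.normal(scenario.osmolality_log_mean,
                                scenario.osmolality_log_sd,
                                n_subj * len(URINE_TIMEPOINTS)))
    k = 0
    for j, subject in enumerate(subjects):
        for t in URINE_TIMEPOINTS:
            post = 1.0 if t == "U3" else 0.0
            x = (fixed[j] + s_urine[j] + post * (shift[j] + r_urine[j])
                 + rng.normal(0.0, scenario.sigma_e, m))
            raw = 10.0 ** x
            raw = np.where(raw < limit, np.nan, raw * osm_all[k])
            sid = f"{subject}-{t}"
            urine_rows.append(raw)
            urine_ids.append(sid)
            sample_rows.append((sid, subject,
                                "mecfs" if case[j] else "control", "urine", t,
                                age[j], bmi[j], osm_all[k]))
            k += 1
    plasma_rows, plasma_ids = [], []
    for j, subject in enumerate(subjects):
        for t in PLASMA_TIMEPOINTS:
            post = 1.0 if t in ("P3", "P4") else 0.0
            x = (fixed[j] + s_plasma[j] + post * (shift[j] + r_plasma[j])
                 + rng.normal(0.0, scenario.sigma_e, m))
            raw = 10.0 ** x
            raw = np.where(raw < limit, np.nan, raw)
            sid = f"{subject}-{t}"
            plasma_rows.append(raw)
            plasma_ids.append(sid)
            sample_rows.append((sid, subject,
                                "mecfs" if case[j] else "control", "plasma", t,
                                age[j], bmi[j], np.nan))

    urine = pd.DataFrame(urine_rows, index=pd.Index(urine_ids, name="sample_id"),
                         columns=pd.Index(mets, name="metabolite_id"))
    plasma = pd.DataFrame(plasma_rows, index=pd.Index(plasma_ids, name="sample_id"),
                          columns=pd.Index(mets, name="metabolite_id"))
    samples = iolayer.validate_samples(
        pd.DataFrame(sample_rows, columns=iolayer.SAMPLE_COLUMNS))

    truth_table = pd.DataFrame(
        {"delta": delta_m, "gamma": gamma_m, "eta": eta_m,
         "rho_control": rho_ctrl, "rho_case": rho_case,
         "responder": responder, "mu": mu, "detection_limit": limit,
         "age_slope": a_m, "bmi_slope": b_m},
        index=pd.Index(mets, name="metabolite_id"))
    truth = SimTruth(truth_table, tuple(scenario.responder_subpathways))
    return SimStudy(urine, plasma, samples, annot, truth)


def simulate_pathway_graphs(annotation: pd.DataFrame, seed: int = 0,
                            n_pathways: int = 12,
                            size_range: tuple[int, int] = (6, 18),
                            extra_nodes: int = 4) -> dict:
    """Random connected pathway graphs over the annotation's HMDB namespace.

    Each pathway draws a set of HMDB-bearing metabolites (plus a few nodes not
    measured in the study, as real reference pathways contain) and wires them
    into a random tree with extra shortcut edges.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    pool = annotation["hmdb_id"].dropna().to_numpy()
    if len(pool) < size_range[0]:
        raise ValueError("annotation has too few HMDB ids to build pathways")
    graphs = {}
    for p in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(pool))
        members = list(rng.choice(pool, size=size, replace=False))
        members += [f"SYNHMDB9{p:02d}{i:02d}" for i in range(extra_nodes)]
        rng.shuffle(members)
        g = nx.Graph()
        for i in range(1, len(members)):
            g.add_edge(members[i], members[int(rng.integers(0, i))])
        for _ in range(len(members) // 3):
            a, b = rng.choice(len(members), size=2, replace=False)
            if a != b:
                g.add_edge(members[a], members[b])
        graphs[f"PW{p + 1:03d}"] = g
    return graphs


def fixture_small(seed: int = 11) -> SimStudy:
    """Deterministic 4+4-subject, 60-metabolite, 6-subpathway test fixture.

    By construction it contains one all-missing non-drug metabolite, one
    drug-flagged metabolite with missing cells, one metabolite detected in
    7/8 control urine samples (just above the 80% rule with 8 samples per
    cohort) and one detected in 6/8 samples of both cohorts (just below).
    """
    scenario = SimScenario(
        n_control=4, n_case=4, n_metabolites=60, n_subpathways=6,
        known_fraction=0.9, partial_fraction=0.0, frac_low_detect=0.1,
        hmdb_fraction=0.8, seed=seed)
    study = simulate_study(scenario)
    mets = study.annotation.index
    m_all_missing, m_drug, m_pass, m_fail = mets[56], mets[57], mets[58], mets[59]

    # make the engineered columns fully detected before carving patterns in
    for col in (m_drug, m_pass, m_fail):
        fill = study.urine[col].median()
        if not np.isfinite(fill):
            fill = 100.0
        study.urine[col] = study.urine[col].fillna(fill)

    study.urine[m_all_missing] = np.nan
    study.plasma[m_all_missing] = np.nan
    study.annotation.loc[m_drug, "is_drug_or_tobacco"] = True
    drug_rows = study.urine.index[:3]
    study.urine.loc[drug_rows, m_drug] = np.nan

    urine_meta = study.samples[study.samples["fluid"] == "urine"]
    ctrl = urine_meta.loc[urine_meta["cohort"] == "control", "sample_id"]
    case = urine_meta.loc[urine_meta["cohort"] == "mecfs", "sample_id"]
    # detected 7/8 control (0.875 >= 0.8) but sparse in cases: retained
    study.urine.loc[ctrl[:1], m_pass] = np.nan
    study.urine.loc[case[:6], m_pass] = np.nan
    # detected 6/8 (0.75) in both cohorts: dropped by the 80% rule
    study.urine.loc[ctrl[:2], m_fail] = np.nan
    study.urine.loc[case[:2], m_fail] = np.nan
    return study


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the five study tables plus a JSON ground-truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "urine": outdir / "urine_raw.tsv",
        "plasma": outdir / "plasma_raw.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.json",
    }
    iolayer.write_abundance(study.urine, paths["urine"])
    iolayer.write_abundance(study.plasma, paths["plasma"])
    iolayer.write_samples(study.samples, paths["samples"])
    iolayer.write_annotation(study.annotation, paths["annotation"])
    truth = {
        "responder_subpathways": list(study.truth.responder_subpathways),
        "per_metabolite": study.truth.table.reset_index().to_dict(orient="list"),
    }
    iolayer.write_run_summary(truth, paths["truth"])
    return paths
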