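"""Per-metabolite linear mixed models and group-by-time contrasts.

Model, per metabolite (transformed log10 values):

    value ~ cohort * timepoint + age + BMI + (1 | subject)

Fitting is by restricted maximum likelihood, profiling the single variance
ratio theta = sigma_u^2 / sigma_e^2: for fixed theta the GLS estimates and the
residual variance are closed-form, so the REML criterion reduces to a 1-D
problem solved by a coarse log-scale grid followed by golden-section
refinement.  Because every metabolite shares one design, the covariance
structure V0 = I + theta Z Z' is diagonalized once (eigendecomposition of
Z Z'), making each criterion evaluation a set of weighted least-squares
operations on diagonal weights.

Five contrast families are produced: case vs. control at baseline and
post-exercise, the within-cohort post-vs-baseline changes, and the
cohort-by-time interaction.  Covariates are centered at their sample means so
cell means are interpretable; the contrasts put zero weight on age and BMI
and are invariant to the centering.  Degrees of freedom use the Satterthwaite
approximation by default (numeric REML information), with a conservative
residual fallback (n_subjects - n_fixed) behind config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iolayer import DesignError, RunConfig
from .prep import ProcessedTable, log2_from_log10, make_ratios

logger = logging.getLogger("urometab")

FIXED_EFFECTS = ["intercept", "case", "post", "case_post", "age", "bmi"]
CONTRASTS = {
    "case_vs_ctrl@baseline": np.array([0, 1, 0, 0, 0, 0], dtype=float),
    "case_vs_ctrl@post":     np.array([0, 1, 0, 1, 0, 0], dtype=float),
    "post_vs_base@ctrl":     np.array([0, 0, 1, 0, 0, 0], dtype=float),
    "post_vs_base@case":     np.array([0, 0, 1, 1, 0, 0], dtype=float),
    "interaction":           np.array([0, 0, 0, 1, 0, 0], dtype=float),
}
THETA_MAX = 1e6
_THETA_GRID = np.concatenate([[0.0], np.logspace(-6, np.log10(THETA_MAX), 49)])
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class LmmDesign:
    """Shared fixed/random design for every metabolite of one fluid pair."""

    sample_ids: pd.Index
    subjects: pd.Index
    X: np.ndarray            # n x p fixed design
    Xt: np.ndarray           # Q'X in the eigenbasis of ZZ'
    Q: np.ndarray            # eigenvectors of ZZ'
    lam: np.ndarray          # eigenvalues of ZZ'
    n: int
    p: int
    n_subjects: int

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, fluid: str = "urine",
                     timepoints: tuple[str, str] = ("U1", "U3")) -> "LmmDesign":
        base_tp, post_tp = timepoints
        sub = samples[(samples["fluid"] == fluid)
                      & samples["timepoint"].isin(timepoints)].copy()
        complete = (sub.groupby("subject_id")["timepoint"].nunique() == 2)
        keep_subjects = complete.index[complete]
        sub = sub[sub["subject_id"].isin(keep_subjects)]
        sub = sub.sort_values(["subject_id", "timepoint"])
        for cohort in ("control", "mecfs"):
            n_c = sub.loc[sub["cohort"] == cohort, "subject_id"].nunique()
            if n_c < 2:
                raise DesignError(
                    f"need >= 2 complete subjects per cohort, {cohort} has {n_c}")
        case = (sub["cohort"] == "mecfs").to_numpy(dtype=float)
        post = (sub["timepoint"] == post_tp).to_numpy(dtype=float)
        age = sub["age"].to_numpy(dtype=float)
        bmi = sub["bmi"].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(sub)), case, post, case * post,
                             age - age.mean(), bmi - bmi.mean()])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            aliased = [FIXED_EFFECTS[i] for i in range(X.shape[1])
                       if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
            raise DesignError(f"design is rank deficient; aliased columns: "
                              f"{aliased or 'unknown'}")
        subjects = pd.Index(sub["subject_id"].unique())
        Z = (sub["subject_id"].to_numpy()[:, None]
             == subjects.to_numpy()[None, :]).astype(float)
        lam, Q = np.linalg.eigh(Z @ Z.T)
        lam = np.clip(lam, 0.0, None)
        return cls(sample_ids=pd.Index(sub["sample_id"]), subjects=subjects,
                   X=X, Xt=Q.T @ X, Q=Q, lam=lam, n=X.shape[0], p=X.shape[1],
                   n_subjects=len(subjects))


@dataclass
class LmmFit:
    beta: pd.Series
    sigma2_u: float
    sigma2_e: float
    theta: float
    loglik: float            # REML criterion (up to an additive constant)
    converged: bool
    cov_beta: np.ndarray     # covariance of fixed effects at the REML solution
    design: LmmDesign
    yt: np.ndarray           # Q'y, kept for df computations


def _profile(design: LmmDesign, yt: np.ndarray, theta: float):
    """Closed-form GLS at fixed theta; returns (reml, beta, sigma2_e, A)."""
    w = 1.0 / (1.0 + theta * design.lam)
    Xw = design.Xt * w[:, None]
    A = design.Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    r = yt - design.Xt @ beta
    rss = float(np.sum(w * r * r))
    dof = design.n - design.p
    sigma2_e = rss / dof
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0 or sigma2_e <= 0:
        return -np.inf, beta, sigma2_e, A
    log_v0 = float(np.sum(np.log1p(theta * design.lam)))
    reml = -0.5 * (log_v0 + logdet_A + dof * np.log(sigma2_e))
    return reml, beta, sigma2_e, A


def fit_lmm(y: np.ndarray | pd.Series, design: LmmDesign) -> LmmFit:
    """Profiled-REML fit of the random-intercept model for one metabolite."""
    if isinstance(y, pd.Series):
        y = y.reindex(design.sample_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise DesignError(f"y must have length {design.n}")
    if not np.isfinite(y).all():
        raise DesignError("y contains non-finite values")
    yt = design.Q.T @ y

    crit = np.array([_profile(design, yt, t)[0] for t in _THETA_GRID])
    best = int(np.nanargmax(crit))
    if best == 0 or best == len(_THETA_GRID) - 1:
        theta = _THETA_GRID[best]
        converged = False
    else:
        # golden-section refinement on log(theta) within the bracketing cell
        lo = np.log(max(_THETA_GRID[best - 1], 1e-12))
        hi = np.log(_THETA_GRID[best + 1])
        a, b = lo, hi
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = _profile(design, yt, np.exp(c))[0]
        fd = _profile(design, yt, np.exp(d))[0]
        for _ in range(60):
            if b - a < 1e-10:
                break
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - _GOLDEN * (b - a)
                fc = _profile(design, yt, np.exp(c))[0]
            else:
                a, c, fc = c, d, fd
                d = a + _GOLDEN * (b - a)
                fd = _profile(design, yt, np.exp(d))[0]
        theta = float(np.exp((a + b) / 2.0))
        converged = True
    reml, beta, sigma2_e, A = _profile(design, yt, theta)
    if not np.isfinite(reml):
        converged = False
    cov_beta = sigma2_e * np.linalg.inv(A)
    return LmmFit(beta=pd.Series(beta, index=FIXED_EFFECTS),
                  sigma2_u=theta * sigma2_e, sigma2_e=sigma2_e, theta=theta,
                  loglik=reml, converged=converged, cov_beta=cov_beta,
                  design=design, yt=yt)


def _reml_varcomp(design: LmmDesign, yt: np.ndarray,
                  s2u: float, s2e: float) -> float:
    """REML log-likelihood as a function of the two variance components."""
    d = s2e + s2u * design.lam
    if (d <= 0).any():
        return -np.inf
    Xd = design.Xt / d[:, None]
    A = design.Xt.T @ Xd
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(A, Xd.T @ yt)
    r = yt - design.Xt @ beta
    quad = float(np.sum(r * r / d))
    return -0.5 * (float(np.sum(np.log(d))) + logdet_A + quad)


def _cvc(design: LmmDesign, c: np.ndarray, s2u: float, s2e: float) -> float:
    """Variance of the contrast c'beta at given variance components."""
    d = s2e + s2u * design.lam
    A = design.Xt.T @ (design.Xt / d[:, None])
    return float(c @ np.linalg.solve(A, c))


def satterthwaite_df(fit: LmmFit, c: np.ndarray) -> float:
    """Effective df for c'beta: 2 f^2 / (g' W g), with f = Var(c'beta),
    g its gradient in the variance components and W their REML covariance
    from the numeric observed information."""
    design = fit.design
    s2u, s2e = max(fit.sigma2_u, 0.0), fit.sigma2_e
    resid_df = float(design.n - design.p)
    if s2u <= 1e-10 * s2e:
        return resid_df  # boundary: OLS-like, exact chi^2_{n-p} for sigma_e^2
    hu = 1e-5 * max(s2u, 1e-8)
    he = 1e-5 * s2e

    def ll(u, e):
        return _reml_varcomp(design, fit.yt, u, e)

    f0 = ll(s2u, s2e)
    huu = (ll(s2u + hu, s2e) - 2 * f0 + ll(s2u - hu, s2e)) / hu ** 2
    hee = (ll(s2u, s2e + he) - 2 * f0 + ll(s2u, s2e - he)) / he ** 2
    hue = (ll(s2u + hu, s2e + he) - ll(s2u + hu, s2e - he)
           - ll(s2u - hu, s2e + he) + ll(s2u - hu, s2e - he)) / (4 * hu * he)
    H = np.array([[huu, hue], [hue, hee]])
    f = _cvc(design, c, s2u, s2e)
    g = np.array([
        (_cvc(design, c, s2u + hu, s2e) - _cvc(design, c, s2u - hu, s2e)) / (2 * hu),
        (_cvc(design, c, s2u, s2e + he) - _cvc(design, c, s2u, s2e - he)) / (2 * he),
    ])
    try:
        W = np.linalg.inv(-H)
        denom = float(g @ W @ g)
    except np.linalg.LinAlgError:
        return resid_df
    if denom <= 0 or not np.isfinite(denom):
        return resid_df
    df = 2.0 * f * f / denom
    return float(np.clip(df, 1.0, resid_df))


def contrasts(fit: LmmFit, df_method: str = "satterthwaite") -> pd.DataFrame:
    """Estimates, SEs, Satterthwaite df, t and two-sided p for the five
    contrast families of one fit."""
    rows = []
    for name, c in CONTRASTS.items():
        estimate = float(c @ fit.beta.to_numpy())
        var = float(c @ fit.cov_beta @ c)
        se = np.sqrt(var)
        if df_method == "satterthwaite":
            df = satterthwaite_df(fit, c)
        elif df_method == "residual":
            df = float(fit.design.n_subjects - fit.design.p)
        else:
            raise ValueError(f"unknown df_method {df_method!r}")
        t = estimate / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append((name, estimate, se, df, t, p))
    return pd.DataFrame(rows, columns=["contrast", "estimate", "se", "df",
                                       "t", "p"])


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cell_means(centered: pd.DataFrame, samples: pd.DataFrame,
                timepoints: tuple[str, str]) -> dict[str, pd.Series]:
    """Mean normalized (median-centered, pre-transform) concentration per
    cohort x timepoint cell."""
    meta = samples.set_index("sample_id").loc[centered.index]
    out = {}
    for cohort in ("control", "mecfs"):
        for tp in timepoints:
            mask = (meta["cohort"] == cohort) & (meta["timepoint"] == tp)
            out[f"{cohort}@{tp}"] = centered[mask.to_numpy()].mean(axis=0)
    return out


def contrast_table(proc: ProcessedTable, samples: pd.DataFrame,
                   config: RunConfig | None = None,
                   fluid: str = "urine",
                   timepoints: tuple[str, str] = ("U1", "U3")) -> pd.DataFrame:
    """Fit every retained metabolite and assemble the full contrast table.

    Columns: metabolite_id, contrast, estimate, se, df, t, p, q (BH within
    contrast family), log2fc, fc (linear fold change of mean normalized
    concentrations), cell means, convergence flag.  BH families are per
    contrast across the retained metabolites.
    """
    config = config or RunConfig()
    design = LmmDesign.from_samples(samples, fluid=fluid, timepoints=timepoints)
    values = proc.filtered_values.loc[design.sample_ids]
    base_tp, post_tp = timepoints
    ratios = make_ratios(proc.values, samples, post_tp, base_tp)
    meta = samples.set_index("sample_id")
    subj_cohort = (meta.drop_duplicates("subject_id")
                   .set_index("subject_id")["cohort"])
    ratio_cohort = subj_cohort.reindex(ratios.index)
    mean_ratio_ctrl = ratios[ratio_cohort == "control"].mean(axis=0)
    mean_ratio_case = ratios[ratio_cohort == "mecfs"].mean(axis=0)
    cells = _cell_means(proc.centered.loc[design.sample_ids], samples, timepoints)

    frames = []
    for met in values.columns:
        fit = fit_lmm(values[met], design)
        tab = contrasts(fit, df_method=config.df_method)
        tab.insert(0, "metabolite_id", met)
        tab["converged"] = fit.converged
        frames.append(tab)
    results = pd.concat(frames, ignore_index=True)

    # fold changes of mean normalized concentration (enrichment input),
    # per contrast family
    log10_ratio_of_ratios = mean_ratio_case - mean_ratio_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_log10 = {
            "case_vs_ctrl@baseline": np.log10(cells[f"mecfs@{base_tp}"]
                                              / cells[f"control@{base_tp}"]),
            "case_vs_ctrl@post": np.log10(cells[f"mecfs@{post_tp}"]
                                          / cells[f"control@{post_tp}"]),
            "post_vs_base@ctrl": np.log10(cells[f"control@{post_tp}"]
                                          / cells[f"control@{base_tp}"]),
            "post_vs_base@case": np.log10(cells[f"mecfs@{post_tp}"]
                                          / cells[f"mecfs@{base_tp}"]),
            "interaction": log10_ratio_of_ratios,
        }
    # volcano fold changes: difference of cohort means of transformed values
    # (ratio of mean per-subject ratios for the interaction)
    tcells = _cell_means(values, samples, timepoints)
    volcano_log10 = {
        "case_vs_ctrl@baseline": tcells[f"mecfs@{base_tp}"]
        - tcells[f"control@{base_tp}"],
        "case_vs_ctrl@post": tcells[f"mecfs@{post_tp}"]
        - tcells[f"control@{post_tp}"],
        "post_vs_base@ctrl": tcells[f"control@{post_tp}"]
        - tcells[f"control@{base_tp}"],
        "post_vs_base@case": tcells[f"mecfs@{post_tp}"]
        - tcells[f"mecfs@{base_tp}"],
        "interaction": log10_ratio_of_ratios,
    }
    results["q"] = np.nan
    results["fc_log10"] = np.nan
    results["log2fc"] = np.nan
    for name in CONTRASTS:
        mask = results["contrast"] == name
        mets = results.loc[mask, "metabolite_id"]
        results.loc[mask, "q"] = bh_adjust(results.loc[mask, "p"].to_numpy())
        results.loc[mask, "fc_log10"] = fc_log10[name].reindex(mets).to_numpy()
        results.loc[mask, "log2fc"] = log2_from_log10(
            volcano_log10[name].reindex(mets).to_numpy())
    for cell, series in cells.items():
        results[f"mean_{cell}"] = series.reindex(results["metabolite_id"]).to_numpy()
    n_sig = {name: int((results.loc[results["contrast"] == name, "q"]
                        < config.lmm_q).sum()) for name in CONTRASTS}
    logger.info("lmm: %d metabolites fitted; significant at q<%g: %s",
                values.shape[1], config.lmm_q, n_sig)
    return results


def volcano_table(results: pd.DataFrame, contrast: str,
                  q_threshold: float = 0.1) -> pd.DataFrame:
    """Plot-ready volcano table for one contrast family."""
    sub = results[results["contrast"] == contrast].copy()
    if sub.empty:
        raise KeyError(f"no results for contrast {contrast!r}")
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(sub["q"].to_numpy())
    return pd.DataFrame({
        "metabolite_id": sub["metabolite_id"].to_numpy(),
        "log2fc": sub["log2fc"].to_numpy(),
        "neg_log10_q": neglog_q,
        "significant": (sub["q"] < q_threshold).to_numpy(),
    })
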