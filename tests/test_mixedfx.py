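"""Mixed-model machinery: REML profiling, contrasts, BH, volcano tables."""

import numpy as np
import pandas as pd
import pytest

import urometab as um
from urometab.iolayer import DesignError
from urometab.mixedfx import (CONTRASTS, LmmDesign, bh_adjust, contrasts,
                              fit_lmm, volcano_table)

from _oracles import _dense_crit


def _random_dataset(rng, n_ctrl=4, n_case=5):
    """Random balanced paired design plus a y with known-ish structure."""
    subjects = [f"c{i}" for i in range(n_ctrl)] + [f"p{i}" for i in range(n_case)]
    rows = []
    for s in subjects:
        cohort = "control" if s.startswith("c") else "mecfs"
        age = float(rng.uniform(30, 65))
        bmi = float(rng.uniform(20, 38))
        for tp in ("U1", "U3"):
            rows.append((f"{s}-{tp}", s, cohort, "urine", tp, age, bmi, 1.0))
    samples = um.iolayer.validate_samples(
        pd.DataFrame(rows, columns=um.iolayer.SAMPLE_COLUMNS))
    design = LmmDesign.from_samples(samples)
    su, se = rng.uniform(0.05, 0.4), rng.uniform(0.1, 0.4)
    u = {s: rng.normal(0, su) for s in subjects}
    meta = samples.set_index("sample_id").loc[design.sample_ids]
    beta = rng.normal(0, 0.3, 6)
    X = design.X
    y = X @ beta + np.array([u[s] for s in meta["subject_id"]]) \
        + rng.normal(0, se, design.n)
    return design, y, meta


class TestFitLmm:
    def test_noise_free_recovers_generator_coefficients(self):
        rng = np.random.default_rng(0)
        design, _, meta = _random_dataset(rng)
        beta_true = np.array([1.0, 0.5, 0.3, -0.3, 0.01, -0.02])
        y = design.X @ beta_true + rng.normal(0, 1e-8, design.n)
        fit = fit_lmm(y, design)
        assert np.allclose(fit.beta.to_numpy(), beta_true, atol=1e-6)

    def test_balanced_interaction_equals_difference_of_paired_means(self):
        """In a complete paired design the interaction estimate is the mean
        case paired difference minus the mean control paired difference."""
        rng = np.random.default_rng(1)
        design, y, meta = _random_dataset(rng)
        fit = fit_lmm(y, design)
        frame = pd.DataFrame({"y": y, "subject": meta["subject_id"].to_numpy(),
                              "cohort": meta["cohort"].to_numpy(),
                              "tp": meta["timepoint"].to_numpy()})
        diffs = (frame.pivot(index="subject", columns="tp", values="y")
                 .eval("U3 - U1"))
        cohort = frame.drop_duplicates("subject").set_index("subject")["cohort"]
        expected = (diffs[cohort == "mecfs"].mean()
                    - diffs[cohort == "control"].mean())
        assert fit.beta["case_post"] == pytest.approx(expected, abs=1e-10)

    def test_reml_criterion_beats_dense_grid(self):
        """The profiled optimum dominates a 1000-point theta grid evaluated
        by an independent dense-matrix criterion."""
        rng = np.random.default_rng(2)
        design, y, meta = _random_dataset(rng)
        fit = fit_lmm(y, design)
        codes = meta["subject_id"].to_numpy()
        Z = (codes[:, None] == np.unique(codes)[None, :]).astype(float)
        ZZT = Z @ Z.T
        grid = np.concatenate([[0.0], np.logspace(-8, 6, 1000)])
        grid_best = max(_dense_crit(t, y, design.X, ZZT)[0] for t in grid)
        ours = _dense_crit(fit.theta, y, design.X, ZZT)[0]
        assert ours >= grid_best - 1e-9

    def test_matches_statsmodels_mixedlm(self, proc, design, study):
        import statsmodels.formula.api as smf

        met = proc.filtered_values.columns[5]
        y = proc.filtered_values[met]
        fit = fit_lmm(y, design)
        meta = study.samples.set_index("sample_id").loc[design.sample_ids]
        frame = pd.DataFrame({
            "y": y.reindex(design.sample_ids).to_numpy(),
            "case": (meta["cohort"] == "mecfs").to_numpy(dtype=float),
            "post": (meta["timepoint"] == "U3").to_numpy(dtype=float),
            "age": (meta["age"] - meta["age"].mean()).to_numpy(),
            "bmi": (meta["bmi"] - meta["bmi"].mean()).to_numpy(),
            "subj": meta["subject_id"].to_numpy()})
        sm_fit = smf.mixedlm("y ~ case*post + age + bmi", frame,
                             groups="subj").fit(reml=True)
        order = ["Intercept", "case", "post", "case:post", "age", "bmi"]
        assert np.allclose(fit.beta.to_numpy(),
                           sm_fit.params[order].to_numpy(), atol=1e-5)
        assert fit.sigma2_e == pytest.approx(float(sm_fit.scale), rel=1e-3)

    def test_rank_deficient_design_names_alias(self, study):
        samples = study.samples.copy()
        samples["age"] = 50.0  # constant age aliases the intercept
        with pytest.raises(DesignError, match="age"):
            LmmDesign.from_samples(samples)

    def test_too_few_subjects_rejected(self, study):
        keep = study.samples["subject_id"] != "C01"
        keep &= study.samples["subject_id"] != "C02"
        keep &= study.samples["subject_id"] != "C03"
        with pytest.raises(DesignError, match="control"):
            LmmDesign.from_samples(study.samples[keep])


class TestContrasts:
    def test_noise_free_contrast_algebra(self):
        """delta=0.5, gamma=0.3, eta=-0.3 noise-free: each contrast family
        returns its generator value."""
        rng = np.random.default_rng(3)
        design, _, _ = _random_dataset(rng)
        beta_true = np.array([2.0, 0.5, 0.3, -0.3, 0.0, 0.0])
        y = design.X @ beta_true + rng.normal(0, 1e-8, design.n)
        tab = contrasts(fit_lmm(y, design)).set_index("contrast")
        assert tab.loc["case_vs_ctrl@baseline", "estimate"] == \
            pytest.approx(0.5, abs=1e-6)
        assert tab.loc["post_vs_base@ctrl", "estimate"] == \
            pytest.approx(0.3, abs=1e-6)
        assert tab.loc["post_vs_base@case", "estimate"] == \
            pytest.approx(0.0, abs=1e-6)
        assert tab.loc["interaction", "estimate"] == \
            pytest.approx(-0.3, abs=1e-6)

    def test_sum_identity(self, lmm_results):
        """case_vs_ctrl@post - case_vs_ctrl@baseline == interaction."""
        wide = lmm_results.pivot(index="metabolite_id", columns="contrast",
                                 values="estimate")
        gap = (wide["case_vs_ctrl@post"] - wide["case_vs_ctrl@baseline"]
               - wide["interaction"]).abs()
        assert gap.max() < 1e-10

    def test_q_never_below_p(self, lmm_results):
        assert (lmm_results["q"] >= lmm_results["p"] - 1e-12).all()


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.001, 0.02, 0.03, 0.2]),
                           [0.004, 0.04, 0.04, 0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestVolcano:
    def test_ratio_of_ratios_fold_change(self, lmm_results, proc, study):
        """Interaction log2fc is the case mean log10 ratio minus the control
        mean log10 ratio, converted to base 2."""
        ratios = um.prep.make_ratios(proc.values, study.samples, "U3", "U1")
        cohort = (study.samples.drop_duplicates("subject_id")
                  .set_index("subject_id")["cohort"]).reindex(ratios.index)
        diff = (ratios[cohort == "mecfs"].mean()
                - ratios[cohort == "control"].mean())
        expected = pd.Series(um.prep.log2_from_log10(diff), index=diff.index)
        inter = (lmm_results[lmm_results["contrast"] == "interaction"]
                 .set_index("metabolite_id"))
        got = inter["log2fc"]
        assert np.allclose(got.to_numpy(),
                           expected.reindex(got.index).to_numpy(), atol=1e-10)

    def test_case_zero_control_doubling_gives_minus_one(self):
        assert um.prep.log2_from_log10(0.0 - 0.30103) == \
            pytest.approx(-1.0, abs=1e-4)

    def test_no_significance_when_all_q_one(self, lmm_results):
        inflated = lmm_results.copy()
        inflated["q"] = 1.0
        table = volcano_table(inflated, "interaction", q_threshold=0.1)
        assert not table["significant"].any()

    def test_significant_flag_matches_threshold(self, lmm_results):
        table = volcano_table(lmm_results, "post_vs_base@ctrl",
                              q_threshold=0.1)
        sub = lmm_results[lmm_results["contrast"] == "post_vs_base@ctrl"]
        assert table["significant"].sum() == (sub["q"] < 0.1).sum()


def test_bh_families_are_per_contrast(lmm_results):
    """Re-running BH within one family reproduces the stored q exactly."""
    for name in CONTRASTS:
        sub = lmm_results[lmm_results["contrast"] == name]
        assert np.allclose(bh_adjust(sub["p"].to_numpy()),
                           sub["q"].to_numpy(), atol=1e-12)
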