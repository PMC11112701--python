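"""Outlier exclusion, descriptives, mixed model and contrasts."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from srtsim.cohort import (
    SRTMixedModel,
    condition_summary,
    exclude_outliers,
    fit_lmm,
)
from srtsim.listeners import CONDITIONS, CohortConfig, cohort_truth_frame, generate_cohort


def _cohort_frame(n=24, mean=-3.0, sd=4.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    ages = rng.uniform(8.5, 13.1, n)
    for i in range(n):
        for cond in CONDITIONS:
            rows.append((f"S{i:03d}", ages[i], cond, rng.normal(mean, sd)))
    return pd.DataFrame(rows, columns=["subject_id", "age_years", "condition", "srt_db"])


class TestExcludeOutliers:
    def test_planted_extremes_excluded(self):
        """A +40 dB SRT in one condition and +31 dB in another are each beyond
        4 leave-one-out SDs of a Normal(-3, 4^2) cohort; exactly those two
        subjects drop, leaving 22 of 24."""
        df = _cohort_frame(seed=42)
        df.loc[(df.subject_id == "S000") & (df.condition == "familiar_masker"), "srt_db"] = 40.0
        df.loc[(df.subject_id == "S005") & (df.condition == "unfamiliar"), "srt_db"] = 31.0
        out = exclude_outliers(df)
        excluded = set(out.loc[out.excluded, "subject_id"])
        assert excluded == {"S000", "S005"}
        assert out.loc[~out.excluded, "subject_id"].nunique() == 22
        assert (out.loc[out.excluded, "exclusion_reason"] != "").all()

    def test_homogeneous_cohort_keeps_everyone(self):
        out = exclude_outliers(_cohort_frame(seed=1))
        assert not out.excluded.any()

    def test_permutation_invariant(self):
        df = _cohort_frame(seed=3)
        df.loc[(df.subject_id == "S010") & (df.condition == "unfamiliar"), "srt_db"] = 38.0
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = exclude_outliers(df).set_index(["subject_id", "condition"])["excluded"]
        b = exclude_outliers(shuffled).set_index(["subject_id", "condition"])["excluded"]
        assert a.sort_index().equals(b.sort_index())

    def test_leave_one_out_catches_marginal_extreme(self):
        """Including the candidate in its own mean/SD can mask a true extreme;
        the leave-one-out statistics must still flag it."""
        rng = np.random.default_rng(8)
        vals = list(rng.normal(-3, 2.0, 23)) + [30.0]
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i:03d}" for i in range(24)],
                "age_years": 10.0,
                "condition": "unfamiliar",
                "srt_db": vals,
            }
        )
        df = pd.concat(
            [df] + [df.assign(condition=c, srt_db=df.srt_db) for c in ("familiar_target",)]
        )
        out = exclude_outliers(df)
        assert "S023" in set(out.loc[out.excluded, "subject_id"])

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            exclude_outliers(_cohort_frame(n=2))


class TestConditionSummary:
    def test_arithmetic(self):
        df = pd.DataFrame(
            {
                "subject_id": ["A", "B"],
                "condition": ["unfamiliar", "unfamiliar"],
                "srt_db": [-4.0, -2.0],
            }
        )
        out = condition_summary(df)
        assert out.loc[0, "mean_srt_db"] == pytest.approx(-3.0)
        assert out.loc[0, "sd_srt_db"] == pytest.approx(np.sqrt(2.0))

    def test_large_cohort_near_generating_means(self):
        cfg = CohortConfig(n_subjects=4000)
        truth = cohort_truth_frame(generate_cohort(cfg, 17)).rename(
            columns={"true_srt_db": "srt_db"}
        )
        out = condition_summary(truth).set_index("condition")
        assert out.loc["familiar_target", "mean_srt_db"] == pytest.approx(-6.11, abs=0.25)
        assert out.loc["unfamiliar", "mean_srt_db"] == pytest.approx(-2.75, abs=0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            condition_summary(pd.DataFrame(columns=["subject_id", "condition", "srt_db"]))


class TestMixedModel:
    def test_noiseless_recovery_exact(self):
        """With both variance components at zero the SRTs are an exact linear
        function of centered log-age and condition; every coefficient must be
        recovered to numerical precision."""
        cfg = CohortConfig(n_subjects=20, sigma_subject=0.0, sigma_resid=0.0)
        truth = cohort_truth_frame(generate_cohort(cfg, 5)).rename(
            columns={"true_srt_db": "srt_db"}
        )
        res = SRTMixedModel(truth).fit()
        b = res.beta
        assert b["Intercept"] == pytest.approx(cfg.beta0, abs=1e-6)
        assert b["clog_age"] == pytest.approx(cfg.beta_age, abs=1e-6)
        assert b["condition[familiar_target]"] == pytest.approx(cfg.beta_fam_target, abs=1e-6)
        assert b["condition[familiar_masker]"] == pytest.approx(cfg.beta_fam_masker, abs=1e-6)
        assert b["clog_age:condition[familiar_target]"] == pytest.approx(0.0, abs=1e-6)

    def test_containment_degrees_of_freedom(self):
        """22 subjects x 3 conditions gives within df = 66-22-4 = 40 for the
        condition terms and between df = 20 for the age slope, reproducing
        the F df pairs (2, 40) and (1, 20)."""
        cfg = CohortConfig(n_subjects=22)
        truth = cohort_truth_frame(generate_cohort(cfg, 2)).rename(
            columns={"true_srt_db": "srt_db"}
        )
        res = SRTMixedModel(truth).fit()
        ct = res.coef_table.set_index("term")
        assert ct.loc["clog_age", "df"] == 20
        assert ct.loc["condition[familiar_target]", "df"] == 40
        ft = res.f_tests().set_index("effect")
        assert tuple(ft.loc["condition", ["df_num", "df_den"]]) == (2, 40)
        assert tuple(ft.loc["age", ["df_num", "df_den"]]) == (1, 20)

    def test_one_tailed_p_is_half_two_tailed(self):
        cfg = CohortConfig(n_subjects=22)
        truth = cohort_truth_frame(generate_cohort(cfg, 2)).rename(
            columns={"true_srt_db": "srt_db"}
        )
        ct = SRTMixedModel(truth).fit().coef_table
        assert np.allclose(ct["p_one_tailed"], ct["p"] / 2)

    def test_matches_r_nlme_oracle(self, tmp_path):
        """Independent oracle: the same REML mixed model fitted by R's nlme
        must agree on fixed effects, their SEs and both variance components."""
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        cfg = CohortConfig(n_subjects=22)
        truth = cohort_truth_frame(generate_cohort(cfg, 42)).rename(
            columns={"true_srt_db": "srt_db"}
        )
        csv = tmp_path / "cohort.csv"
        truth.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(nlme)
                d <- read.csv('{csv}')
                d$clog_age <- log10(d$age_years) - mean(log10(d$age_years))
                d$condition <- relevel(factor(d$condition), ref='unfamiliar')
                m <- lme(srt_db ~ clog_age * condition, random = ~1|subject_id,
                         data=d, method='REML')
                tt <- summary(m)$tTable
                write.csv(data.frame(term=rownames(tt), beta=tt[,'Value'],
                                     se=tt[,'Std.Error']),
                          '{tmp_path / "oracle.csv"}', row.names=FALSE)
                vc <- as.numeric(VarCorr(m)[, 'StdDev'])
                writeLines(as.character(vc), '{tmp_path / "vc.txt"}')
                """
            )
        )
        subprocess.run([rscript, str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "oracle.csv")
        res = SRTMixedModel(truth).fit()
        name_map = {
            "(Intercept)": "Intercept",
            "clog_age": "clog_age",
            "conditionfamiliar_target": "condition[familiar_target]",
            "conditionfamiliar_masker": "condition[familiar_masker]",
            "clog_age:conditionfamiliar_target": "clog_age:condition[familiar_target]",
            "clog_age:conditionfamiliar_masker": "clog_age:condition[familiar_masker]",
        }
        ours = res.coef_table.set_index("term")
        for row in oracle.itertuples(index=False):
            term = name_map[row.term]
            assert ours.loc[term, "beta"] == pytest.approx(row.beta, abs=1e-3)
            assert ours.loc[term, "se"] == pytest.approx(row.se, abs=1e-3)
        sd_subj, sd_resid = [float(v) for v in (tmp_path / "vc.txt").read_text().split()]
        assert res.sigma_subject_hat == pytest.approx(sd_subj, abs=1e-3)
        assert res.sigma_resid_hat == pytest.approx(sd_resid, abs=1e-3)

    def test_excluded_rows_dropped_from_fit(self):
        df = _cohort_frame(seed=11)
        df["excluded"] = df.subject_id == "S000"
        res = SRTMixedModel(df).fit()
        assert res.n_subjects == 23

    def test_too_few_conditions_raises(self):
        df = _cohort_frame(seed=0)
        with pytest.raises(ValueError):
            SRTMixedModel(df[df.condition == "unfamiliar"])


@pytest.fixture(scope="module")
def fitted():
    cfg = CohortConfig(n_subjects=22)
    truth = cohort_truth_frame(generate_cohort(cfg, 31)).rename(
        columns={"true_srt_db": "srt_db"}
    )
    return SRTMixedModel(truth).fit()


class TestContrasts:

    def test_contrast_equals_coefficient_difference(self, fitted):
        """At mean centered age the LS-mean contrasts reduce to differences of
        condition coefficients (interaction terms vanish)."""
        b = fitted.beta
        contr = fitted.pairwise_contrasts().set_index("pair")
        assert contr.loc["familiar_target - unfamiliar", "estimate"] == pytest.approx(
            b["condition[familiar_target]"], abs=1e-10
        )
        assert contr.loc["familiar_target - familiar_masker", "estimate"] == pytest.approx(
            b["condition[familiar_target]"] - b["condition[familiar_masker]"], abs=1e-10
        )

    def test_symmetric_pair_sums_to_zero(self, fitted):
        contr = fitted.pairwise_contrasts().set_index("pair")
        a = contr.loc["familiar_target - unfamiliar", "estimate"]
        b = contr.loc["familiar_masker - unfamiliar", "estimate"]
        c = contr.loc["familiar_target - familiar_masker", "estimate"]
        assert a - b - c == pytest.approx(0.0, abs=1e-10)

    def test_tukey_p_not_smaller_than_unadjusted(self, fitted):
        contr = fitted.pairwise_contrasts()
        assert (contr["p_tukey"] >= contr["p"] - 1e-12).all()

    def test_replicate_contrast_mean(self):
        """Across replicate cohorts the familiar-target vs familiar-masker
        contrast averages to the generating difference -3.36 - (-0.20)."""
        cfg = CohortConfig(n_subjects=22)
        vals = []
        for seed in range(150):
            truth = cohort_truth_frame(generate_cohort(cfg, 1000 + seed)).rename(
                columns={"true_srt_db": "srt_db"}
            )
            contr = SRTMixedModel(truth).fit().pairwise_contrasts().set_index("pair")
            vals.append(contr.loc["familiar_target - familiar_masker", "estimate"])
        assert np.mean(vals) == pytest.approx(-3.16, abs=0.25)


def test_fit_lmm_wrapper():
    cfg = CohortConfig(n_subjects=10)
    truth = cohort_truth_frame(generate_cohort(cfg, 4)).rename(columns={"true_srt_db": "srt_db"})
    res = fit_lmm(truth)
    assert "Intercept" in res.beta and res.sigma_resid_hat >= 0
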