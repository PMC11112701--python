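"""Cohort-level inference on measured SRTs.

Implements the study-level analysis chain:

* leave-one-out 4-SD outlier exclusion per condition;
* per-condition descriptive statistics;
* a linear mixed-effects model of SRT on centered log10(age) crossed with
  familiarity condition, with a random intercept per subject (REML via
  statsmodels MixedLM), the referent condition being
  unfamiliar-target/unfamiliar-masker;
* least-squares-mean pairwise condition contrasts at the mean age, with
  one-tailed t probabilities and Tukey (studentized-range) adjusted values.

Denominator degrees of freedom follow the containment (within/between
groups) convention: terms that vary within subject (condition and the
age-by-condition interaction) use ``n_obs - n_subjects - p_within``; the
between-subject age slope uses ``n_subjects - 2``.  For the canonical design
(22 subjects x 3 conditions) these give the df pairs (2, 40) for condition
and (1, 20) for age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .listeners import BASELINE_CONDITION, CONDITIONS

#: Subjects whose SRT in any condition is more than this many (leave-one-out)
#: standard deviations from the condition mean are excluded from modeling.
DEFAULT_SD_MULTIPLIER = 4.0


# ---------------------------------------------------------------------------
# Outlier exclusion and descriptives


def exclude_outliers(
    subjects: pd.DataFrame, sd_multiplier: float = DEFAULT_SD_MULTIPLIER
) -> pd.DataFrame:
    """Flag subjects with an extreme SRT in any condition.

    ``subjects`` is long format with columns subject_id, condition, srt_db
    (other columns pass through).  A subject is flagged when, in some
    condition, its SRT lies more than ``sd_multiplier`` standard deviations
    from the mean of the *other* subjects in that condition (leave-one-out
    statistics: including the candidate shrinks its own z-score and makes
    borderline extremes survive).  Returns a copy with boolean ``excluded``
    and text ``exclusion_reason`` columns; rows are retained, not dropped.
    """
    df = subjects.copy()
    n_subj = df["subject_id"].nunique()
    if n_subj < 3:
        raise ValueError("need at least 3 subjects for outlier screening")
    df["excluded"] = False
    df["exclusion_reason"] = ""
    reasons: dict[str, str] = {}
    for cond, sub in df.groupby("condition"):
        vals = sub["srt_db"].to_numpy(dtype=float)
        ids = sub["subject_id"].to_numpy()
        for i in range(len(vals)):
            others = np.delete(vals, i)
            mu, sd = others.mean(), others.std(ddof=1)
            if sd > 0 and abs(vals[i] - mu) > sd_multiplier * sd:
                reasons.setdefault(
                    ids[i],
                    f"SRT {vals[i]:+.1f} dB in {cond} exceeds "
                    f"{sd_multiplier:g} SD of the remaining subjects",
                )
    flagged = set(reasons)
    if len(flagged) == n_subj:
        raise ValueError("outlier rule flagged every subject")
    df.loc[df["subject_id"].isin(flagged), "excluded"] = True
    df["exclusion_reason"] = df["subject_id"].map(reasons).fillna("")
    return df


def condition_summary(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of SRT over included subjects."""
    df = subjects
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    if df.empty:
        raise ValueError("no included subjects to summarise")
    out = (
        df.groupby("condition")["srt_db"]
        .agg(n="count", mean_srt_db="mean", sd_srt_db=lambda s: s.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 2).any():
        raise ValueError("a condition has fewer than 2 included subjects")
    return out


# ---------------------------------------------------------------------------
# Mixed-effects model


def center_log10_age(age_years: np.ndarray | pd.Series) -> np.ndarray:
    """log10 age centered at the sample mean of log10 age."""
    la = np.log10(np.asarray(age_years, dtype=float))
    return la - la.mean()


class SRTMixedModel:
    """Linear mixed model: srt ~ clog_age * condition + (1 | subject).

    Age enters as log10(years) centered at the included-cohort mean, so the
    intercept is the referent-condition mean SRT at the average age and the
    condition coefficients are LS-mean differences at that age.

    Parameters
    ----------
    data : DataFrame
        Long format with columns subject_id, age_years, condition, srt_db.
        Rows flagged ``excluded`` are dropped.  One row per
        subject-condition.
    interaction : bool
        Include age-by-condition interaction terms (default True).
    """

    def __init__(self, data: pd.DataFrame, interaction: bool = True,
                 baseline: str = BASELINE_CONDITION):
        df = data.copy()
        if "excluded" in df.columns:
            df = df[~df["excluded"]]
        df = df.dropna(subset=["srt_db"])
        if df["condition"].nunique() < 2:
            raise ValueError("need at least 2 conditions")
        if df["subject_id"].nunique() < 3:
            raise ValueError("need at least 3 subjects")
        if baseline not in set(df["condition"]):
            raise ValueError(f"baseline condition {baseline!r} absent from data")
        df["clog_age"] = center_log10_age(df["age_years"])
        self.data = df.reset_index(drop=True)
        self.interaction = interaction
        self.baseline = baseline
        self.conditions = [baseline] + sorted(set(df["condition"]) - {baseline})

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SRTMixedModel":
        return cls(data, **kwargs)

    def _design(self) -> tuple[np.ndarray, list[str]]:
        df = self.data
        cols = [np.ones(len(df)), df["clog_age"].to_numpy()]
        names = ["Intercept", "clog_age"]
        for cond in self.conditions[1:]:
            ind = (df["condition"] == cond).to_numpy(dtype=float)
            cols.append(ind)
            names.append(f"condition[{cond}]")
        if self.interaction:
            for cond in self.conditions[1:]:
                ind = (df["condition"] == cond).to_numpy(dtype=float)
                cols.append(ind * df["clog_age"].to_numpy())
                names.append(f"clog_age:condition[{cond}]")
        return np.column_stack(cols), names

    def fit(self, reml: bool = True) -> "SRTMixedResults":
        import statsmodels.api as sm

        exog, names = self._design()
        groups = self.data["subject_id"].to_numpy()
        endog = self.data["srt_db"].to_numpy(dtype=float)
        model = sm.MixedLM(endog, exog, groups=groups)
        singular = False
        res = None
        last_err: Exception | None = None
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            # lbfgs occasionally produces a singular Hessian on near-boundary
            # variance estimates; fall through to sturdier optimizers
            for method in ("lbfgs", "bfgs", "cg", "powell"):
                try:
                    res = model.fit(reml=reml, method=method)
                    break
                except np.linalg.LinAlgError as err:
                    last_err = err
            if res is None:
                raise RuntimeError(f"mixed model failed to fit: {last_err}") from last_err
            for w in caught:
                msg = str(w.message).lower()
                if "singular" in msg or "boundary" in msg or "converge" in msg:
                    singular = True
        if float(np.asarray(res.cov_re)[0, 0]) < 1e-10:
            singular = True
        return SRTMixedResults(self, res, names, singular=singular)


@dataclass
class _TermTable:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    df: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_one_tailed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": self.se,
                "df": self.df,
                "t": self.t,
                "p": self.p,
                "p_one_tailed": self.p_one_tailed,
            }
        )


class SRTMixedResults:
    """Fitted mixed model: coefficient table, F tests, variance components, contrasts."""

    def __init__(self, model: SRTMixedModel, smres, names: list[str], singular: bool):
        self.model = model
        self._res = smres
        self.names = names
        self.singular = singular
        self.n_obs = len(model.data)
        self.n_subjects = model.data["subject_id"].nunique()
        self.fe_params = np.asarray(smres.fe_params, dtype=float)
        k = len(self.fe_params)
        self.cov_fe = np.asarray(smres.cov_params())[:k, :k]
        self.sigma_subject_hat = float(np.sqrt(max(np.asarray(smres.cov_re)[0, 0], 0.0)))
        self.sigma_resid_hat = float(np.sqrt(smres.scale))

    # -- degrees of freedom (containment convention) ------------------------

    def _term_df(self) -> np.ndarray:
        p_within = sum(1 for n in self.names if "condition" in n)
        df_within = self.n_obs - self.n_subjects - p_within
        df_between = self.n_subjects - 2  # intercept + one between covariate
        out = []
        for n in self.names:
            if n == "clog_age":
                out.append(df_between)
            else:
                # intercept and all condition-varying terms sit in the
                # within-subject stratum
                out.append(df_within)
        return np.array(out, dtype=float)

    # -- coefficient table ---------------------------------------------------

    @property
    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_fe))
        dfs = self._term_df()
        t = self.fe_params / se
        p_two = 2 * stats.t.sf(np.abs(t), dfs)
        p_one = stats.t.sf(np.abs(t), dfs)
        return _TermTable(self.names, self.fe_params, se, dfs, t, p_two, p_one).to_frame()

    @property
    def beta(self) -> dict[str, float]:
        return dict(zip(self.names, self.fe_params))

    # -- F tests -------------------------------------------------------------

    def _wald_f(self, term_idx: list[int], den_df: float) -> tuple[float, int, float, float]:
        L = np.zeros((len(term_idx), len(self.fe_params)))
        for r, i in enumerate(term_idx):
            L[r, i] = 1.0
        est = L @ self.fe_params
        vmat = L @ self.cov_fe @ L.T
        f = float(est @ np.linalg.solve(vmat, est) / len(term_idx))
        p = float(stats.f.sf(f, len(term_idx), den_df))
        return f, len(term_idx), den_df, p

    def f_tests(self) -> pd.DataFrame:
        """Wald F tests for age, condition and (if present) the interaction."""
        dfs = self._term_df()
        rows = []
        age_idx = [self.names.index("clog_age")]
        cond_idx = [i for i, n in enumerate(self.names) if n.startswith("condition[")]
        f, df1, df2, p = self._wald_f(age_idx, dfs[age_idx[0]])
        rows.append(("age", f, df1, df2, p))
        f, df1, df2, p = self._wald_f(cond_idx, dfs[cond_idx[0]])
        rows.append(("condition", f, df1, df2, p))
        int_idx = [i for i, n in enumerate(self.names) if n.startswith("clog_age:")]
        if int_idx:
            f, df1, df2, p = self._wald_f(int_idx, dfs[int_idx[0]])
            rows.append(("age x condition", f, df1, df2, p))
        return pd.DataFrame(rows, columns=["effect", "F", "df_num", "df_den", "p"])

    def main_effect_f_tests(self) -> pd.DataFrame:
        """F tests for the main effects from the additive (no-interaction) refit.

        Reported alongside the full-model tests because main effects are
        conventionally judged without the interaction present.
        """
        if not self.model.interaction:
            return self.f_tests()
        additive = SRTMixedModel(
            self.model.data, interaction=False, baseline=self.model.baseline
        ).fit()
        return additive.f_tests()

    # -- LS-mean contrasts ----------------------------------------------------

    def pairwise_contrasts(self, alpha: float = 0.05) -> pd.DataFrame:
        """Pairwise LS-mean condition differences at the mean (centered) age.

        At clog_age = 0 the interaction terms vanish, so each contrast is a
        linear combination of the condition coefficients.  One-tailed
        probabilities are oriented toward the planned direction (the
        familiar-target condition better, i.e. lower, than the others;
        familiar-masker lower than baseline); Tukey-adjusted two-sided values
        use the studentized range with the within-subject df.
        """
        conds = self.model.conditions
        coef_of = {c: np.zeros(len(self.fe_params)) for c in conds}
        for c in conds[1:]:
            coef_of[c][self.names.index(f"condition[{c}]")] = 1.0
        pairs = []
        order = [c for c in ("familiar_target", "familiar_masker") if c in conds]
        order += [c for c in conds if c not in order]
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                pairs.append((order[i], order[j]))
        dfs = self._term_df()
        cond_idx = [i for i, n in enumerate(self.names) if n.startswith("condition[")]
        den_df = dfs[cond_idx[0]] if cond_idx else self.n_obs - len(self.fe_params)
        k = len(conds)
        rows = []
        for a, b in pairs:
            L = coef_of[a] - coef_of[b]
            est = float(L @ self.fe_params)
            se = float(np.sqrt(L @ self.cov_fe @ L))
            t = est / se
            # planned direction: first-listed condition has the lower SRT
            p_one = float(stats.t.cdf(t, den_df))
            p_two = float(2 * stats.t.sf(abs(t), den_df))
            q = abs(t) * np.sqrt(2.0)
            p_tukey = float(stats.studentized_range.sf(q, k, den_df))
            rows.append((f"{a} - {b}", est, se, den_df, t, p_one, p_two, p_tukey))
        return pd.DataFrame(
            rows,
            columns=["pair", "estimate", "se", "df", "t", "p_one_tailed", "p", "p_tukey"],
        )

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        ct = self.coef_table
        ft = self.f_tests()
        lines = [
            "Linear mixed model: srt_db ~ clog_age * condition + (1 | subject)  [REML]",
            f"  n obs = {self.n_obs}, n subjects = {self.n_subjects}, "
            f"baseline = {self.model.baseline}",
            f"  sigma_subject = {self.sigma_subject_hat:.3f} dB, "
            f"sigma_resid = {self.sigma_resid_hat:.3f} dB"
            + ("  [SINGULAR FIT]" if self.singular else ""),
            "",
            ct.to_string(index=False, float_format=lambda v: f"{v:9.4f}"),
            "",
            "F tests (full model):",
            ft.to_string(index=False, float_format=lambda v: f"{v:9.4f}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """SRT vs age on a log axis, one marker set per condition, with fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data
        la_mean = np.log10(df["age_years"]).mean()
        ages = np.linspace(df["age_years"].min(), df["age_years"].max(), 100)
        cla = np.log10(ages) - la_mean
        for cond in self.model.conditions:
            sub = df[df["condition"] == cond]
            ax.scatter(sub["age_years"], sub["srt_db"], label=cond, alpha=0.7)
            b = self.beta
            y = b["Intercept"] + b["clog_age"] * cla
            if cond != self.model.baseline:
                y = y + b[f"condition[{cond}]"]
                key = f"clog_age:condition[{cond}]"
                if key in b:
                    y = y + b[key] * cla
            ax.plot(ages, y, lw=1)
        ax.set_xscale("log")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("SRT (dB SNR)")
        ax.legend()
        return ax


def fit_lmm(subjects: pd.DataFrame, interaction: bool = True) -> SRTMixedResults:
    """Convenience wrapper: build and fit the mixed model from a subject table."""
    return SRTMixedModel(subjects, interaction=interaction).fit()
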