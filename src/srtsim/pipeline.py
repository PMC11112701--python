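"""End-to-end orchestration: generate -> measure -> fit -> analyze -> report.

One experiment run mirrors the human protocol per simulated child: a 16-trial
practice block (10 dB SNR start, excluded from analysis), then the three
familiarity conditions in a randomized block order, each condition measured
with two interleaved 20-trial staircases (7 dB SNR start).  The starting
target sentence list is randomized per child and sentences are consumed in
numerical list order without reuse, so practice and the three blocks never
repeat a sentence.  Keyword data per condition are pooled across the two
tracks and ML-fitted; subject-level SRTs then feed outlier screening, the
mixed model and the F0 analysis.

All randomness derives from one seed via ``numpy.random.SeedSequence``
spawning, so a run is fully deterministic given its seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import f0 as f0_mod
from .config import RunConfig
from .corpus import TARGET_LISTS, assign_trial_lists, corpus_to_frame, generate_corpus
from .listeners import CONDITIONS, ListenerModel, generate_cohort
from .psychometric import PsychometricModel, PsychometricResults
from .staircase import TrialRecord, records_to_frame, run_block, run_track

logger = logging.getLogger(__name__)


def measure_subject(
    listener: ListenerModel,
    corpus: dict,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], dict[str, PsychometricResults]]:
    """Run practice plus the three condition blocks for one listener.

    Returns all trial records (practice included, labelled ``practice``) and
    the per-condition psychometric fits (practice excluded).
    """
    order = list(CONDITIONS)
    rng.shuffle(order)
    start_list = int(rng.integers(1, len(TARGET_LISTS) + 1))
    n_practice = cfg.track_practice.n_trials if cfg.include_practice else 0
    n_test = cfg.track_lax.n_trials + cfg.track_strict.n_trials
    sentences = assign_trial_lists(corpus, start_list, n_practice + n_test * len(order))
    records: list[TrialRecord] = []
    pos = 0
    if cfg.include_practice:
        practice_cond = order[0]  # practice precedes testing; condition label only
        rec = run_track(
            listener,
            practice_cond,
            cfg.track_practice,
            sentences[pos : pos + n_practice],
            rng,
            track_label="practice",
        )
        records.extend(rec)
        pos += n_practice
    fits: dict[str, PsychometricResults] = {}
    for cond in order:
        block = run_block(
            listener,
            cond,
            cfg.track_lax,
            cfg.track_strict,
            sentences[pos : pos + n_test],
            rng,
            schedule=cfg.schedule,
        )
        records.extend(block)
        pos += n_test
        fits[cond] = PsychometricModel.from_records(block).fit()
        if not fits[cond].converged:
            logger.info("non-converged fit: %s / %s", listener.subject_id, cond)
    return records, fits


def simulate_cohort_measurements(
    cfg: RunConfig, seed: int | np.random.SeedSequence | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and measure every subject.

    Returns (trials, subjects, truth): trial-level records, the subject-level
    SRT table (one row per subject-condition, with fit diagnostics) and the
    generating truth table.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        cfg.seed if seed is None else seed
    )
    s_corpus, s_cohort, s_measure = ss.spawn(3)
    corpus = generate_corpus(
        np.random.default_rng(s_corpus),
        cfg.corpus.duration_mean_s,
        cfg.corpus.duration_sd_s,
        cfg.corpus.duration_min_s,
    )
    listeners = generate_cohort(cfg.cohort, np.random.default_rng(s_cohort))
    all_records: list[TrialRecord] = []
    subj_rows = []
    for listener, child_ss in zip(listeners, s_measure.spawn(len(listeners))):
        rng = np.random.default_rng(child_ss)
        records, fits = measure_subject(listener, corpus, cfg, rng)
        all_records.extend(records)
        for cond, fit in fits.items():
            subj_rows.append(
                (
                    listener.subject_id,
                    listener.age_years,
                    cond,
                    fit.srt_db,
                    fit.slope_db,
                    fit.r_squared,
                    fit.converged,
                    listener.true_srt_db[cond],
                )
            )
    subjects = pd.DataFrame(
        subj_rows,
        columns=[
            "subject_id",
            "age_years",
            "condition",
            "srt_db",
            "slope_db",
            "r_squared",
            "converged",
            "true_srt_db",
        ],
    )
    from .listeners import cohort_truth_frame

    return records_to_frame(all_records), subjects, cohort_truth_frame(listeners)


def analyze_subjects(subjects: pd.DataFrame, cfg: RunConfig) -> dict:
    """Outlier screening, descriptives, mixed model and contrasts."""
    flagged = cohort_mod.exclude_outliers(subjects, cfg.analysis.exclusion_sd_multiplier)
    summary = cohort_mod.condition_summary(flagged)
    res = cohort_mod.SRTMixedModel(flagged, interaction=cfg.analysis.interaction).fit()
    contrasts = res.pairwise_contrasts(alpha=cfg.analysis.alpha)
    return {
        "subjects": flagged,
        "condition_summary": summary,
        "lmm": res,
        "coefficients": res.coef_table,
        "f_tests": res.f_tests(),
        "main_effect_f_tests": res.main_effect_f_tests(),
        "contrasts": contrasts,
    }


def run_f0_analysis(
    subjects: pd.DataFrame, seed: int | np.random.SeedSequence
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw talker F0s for the cohort and run the semitone analysis."""
    rng = np.random.default_rng(seed)
    ids = sorted(subjects["subject_id"].unique())
    n = len(ids)
    mother = f0_mod.draw_mother_f0s(n, rng)
    u1 = f0_mod.draw_mother_f0s(n, rng)
    u2 = f0_mod.draw_mother_f0s(n, rng)
    pairings = f0_mod.build_pairings(ids, mother, u1, u2)
    corr = f0_mod.condition_partial_correlations(subjects, pairings)
    return pairings, corr


def run_experiment(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Full pipeline writing a results directory; deterministic given cfg.seed."""
    out = Path(out_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    s_main, s_f0 = ss.spawn(2)
    trials, subjects, truth = simulate_cohort_measurements(cfg, s_main)
    analysis = analyze_subjects(subjects, cfg)
    pairings, f0_corr = run_f0_analysis(analysis["subjects"], s_f0)

    trials.to_csv(out / "trials.csv", index=False)
    analysis["subjects"].to_csv(out / "subjects.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    pairings.to_csv(out / "f0_pairings.csv", index=False)
    res_dir = out / "results"
    analysis["coefficients"].to_csv(res_dir / "coefficients.csv", index=False)
    analysis["contrasts"].to_csv(res_dir / "contrasts.csv", index=False)
    analysis["condition_summary"].to_csv(res_dir / "condition_summary.csv", index=False)
    analysis["f_tests"].to_csv(res_dir / "f_tests.csv", index=False)
    f0_corr.to_csv(res_dir / "f0_correlations.csv", index=False)

    lmm = analysis["lmm"]
    summary = {
        "seed": cfg.seed,
        "n_subjects": int(subjects["subject_id"].nunique()),
        "n_excluded": int(
            analysis["subjects"].loc[analysis["subjects"]["excluded"], "subject_id"].nunique()
        ),
        "sigma_subject_hat": lmm.sigma_subject_hat,
        "sigma_resid_hat": lmm.sigma_resid_hat,
        "singular": bool(lmm.singular),
        "condition_means": {
            row.condition: row.mean_srt_db
            for row in analysis["condition_summary"].itertuples(index=False)
        },
    }
    with open(res_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("experiment written to %s", out)
    return out


# ---------------------------------------------------------------------------
# Parameter-recovery replicates


def run_replicates(
    cfg: RunConfig, n_replicates: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Repeat cohort generation + measurement + analysis; one row per replicate.

    Each replicate draws a fresh cohort, runs the full adaptive measurement
    and psychometric fitting, applies outlier screening, and fits the mixed
    model; the recovered fixed effects and the per-condition measured means
    are collected.  Replicates where the mixed model cannot be fitted are
    recorded with NaNs (and counted), not silently dropped.
    """
    n_rep = n_replicates if n_replicates is not None else cfg.n_replicates
    base = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rows = []
    for rep, child in enumerate(base.spawn(n_rep)):
        trials, subjects, _ = simulate_cohort_measurements(cfg, child)
        try:
            analysis = analyze_subjects(subjects, cfg)
        except (ValueError, RuntimeError) as err:
            logger.warning("replicate %d analysis failed: %s", rep, err)
            rows.append({"replicate": rep, "failed": True})
            continue
        lmm = analysis["lmm"]
        beta = lmm.beta
        included = analysis["subjects"]
        included = included[~included["excluded"]]
        row = {
            "replicate": rep,
            "failed": False,
            "n_included": int(included["subject_id"].nunique()),
            "intercept": beta.get("Intercept", np.nan),
            "beta_age": beta.get("clog_age", np.nan),
            "beta_fam_target": beta.get("condition[familiar_target]", np.nan),
            "beta_fam_masker": beta.get("condition[familiar_masker]", np.nan),
            "sigma_subject_hat": lmm.sigma_subject_hat,
            "sigma_resid_hat": lmm.sigma_resid_hat,
        }
        for cond in CONDITIONS:
            sub = included[included["condition"] == cond]["srt_db"]
            row[f"mean_srt[{cond}]"] = float(sub.mean())
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(replicates: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Truth vs mean recovered estimate across replicates, with MC error."""
    ok = replicates[~replicates["failed"].astype(bool)]
    truth = {
        "intercept": cfg.cohort.beta0,
        "beta_age": cfg.cohort.beta_age,
        "beta_fam_target": cfg.cohort.beta_fam_target,
        "beta_fam_masker": cfg.cohort.beta_fam_masker,
        "mean_srt[familiar_target]": cfg.cohort.beta0 + cfg.cohort.beta_fam_target,
        "mean_srt[familiar_masker]": cfg.cohort.beta0 + cfg.cohort.beta_fam_masker,
        "mean_srt[unfamiliar]": cfg.cohort.beta0,
    }
    rows = []
    for name, true_val in truth.items():
        est = ok[name].dropna()
        rows.append(
            (
                name,
                true_val,
                float(est.mean()),
                float(est.std(ddof=1)),
                float(est.std(ddof=1) / np.sqrt(len(est))) if len(est) > 1 else np.nan,
                len(est),
            )
        )
    return pd.DataFrame(
        rows, columns=["quantity", "truth", "mean_estimate", "sd", "mc_se", "n_replicates"]
    )


# ---------------------------------------------------------------------------
# Reporting


def report(results_dir: str | Path) -> str:
    """Human-readable summary of an experiment results directory."""
    res = Path(results_dir)
    if res.name != "results" and (res / "results").is_dir():
        res = res / "results"
    coef_path = res / "coefficients.csv"
    if not coef_path.exists():
        raise FileNotFoundError(f"no coefficients.csv under {res}")
    coef = pd.read_csv(coef_path)
    lines = ["Fixed-effect estimates (srt_db ~ clog_age * condition + (1|subject)):", ""]
    lines.append(coef.to_string(index=False, float_format=lambda v: f"{v:9.4f}"))
    summ_path = res / "condition_summary.csv"
    if summ_path.exists():
        summ = pd.read_csv(summ_path)
        lines += ["", "Condition means:", summ.to_string(index=False, float_format=lambda v: f"{v:8.3f}")]
    contr_path = res / "contrasts.csv"
    if contr_path.exists():
        contr = pd.read_csv(contr_path)
        lines += ["", "Pairwise LS-mean contrasts:", contr.to_string(index=False, float_format=lambda v: f"{v:8.4f}")]
    js = res / "summary.json"
    if js.exists():
        with open(js) as fh:
            meta = json.load(fh)
        lines += [
            "",
            f"seed = {meta['seed']}, subjects = {meta['n_subjects']} "
            f"({meta['n_excluded']} excluded), "
            f"sigma_subject = {meta['sigma_subject_hat']:.2f}, "
            f"sigma_resid = {meta['sigma_resid_hat']:.2f}",
        ]
    return "\n".join(lines)
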