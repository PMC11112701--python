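"""Simulated child listeners and cohort generation.

A listener is a word-level logistic psychometric function per familiarity
condition: the probability that a single keyword is reported correctly at
signal-to-noise ratio ``snr`` is

    p(snr) = 1 / (1 + exp(-(snr - srt) / slope))

with asymptotes at 0 and 100% (no guess or lapse rate), so the word-level
speech reception threshold (SRT) is exactly the 50% point ``srt``.

The cohort generator produces per-subject, per-condition true SRTs from a
linear mixed-effects structure on centered log10 age::

    srt(i, c) = beta0 + beta_age * (log10(age_i) - mean log10 age)
                + beta_c + b_i + eps_ic

with subject random intercepts b_i ~ N(0, sigma_subject^2) and
condition-level residuals eps_ic ~ N(0, sigma_resid^2).  The default fixed
effects are the fitted values from the child speech-in-speech familiarity
study this package emulates: intercept -2.75 dB (baseline
unfamiliar-target/unfamiliar-masker), age slope -16.21 dB per log10(year),
familiar-target effect -3.36 dB, familiar-masker effect -0.20 dB.

Default variance components sigma_subject = 3.4, sigma_resid = 2.2 dB are
chosen so the marginal per-condition SD of SRTs matches the reported 4.1 dB:
with ages uniform on [8.5, 13.1],

    var(srt) = sigma_subject^2 + sigma_resid^2 + beta_age^2 * var(clog age)
             = 3.4^2 + 2.2^2 + 16.21^2 * 0.00294  ~  4.14^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import norm

#: Familiarity conditions. "unfamiliar" (unfamiliar target / unfamiliar
#: masker) is the referent; the other two name which stream is the mother's.
CONDITIONS = ("familiar_target", "familiar_masker", "unfamiliar")
BASELINE_CONDITION = "unfamiliar"


@dataclass
class ListenerModel:
    """A simulated child: per-condition word-level psychometric functions."""

    subject_id: str
    age_years: float
    true_srt_db: dict[str, float]
    slope_db: float = 2.0
    keyword_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_db <= 0:
            raise ValueError("slope_db must be positive")
        if not 0.0 <= self.keyword_rho < 1.0:
            raise ValueError("keyword_rho must be in [0, 1)")

    def p_keyword(self, condition: str, snr_db: float) -> float:
        """Probability of reporting one keyword correctly at this SNR."""
        if condition not in self.true_srt_db:
            raise KeyError(f"unknown condition {condition!r}")
        return float(expit((snr_db - self.true_srt_db[condition]) / self.slope_db))

    def respond_sentence(
        self,
        condition: str,
        snr_db: float,
        n_keywords: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Keyword outcome vector for one sentence presentation.

        Keywords are conditionally independent given the SNR when
        ``keyword_rho`` is 0; otherwise an exchangeable Gaussian copula with
        correlation ``keyword_rho`` induces within-sentence dependence while
        preserving the marginal probability ``p_keyword``.
        """
        if n_keywords not in (3, 4):
            raise ValueError(f"n_keywords must be 3 or 4, got {n_keywords}")
        p = self.p_keyword(condition, snr_db)
        if self.keyword_rho == 0.0:
            return rng.random(n_keywords) < p
        shared = rng.standard_normal()
        own = rng.standard_normal(n_keywords)
        z = np.sqrt(self.keyword_rho) * shared + np.sqrt(1.0 - self.keyword_rho) * own
        # correct iff the latent uniform falls below p
        return ndtr(z) < p


@dataclass
class CohortConfig:
    """Generative parameters for a simulated cohort (dB throughout)."""

    n_subjects: int = 22
    age_range_years: tuple[float, float] = (8.5, 13.1)
    beta0: float = -2.75
    beta_age: float = -16.21
    beta_fam_target: float = -3.36
    beta_fam_masker: float = -0.20
    sigma_subject: float = 3.4
    sigma_resid: float = 2.2
    slope_db: float = 2.0
    keyword_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        lo, hi = self.age_range_years
        if not hi > lo > 0:
            raise ValueError("age range must be non-degenerate and positive")
        if self.sigma_subject < 0 or self.sigma_resid < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def condition_effects(self) -> dict[str, float]:
        return {
            "familiar_target": self.beta_fam_target,
            "familiar_masker": self.beta_fam_masker,
            BASELINE_CONDITION: 0.0,
        }


def generate_cohort(cfg: CohortConfig, rng: np.random.Generator | int) -> list[ListenerModel]:
    """Draw a cohort of simulated listeners.

    Ages are uniform on the configured range; log10 age is centered at the
    generated cohort's own sample mean, matching how the analysis model
    centers age.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = cfg.age_range_years
    ages = rng.uniform(lo, hi, size=cfg.n_subjects)
    clog_age = np.log10(ages) - np.log10(ages).mean()
    b = rng.normal(0.0, cfg.sigma_subject, size=cfg.n_subjects)
    listeners = []
    for i in range(cfg.n_subjects):
        srts = {}
        for cond in CONDITIONS:
            eps = rng.normal(0.0, cfg.sigma_resid)
            srts[cond] = float(
                cfg.beta0
                + cfg.beta_age * clog_age[i]
                + cfg.condition_effects[cond]
                + b[i]
                + eps
            )
        listeners.append(
            ListenerModel(
                subject_id=f"S{i + 1:03d}",
                age_years=float(ages[i]),
                true_srt_db=srts,
                slope_db=cfg.slope_db,
                keyword_rho=cfg.keyword_rho,
            )
        )
    return listeners


def cohort_truth_frame(listeners: list[ListenerModel]) -> pd.DataFrame:
    """Long-format table of true SRTs: subject_id, age_years, condition, true_srt_db."""
    rows = [
        (lst.subject_id, lst.age_years, cond, lst.true_srt_db[cond])
        for lst in listeners
        for cond in CONDITIONS
    ]
    return pd.DataFrame(rows, columns=["subject_id", "age_years", "condition", "true_srt_db"])
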