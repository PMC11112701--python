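"""Exploratory F0 (fundamental-frequency) analysis.

Talker F0 separation is expressed in semitones, 12 * log2(f0_a / f0_b); the
analysis asks whether target/masker F0 separation relates to measured SRTs
once age is controlled for (children benefit from F0 differences mainly when
they exceed about three semitones).

Per-subject mother F0s are unavailable for the original talkers, so the
synthetic generator draws them from a truncated normal calibrated so that
separations beyond three semitones are rare among adult female voices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class F0Pairing:
    """Target/masker talker F0s for one subject-condition."""

    subject_id: str
    condition: str
    target_f0_hz: float
    masker_f0_hz: float

    @property
    def semitone_diff(self) -> float:
        return semitone_diff(self.target_f0_hz, self.masker_f0_hz)

    @property
    def abs_semitones(self) -> float:
        return abs(self.semitone_diff)


def semitone_diff(f0_a: float, f0_b: float) -> float:
    """Signed F0 difference in semitones: 12 * log2(f0_a / f0_b)."""
    if f0_a <= 0 or f0_b <= 0:
        raise ValueError("F0 values must be positive")
    return float(12.0 * np.log2(f0_a / f0_b))


def count_large_separations(
    pairings: Iterable[F0Pairing] | Sequence[float], threshold: float = 3.0
) -> int:
    """Count pairings whose absolute semitone separation exceeds ``threshold``."""
    vals = [
        p.abs_semitones if isinstance(p, F0Pairing) else abs(float(p)) for p in pairings
    ]
    if not vals:
        raise ValueError("no pairings given")
    return int(sum(v > threshold for v in vals))


def age_partial_correlation(
    srt_db: Sequence[float],
    abs_semitones: Sequence[float],
    age_years: Sequence[float],
) -> tuple[float, float]:
    """Partial correlation of SRT and F0 separation, controlling for age.

    Both variables are residualised on centered log10(age) by ordinary least
    squares (the same age scale the mixed model uses); the statistic is the
    Pearson correlation of the residuals with a two-tailed t probability on
    n - 3 degrees of freedom.

    Returns ``(nan, nan)`` when either residual has (numerically) zero
    variance, e.g. when a variable is collinear with age.
    """
    y1 = np.asarray(srt_db, dtype=float)
    y2 = np.asarray(abs_semitones, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if not (len(y1) == len(y2) == len(age)):
        raise ValueError("inputs must have equal length")
    if len(y1) < 5:
        raise ValueError("need at least 5 complete triples")
    x = np.log10(age)
    x = x - x.mean()
    X = np.column_stack([np.ones_like(x), x])

    def _resid(y: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ coef

    r1, r2 = _resid(y1), _resid(y2)
    s1, s2 = np.sqrt(np.sum(r1**2)), np.sqrt(np.sum(r2**2))
    scale = max(np.sqrt(np.sum(y1**2)), 1.0) * max(np.sqrt(np.sum(y2**2)), 1.0)
    if s1 <= 1e-12 * scale or s2 <= 1e-12 * scale:
        return float("nan"), float("nan")
    r = float(np.sum(r1 * r2) / (s1 * s2))
    df = len(y1) - 3
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def draw_mother_f0s(
    n: int,
    rng: np.random.Generator | int,
    mean_hz: float = 200.0,
    sd_hz: float = 15.0,
    lo_hz: float = 160.0,
    hi_hz: float = 250.0,
) -> np.ndarray:
    """Mean F0s for adult female talkers, truncated normal on [lo, hi] Hz."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a, b = (lo_hz - mean_hz) / sd_hz, (hi_hz - mean_hz) / sd_hz
    return stats.truncnorm.rvs(a, b, loc=mean_hz, scale=sd_hz, size=n, random_state=rng)


def build_pairings(
    subject_ids: Sequence[str],
    mother_f0_hz: Sequence[float],
    unfamiliar1_f0_hz: Sequence[float],
    unfamiliar2_f0_hz: Sequence[float],
) -> pd.DataFrame:
    """Assemble per-condition target/masker F0 pairings for each subject.

    Talker roles per condition: familiar_target pairs the mother (target)
    with unfamiliar talker 1 (masker); familiar_masker pairs unfamiliar
    talker 2 (target) with the mother (masker); the unfamiliar baseline pairs
    unfamiliar talker 1 (target) with unfamiliar talker 2 (masker).
    """
    rows = []
    for sid, m, u1, u2 in zip(subject_ids, mother_f0_hz, unfamiliar1_f0_hz, unfamiliar2_f0_hz):
        for cond, tgt, msk in (
            ("familiar_target", m, u1),
            ("familiar_masker", u2, m),
            ("unfamiliar", u1, u2),
        ):
            d = semitone_diff(tgt, msk)
            rows.append((sid, cond, tgt, msk, d, abs(d)))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "target_f0_hz",
            "masker_f0_hz",
            "semitone_diff",
            "abs_semitones",
        ],
    )


def condition_partial_correlations(
    subjects: pd.DataFrame, pairings: pd.DataFrame
) -> pd.DataFrame:
    """Age-controlled SRT vs F0-separation correlation, per condition.

    ``subjects`` needs subject_id, condition, srt_db, age_years (rows flagged
    ``excluded`` are dropped); ``pairings`` as from :func:`build_pairings`.
    """
    df = subjects
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    merged = df.merge(pairings, on=["subject_id", "condition"])
    rows = []
    for cond, sub in merged.groupby("condition"):
        sub = sub.dropna(subset=["srt_db"])
        if len(sub) < 5:
            rows.append((cond, float("nan"), float("nan"), len(sub)))
            continue
        r, p = age_partial_correlation(
            sub["srt_db"].to_numpy(), sub["abs_semitones"].to_numpy(), sub["age_years"].to_numpy()
        )
        rows.append((cond, r, p, len(sub)))
    return pd.DataFrame(rows, columns=["condition", "r", "p", "n"])
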